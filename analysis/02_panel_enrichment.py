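"""Capture/scramble miRNome panel enrichment analysis.

Simulates a 752-miRNA panel experiment (3 capture + 3 scramble
replicates, 25 spiked miRNAs with a 3-cycle capture shift), runs the
full processing chain — inter-plate calibration, Ct-40 imputation, 66%
detection filter, global-mean normalization, ΔΔCt and Welch test — and
reports the counts at each stage plus the top enriched miRNAs.
"""

import argparse
from pathlib import Path

from mirbayes import PanelSpec, default_enriched_set, enrichment_pipeline, simulate_panels


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-spiked", type=int, default=25)
    ap.add_argument("--shift", type=float, default=3.0)
    ap.add_argument("--outdir", default="results/panel")
    args = ap.parse_args()

    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PanelSpec(seed=args.seed)
    spec.enriched_set = default_enriched_set(
        spec, n_spiked=args.n_spiked, shift=args.shift, seed=args.seed
    )
    capture, scramble = simulate_panels(spec)
    summary = enrichment_pipeline(capture, scramble)
    summary.results.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    print(f"panel of {summary.n_input_mirnas} miRNAs (seed {args.seed})")
    print(f"measurable after 66% detection filter: {summary.n_measurable}")
    print(f"called enriched (fold change > 1, Welch p <= 0.05): {summary.n_enriched}")
    spiked_called = summary.results.set_index("mirna_id").reindex(
        list(spec.enriched_set)
    )["enriched"]
    print(f"spiked miRNAs recovered: {int(spiked_called.sum())}/{len(spec.enriched_set)}")
    top = summary.results.head(5)[["mirna_id", "fold_change", "p_value"]]
    print("top enriched:")
    print(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
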