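"""End-to-end orchestration: configuration, stage sequencing, run reports.

The pipeline mirrors the analysis flow of a capture-panel biomarker
study: simulate (or load) data -> panel enrichment -> plasma QC and
group statistics -> single-marker ROC -> combined-score classifier.
Every numeric result in the report carries the stage, the parameters
and the seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import grid_search_combination, roc_curve
from .enrichment import enrichment_pipeline
from .plasma import HEMOLYSIS_THRESHOLD, compare_groups, hemolysis_qc, normalize_expression
from .simulate import (
    PLASMA_MARKERS,
    REFERENCE_MIRNA,
    CohortSpec,
    PanelSpec,
    default_enriched_set,
    simulate_cohort,
    simulate_panels,
)
from .tables import CtTable, SampleMeta

ALL_STAGES = ("simulate", "panel", "plasma", "classify")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    ct_values: str | None = None  # load instead of simulating
    metadata: str | None = None
    alpha: float = 0.05
    detection_fraction: float = 0.66
    ct_ceiling: float = 40.0
    hemolysis_threshold: float = HEMOLYSIS_THRESHOLD
    markers: tuple[str, ...] = PLASMA_MARKERS
    reference: str = REFERENCE_MIRNA
    contrast: tuple[str, str] = ("HC", "AD")
    grid_range: tuple[float, float] = (-50.0, 50.0)
    grid_step: float = 0.1
    priors: str = "empirical"
    n_spiked: int = 25
    spike_shift: float = 3.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("ct_values", "metadata"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.detection_fraction <= 1:
            raise ValueError("detection_fraction must be in (0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.priors not in ("empirical", "equal"):
            raise ValueError("priors must be 'empirical' or 'equal'")

    # round-trippable serialization
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def summarize_population(meta: SampleMeta) -> pd.DataFrame:
    """Demographic table: n, sex split, onset/age/MMSE mean +- SD per group.

    FTD subtype rows (bvFTD/svFTD) are reported as subsets of the FTD row
    when subtypes are present. Undefined statistics (n < 2, or a
    covariate the group lacks) come out as NaN.
    """
    df = meta.data
    if df.empty:
        return pd.DataFrame(
            columns=["group", "n", "males", "females", "onset_mean", "onset_sd",
                     "age_mean", "age_sd", "mmse_mean", "mmse_sd"]
        )
    blocks = [(g, sub) for g, sub in df.groupby("group", sort=False)]
    for sub_name, sub_df in df[df["subtype"] != ""].groupby("subtype", sort=False):
        blocks.append((sub_name, sub_df))
    rows = []
    for name, sub in blocks:
        row = {
            "group": name,
            "n": len(sub),
            "males": int((sub["sex"] == "M").sum()),
            "females": int((sub["sex"] == "F").sum()),
        }
        for cov in ("onset", "age", "mmse"):
            vals = sub[cov].dropna()
            row[f"{cov}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{cov}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write per-stage TSV/JSON outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    table = meta = None
    if config.ct_values is not None:
        table = CtTable.from_csv(config.ct_values)
    if config.metadata is not None:
        meta = SampleMeta.from_csv(config.metadata)

    for stage in config.stages:
        try:
            if stage == "simulate":
                if table is None:
                    table, meta = simulate_cohort(CohortSpec(seed=config.seed))
                    table.to_csv(outdir / "ct_values.csv")
                    meta.to_csv(outdir / "metadata.csv")
                report["stages"]["simulate"] = {
                    "n_subjects": len(table.samples),
                    "seed": config.seed,
                }
            elif stage == "panel":
                pspec = PanelSpec(seed=config.seed)
                pspec.enriched_set = default_enriched_set(
                    pspec, n_spiked=config.n_spiked,
                    shift=config.spike_shift, seed=config.seed,
                )
                capture, scramble = simulate_panels(pspec)
                summary = enrichment_pipeline(
                    capture, scramble, alpha=config.alpha,
                    ceiling=config.ct_ceiling,
                    min_detected_fraction=config.detection_fraction,
                )
                summary.results.to_csv(
                    outdir / "enrichment.tsv", sep="\t", index=False
                )
                report["stages"]["panel"] = {
                    "n_input_mirnas": summary.n_input_mirnas,
                    "n_measurable": summary.n_measurable,
                    "n_enriched": summary.n_enriched,
                    "alpha": config.alpha,
                    "seed": config.seed,
                }
            elif stage == "plasma":
                if table is None or meta is None:
                    raise RuntimeError("plasma stage needs cohort data")
                qc = hemolysis_qc(table, threshold=config.hemolysis_threshold)
                records = normalize_expression(
                    table, reference=config.reference, qc=qc
                )
                stats_df = compare_groups(
                    records, meta, tuple(meta.data["group"].unique()),
                    mirnas=list(config.markers), stratify_by_sex=True,
                )
                records.to_csv(outdir / "expression.tsv", sep="\t", index=False)
                stats_df.to_csv(outdir / "group_stats.tsv", sep="\t", index=False)
                summarize_population(meta).to_csv(
                    outdir / "population.tsv", sep="\t", index=False
                )
                qc_report = {
                    "threshold": config.hemolysis_threshold,
                    "n_samples": int(len(qc)),
                    "n_fail": int((~qc["qc_pass"]).sum()),
                }
                (outdir / "qc_report.json").write_text(json.dumps(qc_report))
                report["stages"]["plasma"] = qc_report
                report["_records"] = records
            elif stage == "classify":
                if table is None or meta is None:
                    raise RuntimeError("classify stage needs cohort data")
                records = report.pop("_records", None)
                if records is None:
                    qc = hemolysis_qc(table, threshold=config.hemolysis_threshold)
                    records = normalize_expression(
                        table, reference=config.reference, qc=qc
                    )
                g0, g1 = config.contrast
                groups = meta.groups()
                dct = records.pivot(
                    index="sample_id", columns="mirna_id", values="delta_ct"
                )[list(config.markers)].dropna()
                keep = dct.index[groups.loc[dct.index].isin([g0, g1])]
                dct = dct.loc[keep]
                labels = groups.loc[keep].to_numpy()

                rocs = {}
                for marker in config.markers:
                    r = roc_curve(dct[marker].to_numpy(), labels, g1)
                    rocs[marker] = {
                        "auc": r.auc,
                        "auc_p_value": r.auc_p_value,
                        "best_accuracy": r.best_accuracy,
                        "best_accuracy_se": r.best_accuracy_se,
                        "sensitivity": r.sensitivity,
                    }
                combo = grid_search_combination(
                    dct.to_numpy(), labels, positive_class=g1,
                    coeff_range=config.grid_range, step=config.grid_step,
                    priors=config.priors,
                )
                combo_out = {
                    "contrast": [g0, g1],
                    "a": combo.a,
                    "b": combo.b,
                    "accuracy": combo.accuracy,
                    "accuracy_se": combo.accuracy_se,
                    "thresholds": combo.thresholds,
                    "sensitivity": combo.sensitivity,
                    "shapiro": {
                        k: {"W": w, "p": p} for k, (w, p) in combo.shapiro.items()
                    },
                    "priors": combo.priors,
                    "seed": config.seed,
                }
                (outdir / "combination.json").write_text(
                    json.dumps(combo_out, indent=2)
                )
                report["stages"]["classify"] = {
                    "roc": rocs, "combination": combo_out,
                }
        except Exception as exc:  # annotate failures with their stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report.pop("_records", None)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
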