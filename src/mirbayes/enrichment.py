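"""Capture/scramble miRNome panel processing.

The processing chain turns raw plate-level Ct values into per-miRNA
enrichment calls:

1. inter-plate calibration on the IPC (UniSp3) spike-in wells,
2. imputation of undetected wells at the Ct ceiling (40 cycles),
3. detection filter keeping miRNAs detected in >= 66% of wells,
4. global-mean normalization (ΔCt against the per-sample mean Ct),
5. ΔΔCt between capture and scramble arms, fold change 2^-ΔΔCt, and a
   per-miRNA Welch t-test on replicate ΔCt values.

A miRNA is called enriched when fold change exceeds 1 and the test is
significant at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CtTable

CT_CEILING = 40.0
DETECTION_FRACTION = 0.66


def calibrate_interplate(table: CtTable) -> CtTable:
    """Align Ct scales across plates using the IPC spike-in wells.

    Each plate's calibration factor is (grand mean of per-plate IPC
    means) minus (this plate's IPC mean); the factor is added to every
    detected Ct on the plate, so IPC means agree across plates afterwards.
    """
    df = table.data
    ipc = df[(df["mirna_id"] == table.ipc_id) & df["detected"]]
    plate_means = ipc.groupby("plate_id")["ct"].mean()
    missing = set(df["plate_id"].unique()) - set(plate_means.index)
    if missing:
        raise ValueError(f"plates lacking a detected IPC well: {sorted(missing)}")
    factors = plate_means.mean() - plate_means
    out = df.copy()
    shift = out["plate_id"].map(factors).to_numpy()
    detected = out["detected"].to_numpy(dtype=bool)
    out.loc[detected, "ct"] = out.loc[detected, "ct"] + shift[detected]
    return CtTable(out, ipc_id=table.ipc_id)


def impute_undetected(table: CtTable, ceiling: float = CT_CEILING) -> CtTable:
    """Replace undetected wells with the Ct ceiling, flagging them imputed."""
    out = table.data.copy()
    undet = ~out["detected"].to_numpy(dtype=bool)
    out.loc[undet, "ct"] = ceiling
    out.loc[undet, "imputed"] = True
    return CtTable(out, ipc_id=table.ipc_id)


def filter_detected(
    table: CtTable,
    min_detected_fraction: float = DETECTION_FRACTION,
    per_sample: bool = False,
) -> CtTable:
    """Keep assays with enough genuinely detected wells.

    Default mode drops miRNAs whose originally-detected fraction across
    all samples falls below ``min_detected_fraction`` (IPC wells are
    never filtered). ``per_sample=True`` instead drops samples whose
    detected fraction across assays is below the threshold.
    """
    df = table.data
    body = df[df["mirna_id"] != table.ipc_id]
    if body.empty:
        raise ValueError("empty Ct table")
    if per_sample:
        frac = body.groupby("sample_id")["detected"].mean()
        keep = frac[frac >= min_detected_fraction].index
        out = df[df["sample_id"].isin(keep)]
    else:
        frac = body.groupby("mirna_id")["detected"].mean()
        keep = frac[frac >= min_detected_fraction].index
        out = df[(df["mirna_id"].isin(keep)) | (df["mirna_id"] == table.ipc_id)]
    return CtTable(out.reset_index(drop=True), ipc_id=table.ipc_id)


def global_mean_normalize(table: CtTable) -> pd.DataFrame:
    """Per-sample ΔCt against the sample's global mean Ct.

    Returns a sample x miRNA ΔCt matrix; each row has mean zero. IPC
    wells are excluded from both the mean and the output.
    """
    wide = table.wide("ct")
    if wide.isna().any().any():
        missing = wide.isna().sum().sum()
        raise ValueError(
            f"{missing} missing Ct values; impute undetected wells first"
        )
    if (wide.count(axis=1) == 0).any():
        raise ValueError("sample with no Ct values")
    return wide.sub(wide.mean(axis=1), axis=0)


@dataclass
class EnrichmentSummary:
    """Counts at each stage of the panel chain, for run reports."""

    n_input_mirnas: int
    n_measurable: int
    n_enriched: int
    results: pd.DataFrame = field(repr=False)


def call_enrichment(
    capture_dct: pd.DataFrame,
    scramble_dct: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-miRNA ΔΔCt, fold change and Welch test between the two arms.

    ΔΔCt = mean ΔCt(capture) - mean ΔCt(scramble); fold change =
    2^-ΔΔCt. Enrichment requires fold change > 1 and p <= alpha
    (Benjamini-Hochberg adjusted when ``fdr`` is set). Rows are sorted
    by fold change, descending. Zero-variance degenerate contrasts get
    p = 1 (equal means) or p = 0 with a warning flag (unequal means).
    """
    shared = capture_dct.columns.intersection(scramble_dct.columns)
    if len(shared) == 0:
        raise ValueError("no shared miRNAs between capture and scramble arms")
    if len(capture_dct) < 2 or len(scramble_dct) < 2:
        raise ValueError("need >= 2 replicates per arm for the t-test")
    cap = capture_dct[shared].to_numpy(dtype=float)
    scr = scramble_dct[shared].to_numpy(dtype=float)

    cap_mean = cap.mean(axis=0)
    scr_mean = scr.mean(axis=0)
    ddct = cap_mean - scr_mean
    fold = np.exp2(-ddct)

    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(cap, scr, axis=0, equal_var=False)
    pvals = np.asarray(t_res.pvalue, dtype=float)
    degenerate = (cap.var(axis=0) == 0.0) & (scr.var(axis=0) == 0.0)
    warn = np.zeros(len(shared), dtype=bool)
    equal = np.isclose(cap_mean, scr_mean)
    pvals = np.where(degenerate & equal, 1.0, pvals)
    pvals = np.where(degenerate & ~equal, 0.0, pvals)
    warn |= degenerate & ~equal

    p_used = pvals
    if fdr:
        p_used = multipletests(pvals, method="fdr_bh")[1]
    enriched = (p_used <= alpha) & (fold > 1.0)

    out = pd.DataFrame(
        {
            "mirna_id": shared,
            "delta_ct_capture_mean": cap_mean,
            "delta_ct_scramble_mean": scr_mean,
            "ddct": ddct,
            "fold_change": fold,
            "p_value": pvals,
            "p_adjusted": p_used,
            "enriched": enriched,
            "zero_variance_warning": warn,
        }
    )
    return out.sort_values(
        "fold_change", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def enrichment_pipeline(
    capture: CtTable,
    scramble: CtTable,
    alpha: float = 0.05,
    ceiling: float = CT_CEILING,
    min_detected_fraction: float = DETECTION_FRACTION,
    calibrate: bool = True,
    fdr: bool = False,
) -> EnrichmentSummary:
    """Run the full panel chain on a capture/scramble table pair."""
    n_input = len(capture.mirnas.union(scramble.mirnas))
    merged = CtTable(
        pd.concat([capture.data, scramble.data], ignore_index=True),
        ipc_id=capture.ipc_id,
    )
    if calibrate:
        merged = calibrate_interplate(merged)
    merged = impute_undetected(merged, ceiling=ceiling)
    merged = filter_detected(merged, min_detected_fraction=min_detected_fraction)
    dct = global_mean_normalize(merged)
    roles = merged.roles()
    cap_dct = dct.loc[roles[roles == "capture"].index]
    scr_dct = dct.loc[roles[roles == "scramble"].index]
    results = call_enrichment(cap_dct, scr_dct, alpha=alpha, fdr=fdr)
    return EnrichmentSummary(
        n_input_mirnas=n_input,
        n_measurable=dct.shape[1],
        n_enriched=int(results["enriched"].sum()),
        results=results,
    )
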