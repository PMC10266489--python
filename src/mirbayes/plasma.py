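"""Plasma miRNA quantification: hemolysis QC, ΔCt normalization, group stats.

Expression of a plasma marker is reported as 2^-ΔCt with ΔCt =
Ct(target) - Ct(endogenous control); lower ΔCt means higher expression.
Red-blood-cell contamination is screened by contrasting miR-23a-3p
(insensitive to hemolysis) with miR-451a (RBC-enriched): a large
Ct(miR-23a-3p) - Ct(miR-451a) gap indicates hemolysis.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import HEMOLYSIS_RBC, HEMOLYSIS_STABLE, REFERENCE_MIRNA
from .tables import CtTable, SampleMeta

#: Conventional cutoff, in cycles, on the miR-23a-3p - miR-451a Ct gap.
HEMOLYSIS_THRESHOLD = 7.0


def hemolysis_qc(
    table: CtTable,
    threshold: float = HEMOLYSIS_THRESHOLD,
    stable_id: str = HEMOLYSIS_STABLE,
    rbc_id: str = HEMOLYSIS_RBC,
) -> pd.DataFrame:
    """Flag hemolysed samples from the indicator miRNA pair.

    A sample fails when Ct(stable) - Ct(RBC marker) >= threshold (the
    boundary value fails). Samples missing either indicator are flagged
    ``unevaluable`` and fail conservatively.
    """
    wide = table.wide("ct")
    out = pd.DataFrame(index=wide.index)
    have = [c for c in (stable_id, rbc_id) if c in wide.columns]
    if len(have) < 2:
        out["delta"] = np.nan
        out["qc_pass"] = False
        out["status"] = "unevaluable"
        return out
    delta = wide[stable_id] - wide[rbc_id]
    out["delta"] = delta
    out["qc_pass"] = delta < threshold
    out["status"] = np.where(
        delta.isna(), "unevaluable", np.where(delta < threshold, "pass", "fail")
    )
    out.loc[delta.isna(), "qc_pass"] = False
    return out


def normalize_expression(
    table: CtTable,
    reference: str = REFERENCE_MIRNA,
    qc: pd.DataFrame | None = None,
    exclude_qc_fail: bool = True,
) -> pd.DataFrame:
    """Per-sample ΔCt against the endogenous control and 2^-ΔCt expression.

    Returns a long DataFrame (sample_id, mirna_id, delta_ct, expression,
    qc_pass). Samples lacking the reference assay are dropped. The
    hemolysis indicators and the reference itself are not reported as
    targets.
    """
    wide = table.wide("ct")
    if reference not in wide.columns:
        raise ValueError(f"reference miRNA {reference!r} not in table")
    ref = wide[reference]
    ok = ref.notna()
    targets = [
        c
        for c in wide.columns
        if c not in (reference, HEMOLYSIS_STABLE, HEMOLYSIS_RBC)
    ]
    dct = wide.loc[ok, targets].sub(ref[ok], axis=0)
    long = dct.stack().rename("delta_ct").reset_index()
    long.columns = ["sample_id", "mirna_id", "delta_ct"]
    long["expression"] = np.exp2(-long["delta_ct"])
    if qc is not None:
        long["qc_pass"] = long["sample_id"].map(qc["qc_pass"]).fillna(False)
        if exclude_qc_fail:
            long = long[long["qc_pass"]].reset_index(drop=True)
    else:
        long["qc_pass"] = True
    return long


def _group_values(records, meta, mirna, group, sex=None):
    g = meta.data.set_index("sample_id")
    sel = records[records["mirna_id"] == mirna].set_index("sample_id")
    sel = sel.join(g[["group", "sex"]], how="inner")
    sel = sel[sel["group"] == group]
    if sex is not None:
        sel = sel[sel["sex"] == sex]
    return sel


def compare_groups(
    records: pd.DataFrame,
    meta: SampleMeta,
    groups: tuple[str, ...],
    mirnas: list[str] | None = None,
    stratify_by_sex: bool = False,
    scale: str = "expression",
    welch: bool = True,
) -> pd.DataFrame:
    """Group contrasts per miRNA: t-test for pairs, ANOVA + Bonferroni for 3+.

    Statistics run on the chosen ``scale`` ("expression" = 2^-ΔCt, or
    "delta_ct"); group means +- SEM are reported on both scales. The
    Bonferroni correction applies to the pairwise post-hoc comparisons
    within one miRNA, not across miRNAs. Groups with fewer than two
    subjects are skipped with a warning row.
    """
    if scale not in ("expression", "delta_ct"):
        raise ValueError("scale must be 'expression' or 'delta_ct'")
    mirnas = mirnas or sorted(records["mirna_id"].unique())
    strata: list[str | None] = [None] + (["M", "F"] if stratify_by_sex else [])
    rows = []
    for mirna in mirnas:
        for sex in strata:
            data = {
                g: _group_values(records, meta, mirna, g, sex) for g in groups
            }
            vals = {g: d[scale].to_numpy(dtype=float) for g, d in data.items()}
            row: dict = {"mirna_id": mirna, "stratum": sex or "all"}
            for g, d in data.items():
                n = len(d)
                row[f"n_{g}"] = n
                for sc in ("expression", "delta_ct"):
                    v = d[sc].to_numpy(dtype=float)
                    row[f"mean_{sc}_{g}"] = v.mean() if n else np.nan
                    row[f"sem_{sc}_{g}"] = (
                        v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                    )
            small = [g for g, v in vals.items() if len(v) < 2]
            if small:
                row["test"] = "skipped"
                row["warning"] = f"groups with n<2: {small}"
                rows.append(row)
                continue
            if len(groups) == 2:
                a, b = (vals[g] for g in groups)
                t, p = stats.ttest_ind(a, b, equal_var=not welch)
                row["test"] = "welch_t" if welch else "pooled_t"
                row["p_value"] = float(p)
            else:
                f, p = stats.f_oneway(*(vals[g] for g in groups))
                row["test"] = "anova_bonferroni"
                row["p_value"] = float(p)
                pairs = list(combinations(groups, 2))
                for ga, gb in pairs:
                    _, praw = stats.ttest_ind(
                        vals[ga], vals[gb], equal_var=not welch
                    )
                    row[f"p_{ga}_vs_{gb}"] = float(min(1.0, praw * len(pairs)))
            rows.append(row)
    return pd.DataFrame(rows)


def correlate(
    records: pd.DataFrame,
    meta: SampleMeta,
    mirna: str,
    covariate: str,
    scale: str = "expression",
) -> tuple[float, float]:
    """Pearson correlation between a marker and a clinical covariate."""
    g = meta.data.set_index("sample_id")
    sel = records[records["mirna_id"] == mirna].set_index("sample_id")
    sel = sel.join(g[[covariate]], how="inner").dropna(subset=[covariate, scale])
    if len(sel) < 3:
        raise ValueError("need >= 3 paired observations")
    x = sel[scale].to_numpy(dtype=float)
    y = sel[covariate].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
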