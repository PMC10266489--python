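"""Synthetic plasma cohorts and capture/scramble miRNome panels.

The generator mirrors the statistical structure the downstream analysis
assumes. ΔCt (cycles relative to the endogenous control) is the Gaussian
variable; relative expression 2^-ΔCt is therefore lognormal, which is why
group means printed on the expression scale are converted back to ΔCt
moments with the lognormal mean/variance formulas before sampling.

Default cohort parameters follow the dementia case/control study design
this package analyses: 43 healthy controls (HC), 42 frontotemporal
dementia (FTD, of which 17 behavioural and 17 semantic variant) and 33
Alzheimer's disease (AD) subjects, with three plasma markers
(miR-92a-3p, miR-320a, miR-320b) normalized to miR-93a-5p and a
miR-23a-3p / miR-451a hemolysis indicator pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .tables import DEFAULT_IPC_ID, CtTable, SampleMeta

LN2 = math.log(2.0)

REFERENCE_MIRNA = "hsa-miR-93a-5p"
HEMOLYSIS_STABLE = "hsa-miR-23a-3p"
HEMOLYSIS_RBC = "hsa-miR-451a"
PLASMA_MARKERS = ("hsa-miR-92a-3p", "hsa-miR-320a", "hsa-miR-320b")

#: Nominal endogenous-control Ct (cycles) and its between-subject SD.
REFERENCE_CT_MEAN = 25.0
REFERENCE_CT_SD = 0.25


def lognormal_dct_params(mean: float, sd: float) -> tuple[float, float]:
    """ΔCt Gaussian parameters reproducing given 2^-ΔCt mean and SD.

    If ΔCt ~ N(mu, sigma^2) then 2^-ΔCt is lognormal with
    E = exp(-mu*ln2 + (sigma*ln2)^2 / 2) and
    Var = (exp((sigma*ln2)^2) - 1) * E^2.
    Inverting these moments gives the (mu, sigma) returned here.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("expression mean and SD must be positive")
    s2 = math.log1p((sd / mean) ** 2) / LN2**2
    mu = (-math.log(mean) + LN2**2 * s2 / 2.0) / LN2
    return mu, math.sqrt(s2)


# -- study defaults ---------------------------------------------------------

#: Group sizes of the emulated cohort (the FTD subtype rows are subsets).
STUDY_GROUP_SIZES = {"HC": 43, "FTD": 42, "AD": 33}
STUDY_SEX_SPLIT = {"HC": (18, 25), "FTD": (14, 28), "AD": (14, 19)}  # (M, F)
STUDY_FTD_SUBTYPES = {"bvFTD": 17, "svFTD": 17}  # remaining FTD unclassified
STUDY_FTD_SUBTYPE_SEX = {"bvFTD": (9, 8), "svFTD": (4, 13)}  # (M, F)

#: Per-group covariate (mean, SD); None where the study records no value.
STUDY_COVARIATES = {
    "HC": {"age": (72.74, 7.40), "onset": None, "mmse": None},
    "FTD": {"age": (71.07, 8.72), "onset": (66.62, 8.31), "mmse": (21.47, 5.93)},
    "AD": {"age": (69.15, 10.46), "onset": (65.32, 7.54), "mmse": (16.71, 5.73)},
}

#: Group-level relative expression 2^-ΔCt as (mean, SEM) — the published
#: plasma contrasts. The HC level of miR-320a is not printed for the whole
#: population (the marker does not separate patients from controls); 1.20,
#: between the two patient-group means, stands in for it.
STUDY_EXPRESSION = {
    "hsa-miR-92a-3p": {"HC": (1.36, 0.20), "FTD": (0.83, 0.10), "AD": (0.78, 0.20)},
    "hsa-miR-320a": {"HC": (1.20, 0.20), "FTD": (1.45, 0.10), "AD": (0.81, 0.20)},
    "hsa-miR-320b": {"HC": (0.09, 0.008), "FTD": (0.17, 0.02), "AD": (0.17, 0.05)},
}


def study_marker_params(
    expression: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    group_sizes: Mapping[str, int] | None = None,
) -> dict[str, dict[str, tuple[float, float]]]:
    """ΔCt (mu, sigma) per (miRNA, group) from expression-scale (mean, SEM).

    SEMs are scaled by sqrt(n) of the group to recover between-subject SDs
    before the lognormal inversion.
    """
    expression = expression or STUDY_EXPRESSION
    group_sizes = group_sizes or STUDY_GROUP_SIZES
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for mirna, per_group in expression.items():
        out[mirna] = {}
        for group, (mean, sem) in per_group.items():
            sd = sem * math.sqrt(group_sizes[group])
            out[mirna][group] = lognormal_dct_params(mean, sd)
    return out


# -- cohort spec ------------------------------------------------------------


@dataclass
class CohortSpec:
    """Recipe for a synthetic plasma cohort.

    ``marker_params`` maps miRNA -> group -> (mean, SD) of ΔCt in cycles.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_GROUP_SIZES)
    )
    sex_split: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(STUDY_SEX_SPLIT)
    )
    marker_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=study_marker_params
    )
    covariate_params: dict[str, dict[str, tuple[float, float] | None]] = field(
        default_factory=lambda: {g: dict(v) for g, v in STUDY_COVARIATES.items()}
    )
    ftd_subtypes: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_FTD_SUBTYPES)
    )
    ftd_subtype_sex: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(STUDY_FTD_SUBTYPE_SEX)
    )
    hemolysis_rate: float = 0.05
    hemolysis_threshold: float = 7.0
    hemolysis_excess: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        for group, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group_sizes[{group!r}] must be >= 0, got {n}")
        for group, (m, f) in self.sex_split.items():
            if m < 0 or f < 0:
                raise ValueError(f"sex_split[{group!r}] counts must be >= 0")
            if group in self.group_sizes and m + f != self.group_sizes[group]:
                raise ValueError(
                    f"sex_split[{group!r}] sums to {m + f}, "
                    f"expected group size {self.group_sizes[group]}"
                )
        for mirna, per_group in self.marker_params.items():
            for group, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(
                        f"marker_params[{mirna!r}][{group!r}] SD must be >= 0"
                    )
        if not 0.0 <= self.hemolysis_rate <= 1.0:
            raise ValueError(
                f"hemolysis_rate must be in [0, 1], got {self.hemolysis_rate}"
            )
        if "FTD" in self.group_sizes:
            if sum(self.ftd_subtypes.values()) > self.group_sizes["FTD"]:
                raise ValueError("ftd_subtypes counts exceed the FTD group size")
            for sub, (m, f) in self.ftd_subtype_sex.items():
                if sub in self.ftd_subtypes and m + f != self.ftd_subtypes[sub]:
                    raise ValueError(
                        f"ftd_subtype_sex[{sub!r}] sums to {m + f}, "
                        f"expected subtype size {self.ftd_subtypes[sub]}"
                    )


def simulate_cohort(spec: CohortSpec) -> tuple[CtTable, SampleMeta]:
    """Draw a plasma cohort: metadata plus long-format raw Ct values.

    Raw Cts are reconstructed as reference Ct (nominal 25 +- 0.25 cycles)
    plus the marker's Gaussian ΔCt, so downstream ΔCt normalization
    recovers the simulated values exactly up to reference noise.
    Hemolysed subjects get their miR-451a Ct lowered until the
    miR-23a-3p - miR-451a gap exceeds the QC threshold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    meta_rows = []
    ct_rows = []
    idx = 0
    for group, n in spec.group_sizes.items():
        males, females = spec.sex_split.get(group, (n, 0))
        if group == "FTD" and spec.ftd_subtypes:
            # honour subtype-level sex splits, remainder gets the leftover
            sexes, subtypes = [], []
            used_m = used_f = 0
            for sub, k in spec.ftd_subtypes.items():
                m, f = spec.ftd_subtype_sex.get(sub, (k, 0))
                sexes += ["M"] * m + ["F"] * f
                subtypes += [sub] * k
                used_m += m
                used_f += f
            sexes += ["M"] * (males - used_m) + ["F"] * (females - used_f)
            subtypes += [""] * (n - len(subtypes))
        else:
            sexes = ["M"] * males + ["F"] * females
            subtypes = [""] * n
        cov = spec.covariate_params.get(group, {})
        for j in range(n):
            sid = f"S{idx:03d}"
            idx += 1
            row = {
                "sample_id": sid,
                "group": group,
                "subtype": subtypes[j],
                "sex": sexes[j],
            }
            for name in ("age", "onset", "mmse"):
                params = cov.get(name)
                if params is None:
                    row[name] = np.nan
                else:
                    val = rng.normal(*params)
                    if name == "mmse":
                        val = float(np.clip(val, 0.0, 30.0))
                    row[name] = round(float(val), 2)
            meta_rows.append(row)

            ref_ct = rng.normal(REFERENCE_CT_MEAN, REFERENCE_CT_SD)
            ct_rows.append((sid, REFERENCE_MIRNA, "plasma", ref_ct))
            for mirna, per_group in spec.marker_params.items():
                if group not in per_group:
                    continue
                mu, sd = per_group[group]
                dct = rng.normal(mu, sd) if sd > 0 else mu
                ct_rows.append((sid, mirna, "plasma", ref_ct + dct))

            # hemolysis indicator pair
            ct_23a = rng.normal(24.0, 0.5)
            if rng.random() < spec.hemolysis_rate:
                gap = spec.hemolysis_threshold + spec.hemolysis_excess
                gap += abs(rng.normal(0.0, 0.5))
            else:
                gap = rng.normal(4.0, 0.8)
                gap = min(gap, spec.hemolysis_threshold - 0.5)
            ct_rows.append((sid, HEMOLYSIS_STABLE, "plasma", ct_23a))
            ct_rows.append((sid, HEMOLYSIS_RBC, "plasma", ct_23a - gap))

    ct_df = pd.DataFrame(
        ct_rows, columns=["sample_id", "mirna_id", "plate_id", "ct"]
    )
    ct_df["detected"] = True
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "group", "subtype", "sex", "age", "onset", "mmse"],
    )
    return CtTable(ct_df), SampleMeta(meta)


# -- panel spec -------------------------------------------------------------


def logistic_dropout(midpoint: float = 37.0, scale: float = 1.0) -> Callable:
    """Probability of an undetected well rising with true Ct."""

    def prob(ct):
        return 1.0 / (1.0 + np.exp(-(np.asarray(ct, dtype=float) - midpoint) / scale))

    return prob


@dataclass
class PanelSpec:
    """Recipe for a capture/scramble miRNome panel experiment.

    ``enriched_set`` maps miRNA identifiers to their true capture-side
    ΔΔCt shift in cycles (a 3-cycle shift is an 8-fold enrichment).
    ``present_fraction`` controls how many panel assays have template at
    all in a pull-down eluate; absent miRNAs drop out of detection and
    are removed by the downstream 66% filter, emulating the study's
    ~272-of-752 measurable count.
    """

    n_mirnas: int = 752
    n_capture: int = 3
    n_scramble: int = 3
    enriched_set: dict[str, float] = field(default_factory=dict)
    present_fraction: float = 272 / 752
    dropout_model: Callable = field(default_factory=logistic_dropout)
    ipc_offsets: dict[str, float] | None = None
    ipc_offset_sd: float = 0.5
    noise_sd: float = 0.1
    ct_range: tuple[float, float] = (22.0, 34.0)
    #: spiked miRNAs model abundantly captured species, so their template
    #: sits well above the detection limit in every replicate
    spike_ct_range: tuple[float, float] = (22.0, 28.0)
    seed: int = 0

    def mirna_ids(self) -> list[str]:
        return [f"hsa-miR-s{i:04d}" for i in range(1, self.n_mirnas + 1)]

    def validate(self) -> None:
        if self.n_mirnas <= 0:
            raise ValueError("n_mirnas must be positive")
        if self.n_capture < 1 or self.n_scramble < 1:
            raise ValueError("need at least one capture and one scramble replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.present_fraction <= 1.0:
            raise ValueError("present_fraction must be in (0, 1]")
        unknown = set(self.enriched_set) - set(self.mirna_ids())
        if unknown:
            raise ValueError(
                f"enriched_set identifiers not on the panel: {sorted(unknown)[:5]}"
            )


def default_enriched_set(
    spec: PanelSpec, n_spiked: int = 25, shift: float = 3.0, seed: int = 0
) -> dict[str, float]:
    """Pick ``n_spiked`` panel miRNAs and give each a true shift in cycles."""
    rng = np.random.default_rng(seed)
    ids = rng.choice(spec.mirna_ids(), size=n_spiked, replace=False)
    return {str(m): float(shift) for m in sorted(ids)}


def simulate_panels(spec: PanelSpec) -> tuple[CtTable, CtTable]:
    """Simulate capture and scramble plate pairs for a miRNome panel.

    Each sample is measured on two plates (first and second half of the
    panel), each carrying IPC spike-in wells with a per-plate Ct offset.
    Returns (capture table, scramble table); both carry a ``role`` column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = spec.mirna_ids()
    n = spec.n_mirnas

    present = rng.random(n) < spec.present_fraction
    base_ct = rng.uniform(*spec.ct_range, size=n)
    base_ct = np.where(present, base_ct, 45.0)
    shifts = np.array([spec.enriched_set.get(m, 0.0) for m in ids])
    spike_ct = rng.uniform(*spec.spike_ct_range, size=n)
    base_ct = np.where(shifts != 0.0, spike_ct, base_ct)

    half = n // 2
    panel_of = np.where(np.arange(n) < half, "P1", "P2")

    samples = [(f"capture_{i + 1}", "capture") for i in range(spec.n_capture)]
    samples += [(f"scramble_{i + 1}", "scramble") for i in range(spec.n_scramble)]

    rows = []
    for sample, role in samples:
        for panel in ("P1", "P2"):
            plate = f"{sample}:{panel}"
            if spec.ipc_offsets is not None:
                offset = spec.ipc_offsets.get(plate, 0.0)
            else:
                offset = rng.normal(0.0, spec.ipc_offset_sd)
            ipc_ct = 20.0 + offset + rng.normal(0.0, 0.05)
            rows.append((sample, DEFAULT_IPC_ID, plate, ipc_ct, True, role))
            on_plate = panel_of == panel
            true_ct = base_ct[on_plate].copy()
            if role == "capture":
                true_ct = true_ct - shifts[on_plate]
            well_ct = true_ct + offset + rng.normal(0.0, spec.noise_sd, true_ct.size)
            p_drop = np.asarray(spec.dropout_model(true_ct), dtype=float)
            undet = (rng.random(true_ct.size) < p_drop) | (true_ct > 40.0)
            for mid, ct, bad in zip(np.array(ids)[on_plate], well_ct, undet):
                rows.append(
                    (sample, mid, plate, np.nan if bad else float(ct), not bad, role)
                )

    df = pd.DataFrame(
        rows, columns=["sample_id", "mirna_id", "plate_id", "ct", "detected", "role"]
    )
    capture = CtTable(df[df["role"] == "capture"].reset_index(drop=True))
    scramble = CtTable(df[df["role"] == "scramble"].reset_index(drop=True))
    return capture, scramble
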