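"""Long-format Ct table container shared by all pipeline stages.

A Ct (cycle threshold) value is the qPCR cycle at which fluorescence
crosses the detection threshold; lower Ct means more template. Undetected
wells carry no Ct value and are flagged ``detected=False`` — they stay
explicitly missing until an imputation step decides what to do with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default identifier for the inter-plate calibrator spike-in wells.
DEFAULT_IPC_ID = "UniSp3"

REQUIRED_COLUMNS = ("sample_id", "mirna_id", "plate_id", "ct", "detected")


@dataclass
class CtTable:
    """Rectangular store of raw or calibrated Ct values in long format.

    Parameters
    ----------
    data
        DataFrame with columns ``sample_id, mirna_id, plate_id, ct,
        detected`` and optionally ``role`` (``capture`` | ``scramble``)
        and ``imputed``. Undetected entries have ``ct`` NaN and
        ``detected`` False.
    ipc_id
        miRNA identifier of the inter-plate calibrator spike-in.
    """

    data: pd.DataFrame
    ipc_id: str = DEFAULT_IPC_ID

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CtTable missing required columns: {missing}")
        if "imputed" not in self.data.columns:
            self.data = self.data.assign(imputed=False)
        detected = self.data["detected"].to_numpy(dtype=bool)
        ct = self.data["ct"].to_numpy(dtype=float)
        bad = detected & ~((ct > 0) & np.isfinite(ct))
        if bad.any():
            raise ValueError(
                f"{bad.sum()} detected entries have non-positive or missing Ct"
            )
        dup = self.data.duplicated(["sample_id", "mirna_id", "plate_id"])
        if dup.any():
            raise ValueError("duplicate (sample_id, mirna_id, plate_id) entries")

    # -- views -------------------------------------------------------------

    @property
    def mirnas(self) -> pd.Index:
        """All assay identifiers excluding the IPC spike-in."""
        ids = self.data.loc[self.data["mirna_id"] != self.ipc_id, "mirna_id"]
        return pd.Index(ids.unique())

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.data["sample_id"].unique())

    def roles(self) -> pd.Series:
        """Per-sample role labels (capture/scramble), if present."""
        if "role" not in self.data.columns:
            raise KeyError("table carries no role column")
        return self.data.groupby("sample_id")["role"].first()

    def wide(self, values: str = "ct") -> pd.DataFrame:
        """Pivot to a sample x miRNA matrix (IPC wells excluded)."""
        body = self.data[self.data["mirna_id"] != self.ipc_id]
        return body.pivot_table(
            index="sample_id", columns="mirna_id", values=values, aggfunc="mean"
        )

    def copy(self) -> "CtTable":
        return CtTable(self.data.copy(), ipc_id=self.ipc_id)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, ipc_id: str = DEFAULT_IPC_ID) -> "CtTable":
        df = pd.read_csv(path)
        if "detected" in df.columns:
            df["detected"] = df["detected"].astype(bool)
        return cls(df, ipc_id=ipc_id)


@dataclass
class SampleMeta:
    """Per-subject labels for a plasma cohort."""

    data: pd.DataFrame = field(repr=False)

    COLUMNS = ("sample_id", "group", "subtype", "sex", "age", "onset", "mmse")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")

    def groups(self) -> pd.Series:
        return self.data.set_index("sample_id")["group"]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleMeta":
        return cls(pd.read_csv(path))
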