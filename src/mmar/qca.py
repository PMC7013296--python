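"""Lesion geometry and the derived angiographic indices.

Quantitative coronary angiography (QCA) reduces a lesion to its minimal
lumen diameter (MLD), the interpolated reference diameter (RD), lesion
length and the percent diameter stenosis DS = (1 - MLD/RD) x 100.  The
demand-to-supply index studied here divides the myocardial mass at risk by
the MLD: MMAR/MLD in ml/mm, with higher values predicting FFR <= 0.8.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import pandas as pd

FFR_THRESHOLD = 0.8
MMAR_MLD_CUTOFF = 29.5  # ml/mm, published optimal cut-off

LESION_COLUMNS = [
    "lesion_id",
    "artery",
    "proximal",
    "mld_mm",
    "rd_mm",
    "length_mm",
    "ds_pct",
    "mmar_ml",
    "pct_mmar",
    "ffr",
]


def diameter_stenosis(mld: float, rd: float) -> float:
    """Percent diameter stenosis (1 - MLD/RD) x 100."""
    if mld <= 0 or rd <= 0:
        raise ValueError("MLD and RD must be positive")
    if mld > rd:
        raise ValueError(f"MLD {mld} exceeds reference diameter {rd}")
    return (1.0 - mld / rd) * 100.0


def mmar_mld_ratio(mmar_ml: float, mld: float) -> float:
    """The MMAR/MLD index in ml/mm."""
    if mld <= 0:
        raise ValueError("MLD must be positive")
    if mmar_ml < 0:
        raise ValueError("MMAR must be non-negative")
    return mmar_ml / mld


def classify(value: float, cutoff: float = MMAR_MLD_CUTOFF) -> bool:
    """Predicted functionally significant (FFR <= 0.8) when value >= cutoff.

    Ties at the cut-off count as positive (inclusive-≥ convention, applied
    consistently throughout the package).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return value >= cutoff


@dataclass
class LesionGeometry:
    mld: float      # mm
    rd: float       # mm
    length: float   # mm
    artery: str
    proximal: bool

    def __post_init__(self) -> None:
        if not (0 < self.mld <= self.rd):
            raise ValueError("requires 0 < MLD <= RD")
        if self.length <= 0:
            raise ValueError("lesion length must be positive")

    @property
    def ds(self) -> float:
        return diameter_stenosis(self.mld, self.rd)


@dataclass
class LesionRecord:
    geometry: LesionGeometry
    mmar_ml: float
    pct_mmar: float
    ffr: float

    def __post_init__(self) -> None:
        if not (0 < self.ffr <= 1):
            raise ValueError("FFR must lie in (0, 1]")
        if self.mmar_ml < 0 or not (0 <= self.pct_mmar <= 100):
            raise ValueError("invalid MMAR values")

    @property
    def mmar_mld(self) -> float:
        return mmar_mld_ratio(self.mmar_ml, self.geometry.mld)

    @property
    def significant(self) -> bool:
        return self.ffr <= FFR_THRESHOLD


def validate_lesion_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check lesion-table invariants; returns the frame with mmar_mld added.

    DS is recomputed from MLD and RD; a supplied ds_pct that disagrees by
    more than one percentage point raises a warning (published medians need
    not compose exactly), and the recomputed value is kept.
    """
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion table missing columns: {missing}")
    if (df["mld_mm"] <= 0).any() or (df["mld_mm"] > df["rd_mm"]).any():
        raise ValueError("lesion table violates 0 < MLD <= RD")
    if (df["length_mm"] <= 0).any():
        raise ValueError("lesion lengths must be positive")
    if ((df["ffr"] <= 0) | (df["ffr"] > 1)).any():
        raise ValueError("FFR must lie in (0, 1]")
    if (df["mmar_ml"] < 0).any():
        raise ValueError("MMAR must be non-negative")
    ds = (1.0 - df["mld_mm"] / df["rd_mm"]) * 100.0
    if df["ds_pct"].notna().all() and (df["ds_pct"] - ds).abs().max() > 1.0:
        warnings.warn(
            "supplied ds_pct deviates from (1 - MLD/RD) x 100 by > 1 point; "
            "recomputed values are used",
            stacklevel=2,
        )
    out = df.copy()
    out["ds_pct"] = ds
    out["mmar_mld"] = out["mmar_ml"] / out["mld_mm"]
    out["significant"] = out["ffr"] <= FFR_THRESHOLD
    return out


def read_lesion_table(path) -> pd.DataFrame:
    return validate_lesion_table(pd.read_csv(path))


def write_lesion_table(df: pd.DataFrame, path=None) -> str:
    """Write the canonical lesion CSV; returns the text written."""
    buf = io.StringIO()
    df[LESION_COLUMNS].to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", newline="") as fh:
            fh.write(text)
    return text
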