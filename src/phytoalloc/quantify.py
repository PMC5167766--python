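"""Assay quantitation: immunoblot standard curves, chlorophyll a, elemental N.

Converts raw readouts into per-cell contents with the protocol's constants:

* Immunoblots run sample lanes (0.5 ug total protein for RbcL, 1 ug for PsbA)
  alongside standard ladders (1500/750/375/187.5 fmol RbcL;
  125/62.5/31.25/15.625 fmol PsbA).  A linear standard curve maps signal to
  fmol by inverse regression; sample signals must fall within the ladder
  range and saturated lanes are rejected outright — no extrapolation.
* Chlorophyll a is measured on a 10x acetone dilution of the protein extract
  (50 uL into 450 uL 90 % acetone) from absorbances at 664, 630 and 750 nm:
  [Chl a] = 11.47 (A664 - A750) - 0.4 (A630 - A750) in ug mL^-1 of extract.
* Cellular N follows from carbon content and the elemental-analyzer mass C:N.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantifyError",
    "OutOfRangeError",
    "SaturatedLaneError",
    "CalibrationError",
    "RBCL_LADDER_FMOL",
    "PSBA_LADDER_FMOL",
    "BLOT_LOAD_UG",
    "BlotTable",
    "StandardCurve",
    "AbsorbanceReading",
    "CellComposition",
    "fit_standard_curve",
    "quantify_lane",
    "per_cell_amount",
    "chl_a_concentration",
    "chl_a_per_cell",
    "nitrogen_per_cell",
    "quantify_blot",
    "read_blot_table",
    "write_blot_table",
    "read_absorbance",
    "write_absorbance",
]

#: standard-ladder amounts, fmol per lane
RBCL_LADDER_FMOL = (1500.0, 750.0, 375.0, 187.5)
PSBA_LADDER_FMOL = (125.0, 62.5, 31.25, 15.625)
#: total protein loaded per sample lane, ug
BLOT_LOAD_UG = {"RbcL": 0.5, "PsbA": 1.0}

CHL_A_COEF_664 = 11.47
CHL_A_COEF_630 = 0.4


class QuantifyError(ValueError):
    """Base error for quantitation problems."""


class OutOfRangeError(QuantifyError):
    """Sample signal implies an amount outside the standard-curve range."""


class SaturatedLaneError(QuantifyError):
    """Lane flagged saturated upstream; its signal is not quantifiable."""


class CalibrationError(QuantifyError):
    """Standard curve cannot be fitted (too few lanes, non-positive slope)."""


@dataclass
class BlotTable:
    """Lanes of one blot: standards with known fmol plus sample lanes."""

    lanes: pd.DataFrame  # columns: lane_id, kind, amount_fmol, signal, saturated
    target: str  # "RbcL" | "PsbA"
    load_ug: float

    def __post_init__(self):
        required = {"lane_id", "kind", "amount_fmol", "signal", "saturated"}
        if not required <= set(self.lanes.columns):
            raise QuantifyError(f"blot table missing columns {sorted(required - set(self.lanes.columns))}")
        if (self.lanes["signal"] < 0).any():
            raise QuantifyError("blot signals must be >= 0")
        n_std = int((self.lanes["kind"] == "standard").sum())
        if n_std < 3:
            raise QuantifyError(f"need >= 3 standard lanes, got {n_std}")

    @property
    def standards(self) -> pd.DataFrame:
        return self.lanes[self.lanes["kind"] == "standard"]

    @property
    def samples(self) -> pd.DataFrame:
        return self.lanes[self.lanes["kind"] == "sample"]


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    fmol_min: float
    fmol_max: float
    n_standards: int
    flags: tuple = ()


@dataclass
class AbsorbanceReading:
    """Spectrophotometer triplet on the acetone phase, plus the factors needed
    to back-calculate per-cell pigment: the 10x extract dilution (50 uL of
    protein extract into 450 uL acetone), the protein-extract volume (mL),
    the culture volume filtered (mL) and the cell density (cells mL^-1)."""

    a664: float
    a630: float
    a750: float
    extract_dilution: float = 10.0
    extract_volume_ml: float = 0.45
    filtered_volume_ml: float = 50.0
    cell_density_per_ml: float = float("nan")

    def __post_init__(self):
        for name in ("a664", "a630", "a750"):
            if not np.isfinite(getattr(self, name)):
                raise QuantifyError(f"{name} must be finite")
        if not self.filtered_volume_ml > 0:
            raise QuantifyError("filtered volume must be > 0")


@dataclass
class CellComposition:
    """Per-cell contents; N is derived from carbon and the mass C:N ratio."""

    c_pg: float = float("nan")
    cn_mass: float = float("nan")
    chla_pg: float = float("nan")
    protein_pg: float = float("nan")
    psba_amol: float = float("nan")
    rbcl_amol: float = float("nan")

    @property
    def n_pg(self) -> float:
        return nitrogen_per_cell(self.c_pg, self.cn_mass)


def fit_standard_curve(table: BlotTable) -> StandardCurve:
    """Linear signal = slope * fmol + intercept over unsaturated standards.

    Saturated standard lanes are excluded (shrinking the usable range); a
    non-positive slope is a calibration failure and r^2 < 0.95 sets a warning
    flag on the curve.
    """
    std = table.standards
    usable = std[~std["saturated"].astype(bool)]
    if len(usable) < 3:
        raise CalibrationError(
            f"need >= 3 unsaturated standard lanes, got {len(usable)}"
        )
    fmol = usable["amount_fmol"].to_numpy(dtype=float)
    signal = usable["signal"].to_numpy(dtype=float)
    res = stats.linregress(fmol, signal)
    if not res.slope > 0:
        raise CalibrationError(f"standard-curve slope must be > 0, got {res.slope:g}")
    r2 = float(res.rvalue**2)
    flags = ("low_r2",) if r2 < 0.95 else ()
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        fmol_min=float(fmol.min()),
        fmol_max=float(fmol.max()),
        n_standards=len(usable),
        flags=flags,
    )


def quantify_lane(signal: float, curve: StandardCurve, saturated: bool = False) -> float:
    """Inverse regression of one sample lane signal to fmol.

    Raises :class:`SaturatedLaneError` for saturated lanes and
    :class:`OutOfRangeError` when the implied amount leaves the closed
    standard range (a tiny relative tolerance keeps exact-boundary signals
    acceptable).
    """
    if saturated:
        raise SaturatedLaneError("lane flagged saturated; cannot quantify")
    fmol = (signal - curve.intercept) / curve.slope
    tol = 1e-9 * curve.fmol_max
    if fmol < curve.fmol_min - tol:
        raise OutOfRangeError(
            f"implied {fmol:.4g} fmol below bottom standard ({curve.fmol_min:g} fmol)"
        )
    if fmol > curve.fmol_max + tol:
        raise OutOfRangeError(
            f"implied {fmol:.4g} fmol above top standard ({curve.fmol_max:g} fmol)"
        )
    return float(np.clip(fmol, curve.fmol_min, curve.fmol_max))


def per_cell_amount(fmol_lane: float, load_ug: float, protein_pg_cell: float) -> float:
    """Convert a lane amount to per-cell content, amol cell^-1.

    fmol per ug of loaded protein times pg protein per cell:
    (fmol/ug) * (pg/cell) = 1e-3 amol/cell.
    """
    if not load_ug > 0:
        raise QuantifyError("protein load must be > 0")
    if not protein_pg_cell > 0:
        raise QuantifyError("protein per cell must be > 0")
    return (fmol_lane / load_ug) * protein_pg_cell * 1e-3


def chl_a_concentration(reading: AbsorbanceReading) -> float:
    """Chl a in the acetone extract, ug mL^-1 (trichromatic-style equation).

    Negative values (blank-level noise) are returned as-is; callers may flag.
    """
    e664 = reading.a664 - reading.a750
    e630 = reading.a630 - reading.a750
    return CHL_A_COEF_664 * e664 - CHL_A_COEF_630 * e630


def chl_a_per_cell(extract_conc_ug_ml: float, reading: AbsorbanceReading) -> float:
    """Back-calculate pg Chl a per cell from the acetone-phase concentration.

    The acetone phase is a ``extract_dilution``-fold dilution of the protein
    extract; the whole extract volume holds the pigment of every filtered
    cell (cell density x filtered volume).
    """
    if not reading.cell_density_per_ml > 0:
        raise QuantifyError("cell density must be > 0")
    total_ug = extract_conc_ug_ml * reading.extract_dilution * reading.extract_volume_ml
    cells = reading.cell_density_per_ml * reading.filtered_volume_ml
    return total_ug / cells * 1e6  # ug -> pg


def nitrogen_per_cell(c_pg: float, cn_mass: float) -> float:
    """N per cell (pg) from carbon content and the mass C:N ratio."""
    if not cn_mass > 0:
        raise QuantifyError("C:N must be > 0")
    return c_pg / cn_mass


def quantify_blot(table: BlotTable, protein_pg_cell: float) -> dict:
    """Full blot workflow: curve fit, per-lane inverse regression, per-cell
    conversion.  Returns the curve, per-lane fmol and the mean per-cell
    content (amol cell^-1) over quantifiable sample lanes; lanes rejected by
    the range/saturation rules are reported under ``errors``."""
    curve = fit_standard_curve(table)
    lane_fmol: dict = {}
    errors: dict = {}
    for _, row in table.samples.iterrows():
        try:
            lane_fmol[row["lane_id"]] = quantify_lane(
                float(row["signal"]), curve, bool(row["saturated"])
            )
        except QuantifyError as exc:
            errors[row["lane_id"]] = str(exc)
    if lane_fmol:
        mean_fmol = float(np.mean(list(lane_fmol.values())))
        amol_cell = per_cell_amount(mean_fmol, table.load_ug, protein_pg_cell)
    else:
        mean_fmol = float("nan")
        amol_cell = float("nan")
    return {
        "curve": curve,
        "lane_fmol": lane_fmol,
        "mean_fmol": mean_fmol,
        "amol_per_cell": amol_cell,
        "errors": errors,
    }


# ---------------------------------------------------------------------------
# I/O


def read_blot_table(path) -> BlotTable:
    df = pd.read_csv(path)
    required = {"lane_id", "kind", "amount_fmol", "signal", "saturated", "target", "load_ug"}
    if not required <= set(df.columns):
        raise QuantifyError(f"blot file {path} missing columns {sorted(required - set(df.columns))}")
    return BlotTable(
        lanes=df[["lane_id", "kind", "amount_fmol", "signal", "saturated"]].copy(),
        target=str(df["target"].iloc[0]),
        load_ug=float(df["load_ug"].iloc[0]),
    )


def write_blot_table(table: BlotTable, path) -> None:
    df = table.lanes.copy()
    df["target"] = table.target
    df["load_ug"] = table.load_ug
    df.to_csv(path, index=False, float_format="%.12g")


def read_absorbance(path) -> AbsorbanceReading:
    df = pd.read_csv(path)
    row = df.iloc[0]
    return AbsorbanceReading(
        a664=float(row["a664"]),
        a630=float(row["a630"]),
        a750=float(row["a750"]),
        extract_dilution=float(row.get("extract_dilution", 10.0)),
        extract_volume_ml=float(row.get("extract_volume_ml", 0.45)),
        filtered_volume_ml=float(row["filtered_volume_ml"]),
        cell_density_per_ml=float(row["cell_density_per_ml"]),
    )


def write_absorbance(reading: AbsorbanceReading, path) -> None:
    pd.DataFrame([reading.__dict__]).to_csv(path, index=False, float_format="%.12g")
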