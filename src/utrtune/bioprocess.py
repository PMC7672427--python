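"""Batch-culture productivity and enzyme-activity metrics.

Cumulative cell days (trapezoidal integral of viable cell density),
cell-specific productivity qP, protein concentration from A280, and the
chromogenic sulfatase activity assay (volumetric and protein-specific).

Units: VCD cells/mL, titer ug/mL, qP pg/cell/day, concentration g/L,
activity U = umol substrate converted per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinSpec",
    "ActivityAssay",
    "ASA_SPEC",
    "cumulative_cell_days",
    "specific_productivity",
    "protein_conc_a280",
    "asa_activity",
]


@dataclass(frozen=True)
class ProteinSpec:
    """Molar extinction coefficient (1/(M cm)) and molecular weight (kDa)."""

    ext_coeff: float
    mw: float

    def __post_init__(self):
        if self.ext_coeff <= 0 or self.mw <= 0:
            raise ValueError("extinction coefficient and MW must be > 0")


#: Arylsulfatase A (52.677 kDa, eps280 = 39350 1/(M cm)).
ASA_SPEC = ProteinSpec(ext_coeff=39350.0, mw=52.677)


def _validate_batch(batch: pd.DataFrame):
    for col in ("day", "vcd"):
        if col not in batch.columns:
            raise ValueError(f"batch series missing column {col!r}")
    day = batch["day"].to_numpy(dtype=float)
    vcd = batch["vcd"].to_numpy(dtype=float)
    if not (np.diff(day) > 0).all():
        raise ValueError("days must be strictly increasing")
    if (vcd < 0).any():
        raise ValueError("VCD must be >= 0")
    return day, vcd


def cumulative_cell_days(batch: pd.DataFrame, t0: float = None,
                         t1: float = None) -> float:
    """Trapezoidal integral of VCD over [t0, t1], cell*days/mL.

    Interval endpoints default to the full series and may fall between
    sampled days (VCD linearly interpolated).
    """
    day, vcd = _validate_batch(batch)
    t0 = day[0] if t0 is None else float(t0)
    t1 = day[-1] if t1 is None else float(t1)
    if t1 == t0:
        return 0.0
    if t1 < t0:
        raise ValueError("t1 must be > t0")
    if t0 < day[0] or t1 > day[-1]:
        raise ValueError("integration interval outside the sampled days")
    grid = np.unique(np.concatenate([[t0, t1], day[(day > t0) & (day < t1)]]))
    return float(np.trapezoid(np.interp(grid, day, vcd), grid))


def specific_productivity(batch: pd.DataFrame, per_interval: bool = False):
    """Cell-specific productivity qP in pg/cell/day.

    Default: one end-of-batch value, (titer_end - titer_start) * 1e6
    divided by the cumulative cell days over the full span.  With
    ``per_interval=True`` a per-sampling-interval series is returned
    instead.
    """
    day, _ = _validate_batch(batch)
    if "titer" not in batch.columns:
        raise ValueError("batch series missing column 'titer'")
    titer = batch["titer"].to_numpy(dtype=float)
    titer = np.where(titer < 0, 0.0, titer)  # below-detection clamp
    if (batch["titer"].to_numpy(dtype=float) < 0).any():
        warnings.warn("negative titer readings treated as below detection (0)")
    if per_interval:
        rows = []
        for i in range(len(day) - 1):
            ivcd = cumulative_cell_days(batch, day[i], day[i + 1])
            if ivcd == 0:
                raise ValueError(f"zero cumulative cell days in interval {i}")
            rows.append({"day_start": day[i], "day_end": day[i + 1],
                         "qp": (titer[i + 1] - titer[i]) * 1e6 / ivcd})
        return pd.DataFrame(rows)
    ivcd = cumulative_cell_days(batch)
    if ivcd == 0:
        raise ValueError("zero cumulative cell days over the batch")
    return float((titer[-1] - titer[0]) * 1e6 / ivcd)


def protein_conc_a280(a280: float, spec: ProteinSpec = ASA_SPEC,
                      path_cm: float = 1.0) -> float:
    """Protein concentration in g/L from an A280 reading.

    conc = A280 / (eps * path) mol/L, times MW in g/mol:
    A280 / (eps * path) * mw_kDa * 1000.
    """
    if a280 < 0:
        raise ValueError("A280 must be >= 0")
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    return a280 / (spec.ext_coeff * path_cm) * spec.mw * 1000.0


@dataclass(frozen=True)
class ActivityAssay:
    """Timed A515 readings of the chromogenic product plus calibration.

    ``std_curve`` is (slope in A515 per nmol product in the reaction,
    intercept in A515); ``readings`` is a sequence of (time_min, a515).
    """

    std_curve: tuple
    readings: tuple
    sample_volume_ml: float
    protein_conc_mg_ml: float = None

    def __post_init__(self):
        slope, _ = self.std_curve
        if slope <= 0:
            raise ValueError("standard-curve slope must be > 0")
        if len(self.readings) < 2:
            raise ValueError("need at least two timed readings")
        if self.sample_volume_ml <= 0:
            raise ValueError("sample volume must be > 0")


def asa_activity(assay: ActivityAssay) -> dict:
    """Volumetric (U/mL) and protein-specific (U/mg) activity.

    Product amounts (nmol) are read off the standard curve; their slope
    versus time (least squares) is the conversion rate.  1 U = 1
    umol/min, so U/mL = rate_nmol_per_min * 1e-3 / sample volume.
    """
    slope_std, intercept_std = assay.std_curve
    times = np.array([r[0] for r in assay.readings], dtype=float)
    a515 = np.array([r[1] for r in assay.readings], dtype=float)
    if times.max() - times.min() <= 0:
        raise ValueError("readings must span a positive time interval")
    nmol = (a515 - intercept_std) / slope_std
    rate = float(np.polyfit(times, nmol, 1)[0])  # nmol/min
    if rate < 0:
        warnings.warn("negative fitted conversion rate clamped to 0")
        rate = 0.0
    u_per_ml = rate * 1e-3 / assay.sample_volume_ml
    out = {"u_per_ml": u_per_ml}
    if assay.protein_conc_mg_ml is not None:
        if assay.protein_conc_mg_ml <= 0:
            raise ValueError("protein concentration must be > 0")
        out["u_per_mg"] = u_per_ml / assay.protein_conc_mg_ml
    return out
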