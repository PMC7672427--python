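"""Product-quality quantification from 1-D signal traces.

Size-exclusion chromatograms are integrated into HMW / main (mAb) /
LMW area fractions; gel-lane densitometry profiles yield band ratios
(full-size vs heavy-chain dimer); the helper-factor western-blot
normalization combines lysate and supernatant signals into a relative
expression level versus the unregulated control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Sumf1Obs",
    "integrate_chromatogram",
    "classify_peaks",
    "lane_band_ratio",
    "sumf1_relative_level",
]


def _validate_chromatogram(c: pd.DataFrame):
    for col in ("time_min", "a280"):
        if col not in c.columns:
            raise ValueError(f"chromatogram missing column {col!r}")
    t = c["time_min"].to_numpy(dtype=float)
    y = c["a280"].to_numpy(dtype=float)
    if len(t) < 50:
        raise ValueError("chromatogram needs at least 50 points")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("chromatogram contains non-finite values")
    if not (np.diff(t) > 0).all():
        raise ValueError("time axis must be strictly increasing")
    return t, y


def _baseline(t: np.ndarray, y: np.ndarray, flank: float = 0.05) -> np.ndarray:
    """Linear baseline fitted on the first and last ``flank`` of points."""
    k = max(int(flank * len(t)), 5)
    idx = np.r_[np.arange(k), np.arange(len(t) - k, len(t))]
    coef = np.polyfit(t[idx], y[idx], 1)
    return np.polyval(coef, t)


def integrate_chromatogram(chrom: pd.DataFrame, prominence_frac: float = 0.02,
                           floor_frac: float = 0.005) -> pd.DataFrame:
    """Integrate a chromatogram into peaks and area fractions.

    A linear baseline fitted on the flanking low-signal regions is
    subtracted; peaks above a relative prominence threshold are detected
    and their boundaries set valley-to-valley (outermost boundaries
    where the signal drops below ``floor_frac`` of the maximum).  Areas
    are trapezoidal; fractions are normalized to sum to exactly 100.
    """
    t, y = _validate_chromatogram(chrom)
    signal = y - _baseline(t, y)
    top = signal.max()
    if top <= 0:
        raise ValueError("no peaks: signal never rises above baseline")
    peaks, props = find_peaks(signal, prominence=prominence_frac * top)
    if len(peaks) == 0:
        raise ValueError("no peaks above the prominence threshold")
    plateau, _ = find_peaks(signal, prominence=prominence_frac * top, plateau_size=5)
    if len(plateau):
        warnings.warn("flat-topped peak detected; detector may be saturated")

    floor = floor_frac * top
    bounds = []
    for k, p in enumerate(peaks):
        # left boundary: previous inter-peak valley, or last sub-floor point
        lo = peaks[k - 1] if k > 0 else 0
        if k > 0:
            left = lo + int(np.argmin(signal[lo:p + 1]))
        else:
            below = np.nonzero(signal[:p] < floor)[0]
            left = below[-1] if len(below) else 0
        hi = peaks[k + 1] if k < len(peaks) - 1 else len(signal) - 1
        if k < len(peaks) - 1:
            right = p + int(np.argmin(signal[p:hi + 1]))
        else:
            above = np.nonzero(signal[p:] >= floor)[0]
            right = p + (above[-1] if len(above) else 0)
        bounds.append((left, right))

    rows = []
    for (left, right), p in zip(bounds, peaks):
        area = float(np.trapezoid(signal[left:right + 1], t[left:right + 1]))
        rows.append({"left": t[left], "right": t[right], "apex": t[p],
                     "area": max(area, 0.0)})
    table = pd.DataFrame(rows)
    total = table["area"].sum()
    if total <= 0:
        raise ValueError("no peaks: zero integrated area")
    table["fraction"] = 100.0 * table["area"] / total
    return table


def classify_peaks(peaks: pd.DataFrame, main_window=None) -> pd.DataFrame:
    """Label peaks HMW / mAb / LMW by elution order around the main peak.

    The main (monomer) peak is the largest one, or the largest within
    ``main_window = (t_lo, t_hi)`` minutes when given.  Earlier-eluting
    peaks are HMW aggregates, later-eluting ones LMW fragments.
    """
    out = peaks.copy()
    cand = out
    if main_window is not None:
        lo, hi = main_window
        cand = out[(out["apex"] >= lo) & (out["apex"] <= hi)]
        if len(cand) == 0:
            raise ValueError("no peak inside the main window")
    top = cand["area"].max()
    ties = cand[np.isclose(cand["area"], top)]
    if len(ties) > 1:
        warnings.warn("two candidate main peaks of equal area; "
                      "breaking the tie toward earlier elution")
    main_idx = ties.sort_values("apex").index[0]
    main_apex = out.loc[main_idx, "apex"]
    klass = np.where(out["apex"] < main_apex, "HMW",
                     np.where(out["apex"] > main_apex, "LMW", "mAb"))
    out["klass"] = klass
    return out


# ---------------------------------------------------------------------------
# gel densitometry
# ---------------------------------------------------------------------------

def _band_area(pos: np.ndarray, intensity: np.ndarray, window) -> tuple:
    """Background-subtracted band area within a window.

    Background is the straight line between the mean intensities just
    outside the two window edges; returns (area, background MAD).
    """
    lo, hi = window
    inside = (pos >= lo) & (pos <= hi)
    if inside.sum() < 3:
        raise ValueError(f"band window {window} covers too few points")
    step = np.median(np.diff(pos))
    edge = max(3, int(round(0.05 * (hi - lo) / step)))
    left_idx = np.nonzero(pos < lo)[0]
    right_idx = np.nonzero(pos > hi)[0]
    left = intensity[left_idx[-edge:]] if len(left_idx) else intensity[inside][:1]
    right = intensity[right_idx[:edge]] if len(right_idx) else intensity[inside][-1:]
    x0, y0 = (pos[left_idx[-edge:]].mean() if len(left_idx) else lo), left.mean()
    x1, y1 = (pos[right_idx[:edge]].mean() if len(right_idx) else hi), right.mean()
    bg = y0 + (y1 - y0) * (pos[inside] - x0) / (x1 - x0)
    resid = np.concatenate([left - left.mean(), right - right.mean()])
    mad = float(np.median(np.abs(resid - np.median(resid)))) if len(resid) else 0.0
    corrected = np.clip(intensity[inside] - bg, 0.0, None)
    return float(np.trapezoid(corrected, pos[inside])), mad


def lane_band_ratio(lane: pd.DataFrame, windows: dict, species_a: str = "fs",
                    species_b: str = "2HC", control_ratio: float = None) -> dict:
    """Band-intensity ratio of two species in one lane, and its FC.

    ``windows`` maps species -> (lo, hi) migration-coordinate windows.
    A denominator band below the detection floor (3x the local
    background MAD times the window width) yields ``ratio = None``
    flagged not-detected rather than infinity.
    """
    pos = lane["position"].to_numpy(dtype=float)
    intensity = lane["intensity"].to_numpy(dtype=float)
    for sp in (species_a, species_b):
        if sp not in windows:
            raise ValueError(f"no band window annotated for species {sp!r}")
    area_a, _ = _band_area(pos, intensity, windows[species_a])
    area_b, mad_b = _band_area(pos, intensity, windows[species_b])
    lo, hi = windows[species_b]
    floor = 3.0 * mad_b * (hi - lo)
    out = {"area_a": area_a, "area_b": area_b, "detected": area_b > floor}
    if not out["detected"]:
        out["ratio"] = None
        out["fc"] = None
        return out
    out["ratio"] = area_a / area_b
    out["fc"] = out["ratio"] / control_ratio if control_ratio else None
    return out


# ---------------------------------------------------------------------------
# helper-factor western-blot normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sumf1Obs:
    """Western-blot band intensities and culture densities for one sample.

    ``lysate_band`` and ``supernatant_band`` are raw band intensities;
    ``ladder55_band`` is the 55 kDa ladder band used for normalization;
    ``vcd_day4`` (cells/mL) normalizes the intracellular signal and
    ``ccd_0_4`` (cell*days/mL) the accumulated secreted signal.
    """

    lysate_band: float
    supernatant_band: float
    ladder55_band: float
    vcd_day4: float
    ccd_0_4: float

    def __post_init__(self):
        if self.ladder55_band <= 0:
            raise ValueError("ladder band intensity must be > 0")
        if self.vcd_day4 <= 0 or self.ccd_0_4 <= 0:
            raise ValueError("cell densities must be > 0")


def sumf1_relative_level(obs: Sumf1Obs, control: Sumf1Obs,
                         combine: str = "sum") -> float:
    """Relative helper-factor level versus the unregulated control.

    L = (lysate / ladder55) / vcd_day4,
    S = (supernatant / ladder55) / ccd_0_4; the two compartments are
    combined (sum by default, mean as an option) and divided by the
    control's combined value.
    """
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")

    def combined(o: Sumf1Obs) -> float:
        lys = (o.lysate_band / o.ladder55_band) / o.vcd_day4
        sup = (o.supernatant_band / o.ladder55_band) / o.ccd_0_4
        total = lys + sup
        return total / 2.0 if combine == "mean" else total

    denom = combined(control)
    if denom <= 0:
        raise ValueError("control has zero combined signal")
    return combined(obs) / denom
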