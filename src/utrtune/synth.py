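"""Synthetic-data generators with planted ground truth.

Every input the analysis modules consume can be emulated here with
planted ground truth: per-cell bivariate lognormal reporter
fluorescence with transfection-dose heterogeneity and a multiplicative
translation dosage on the RFP channel, untransfected/debris/doublet
subpopulations, qPCR CT tables, logistic batch growth with titer
accumulation proportional to integrated cell density, Gaussian-mixture
chromatograms and gel lanes, and a saturating helper-factor dose
response with a breakpoint.

Every generator is deterministic for a fixed config + seed, and every
dataset carries (or ships alongside) its planted truth.

Noise conventions: multiplicative lognormal for fluorescence and
culture observables, additive normal for CT and absorbance readings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlowSimConfig",
    "BatchSimConfig",
    "DoseResponseSimConfig",
    "simulate_flow_sample",
    "simulate_qpcr",
    "simulate_batch",
    "simulate_chromatogram",
    "simulate_gel_lanes",
    "GEL_BAND_POSITIONS",
    "simulate_sumf1_dose_response",
    "simulate_asa_assay",
    "write_with_truth",
]

# instrument model constants (arbitrary units; one place on purpose)
_FSC_CELL_LOG, _FSC_CELL_SD = np.log(5.0e4), 0.20
_SSC_CELL_LOG, _SSC_CELL_SD = np.log(3.0e4), 0.25
_FSC_DEBRIS_LOG, _FSC_DEBRIS_SD = np.log(6.0e3), 0.50
_SSC_DEBRIS_LOG, _SSC_DEBRIS_SD = np.log(2.0e3), 0.50
_SINGLET_JITTER = 0.02                 # SSC-A/SSC-H spread for true singlets
_AUTO_BFP_LOG, _AUTO_BFP_SD = np.log(60.0), 0.5   # overlaps the BFP gate
_AUTO_RFP_LOG, _AUTO_RFP_SD = np.log(0.2), 0.5
_RFP_GAIN = 1.0                        # RFP per unit (dose * dosage)


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class FlowSimConfig:
    """Parameters of one simulated flow-cytometry sample."""

    n_events: int = 150_000
    transfected_fraction: float = 0.6
    dosage: float = 1.0                 # planted translation factor (truth)
    bfp_log_mean: float = float(np.log(2000.0))
    bfp_log_sd: float = 0.8
    channel_noise_cv: float = 0.15
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.dosage < 0:
            raise ValueError("dosage must be >= 0")
        for name in ("transfected_fraction", "debris_fraction", "doublet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.debris_fraction + self.doublet_fraction > 1.0:
            raise ValueError("debris + doublet fractions exceed 1")
        if self.channel_noise_cv < 0:
            raise ValueError("channel_noise_cv must be >= 0")


def simulate_flow_sample(config: FlowSimConfig) -> pd.DataFrame:
    """One flow sample with per-event ``truth_label``.

    Transfected cells receive a lognormal plasmid dose D; BFP reports D
    and RFP reports ``dosage * D`` (both on top of an autofluorescence
    floor, both with multiplicative lognormal channel noise of median
    1 so geometric means are unbiased).  Labels partition the events
    into {transfected, untransfected, debris, doublet}.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    n_debris = int(round(config.debris_fraction * n))
    n_doublet = int(round(config.doublet_fraction * n))
    n_cells = n - n_debris - n_doublet
    n_trans = int(round(config.transfected_fraction * n_cells))
    n_untrans = n_cells - n_trans

    sigma = _cv_to_sigma(config.channel_noise_cv)

    def channel_noise(size):
        return rng.lognormal(0.0, sigma, size) if sigma > 0 else np.ones(size)

    def auto(size, mu, sd):
        return rng.lognormal(mu, sd, size)

    parts = []

    def scatter_block(size, doublet=False):
        fsc = rng.lognormal(_FSC_CELL_LOG, _FSC_CELL_SD, size)
        ssc_h = rng.lognormal(_SSC_CELL_LOG, _SSC_CELL_SD, size)
        factor = 2.0 if doublet else 1.0
        ssc_a = factor * ssc_h * rng.normal(1.0, _SINGLET_JITTER, size)
        if doublet:
            fsc = fsc * 1.8
        return fsc, ssc_a, ssc_h

    if n_trans:
        dose = rng.lognormal(config.bfp_log_mean, config.bfp_log_sd, n_trans)
        bfp = auto(n_trans, _AUTO_BFP_LOG, _AUTO_BFP_SD) + dose * channel_noise(n_trans)
        rfp = (auto(n_trans, _AUTO_RFP_LOG, _AUTO_RFP_SD)
               + config.dosage * _RFP_GAIN * dose * channel_noise(n_trans))
        fsc, ssc_a, ssc_h = scatter_block(n_trans)
        parts.append(pd.DataFrame({"fsc_a": fsc, "ssc_a": ssc_a, "ssc_h": ssc_h,
                                   "bfp": bfp, "rfp": rfp,
                                   "truth_label": "transfected"}))
    if n_untrans:
        fsc, ssc_a, ssc_h = scatter_block(n_untrans)
        parts.append(pd.DataFrame({"fsc_a": fsc, "ssc_a": ssc_a, "ssc_h": ssc_h,
                                   "bfp": auto(n_untrans, _AUTO_BFP_LOG, _AUTO_BFP_SD),
                                   "rfp": auto(n_untrans, _AUTO_RFP_LOG, _AUTO_RFP_SD),
                                   "truth_label": "untransfected"}))
    if n_doublet:
        # a doublet is transfected if either constituent cell is
        trans = rng.random(n_doublet) < config.transfected_fraction
        dose = (2.0 * rng.lognormal(config.bfp_log_mean, config.bfp_log_sd, n_doublet)
                * trans)
        fsc, ssc_a, ssc_h = scatter_block(n_doublet, doublet=True)
        parts.append(pd.DataFrame({"fsc_a": fsc, "ssc_a": ssc_a, "ssc_h": ssc_h,
                                   "bfp": auto(n_doublet, _AUTO_BFP_LOG, _AUTO_BFP_SD)
                                   + dose * channel_noise(n_doublet),
                                   "rfp": auto(n_doublet, _AUTO_RFP_LOG, _AUTO_RFP_SD)
                                   + config.dosage * _RFP_GAIN * dose * channel_noise(n_doublet),
                                   "truth_label": "doublet"}))
    if n_debris:
        fsc = rng.lognormal(_FSC_DEBRIS_LOG, _FSC_DEBRIS_SD, n_debris)
        ssc_h = rng.lognormal(_SSC_DEBRIS_LOG, _SSC_DEBRIS_SD, n_debris)
        parts.append(pd.DataFrame({"fsc_a": fsc,
                                   "ssc_a": ssc_h * rng.normal(1.0, 0.1, n_debris),
                                   "ssc_h": ssc_h,
                                   "bfp": auto(n_debris, _AUTO_BFP_LOG - 1.0, _AUTO_BFP_SD),
                                   "rfp": auto(n_debris, _AUTO_RFP_LOG, _AUTO_RFP_SD),
                                   "truth_label": "debris"}))
    table = pd.concat(parts, ignore_index=True)
    # shuffle so subpopulations are interleaved as on an instrument
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


def simulate_qpcr(rel_true: dict, control_sample: str = "CMV",
                  target_gene: str = "RFP", ref_gene: str = "GAPDH",
                  replicates: int = 4, ct_sd: float = 0.2, seed: int = 0,
                  base_ct_target: float = 22.0, base_ct_ref: float = 18.0) -> pd.DataFrame:
    """CT table planting a relative expression per sample.

    ``rel_true`` maps sample -> planted 2^-ddCT relative to the control
    (the control itself is added with rel 1 when absent).  Amplification
    efficiency is exactly 2, so CT_target(sample) =
    base - log2(rel); replicate noise is additive normal.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rel = dict(rel_true)
    rel.setdefault(control_sample, 1.0)
    rows = []
    for sample, r in rel.items():
        if r <= 0:
            raise ValueError(f"planted relative expression must be > 0 ({sample})")
        for gene, mean in ((target_gene, base_ct_target - np.log2(r)),
                           (ref_gene, base_ct_ref)):
            for rep in range(1, replicates + 1):
                rows.append({"sample": sample, "gene": gene, "replicate": rep,
                             "ct": mean + rng.normal(0.0, ct_sd)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BatchSimConfig:
    """Parameters of one simulated batch culture."""

    days: tuple = tuple(range(0, 9))
    vcd0: float = 0.3e6                 # cells/mL at day 0
    vcd_max: float = 6.0e6              # logistic carrying capacity
    growth_rate: float = 0.9            # 1/day
    qp_true: float = 2.0                # pg/cell/day (truth)
    viability_decline: float = 3.0      # %/day once VCD nears capacity
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.vcd0 >= self.vcd_max:
            raise ValueError("vcd0 must be < vcd_max")
        if self.qp_true < 0:
            raise ValueError("qp_true must be >= 0")
        if len(self.days) < 2:
            raise ValueError("need at least 2 sampling days")


def simulate_batch(config: BatchSimConfig) -> pd.DataFrame:
    """Daily VCD / viability / titer series; truth in ``df.attrs``.

    VCD follows logistic growth; titer is ``qp_true`` times the running
    trapezoidal integral of the *noise-free* VCD (pg -> ug conversion
    1e-6); observation noise is multiplicative lognormal with median 1.
    """
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days, dtype=float)
    r, k, v0 = config.growth_rate, config.vcd_max, config.vcd0
    if r == 0:
        vcd_true = np.full_like(days, v0)
    else:
        e = np.exp(r * days)
        vcd_true = k * v0 * e / (k + v0 * (e - 1.0))
    ivcd_true = np.concatenate(
        [[0.0], np.cumsum(0.5 * (vcd_true[1:] + vcd_true[:-1]) * np.diff(days))])
    titer_true = config.qp_true * ivcd_true * 1e-6   # ug/mL
    viability = np.where(vcd_true < 0.9 * config.vcd_max, 98.0,
                         98.0 - config.viability_decline
                         * np.maximum(days - days[np.argmax(vcd_true >= 0.9 * k)], 0.0))
    viability = np.clip(viability, 40.0, 100.0)
    sigma = _cv_to_sigma(config.noise_cv)
    noise = (lambda size: rng.lognormal(0.0, sigma, size)) if sigma > 0 \
        else (lambda size: np.ones(size))
    out = pd.DataFrame({"day": days,
                        "vcd": vcd_true * noise(len(days)),
                        "viability": viability,
                        "titer": titer_true * noise(len(days))})
    out.attrs["truth"] = {"qp_true": config.qp_true,
                          "vcd_true": vcd_true.tolist(),
                          "titer_true": titer_true.tolist()}
    return out


def simulate_chromatogram(fractions, centers=(8.0, 12.0, 17.0),
                          widths=(0.35, 0.45, 0.5), baseline_drift=(0.5, 0.02),
                          noise_sd: float = 0.0, seed: int = 0,
                          t_max: float = 25.0, n_points: int = 1500,
                          total_area: float = 50.0) -> pd.DataFrame:
    """Gaussian-mixture A280 trace with planted area fractions.

    ``fractions`` (summing to 1 or 100) give the area shares of the
    Gaussian peaks at ``centers``/``widths``; a linear baseline
    (offset, slope) and optional additive noise are superimposed.
    """
    fractions = np.asarray(fractions, dtype=float)
    if (fractions < 0).any() or fractions.sum() <= 0:
        raise ValueError("fractions must be nonnegative with positive sum")
    fractions = fractions / fractions.sum()
    centers = np.asarray(centers, dtype=float)[:len(fractions)]
    widths = np.asarray(widths, dtype=float)[:len(fractions)]
    if len(centers) != len(fractions) or len(widths) != len(fractions):
        raise ValueError("need one center and width per fraction")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    offset, slope = baseline_drift
    y = offset + slope * t
    for frac, mu, sd in zip(fractions, centers, widths):
        area = frac * total_area
        y = y + area / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_points)
    out = pd.DataFrame({"time_min": t, "a280": y})
    out.attrs["truth"] = {"fractions_pct": (100.0 * fractions).tolist(),
                          "centers": centers.tolist()}
    return out


#: Migration coordinate (arbitrary, increases with mobility) of each species.
GEL_BAND_POSITIONS = {"fs": 25.0, "HC-LC": 45.0, "2HC": 55.0, "HC": 70.0, "LC": 85.0}


def simulate_gel_lanes(band_amounts, spread: float = 1.5,
                       background: float = 5.0, noise_sd: float = 0.0,
                       seed: int = 0, n_points: int = 1000):
    """Densitometry profiles for one or more gel lanes.

    ``band_amounts`` is a list of dicts (one per lane) mapping species
    name -> integrated band amount.  Bands are Gaussians of common
    ``spread`` at the species' migration positions over a smooth
    background.  Returns ``(lanes, windows)`` where ``windows`` maps
    species -> (lo, hi) integration window (+-4 spreads).
    """
    if isinstance(band_amounts, dict):
        band_amounts = [band_amounts]
    rng = np.random.default_rng(seed)
    pos = np.linspace(0.0, 100.0, n_points)
    lanes = []
    for lane_bands in band_amounts:
        y = background * (1.0 + 0.002 * pos)   # gentle smooth background
        for species, amount in lane_bands.items():
            if species not in GEL_BAND_POSITIONS:
                raise ValueError(f"unknown species {species!r}")
            if amount < 0:
                raise ValueError("band amounts must be >= 0")
            mu = GEL_BAND_POSITIONS[species]
            y = y + amount / (spread * np.sqrt(2 * np.pi)) \
                * np.exp(-0.5 * ((pos - mu) / spread) ** 2)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, n_points)
        lane = pd.DataFrame({"position": pos, "intensity": y})
        lane.attrs["truth"] = dict(lane_bands)
        lanes.append(lane)
    windows = {sp: (mu - 4 * spread, mu + 4 * spread)
               for sp, mu in GEL_BAND_POSITIONS.items()}
    return lanes, windows


@dataclass(frozen=True)
class DoseResponseSimConfig:
    """Helper-factor dose-response generator parameters."""

    sumf1_levels: tuple = (0.05, 0.1, 0.2, 0.3, 0.4, 0.55, 0.7, 0.85, 1.0, 1.2)
    breakpoint: float = 0.4             # truth
    activity_plateau: float = 4.5       # U/mg (truth)
    qp_intercept: float = 2.0           # pg/cell/day at level 0 (truth)
    qp_slope: float = 1.2               # decline per unit level (truth)
    noise_sd: float = 0.15              # on activity, U/mg
    qp_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        lv = np.asarray(self.sumf1_levels, dtype=float)
        if not (lv.min() <= self.breakpoint <= lv.max()):
            raise ValueError("breakpoint must lie within the level range")
        if self.activity_plateau <= 0:
            raise ValueError("activity plateau must be > 0")


def simulate_sumf1_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """Activity saturating at the breakpoint; qP declining linearly."""
    rng = np.random.default_rng(config.seed)
    levels = np.asarray(config.sumf1_levels, dtype=float)
    activity = config.activity_plateau * np.minimum(levels / config.breakpoint, 1.0)
    qp = config.qp_intercept - config.qp_slope * levels
    out = pd.DataFrame({
        "level": levels,
        "specific_activity": activity + rng.normal(0.0, config.noise_sd, len(levels)),
        "qp": qp + rng.normal(0.0, config.qp_noise_sd, len(levels)),
    })
    out.attrs["truth"] = {"breakpoint": config.breakpoint,
                          "activity_plateau": config.activity_plateau,
                          "qp_intercept": config.qp_intercept,
                          "qp_slope": config.qp_slope}
    return out


def simulate_asa_assay(specific_activity_true: float, protein_conc_mg_ml: float,
                       std_curve=(0.012, 0.04), read_times=(0.0, 5.0, 10.0, 15.0),
                       sample_volume_ml: float = 0.1, noise_sd: float = 0.0,
                       seed: int = 0):
    """Timed A515 readings implied by a planted specific activity.

    The planted activity (U/mg) times the protein concentration gives
    U/mL; the product-formation rate in the reaction is
    ``U/mL * sample_volume * 1e3`` nmol/min, mapped to absorbance via
    the standard curve.  Returns an :class:`~utrtune.bioprocess.ActivityAssay`.
    """
    from .bioprocess import ActivityAssay

    if specific_activity_true < 0:
        raise ValueError("specific activity must be >= 0")
    rng = np.random.default_rng(seed)
    slope, intercept = std_curve
    u_per_ml = specific_activity_true * protein_conc_mg_ml
    rate_nmol_min = u_per_ml * sample_volume_ml * 1e3
    readings = []
    for t in read_times:
        a515 = intercept + slope * rate_nmol_min * t
        if noise_sd > 0:
            a515 += rng.normal(0.0, noise_sd)
        readings.append((float(t), float(a515)))
    return ActivityAssay(std_curve=(slope, intercept), readings=tuple(readings),
                         sample_volume_ml=sample_volume_ml,
                         protein_conc_mg_ml=protein_conc_mg_ml)


def write_with_truth(df: pd.DataFrame, path, truth: dict = None) -> None:
    """Write a dataset as CSV plus a sidecar JSON with the planted truth."""
    df.to_csv(path, index=False)
    truth = truth if truth is not None else df.attrs.get("truth", {})
    with open(str(path) + ".truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
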