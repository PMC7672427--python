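"""Single-cell ratiometric expression quantification.

Implements the flow-cytometry analysis chain: scatter viability gate,
SSC-A/SSC-H singlet gate, BFP-positivity gate against an untransfected
reference, then the per-cell RFP/BFP ratio whose geometric mean, taken
relative to the unregulated control sample, is the fold change (FC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "EVENT_COLUMNS",
    "GatingConfig",
    "SampleQuant",
    "validate_events",
    "gate_events",
    "ratiometric_fc",
    "fc_panel",
]

#: Required columns of a cell-event table.
EVENT_COLUMNS = ("fsc_a", "ssc_a", "ssc_h", "bfp", "rfp")


def validate_events(table: pd.DataFrame) -> pd.DataFrame:
    """Check a cell-event table for the required finite channels."""
    if len(table) == 0:
        raise ValueError("empty event table")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    vals = table[list(EVENT_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("event table contains non-finite channel values")
    return table


@dataclass(frozen=True)
class GatingConfig:
    """Gate parameters.

    The paper names the gates but gives no numeric boundaries, so the
    defaults here are calibrated to the synthetic instrument model and
    every one of them can be overridden.
    """

    fsc_min: float = 2.0e4
    fsc_max: float = 6.0e5
    ssc_min: float = 5.0e3
    ssc_max: float = 6.0e5
    singlet_tolerance: float = 0.15      # relative band around the median A/H ratio
    bfp_positive_quantile: float = 0.999

    def __post_init__(self):
        if not 0.5 < self.bfp_positive_quantile < 1.0:
            raise ValueError("bfp_positive_quantile must lie in (0.5, 1)")
        if self.singlet_tolerance <= 0:
            raise ValueError("singlet_tolerance must be > 0")


@dataclass(frozen=True)
class SampleQuant:
    """Quantification of one sample relative to a control."""

    name: str
    n_gated: int
    geo_mean_ratio: float
    fc: float
    n_dropped: int = 0
    sem: float = field(default=float("nan"))


def gate_events(table: pd.DataFrame, config: GatingConfig = GatingConfig(),
                untransfected_ref: pd.DataFrame = None) -> pd.DataFrame:
    """Apply the scatter -> singlet -> BFP-positivity gating chain.

    ``untransfected_ref`` supplies the BFP background distribution; the
    positivity threshold is its ``bfp_positive_quantile`` quantile.
    Event order is preserved.  Raises if the chain empties the table,
    reporting per-stage counts.
    """
    validate_events(table)
    if untransfected_ref is None or len(untransfected_ref) == 0:
        raise ValueError("untransfected reference table is required and nonempty")

    scatter = (table["fsc_a"].between(config.fsc_min, config.fsc_max)
               & table["ssc_a"].between(config.ssc_min, config.ssc_max))

    ratio = table["ssc_a"] / table["ssc_h"].replace(0, np.nan)
    center = float(np.nanmedian(ratio[scatter]))
    singlet = (ratio - center).abs() <= config.singlet_tolerance * center
    singlet = singlet.fillna(False)

    threshold = float(np.quantile(untransfected_ref["bfp"].to_numpy(dtype=float),
                                  config.bfp_positive_quantile))
    positive = table["bfp"] > threshold

    keep = scatter & singlet & positive
    counts = {"input": len(table), "scatter": int(scatter.sum()),
              "scatter+singlet": int((scatter & singlet).sum()),
              "scatter+singlet+bfp": int(keep.sum())}
    log.debug("gating counts: %s (bfp threshold %.3g)", counts, threshold)
    if counts["scatter+singlet+bfp"] == 0:
        raise ValueError(f"empty gate: {counts}")
    return table.loc[keep]


def _geo_mean_log(ratios: np.ndarray, sample: str):
    """Log-space geometric mean; nonpositive ratios are dropped."""
    ok = ratios > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("%s: dropped %d nonpositive per-cell ratios", sample, n_dropped)
        if n_dropped > 0.05 * len(ratios):
            warnings.warn(f"{sample}: >5% of per-cell ratios nonpositive "
                          f"({n_dropped}/{len(ratios)})")
    if ok.sum() == 0:
        raise ValueError(f"{sample}: all per-cell ratios nonpositive")
    logs = np.log(ratios[ok])
    return float(np.exp(logs.mean())), logs, n_dropped


def ratiometric_fc(sample: pd.DataFrame, control: pd.DataFrame,
                   name: str = "sample") -> SampleQuant:
    """Fold change of the per-cell RFP/BFP geometric mean vs the control.

    Both tables must already be gated.  r_i = rfp_i / bfp_i,
    G = exp(mean(ln r_i)), FC = G_sample / G_control.
    """
    validate_events(sample)
    validate_events(control)
    g_s, logs, n_drop = _geo_mean_log(
        (sample["rfp"] / sample["bfp"]).to_numpy(dtype=float), name)
    g_c, _, _ = _geo_mean_log(
        (control["rfp"] / control["bfp"]).to_numpy(dtype=float), "control")
    sem_log = float(logs.std(ddof=1) / np.sqrt(len(logs))) if len(logs) > 1 else float("nan")
    fc = g_s / g_c
    return SampleQuant(name=name, n_gated=len(logs), geo_mean_ratio=g_s,
                       fc=fc, n_dropped=n_drop, sem=fc * sem_log)


def fc_panel(samples: dict, control_name: str,
             replicate_groups: dict = None) -> pd.DataFrame:
    """Quantify a panel of gated samples against one named control.

    ``samples`` maps sample name -> gated event table.  When
    ``replicate_groups`` maps a group name to a list of sample names,
    per-group mean FC and SEM are appended.  Rows are ordered by mean
    fold change (ties by name).
    """
    if control_name not in samples:
        raise ValueError(f"control sample {control_name!r} not in panel")
    control = samples[control_name]
    rows = []
    for name in samples:
        q = ratiometric_fc(samples[name], control, name=name)
        rows.append({"sample": name, "n_gated": q.n_gated,
                     "geo_mean_ratio": q.geo_mean_ratio, "fc": q.fc,
                     "sem": q.sem})
    panel = pd.DataFrame(rows)
    if replicate_groups:
        fc_by_name = panel.set_index("sample")["fc"]
        grows = []
        for group, members in replicate_groups.items():
            vals = fc_by_name.loc[list(members)].to_numpy(dtype=float)
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else float("nan")
            grows.append({"group": group, "n_replicates": len(vals),
                          "mean_fc": vals.mean(), "sem": sem})
        groups = pd.DataFrame(grows).sort_values(
            ["mean_fc", "group"], kind="stable").reset_index(drop=True)
        return panel.sort_values(["fc", "sample"], kind="stable").reset_index(drop=True), groups
    return panel.sort_values(["fc", "sample"], kind="stable").reset_index(drop=True)
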