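"""Relative mRNA quantification from qPCR cycle thresholds.

2^-ddCT quantification against a reference gene and a control sample
(amplification efficiency fixed at exactly 2), the reporter-ratio
(RFP/BFP) mRNA fold change, and the RNA-to-protein fold-change ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "validate_ct_table",
    "delta_delta_ct",
    "mrna_ratio_fc",
    "rna_protein_ratio",
]

CT_COLUMNS = ("sample", "gene", "replicate", "ct")


def validate_ct_table(cts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in cts.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    ct = cts["ct"].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any() or (ct >= 45).any():
        raise ValueError("CT values must be finite and in (0, 45)")
    counts = cts.groupby(["sample", "gene"])["ct"].size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"fewer than 2 replicates for {bad}")
    return cts


def delta_delta_ct(cts: pd.DataFrame, target_gene: str, ref_gene: str,
                   control_sample: str) -> pd.DataFrame:
    """Per-sample relative expression by the 2^-ddCT method.

    Replicate CTs are averaged per (sample, gene) before differencing:
    dCT = CT_target - CT_ref, ddCT = dCT_sample - dCT_control,
    rel = 2^-ddCT.  A replicate SD above 0.5 cycles triggers a warning.
    """
    validate_ct_table(cts)
    means = cts.groupby(["sample", "gene"])["ct"].mean().unstack()
    sds = cts.groupby(["sample", "gene"])["ct"].std(ddof=1).unstack()
    for gene in (target_gene, ref_gene):
        if gene not in means.columns:
            raise ValueError(f"gene {gene!r} missing from CT table")
        absent = means.index[means[gene].isna()].tolist()
        if absent:
            raise ValueError(f"gene {gene!r} missing for samples {absent}")
    if control_sample not in means.index:
        raise ValueError(f"control sample {control_sample!r} missing from CT table")
    noisy = sds[[target_gene, ref_gene]].stack()
    noisy = noisy[noisy > 0.5]
    if len(noisy):
        warnings.warn(f"replicate CT SD > 0.5 cycles for {noisy.index.tolist()}")

    dct = means[target_gene] - means[ref_gene]
    ddct = dct - dct.loc[control_sample]
    out = pd.DataFrame({"sample": ddct.index, "gene": target_gene,
                        "ddct": ddct.to_numpy(dtype=float)})
    out["rel"] = np.exp2(-out["ddct"])
    return out.reset_index(drop=True)


def mrna_ratio_fc(rel_rfp: pd.DataFrame, rel_bfp: pd.DataFrame,
                  control_sample: str) -> pd.DataFrame:
    """Fold change of the RFP/BFP mRNA ratio relative to the control."""
    a = rel_rfp.set_index("sample")["rel"]
    b = rel_bfp.set_index("sample")["rel"]
    if set(a.index) != set(b.index):
        raise ValueError("RFP and BFP relative-expression tables list different samples")
    if control_sample not in a.index:
        raise ValueError(f"control sample {control_sample!r} missing")
    ratio = a / b
    fc = ratio / ratio.loc[control_sample]
    return pd.DataFrame({"sample": fc.index,
                         "fc_mrna": fc.to_numpy(dtype=float)}).reset_index(drop=True)


def rna_protein_ratio(fc_mrna: float, fc_protein: float) -> float:
    """RNA-to-protein fold-change ratio for one element."""
    if fc_mrna <= 0 or fc_protein <= 0:
        raise ValueError("fold changes must be > 0")
    return fc_mrna / fc_protein
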