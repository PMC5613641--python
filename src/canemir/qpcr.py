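"""Stem-loop RT-qPCR analysis: -ddCt relative expression and
cross-platform correlation with sequencing TPM.

Ct values above the cap (35 cycles) are set to the cap before replicate
averaging.  For each (sample, assay), dCt = Ct(assay) - Ct(reference),
ddCt = dCt(sample) - dCt(calibrator sample), and the relatively
normalised expression is RNE = 2 ** -ddCt; the calibrator sample is 1 by
construction for every assay.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

__all__ = ["cap_ct", "relative_expression", "correlate_platforms"]

_CT_COLUMNS = ["sample", "assay", "replicate", "ct"]


def cap_ct(ct: pd.Series | np.ndarray, cap: float = RunConfig.ct_cap) -> np.ndarray:
    """Replace Ct values greater than the cap by the cap (idempotent)."""
    return np.minimum(np.asarray(ct, dtype=float), cap)


def relative_expression(
    ct_table: pd.DataFrame,
    reference_assay: str,
    calibrator_sample: str,
    cap: float = RunConfig.ct_cap,
) -> pd.DataFrame:
    """-ddCt relative expression per (sample, assay).

    ``ct_table`` needs columns sample, assay, replicate, ct (one row per
    technical replicate).  Replicates are aggregated by arithmetic mean
    of the capped Ct; the per-assay SD of capped Ct is reported.
    """
    missing = [c for c in _CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle numbers")
    work = ct_table.copy()
    work["ct"] = cap_ct(work["ct"], cap)
    mean_ct = work.groupby(["sample", "assay"])["ct"].agg(["mean", "std", "count"])
    samples = mean_ct.index.get_level_values("sample").unique()
    for sample in samples:
        if (sample, reference_assay) not in mean_ct.index:
            raise ValueError(f"reference assay {reference_assay!r} missing in sample {sample!r}")
    if calibrator_sample not in set(samples):
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from Ct table")

    rows = []
    ref_ct = {s: mean_ct.loc[(s, reference_assay), "mean"] for s in samples}
    dct = {
        (s, a): mean_ct.loc[(s, a), "mean"] - ref_ct[s]
        for s, a in mean_ct.index
        if a != reference_assay
    }
    for (sample, assay), delta in dct.items():
        if (calibrator_sample, assay) not in dct:
            raise ValueError(
                f"assay {assay!r} missing in calibrator sample {calibrator_sample!r}"
            )
        ddct = delta - dct[(calibrator_sample, assay)]
        rows.append(
            {
                "sample": sample,
                "assay": assay,
                "mean_ct": mean_ct.loc[(sample, assay), "mean"],
                "sd_ct": mean_ct.loc[(sample, assay), "std"],
                "dct": delta,
                "ddct": ddct,
                "rne": 2.0 ** (-ddct),
            }
        )
    out = pd.DataFrame(rows).sort_values(["assay", "sample"]).reset_index(drop=True)
    return out


def correlate_platforms(
    rne: pd.DataFrame,
    tpm: pd.DataFrame,
    assay_to_mirna: Mapping[str, str],
    calibrator_sample: str,
    log_scale: bool = True,
    pseudocount: float = 0.25,
) -> tuple[float, int]:
    """Pearson correlation of qPCR RNE against sequencing TPM ratios.

    Observations are paired by (miRNA, sample); the sequencing value is
    the TPM ratio to the calibrator sample (with a pseudocount guarding
    zeros).  By default both platforms are compared on log2 scale.
    Returns (r, number of pairs); fewer than 3 pairs is an error.
    """
    xs, ys = [], []
    for _, row in rne.iterrows():
        mirna = assay_to_mirna.get(row["assay"])
        if mirna is None or mirna not in tpm.index:
            continue
        sample = row["sample"]
        if sample not in tpm.columns or calibrator_sample not in tpm.columns:
            continue
        ratio = (tpm.loc[mirna, sample] + pseudocount) / (
            tpm.loc[mirna, calibrator_sample] + pseudocount
        )
        if log_scale:
            xs.append(np.log2(row["rne"]))
            ys.append(np.log2(ratio))
        else:
            xs.append(row["rne"])
            ys.append(ratio)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(xs)}")
    r, _ = stats.pearsonr(xs, ys)
    return float(r), len(xs)
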