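"""miRNA expression profiling: counting, TPM normalisation, presence sets.

A clean read contributes to a mature miRNA's count iff it aligns to the
precursor with zero mismatches and overlaps the mature interval by more
than 18 nt (strict).  Counts are normalised per sample as

    TPM = 1e6 * mapped_reads / total_clean_reads

i.e. the denominator is the library's total clean reads, not the reads
mapping to miRNAs (the two differ by roughly an order of magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .discovery import PreMiRNA
from .io import normalize_t

__all__ = ["ExpressionMatrix", "count_mature", "tpm_normalize", "presence_sets", "filter_low_tpm"]


@dataclass
class ExpressionMatrix:
    """miRNA x sample raw counts and TPM, plus per-sample clean totals."""

    counts: pd.DataFrame          # int, miRNA x sample
    tpm: pd.DataFrame             # float, same shape
    total_clean_reads: pd.Series  # per sample

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.tpm.columns):
            raise ValueError("counts and tpm must share sample columns")


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All 0-based start offsets of ``needle`` in ``haystack``."""
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def count_mature(
    collapsed: pd.DataFrame,
    precursors: Sequence[PreMiRNA],
    min_overlap: int = RunConfig.count_min_overlap,
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw read counts per mature miRNA per sample.

    ``collapsed`` is the unique-sequence x sample table from
    :func:`canemir.preprocess.collapse_reads`.  A read counts for every
    miRNA it matches (multi-miRNA reads are flagged in the returned
    boolean Series).  Overlap with the mature interval must be strictly
    greater than ``min_overlap`` nucleotides.
    """
    ids = [p.id for p in precursors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate precursor ids")
    for p in precursors:
        m0, m1 = p.mature_local()
        if not (0 <= m0 <= m1 < len(p.sequence)):
            raise ValueError(f"mature interval of {p.id} outside its precursor")

    counts = pd.DataFrame(0, index=ids, columns=collapsed.columns, dtype=int)
    multi = pd.Series(False, index=pd.Index(collapsed.index, name="sequence"))
    for seq, row in collapsed.iterrows():
        seq_n = normalize_t(str(seq))
        hit_ids = []
        for p in precursors:
            m0, m1 = p.mature_local()
            for off in _occurrences(seq_n, p.sequence):
                lo = max(off, m0)
                hi = min(off + len(seq_n) - 1, m1)
                if hi - lo + 1 > min_overlap:
                    hit_ids.append(p.id)
                    break
        for pid in hit_ids:
            counts.loc[pid] += row.astype(int)
        if len(hit_ids) > 1:
            multi[seq] = True
    counts.index.name = "mirna"
    return counts, multi


def tpm_normalize(
    counts: pd.DataFrame, total_clean_reads: Mapping[str, int] | pd.Series
) -> ExpressionMatrix:
    """Normalise raw counts to TPM using total clean reads per sample."""
    totals = pd.Series(total_clean_reads, dtype=float).reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"missing total clean reads for sample(s) {missing}")
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive total clean reads for sample(s) {bad}")
    tpm = 1e6 * counts.astype(float) / totals
    return ExpressionMatrix(counts=counts, tpm=tpm, total_clean_reads=totals.astype(int))


def presence_sets(
    tpm: pd.DataFrame, threshold: float = RunConfig.detect_tpm
) -> tuple[dict[str, set[str]], dict[str, object]]:
    """Per-sample detected miRNA sets at a strict TPM threshold.

    A miRNA is detected in a sample iff its TPM is strictly greater than
    ``threshold``.  The summary reports the common-to-all intersection
    and, per sample, the miRNAs exclusive to that sample.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    detected = {s: set(tpm.index[tpm[s] > threshold]) for s in tpm.columns}
    if detected:
        common = set.intersection(*detected.values()) if len(detected) else set()
    else:
        common = set()
    exclusive = {
        s: mems - set.union(set(), *(m for t, m in detected.items() if t != s))
        for s, mems in detected.items()
    }
    summary = {
        "detected": {s: len(m) for s, m in detected.items()},
        "common_all": len(common),
        "exclusive": {s: len(m) for s, m in exclusive.items()},
    }
    return detected, summary


def filter_low_tpm(
    matrix: ExpressionMatrix, floor: float = RunConfig.floor_tpm
) -> ExpressionMatrix:
    """Drop miRNAs whose TPM never exceeds ``floor`` in any sample.

    Membership is strict: a miRNA at exactly ``floor`` TPM everywhere is
    removed.
    """
    keep = (matrix.tpm > floor).any(axis=1)
    return ExpressionMatrix(
        counts=matrix.counts.loc[keep],
        tpm=matrix.tpm.loc[keep],
        total_clean_reads=matrix.total_clean_reads,
    )
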