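"""isomiR / SNP scanning in mature miRNAs.

Clean reads are aligned to the predicted precursors allowing at most one
substitution.  Perfect-match reads overlapping the mature interval feed
the normal count; reads with exactly one substitution located inside the
mature interval become variant candidates (single-substitution isomiRs).
Reads whose sole mismatch lies outside the mature interval are
discarded, as are reads with two or more substitutions.  Counting
mirrors the expression stage: the read/mature overlap must exceed 18 nt.

Kept variants must reach 10 total reads and a pooled
variant/(variant+normal) ratio of 1% (both boundaries inclusive: the
published conditions are removal rules "< 10 reads" and "< 1%").
miRNAs carrying two or more surviving substitution positions are dropped
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .discovery import PreMiRNA
from .io import normalize_t
from . import targets as _targets

__all__ = ["VariantMiRNA", "call_variant_mirnas", "filter_variants", "annotate_variant"]

SEED_REGION = (2, 7)  # miRNA positions (1-based, inclusive) of the seed


@dataclass
class VariantMiRNA:
    """A single-substitution isomiR of a mature miRNA."""

    mirna_id: str
    position: int                  # 1-based offset from the mature 5' end
    ref: str
    alt: str
    variant_counts: dict[str, int] = field(default_factory=dict)
    normal_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("variant must substitute a different base")

    @property
    def total_variant(self) -> int:
        return sum(self.variant_counts.values())

    @property
    def total_normal(self) -> int:
        return sum(self.normal_counts.values())

    @property
    def ratio(self) -> float:
        denom = self.total_variant + self.total_normal
        return self.total_variant / denom if denom else 0.0

    @property
    def in_seed(self) -> bool:
        return SEED_REGION[0] <= self.position <= SEED_REGION[1]


_VAR_K = 9  # seed size: a read >= 18 nt with <= 1 mismatch has an exact half


def _precursor_index(precursors: Sequence[PreMiRNA]) -> dict[str, set[tuple[int, int]]]:
    """k-mer -> {(precursor idx, position)} over all precursor sequences."""
    index: dict[str, set[tuple[int, int]]] = {}
    for pi, p in enumerate(precursors):
        seq = p.sequence
        for pos in range(len(seq) - _VAR_K + 1):
            index.setdefault(seq[pos : pos + _VAR_K], set()).add((pi, pos))
    return index


def _candidate_offsets(
    read: str, index: Mapping[str, set[tuple[int, int]]]
) -> dict[int, set[int]]:
    """Possible (precursor, offset) placements with <= 1 substitution, by
    the pigeonhole principle: one of the two read halves must be exact."""
    out: dict[int, set[int]] = {}
    for off in (0, len(read) // 2):
        if off + _VAR_K > len(read):
            continue
        for pi, pos in index.get(read[off : off + _VAR_K], ()):
            out.setdefault(pi, set()).add(pos - off)
    return out


def _align_one_mismatch(
    read: str, precursor: str, offsets: set[int] | None = None
) -> tuple[int, int] | None:
    """Best ungapped alignment of read to precursor with <= 1 substitution.

    Returns (0-based offset, mismatch offset within read or -1) for the
    alignment with fewest mismatches (leftmost on ties), else None.
    ``offsets`` restricts the candidate placements (seed prefilter).
    """
    best: tuple[int, int] | None = None
    pool = (
        range(len(precursor) - len(read) + 1)
        if offsets is None
        else sorted(o for o in offsets if 0 <= o <= len(precursor) - len(read))
    )
    for off in pool:
        mism_at = -1
        n_mism = 0
        for i, (a, b) in enumerate(zip(read, precursor[off : off + len(read)])):
            if a != b:
                n_mism += 1
                if n_mism > 1:
                    break
                mism_at = i
        else:
            if n_mism == 0:
                return off, -1
            if best is None:
                best = (off, mism_at)
    return best


def call_variant_mirnas(
    collapsed: pd.DataFrame,
    precursors: Sequence[PreMiRNA],
    min_overlap: int = RunConfig.count_min_overlap,
) -> tuple[list[VariantMiRNA], pd.DataFrame]:
    """Detect single-substitution variants of each mature miRNA.

    Returns the candidate list and the per-miRNA normal (perfect-match)
    count table.  Candidates are keyed by (miRNA, position, ref, alt)
    with per-sample counts aggregated over all supporting reads.
    """
    samples = list(collapsed.columns)
    normal = pd.DataFrame(0, index=[p.id for p in precursors], columns=samples, dtype=int)
    index = _precursor_index(precursors)
    cands: dict[tuple[str, int, str, str], VariantMiRNA] = {}
    for seq, row in collapsed.iterrows():
        read = normalize_t(str(seq))
        counts = row.astype(int)
        placements = _candidate_offsets(read, index)
        for pi, offsets in placements.items():
            p = precursors[pi]
            hit = _align_one_mismatch(read, p.sequence, offsets)
            if hit is None:
                continue
            off, mism_at = hit
            m0, m1 = p.mature_local()
            lo = max(off, m0)
            hi = min(off + len(read) - 1, m1)
            if hi - lo + 1 <= min_overlap:
                continue
            if mism_at == -1:
                normal.loc[p.id] += counts
                continue
            pos_pre = off + mism_at            # precursor-local mismatch site
            if not m0 <= pos_pre <= m1:
                continue                        # substitution outside the mature arm
            position = pos_pre - m0 + 1         # 1-based from the mature 5' end
            ref = p.sequence[pos_pre]
            alt = read[mism_at]
            key = (p.id, position, ref, alt)
            if key not in cands:
                cands[key] = VariantMiRNA(p.id, position, ref, alt)
            acc = cands[key].variant_counts
            for s in samples:
                acc[s] = acc.get(s, 0) + int(counts[s])
    out = list(cands.values())
    for v in out:
        v.normal_counts = {s: int(normal.loc[v.mirna_id, s]) for s in samples}
    out.sort(key=lambda v: (v.mirna_id, v.position, v.ref, v.alt))
    normal.index.name = "mirna"
    return out, normal


def filter_variants(
    candidates: Sequence[VariantMiRNA],
    min_reads: int = RunConfig.variant_min_reads,
    min_ratio: float = RunConfig.variant_min_ratio,
) -> list[VariantMiRNA]:
    """Apply the expression and ratio filters, then the multi-SNP rule.

    A candidate survives iff total variant reads >= ``min_reads`` AND
    pooled ratio >= ``min_ratio``.  miRNAs with two or more distinct
    surviving substitution positions are excluded entirely.
    """
    surviving = [
        v for v in candidates if v.total_variant >= min_reads and v.ratio >= min_ratio
    ]
    positions: dict[str, set[int]] = {}
    for v in surviving:
        positions.setdefault(v.mirna_id, set()).add(v.position)
    return [v for v in surviving if len(positions[v.mirna_id]) < 2]


def annotate_variant(
    variant: VariantMiRNA,
    mature_seq: str,
    transcripts: Mapping[str, str],
    max_score: float = RunConfig.target_max_score,
    mfe_min_ratio: float = RunConfig.target_mfe_min_ratio,
) -> dict[str, object]:
    """Seed-region flag and normal-vs-variant retargeting report.

    The variant mature sequence is the normal mature with the single
    substitution applied; target sets are predicted for both forms and
    diffed (shared / lost / gained transcript ids).
    """
    mature = normalize_t(mature_seq)
    if mature[variant.position - 1] != variant.ref:
        raise ValueError(
            f"reference base mismatch at position {variant.position}: "
            f"mature has {mature[variant.position - 1]}, variant says {variant.ref}"
        )
    var_seq = (
        mature[: variant.position - 1] + variant.alt + mature[variant.position :]
    )
    normal_targets = {
        s.transcript_id
        for s in _targets.predict_targets(
            variant.mirna_id, mature, transcripts, max_score, mfe_min_ratio
        )
    }
    variant_targets = {
        s.transcript_id
        for s in _targets.predict_targets(
            variant.mirna_id + "V", var_seq, transcripts, max_score, mfe_min_ratio
        )
    }
    shared, lost, gained = _targets.compare_target_sets(normal_targets, variant_targets)
    return {
        "mirna_id": variant.mirna_id,
        "position": variant.position,
        "ref": variant.ref,
        "alt": variant.alt,
        "in_seed": variant.in_seed,
        "variant_seq": var_seq,
        "shared": shared,
        "lost": lost,
        "gained": gained,
    }
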