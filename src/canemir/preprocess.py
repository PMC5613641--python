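"""Read cleaning, collapsing, and length-distribution summaries.

Cleaning removes the 3' adapter, reads whose insert is shorter than 18 nt
or longer than 30 nt, and low-quality reads (mean Phred below a cutoff).
Unique clean sequences are then collapsed to a sequence x sample count
table, the working unit of every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import config
from .io import RawRead

__all__ = ["CleanStats", "clean_reads", "collapse_reads", "length_distribution"]


@dataclass
class CleanStats:
    """Per-library cleaning accounting; raw = clean + sum(discards)."""

    raw: int = 0
    clean: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {"no_adapter": 0, "short": 0, "long": 0, "low_quality": 0}
    )

    def conserved(self) -> bool:
        return self.raw == self.clean + sum(self.discarded.values())


def find_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = config.RunConfig.adapter_min_overlap,
    max_mismatch: int = config.RunConfig.adapter_max_mismatch,
) -> int | None:
    """Leftmost start of the 3' adapter in ``sequence``, or None.

    A prefix of the adapter must match at the candidate position with at
    most ``max_mismatch`` substitutions; the matched prefix may run off
    the read's 3' end but must cover at least ``min_overlap`` bases.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(sequence)
    for pos in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - pos)
        mism = 0
        for a, b in zip(adapter[:overlap], sequence[pos : pos + overlap]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return pos
    return None


def clean_reads(
    raw: Iterable[RawRead],
    adapter: str = config.TRUSEQ_SMALL_RNA_ADAPTER,
    min_len: int = config.RunConfig.min_len,
    max_len: int = config.RunConfig.max_len,
    min_mean_q: float = config.RunConfig.min_mean_q,
    *,
    adapter_min_overlap: int = config.RunConfig.adapter_min_overlap,
    adapter_max_mismatch: int = config.RunConfig.adapter_max_mismatch,
    require_adapter: bool = True,
) -> tuple[list[str], CleanStats]:
    """Trim adapters and filter by insert length and mean quality.

    Reads with no adapter match are discarded when ``require_adapter`` is
    True (a short-RNA insert is always followed by adapter on the
    sequencer); with ``require_adapter=False`` such reads are kept whole,
    which makes cleaning idempotent on already-trimmed input.
    """
    stats = CleanStats()
    kept: list[str] = []
    for read in raw:
        stats.raw += 1
        pos = find_adapter(
            read.sequence, adapter, adapter_min_overlap, adapter_max_mismatch
        )
        if pos is None:
            if require_adapter:
                stats.discarded["no_adapter"] += 1
                continue
            pos = len(read.sequence)
        insert = read.sequence[:pos]
        quals = read.quality[:pos]
        if len(insert) < min_len:
            stats.discarded["short"] += 1
        elif len(insert) > max_len:
            stats.discarded["long"] += 1
        elif quals and sum(quals) / len(quals) < min_mean_q:
            stats.discarded["low_quality"] += 1
        else:
            stats.clean += 1
            kept.append(insert)
    return kept, stats


def collapse_reads(clean_per_sample: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Collapse clean sequences to a unique-sequence x sample count table.

    The returned frame is indexed by sequence with one integer column per
    sample; column sums equal each sample's clean-read count and the row
    order is deterministic (lexicographic) regardless of input order.
    """
    samples = list(clean_per_sample)
    counters = {
        sample: pd.Series(list(seqs), dtype="object").value_counts()
        for sample, seqs in clean_per_sample.items()
    }
    table = pd.DataFrame(counters).fillna(0).astype(int)
    table = table.reindex(columns=samples).sort_index()
    table.index.name = "sequence"
    return table


def length_distribution(
    clean: Iterable[str],
    min_len: int = config.RunConfig.min_len,
    max_len: int = config.RunConfig.max_len,
) -> pd.Series:
    """Histogram of clean-read lengths over the fixed 18..30 bins."""
    hist = pd.Series(0, index=range(min_len, max_len + 1), name="reads")
    hist.index.name = "length"
    for seq in clean:
        n = len(seq)
        if min_len <= n <= max_len:
            hist[n] += 1
    return hist
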