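"""Rule-based plant miRNA target prediction.

Every transcript window of miRNA length is scored as an ungapped
antisense duplex (miRNA position 1 = 5' end, paired against the window
read 3'->5').  Positional states are match, G:U wobble, or mismatch; the
mismatch score counts a full mismatch as 1 and a wobble as 0.5.  A site
passes when the six criteria hold:

  i.   mismatch score <= 3 over the whole duplex,
  ii.  no more than two adjacent mismatches anywhere,
  iii. no adjacent mismatches within positions 2-12,
  iv.  no mismatches at positions 10-11 (the cleavage site),
  v.   mismatch score <= 2.5 within positions 1-12,
  vi.  duplex energy >= 75% of the miRNA bound to its perfect complement
       (energies computed with the same per-pair model as the folding
       engine: G:C -3, A:U -2, G:U -1 kcal/mol, mismatch 0).

G:U wobbles count as half a mismatch toward rules i and v and, by the
conservative default, as mismatches for the adjacency rules ii/iii and
the cleavage-site rule iv (``gu_in_adjacency=False`` relaxes ii/iii).
Duplexes are ungapped: no target-side bulges are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import RunConfig
from .io import normalize_t

__all__ = [
    "MATCH",
    "GU",
    "MISMATCH",
    "DuplexSite",
    "duplex_states",
    "find_candidate_sites",
    "score_duplex",
    "duplex_mfe_ratio",
    "predict_targets",
    "compare_target_sets",
]

MATCH, GU, MISMATCH = 0, 1, 2

_PENALTY = {MATCH: 0.0, GU: 0.5, MISMATCH: 1.0}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# pairwise duplex energies (kcal/mol) by state and miRNA base
_PAIR_E = {"G": -3.0, "C": -3.0, "A": -2.0, "T": -2.0}


@dataclass
class DuplexSite:
    """A candidate miRNA/target duplex on a transcript window."""

    mirna_id: str
    transcript_id: str
    start: int                      # 1-based window start on the transcript
    end: int                        # 1-based inclusive
    mirna_seq: str                  # 5'->3', T alphabet
    states: tuple[int, ...]         # per miRNA position 1..L
    mismatch_score: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.mirna_seq):
            raise ValueError("state vector length must equal miRNA length")
        self.mismatch_score = float(sum(_PENALTY[s] for s in self.states))

    def runs(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive non-match states as (start, end)
        1-based miRNA positions (the adjacency ledger)."""
        out: list[tuple[int, int]] = []
        run_start = None
        for pos, s in enumerate(self.states, 1):
            if s != MATCH and run_start is None:
                run_start = pos
            elif s == MATCH and run_start is not None:
                out.append((run_start, pos - 1))
                run_start = None
        if run_start is not None:
            out.append((run_start, len(self.states)))
        return out


def duplex_states(mirna: str, window: str) -> tuple[int, ...]:
    """Positional states of an ungapped antisense duplex.

    miRNA position i (1-based from its 5' end) faces transcript window
    base L - i (0-based): the target is read 3'->5' against the miRNA.
    """
    m = normalize_t(mirna)
    w = normalize_t(window)
    if len(m) != len(w):
        raise ValueError("window length must equal miRNA length")
    states = []
    L = len(m)
    for i in range(1, L + 1):
        mb, tb = m[i - 1], w[L - i]
        if tb == _COMP[mb]:
            states.append(MATCH)
        elif (mb == "G" and tb == "T") or (mb == "T" and tb == "G"):
            states.append(GU)
        else:
            states.append(MISMATCH)
    return tuple(states)


def find_candidate_sites(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    max_score: float = RunConfig.target_max_score,
) -> list[DuplexSite]:
    """Enumerate every transcript window whose mismatch score <= max_score.

    This is the rule-i pre-screen; all windows are scanned exhaustively
    (vectorised over window positions, no heuristic skipping).
    """
    m = normalize_t(mirna)
    if not 18 <= len(m) <= 25:
        raise ValueError(f"miRNA length {len(m)} outside [18, 25]")
    t = normalize_t(transcript)
    L = len(m)
    if len(t) < L:
        return []
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    tv = np.array([codes.get(c, 4) for c in t], dtype=np.int8)
    windows = np.lib.stride_tricks.sliding_window_view(tv, L)
    # miRNA position i faces window column L - i  -> reverse the window
    rev = windows[:, ::-1]
    mv = np.array([codes[c] for c in m], dtype=np.int8)
    comp = np.array([3, 2, 1, 0], dtype=np.int8)[mv]          # complement code
    is_match = rev == comp[None, :]
    is_gu = ((mv == 2)[None, :] & (rev == 3)) | ((mv == 3)[None, :] & (rev == 2))
    penalty = np.where(is_match, 0.0, np.where(is_gu, 0.5, 1.0))
    scores = penalty.sum(axis=1)
    sites = []
    for off in np.flatnonzero(scores <= max_score):
        states = tuple(
            MATCH if is_match[off, i - 1] else (GU if is_gu[off, i - 1] else MISMATCH)
            for i in range(1, L + 1)
        )
        sites.append(
            DuplexSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                start=int(off) + 1,
                end=int(off) + L,
                mirna_seq=m,
                states=states,
            )
        )
    return sites


def score_duplex(
    site: DuplexSite, gu_in_adjacency: bool = RunConfig.target_gu_in_adjacency
) -> tuple[bool, list[str]]:
    """Apply rules i-v; returns (passes, list of failed rule names)."""
    states = site.states
    failed: list[str] = []
    if site.mismatch_score > 3.0:
        failed.append("i")
    bad = (
        (lambda s: s != MATCH) if gu_in_adjacency else (lambda s: s == MISMATCH)
    )
    run = best_run = 0
    for s in states:
        run = run + 1 if bad(s) else 0
        best_run = max(best_run, run)
    if best_run > 2:
        failed.append("ii")
    hi = min(12, len(states))
    if any(bad(states[p - 1]) and bad(states[p]) for p in range(2, hi)):
        failed.append("iii")
    if len(states) >= 11 and (states[9] != MATCH or states[10] != MATCH):
        failed.append("iv")
    seed_score = sum(_PENALTY[s] for s in states[:12])
    if seed_score > 2.5:
        failed.append("v")
    return (not failed, failed)


def duplex_mfe_ratio(
    site: DuplexSite, min_ratio: float = RunConfig.target_mfe_min_ratio
) -> tuple[float, bool]:
    """Rule vi: duplex energy relative to the perfect-complement duplex.

    ratio = E(duplex) / E(perfect); both energies are negative, so the
    ratio lies in [0, 1] and the site passes iff ratio >= min_ratio
    (inclusive boundary).
    """
    duplex_e = 0.0
    perfect_e = 0.0
    for base, state in zip(site.mirna_seq, site.states):
        perfect_e += _PAIR_E[base]
        if state == MATCH:
            duplex_e += _PAIR_E[base]
        elif state == GU:
            duplex_e += -1.0
    if perfect_e == 0.0:
        raise ValueError("perfect-complement energy is zero; ratio undefined")
    ratio = duplex_e / perfect_e
    return ratio, ratio >= min_ratio


def predict_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Mapping[str, str],
    max_score: float = RunConfig.target_max_score,
    mfe_min_ratio: float = RunConfig.target_mfe_min_ratio,
    gu_in_adjacency: bool = RunConfig.target_gu_in_adjacency,
) -> list[DuplexSite]:
    """All sites passing rules i-vi, across a transcript set."""
    hits = []
    for tid, tseq in transcripts.items():
        for site in find_candidate_sites(mirna_id, mirna, tid, tseq, max_score):
            ok_rules, _ = score_duplex(site, gu_in_adjacency)
            if not ok_rules:
                continue
            _, ok_mfe = duplex_mfe_ratio(site, mfe_min_ratio)
            if ok_mfe:
                hits.append(site)
    return hits


def compare_target_sets(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two target-gene sets into (shared, lost, gained)."""
    a, b = set(set_a), set(set_b)
    return a & b, a - b, b - a
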