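"""Hairpin-based miRNA discovery on a transcriptome reference.

Collapsed reads are mapped to transcripts (substitutions only, <= 2
mismatches, <= 20 loci), read-supported arms seed candidate precursors,
each candidate is folded and validated against the eight precursor
parameters (mature length 18-25 nt, arm spacing 16-300 nt, duplex bulge
<= 4 nt, energy <= -18 kcal/mol, 20-nt flanks), redundant precursors
overlapping > 80% are merged, and mature products are classified as
conserved (> 90% catalog identity and > 10 reads) or novel.

Folding engine
--------------
The default folder is a Nussinov-style dynamic program (minimum hairpin
loop 3) that minimises a simple stacked-pair energy: G:C -3, A:U -2,
G:U -1 kcal/mol per pair.  It is not a nearest-neighbour thermodynamic
model; the -18 kcal/mol precursor threshold applies to whichever engine
is active and is an explicit knob.  Any callable with the signature
``engine(seq) -> (dot_bracket, energy)`` can be plugged in instead
(e.g. an external RNAfold wrapper).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .config import HairpinParams, RunConfig
from .io import VALID_BASES, normalize_t, revcomp

__all__ = [
    "Alignment",
    "PreMiRNA",
    "map_reads",
    "fold_rna",
    "pair_table",
    "predict_hairpins",
    "merge_precursors",
    "classify_conserved",
    "levenshtein",
]

#: per-pair energies of the built-in folding engine (kcal/mol, model-relative)
PAIR_ENERGIES: dict[frozenset[str], float] = {
    frozenset("GC"): -3.0,
    frozenset("AT"): -2.0,
    frozenset("GT"): -1.0,
}

MIN_LOOP = 3  # minimum hairpin loop length enforced by the folder

_SEED_K = 6  # k-mer size of the mapping index; 18 nt / (2 mm + 1) = 6


@dataclass(frozen=True)
class Alignment:
    """An ungapped read-to-transcript alignment (sense strand only)."""

    read: str
    transcript_id: str
    start: int  # 1-based, inclusive
    mismatches: int
    strand: str = "+"

    @property
    def end(self) -> int:  # 1-based, inclusive
        return self.start + len(self.read) - 1


@dataclass
class PreMiRNA:
    """A predicted miRNA precursor with its arm annotation.

    Intervals are 1-based closed coordinates on the source transcript.
    """

    id: str
    transcript_id: str
    start: int                      # precursor start on transcript
    sequence: str                   # precursor incl. flanks
    structure: str                  # dot-bracket from the active engine
    energy: float                   # kcal/mol, model-relative
    mature: tuple[int, int]         # mature arm interval (transcript coords)
    star: tuple[int, int]           # star arm interval (transcript coords)
    arm: str                        # "5p" | "3p": mature position vs the loop
    mature_seq: str
    mature_count: int               # reads supporting the mature arm
    star_count: int = 0             # reads supporting the star arm (may be 0)
    label: str = "novel"            # {"conserved", "novel"}
    best_hit: str | None = None     # catalog name of the closest match

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def mature_local(self) -> tuple[int, int]:
        """Mature interval in 0-based precursor-local coordinates."""
        return self.mature[0] - self.start, self.mature[1] - self.start


# ---------------------------------------------------------------------------
# read mapping
# ---------------------------------------------------------------------------

def _kmer_index(transcripts: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tid, seq in transcripts.items():
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((tid, pos))
    return index


def _hamming_leq(a: str, b: str, cap: int) -> int | None:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > cap:
                return None
    return mism


def map_reads(
    reads: Iterable[str],
    transcripts: Mapping[str, str],
    max_mismatch: int = RunConfig.max_mismatch,
    max_loci: int = HairpinParams.max_copy,
) -> tuple[dict[str, list[Alignment]], set[str]]:
    """Map unique read sequences to the sense strand of transcripts.

    Substitutions only (no indels), at most ``max_mismatch`` of them.
    Reads aligning to more than ``max_loci`` loci are returned in the
    flagged set; their alignments are reported but hairpin seeding skips
    them (the multi-copy cap of the discovery parameter set).

    Seeding uses the pigeonhole principle: a read is split into
    ``max_mismatch + 1`` blocks and at least one block must match
    exactly, so exact 6-mer seeds from each block find every valid locus
    for reads of length >= 18.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    index = _kmer_index(transcripts, _SEED_K)
    alignments: dict[str, list[Alignment]] = {}
    flagged: set[str] = set()
    for read in reads:
        read = normalize_t(read)
        L = len(read)
        if L < _SEED_K:
            continue
        block = L // (max_mismatch + 1)
        offsets = sorted({i * block for i in range(max_mismatch + 1)})
        seen: set[tuple[str, int]] = set()
        hits: list[Alignment] = []
        for off in offsets:
            if off + _SEED_K > L:
                continue
            for tid, pos in index.get(read[off : off + _SEED_K], ()):
                start = pos - off
                if start < 0 or start + L > len(transcripts[tid]):
                    continue
                if (tid, start) in seen:
                    continue
                seen.add((tid, start))
                mism = _hamming_leq(read, transcripts[tid][start : start + L], max_mismatch)
                if mism is not None:
                    hits.append(Alignment(read, tid, start + 1, mism))
        if hits:
            hits.sort(key=lambda a: (a.transcript_id, a.start))
            alignments[read] = hits
            if len(hits) > max_loci:
                flagged.add(read)
    return alignments, flagged


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def _pair_energy_matrix(seq: str, objective: str) -> np.ndarray:
    n = len(seq)
    e = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            val = PAIR_ENERGIES.get(frozenset((seq[i], seq[j])))
            if val is not None:
                e[i, j] = -1.0 if objective == "pairs" else val
    return e


def fold_rna(
    sequence: str,
    objective: str = "energy",
    engine: Callable[[str], tuple[str, float]] | None = None,
) -> tuple[str, float]:
    """Fold an RNA sequence into a nested secondary structure.

    Returns ``(dot_bracket, score)`` where the score is the summed pair
    energy (kcal/mol, model-relative) for ``objective="energy"`` or the
    negated base-pair count for ``objective="pairs"``.  ``engine``
    overrides the built-in folder entirely (thermodynamic plug-in hook).
    """
    if engine is not None:
        return engine(sequence)
    seq = normalize_t(sequence)
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} < 10 nt)")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide character(s) in sequence: {sorted(bad)}")
    if objective not in ("energy", "pairs"):
        raise ValueError(f"unknown folding objective {objective!r}")

    n = len(seq)
    e = _pair_energy_matrix(seq, objective)
    # S[i+1, j+1] holds the optimum for the closed interval [i, j];
    # padding rows/cols make empty-interval lookups read 0.
    S = np.zeros((n + 2, n + 2))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = S[i + 2, j + 1]  # i unpaired
            ks = np.arange(i + MIN_LOOP + 1, j + 1)
            vals = e[i, ks] + S[i + 2, ks] + S[ks + 2, j + 1]
            vmin = vals.min()
            if vmin < best:
                best = vmin
            S[i + 1, j + 1] = best

    structure = ["."] * n

    def trace(i: int, j: int) -> None:
        while j - i > MIN_LOOP:
            target = S[i + 1, j + 1]
            if target == S[i + 2, j + 1]:  # leaving i unpaired is optimal
                i += 1
                continue
            # ties broken toward the farthest partner: among equal-energy
            # optima this favours long-range stems (hairpin arms) over
            # incidental pairing with nearby loop bases
            for k in range(j, i + MIN_LOOP, -1):
                if math.isinf(e[i, k]):
                    continue
                if target == e[i, k] + S[i + 2, k] + S[k + 2, j + 1]:
                    structure[i] = "("
                    structure[k] = ")"
                    trace(i + 1, k - 1)
                    i = k + 1
                    break
            else:  # pragma: no cover - defensive; recurrence always resolves
                raise RuntimeError("fold traceback failed")

    trace(0, n - 1)
    return "".join(structure), float(S[1, n])


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    stack: list[int] = []
    partners = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partners[i], partners[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partners


# ---------------------------------------------------------------------------
# hairpin prediction
# ---------------------------------------------------------------------------

def _window_matches(tseq: str, rc: str, starts: np.ndarray) -> np.ndarray:
    """Match counts of ``rc`` against windows of ``tseq`` at ``starts``."""
    L = len(rc)
    tv = np.frombuffer(tseq.encode(), dtype=np.uint8)
    rcv = np.frombuffer(rc.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tv, L)
    return (windows[starts] == rcv[None, :]).sum(axis=1)


def _best_star_offset(
    tseq: str, m0: int, m1: int, mature_seq: str, params: HairpinParams
) -> tuple[int, int, int] | None:
    """Scan both sides of the mature arm for the best reverse-complement
    match; returns 0-based (star_start, star_end, matches) or None.

    ``m0``/``m1`` are 0-based inclusive mature bounds on the transcript.
    Candidate star starts respect the allowed arm spacing; the scan is
    exhaustive over both directions (vectorised).
    """
    rc = revcomp(mature_seq)
    L = len(mature_seq)
    max_start = len(tseq) - L
    if max_start < 0:
        return None
    down = np.arange(m1 + 1 + params.min_space, m1 + 1 + params.max_space + 1)
    up = np.arange(m0 - params.max_space - L, m0 - params.min_space - L + 1)
    starts = np.concatenate([down[(down >= 0) & (down <= max_start)],
                             up[(up >= 0) & (up <= max_start)]])
    if starts.size == 0:
        return None
    matches = _window_matches(tseq, rc, starts)
    best_i = int(np.argmax(matches))
    best_matches = int(matches[best_i])
    # the ungapped scan expects a mostly contiguous duplex; 85% exact
    # reverse-complement identity keeps random windows out while any real
    # star arm (small bulges included) clears it easily
    if best_matches < math.ceil(0.85 * L):
        return None
    s0 = int(starts[best_i])
    return s0, s0 + L - 1, best_matches




def predict_hairpins(
    alignments: Mapping[str, list[Alignment]],
    read_counts: Mapping[str, int],
    transcripts: Mapping[str, str],
    params: HairpinParams = HairpinParams(),
    flagged: frozenset[str] | set[str] = frozenset(),
    engine: Callable[[str], tuple[str, float]] | None = None,
) -> list[PreMiRNA]:
    """Predict candidate precursors from read-supported arms.

    Every perfect-match alignment of a read of mature length seeds a
    candidate.  The star arm is located by exhaustive reverse-complement
    scanning within the allowed arm spacing (16-300 nt); the duplex
    geometry (star interval, arm spacing) comes from that ungapped scan,
    while the folding engine supplies the precursor structure and the
    energy gate.  A candidate is kept only if every parameter bound
    holds.  Candidates seeded from the star arm of a real hairpin are
    produced too and collapse onto the mature-seeded precursor in
    :func:`merge_precursors` (the higher-count arm wins).

    The ungapped scan means a bulged mature/star duplex is recovered
    only while its exact reverse-complement identity stays >= 85%; the
    duplex bulge bound is enforced implicitly (an ungapped duplex has
    bulge 0).
    """
    # candidate arms: (transcript, start, read) with perfect match
    seeds: list[tuple[int, str, int, str]] = []
    for read, hits in alignments.items():
        if read in flagged:
            continue
        if not params.min_mature <= len(read) <= params.max_mature:
            continue
        count = int(read_counts.get(read, 0))
        for aln in hits:
            if aln.mismatches == 0:
                seeds.append((count, aln.transcript_id, aln.start, read))
    # deterministic order: strongest arms first
    seeds.sort(key=lambda s: (-s[0], s[1], s[2], s[3]))

    # perfect alignments grouped by transcript, for star-support lookup
    perfect_by_tid: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for r2, hits2 in alignments.items():
        c2 = int(read_counts.get(r2, 0))
        for a2 in hits2:
            if a2.mismatches == 0:
                perfect_by_tid[a2.transcript_id].append((a2.start, a2.end, c2))

    out: list[PreMiRNA] = []
    seen_locus: set[tuple[str, int, int]] = set()
    for count, tid, start1, read in seeds:
        tseq = transcripts[tid]
        m0, m1 = start1 - 1, start1 - 1 + len(read) - 1
        locus = (tid, m0, m1)
        if locus in seen_locus:
            continue
        seen_locus.add(locus)
        star = _best_star_offset(tseq, m0, m1, read, params)
        if star is None:
            continue
        s0, s1, _ = star
        p0 = max(0, min(m0, s0) - params.flank)
        p1 = min(len(tseq) - 1, max(m1, s1) + params.flank)
        precursor = tseq[p0 : p1 + 1]
        structure, energy = fold_rna(precursor, engine=engine)
        if energy > params.max_energy:
            continue
        star_iv = (s0 + 1, s1 + 1)  # 1-based transcript coords
        mature_iv = (m0 + 1, m1 + 1)
        if star_iv[0] > mature_iv[1]:
            space = star_iv[0] - mature_iv[1] - 1
            arm = "5p"
        elif mature_iv[0] > star_iv[1]:
            space = mature_iv[0] - star_iv[1] - 1
            arm = "3p"
        else:
            continue  # overlapping arms: not a fold-back
        if not params.min_space <= space <= params.max_space:
            continue
        # star read support: perfect-match reads inside the star interval
        star_count = sum(
            c2
            for s2, e2, c2 in perfect_by_tid.get(tid, ())
            if s2 >= star_iv[0] and e2 <= star_iv[1]
        )
        out.append(
            PreMiRNA(
                id=f"{tid}|{mature_iv[0]}|{arm}",
                transcript_id=tid,
                start=p0 + 1,
                sequence=precursor,
                structure=structure,
                energy=energy,
                mature=mature_iv,
                star=star_iv,
                arm=arm,
                mature_seq=read,
                mature_count=count,
                star_count=star_count,
            )
        )
    return out


def merge_precursors(candidates: Sequence[PreMiRNA]) -> list[PreMiRNA]:
    """Collapse precursors overlapping > 80% of the shorter one.

    The retained representative has the higher mature read count, ties
    broken by longer precursor then lexicographically smaller id; the
    procedure is order-invariant and idempotent.
    """
    ranked = sorted(
        candidates, key=lambda c: (-c.mature_count, -len(c.sequence), c.id)
    )
    kept: list[PreMiRNA] = []
    for cand in ranked:
        redundant = False
        for other in kept:
            if other.transcript_id != cand.transcript_id:
                continue
            ov = min(cand.end, other.end) - max(cand.start, other.start) + 1
            if ov <= 0:
                continue
            frac = ov / min(len(cand.sequence), len(other.sequence))
            if frac > 0.80:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda c: (c.transcript_id, c.start, c.id))
    return kept


# ---------------------------------------------------------------------------
# conserved / novel classification
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitution/insertion/deletion, unit costs)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def classify_conserved(
    matures: Mapping[str, tuple[str, int]],
    catalog: Mapping[str, str],
    min_identity: float = RunConfig.conserved_min_identity,
    min_reads: int = RunConfig.conserved_min_reads,
) -> dict[str, tuple[str, str | None, float]]:
    """Label each mature miRNA conserved or novel against a known catalog.

    conserved iff best identity > ``min_identity`` AND mapped reads
    > ``min_reads`` (both strict); identity is
    ``1 - levenshtein / max(lengths)``.  Returns
    ``id -> (label, best_hit_name, best_identity)``.
    """
    if not catalog:
        raise ValueError("known-miRNA catalog is empty")
    cat = {name: normalize_t(seq) for name, seq in catalog.items()}
    out: dict[str, tuple[str, str | None, float]] = {}
    for mid, (seq, reads) in matures.items():
        seq = normalize_t(seq)
        best_name, best_ident = None, -1.0
        for name, cseq in cat.items():
            ident = 1.0 - levenshtein(seq, cseq) / max(len(seq), len(cseq))
            if ident > best_ident or (ident == best_ident and name < str(best_name)):
                best_name, best_ident = name, ident
        label = (
            "conserved"
            if best_ident > min_identity and reads > min_reads
            else "novel"
        )
        out[mid] = (label, best_name, best_ident)
    return out
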