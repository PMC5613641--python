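"""Synthetic small-RNA world with known ground truth.

Generates reference transcripts carrying planted miRNA hairpins
(mature arm, >= 16 nt loop, reverse-complement star arm, flanks) and
near-complementary target sites; simulates two-group read libraries with
negative-binomial per-sample counts, planted group fold changes,
single-substitution variant reads at controlled fractions, a 3' adapter
on every read, and a junk-read admixture; and writes the whole fixture
set (FASTQ/FASTA/TSV/config) to disk.  Every planted object is recorded
in a :class:`TruthManifest` so downstream recovery is checkable.

The defaults state the emulated world once: six libraries (two groups of
three), read lengths peaking at 21 and 24 nt, log-uniform per-miRNA
abundance, NB dispersion 0.1, 4-fold planted changes, and variant
fractions straddling the 10-read / 1% filters.  They are not tuning
knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import discovery
from .config import TRUSEQ_SMALL_RNA_ADAPTER, RunConfig
from .io import RawRead, revcomp, write_fasta, write_fastq, write_tsv

__all__ = [
    "PlantedHairpin",
    "PlantedVariant",
    "PlantedTargetSite",
    "TruthManifest",
    "simulate_reference",
    "simulate_library",
    "write_fixtures",
]

BASES = np.array(list("ACGT"))

#: low-abundance tail of mature lengths; the abundant products are pinned
#: to the dominant 21 nt (miRNA) and 24 nt (siRNA-like) classes
MATURE_TAIL_LENS = (20, 22, 23, 21, 24)
#: background (non-miRNA) clean-read lengths, same two peaks
BACKGROUND_LEN_P = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.37, 22: 0.08, 23: 0.07,
    24: 0.27, 25: 0.04, 26: 0.02, 27: 0.015, 28: 0.015, 29: 0.01, 30: 0.01,
}

_GOOD_Q = 40
_JUNK_Q = 10


@dataclass(frozen=True)
class PlantedHairpin:
    mirna_id: str
    transcript_id: str
    start: int                   # 1-based precursor start on the transcript
    precursor_seq: str
    mature: tuple[int, int]      # 1-based transcript coords, inclusive
    star: tuple[int, int]
    mature_seq: str


@dataclass(frozen=True)
class PlantedVariant:
    mirna_id: str
    position: int                # 1-based from the mature 5' end
    ref: str
    alt: str
    fraction: float              # per-sample substitution fraction in (0, 1)


@dataclass(frozen=True)
class PlantedTargetSite:
    mirna_id: str
    transcript_id: str
    start: int                   # 1-based site start on the transcript
    designed_score: float        # intended duplex mismatch score
    for_variant: bool = False    # site engineered against the variant form


@dataclass
class TruthManifest:
    planted_hairpins: list[PlantedHairpin]
    planted_fold_changes: dict[str, float]
    planted_variants: list[PlantedVariant]
    planted_target_sites: list[PlantedTargetSite]
    dispersion: float
    seed: int
    baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.planted_hairpins:
            if not 18 <= h.mature[1] - h.mature[0] + 1 <= 25:
                raise ValueError(f"{h.mirna_id}: mature length outside [18, 25]")
        for v in self.planted_variants:
            if not 0.0 < v.fraction < 1.0:
                raise ValueError(f"{v.mirna_id}: variant fraction outside (0, 1)")
        for m, fc in self.planted_fold_changes.items():
            if fc <= 0:
                raise ValueError(f"{m}: fold change must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def hairpin(self, mirna_id: str) -> PlantedHairpin:
        for h in self.planted_hairpins:
            if h.mirna_id == mirna_id:
                return h
        raise KeyError(mirna_id)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _choice_len(rng: np.random.Generator, law: Mapping[int, float]) -> int:
    lens = np.array(list(law))
    p = np.array(list(law.values()))
    return int(rng.choice(lens, p=p / p.sum()))


def _mutate_site(rc: str, mature: str, score: float) -> tuple[str, float]:
    """Degrade a perfect-complement site to a designed mismatch score.

    Penalties are placed in the 3' half of the miRNA (positions >= 13,
    non-adjacent, away from 10-11) so the site still passes the
    acceptance rules.  Returns (site sequence, achieved score).
    site position for miRNA position i (1-based) is rc index L - i.
    """
    site = list(rc)
    L = len(mature)
    achieved = 0.0
    full_positions = [13, 15, 17, 19]
    # wobble positions chosen never adjacent to the full-mismatch ones the
    # default scores can reach (13, 15), so planted sites pass rules ii/iii
    gu_positions = [21, 17, 19]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    remaining = score
    used: set[int] = set()
    for pos in full_positions:
        if remaining < 1.0 or pos > L:
            break
        mb = mature[pos - 1]
        # any base that is neither the complement nor a wobble partner
        for alt in "ACGT":
            wobble = (mb == "G" and alt == "T") or (mb == "T" and alt == "G")
            if alt != comp[mb] and not wobble:
                site[L - pos] = alt
                achieved += 1.0
                remaining -= 1.0
                used.add(pos)
                break
    if remaining >= 0.5:
        for pos in gu_positions:
            if pos > L or pos in used:
                continue
            mb = mature[pos - 1]
            if mb == "G":
                site[L - pos] = "T"
            elif mb == "T":
                site[L - pos] = "G"
            else:
                continue
            achieved += 0.5
            break
    return "".join(site), achieved


def simulate_reference(
    n_transcripts: int = 30,
    n_hairpins: int = 20,
    seed: int = 0,
    *,
    transcript_len: tuple[int, int] = (400, 900),
    loop_range: tuple[int, int] = (16, 40),
    dispersion: float = 0.1,
    n_up: int = 4,
    n_down: int = 2,
    fold_change_up: float = 4.0,
    fold_change_down: float = 0.25,
    variant_fractions: Sequence[float] = (0.4, 0.1, 0.002),
    target_site_scores: Sequence[float] = (0.0, 1.5, 2.5),
    validate: bool = True,
) -> tuple[dict[str, str], TruthManifest]:
    """Build a transcript set with planted hairpins, sites and truth.

    One hairpin per transcript on the first ``n_hairpins`` transcripts;
    target sites and background reads use the hairpin-free transcripts.
    With ``validate=True`` each planted precursor is folded by
    :func:`canemir.discovery.fold_rna` and checked against the energy
    threshold (construction guarantees it; the check is cheap insurance).
    """
    if n_hairpins > n_transcripts:
        raise ValueError(
            f"n_hairpins ({n_hairpins}) must not exceed n_transcripts ({n_transcripts})"
        )
    if n_hairpins < 1:
        raise ValueError("need at least one hairpin")
    rng = np.random.default_rng(seed)
    tids = [f"tx{i:04d}" for i in range(n_transcripts)]
    transcripts: dict[str, str] = {}
    hairpins: list[PlantedHairpin] = []
    flank = RunConfig().hairpin.flank

    # abundance first, then lengths: the read-weighted length profile must
    # peak at 21 and 24 nt, so the dominant products alternate between
    # those two classes and minority lengths sit in the low-weight tail
    weights = 10.0 ** rng.uniform(0.0, 3.0, size=n_hairpins)
    mature_lens = np.empty(n_hairpins, dtype=int)
    n_head = max(4, int(round(0.7 * n_hairpins)))
    for r, idx in enumerate(np.argsort(-weights)):
        if r < n_head:
            mature_lens[idx] = 21 if r % 2 == 0 else 24
        else:
            mature_lens[idx] = MATURE_TAIL_LENS[r % len(MATURE_TAIL_LENS)]

    for i, tid in enumerate(tids):
        length = int(rng.integers(transcript_len[0], transcript_len[1] + 1))
        seq = _random_seq(rng, length)
        if i < n_hairpins:
            mlen = int(mature_lens[i])
            mature = _random_seq(rng, mlen)
            loop = _random_seq(rng, int(rng.integers(loop_range[0], loop_range[1] + 1)))
            insert = mature + loop + revcomp(mature)
            pos = int(rng.integers(flank, max(flank + 1, length - len(insert) - flank)))
            seq = seq[:pos] + insert + seq[pos + len(insert):]
            mirna_id = f"syn-miR{i + 1:03d}"
            m0 = pos + 1                                  # 1-based mature start
            star0 = pos + mlen + len(loop) + 1
            p_start = max(1, m0 - flank)
            p_end = min(len(seq), star0 + mlen - 1 + flank)
            hairpins.append(
                PlantedHairpin(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    start=p_start,
                    precursor_seq=seq[p_start - 1 : p_end],
                    mature=(m0, m0 + mlen - 1),
                    star=(star0, star0 + mlen - 1),
                    mature_seq=mature,
                )
            )
        transcripts[tid] = seq

    # per-miRNA abundance: log-uniform so most miRNAs sit in the low-TPM bulk
    baseline = {h.mirna_id: float(w) for h, w in zip(hairpins, weights)}

    # planted group fold changes on mid/high-abundance miRNAs (detectable)
    by_abund = sorted(hairpins, key=lambda h: -baseline[h.mirna_id])
    fold_changes = {h.mirna_id: 1.0 for h in hairpins}
    de_pool = [h.mirna_id for h in by_abund[3 : 3 + n_up + n_down]]
    for mid in de_pool[:n_up]:
        fold_changes[mid] = fold_change_up
    for mid in de_pool[n_up : n_up + n_down]:
        fold_changes[mid] = fold_change_down

    # planted variants on the most abundant miRNAs, first one pinned in seed
    variants: list[PlantedVariant] = []
    for k, frac in enumerate(variant_fractions):
        if k >= len(by_abund):
            break
        host = by_abund[k].mature_seq
        mid = by_abund[k].mirna_id
        position = 6 if k == 0 else int(rng.integers(1, len(host) + 1))
        ref = host[position - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        variants.append(PlantedVariant(mid, position, ref, str(alt), float(frac)))

    # planted target sites on hairpin-free transcripts (skipped when every
    # transcript carries a hairpin: sites would corrupt the planted loci)
    sites: list[PlantedTargetSite] = []
    site_hosts = tids[n_hairpins:]
    if site_hosts:
        # scored sites belong to the DE-planted miRNAs first, so the
        # up/down target sets downstream contain planted signal
        owners = de_pool + [h.mirna_id for h in by_abund]
        by_id = {h.mirna_id: h for h in hairpins}
        for k, score in enumerate(target_site_scores):
            h = by_id[owners[k % len(owners)]]
            tid = site_hosts[k % len(site_hosts)]
            site_seq, achieved = _mutate_site(revcomp(h.mature_seq), h.mature_seq, score)
            tseq = transcripts[tid]
            pos = int(rng.integers(10, len(tseq) - len(site_seq) - 10))
            transcripts[tid] = tseq[:pos] + site_seq + tseq[pos + len(site_seq):]
            sites.append(PlantedTargetSite(h.mirna_id, tid, pos + 1, achieved))

    if site_hosts and variants:
        # retargeting pair for the seed variant: one site only the normal form
        # accepts, one site only the variant form accepts (extra mismatch at
        # position 7 becomes adjacent to the position-6 substitution).
        var = variants[0]
        host = next(h for h in hairpins if h.mirna_id == var.mirna_id)
        var_mature = (
            host.mature_seq[: var.position - 1] + var.alt + host.mature_seq[var.position :]
        )
        for form_seq, for_variant in ((host.mature_seq, False), (var_mature, True)):
            site_seq, achieved = _mutate_site_at(revcomp(form_seq), form_seq, position=7)
            tid = site_hosts[(len(target_site_scores) + int(for_variant)) % len(site_hosts)]
            tseq = transcripts[tid]
            pos = int(rng.integers(10, len(tseq) - len(site_seq) - 10))
            transcripts[tid] = tseq[:pos] + site_seq + tseq[pos + len(site_seq):]
            sites.append(
                PlantedTargetSite(var.mirna_id, tid, pos + 1, achieved, for_variant)
            )

    manifest = TruthManifest(
        planted_hairpins=hairpins,
        planted_fold_changes=fold_changes,
        planted_variants=variants,
        planted_target_sites=sites,
        dispersion=float(dispersion),
        seed=int(seed),
        baseline=baseline,
    )
    if validate:
        for h in hairpins:
            _, energy = discovery.fold_rna(h.precursor_seq)
            if energy > RunConfig().hairpin.max_energy:
                raise AssertionError(
                    f"planted precursor {h.mirna_id} folds above the energy threshold"
                )
    return transcripts, manifest


def _mutate_site_at(rc: str, mature: str, position: int) -> tuple[str, float]:
    """Perfect-complement site with one full mismatch at a given miRNA
    position (used to engineer normal/variant retargeting differences)."""
    site = list(rc)
    L = len(mature)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mb = mature[position - 1]
    for alt in "ACGT":
        wobble = (mb == "G" and alt == "T") or (mb == "T" and alt == "G")
        if alt != comp[mb] and not wobble:
            site[L - position] = alt
            break
    return "".join(site), 1.0


def group_design(n_per_group: int = 3) -> dict[str, str]:
    """The two-group sample map: three control (LPSP-like) and three
    treatment (LASP-like) libraries by default."""
    design = {f"LPSP_{i + 1}": "LPSP" for i in range(n_per_group)}
    design.update({f"LASP_{i + 1}": "LASP" for i in range(n_per_group)})
    return design


def _nb_counts(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi == 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return int(rng.poisson(lam))


def simulate_library(
    manifest: TruthManifest,
    transcripts: Mapping[str, str],
    n_per_group: int = 3,
    depth: int = 20000,
    seed: int | None = None,
    *,
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    read_len: int = 36,
    junk_fraction: float = 0.03,
    background_fraction: float = 0.35,
    phi: float | None = None,
) -> tuple[dict[str, list[RawRead]], pd.DataFrame, pd.DataFrame]:
    """Simulate FASTQ-like reads for the two-group design.

    Returns ``(reads per sample, true miRNA counts, true variant counts)``;
    the count tables are the sidecar truth for recovery checks.  miRNA
    counts are NB(baseline share of depth x fold change, phi), variant
    reads are Binomial(count, fraction) with the substitution applied,
    every read carries the 3' adapter (then truncated to ``read_len``),
    and ``junk_fraction`` of reads are too short or low-quality.
    Background reads are drawn from hairpin-free transcripts with the
    21/24-peaked length law, so they clean up fine but never touch a
    mature arm.
    """
    if not manifest.planted_hairpins:
        raise ValueError("manifest has no planted hairpins")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(manifest.seed + 1 if seed is None else seed)
    phi = manifest.dispersion if phi is None else phi
    design = group_design(n_per_group)
    samples = list(design)
    mirna_ids = [h.mirna_id for h in manifest.planted_hairpins]
    weights = np.array([manifest.baseline[m] for m in mirna_ids])
    weights = weights / weights.sum()
    mirna_share = depth * (1.0 - junk_fraction - background_fraction)

    variant_by_mirna = {v.mirna_id: v for v in manifest.planted_variants}
    hairpin_tids = {h.transcript_id for h in manifest.planted_hairpins}
    bg_tids = [t for t in transcripts if t not in hairpin_tids] or list(transcripts)

    truth = pd.DataFrame(0, index=mirna_ids, columns=samples, dtype=int)
    truth_var = pd.DataFrame(0, index=mirna_ids, columns=samples, dtype=int)
    reads: dict[str, list[RawRead]] = {}
    qual_cache: dict[tuple[int, int], list[int]] = {}

    def make_read(sample: str, idx: int, insert: str, q: int) -> RawRead:
        seq = (insert + adapter)[:read_len]
        qual = qual_cache.setdefault((len(seq), q), [q] * len(seq))
        return RawRead(id=f"{sample}_{idx}", sequence=seq, quality=qual)

    for sample in samples:
        group = design[sample]
        out: list[RawRead] = []
        idx = 0
        for h, w in zip(manifest.planted_hairpins, weights):
            fc = manifest.planted_fold_changes[h.mirna_id] if group == "LASP" else 1.0
            mean = mirna_share * w * fc
            count = _nb_counts(rng, mean, phi)
            var = variant_by_mirna.get(h.mirna_id)
            n_var = int(rng.binomial(count, var.fraction)) if var is not None else 0
            truth.loc[h.mirna_id, sample] = count
            truth_var.loc[h.mirna_id, sample] = n_var
            if var is not None:
                var_seq = (
                    h.mature_seq[: var.position - 1]
                    + var.alt
                    + h.mature_seq[var.position :]
                )
            for _ in range(count - n_var):
                out.append(make_read(sample, idx, h.mature_seq, _GOOD_Q))
                idx += 1
            for _ in range(n_var):
                out.append(make_read(sample, idx, var_seq, _GOOD_Q))
                idx += 1
            # sparse star-arm support (~10% of the mature arm)
            star_seq = revcomp(h.mature_seq)
            for _ in range(int(rng.poisson(0.1 * mean))):
                out.append(make_read(sample, idx, star_seq, _GOOD_Q))
                idx += 1
        n_bg = int(rng.poisson(depth * background_fraction))
        for _ in range(n_bg):
            tid = bg_tids[int(rng.integers(len(bg_tids)))]
            L = _choice_len(rng, BACKGROUND_LEN_P)
            tseq = transcripts[tid]
            pos = int(rng.integers(0, len(tseq) - L))
            out.append(make_read(sample, idx, tseq[pos : pos + L], _GOOD_Q))
            idx += 1
        n_junk = int(rng.poisson(depth * junk_fraction))
        for j in range(n_junk):
            if j % 2 == 0:
                insert = _random_seq(rng, int(rng.integers(10, 18)))
                out.append(make_read(sample, idx, insert, _GOOD_Q))
            else:
                out.append(make_read(sample, idx, _random_seq(rng, 21), _JUNK_Q))
            idx += 1
        reads[sample] = out
    truth.index.name = "mirna"
    truth_var.index.name = "mirna"
    return reads, truth, truth_var


def write_fixtures(
    outdir: str | Path,
    n_transcripts: int = 30,
    n_hairpins: int = 20,
    seed: int = 0,
    depth: int = 20000,
    n_per_group: int = 3,
    catalog_fraction: float = 0.5,
) -> dict[str, object]:
    """Generate and write the complete fixture set.

    Emits the transcript FASTA, one FASTQ per sample (two groups of
    ``n_per_group``), a known-miRNA catalog FASTA (a seeded half of the
    planted matures under catalog names, plus decoys), a gene-to-term
    annotation TSV, truth tables, and a YAML run config naming samples
    and groups.  Re-running with the same seed reproduces every file
    byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, manifest = simulate_reference(n_transcripts, n_hairpins, seed)
    reads, truth, truth_var = simulate_library(
        manifest, transcripts, n_per_group=n_per_group, depth=depth
    )
    rng = np.random.default_rng(seed + 17)

    write_fasta(transcripts, outdir / "transcripts.fasta")
    paths: dict[str, str] = {"transcripts": str(outdir / "transcripts.fasta")}
    for sample, rlist in reads.items():
        p = outdir / f"reads_{sample}.fastq"
        write_fastq(rlist, p)
        paths[f"reads_{sample}"] = str(p)

    # catalog: first half of planted matures (as if known in miRBase) + decoys
    n_cat = max(1, int(round(catalog_fraction * len(manifest.planted_hairpins))))
    catalog = {
        f"cat-miR{i + 1:03d}": h.mature_seq
        for i, h in enumerate(manifest.planted_hairpins[:n_cat])
    }
    for d in range(5):
        catalog[f"cat-decoy{d + 1}"] = _random_seq(rng, 21)
    write_fasta(catalog, outdir / "catalog.fasta")
    paths["catalog"] = str(outdir / "catalog.fasta")

    # gene -> term annotation: planted target hosts share an enriched term
    terms = [f"TERM:{i:04d}" for i in range(8)]
    rows = []
    target_hosts = {s.transcript_id for s in manifest.planted_target_sites}
    for tid in transcripts:
        if tid in target_hosts:
            rows.append({"gene": tid, "term": terms[0], "name": "planted-target process"})
        for t in rng.choice(terms[1:], size=int(rng.integers(1, 3)), replace=False):
            rows.append({"gene": tid, "term": str(t), "name": f"background {t}"})
    annotation = pd.DataFrame(rows)
    write_tsv(annotation, outdir / "annotation.tsv")
    paths["annotation"] = str(outdir / "annotation.tsv")

    write_tsv(
        pd.DataFrame(
            [
                {
                    "mirna": h.mirna_id,
                    "transcript": h.transcript_id,
                    "precursor_start": h.start,
                    "mature_start": h.mature[0],
                    "mature_end": h.mature[1],
                    "star_start": h.star[0],
                    "star_end": h.star[1],
                    "mature_seq": h.mature_seq,
                }
                for h in manifest.planted_hairpins
            ]
        ),
        outdir / "truth_hairpins.tsv",
    )
    write_tsv(truth.reset_index(), outdir / "truth_counts.tsv")
    write_tsv(truth_var.reset_index(), outdir / "truth_variant_counts.tsv")
    write_tsv(
        pd.DataFrame(
            [
                {"mirna": m, "fold_change": fc}
                for m, fc in manifest.planted_fold_changes.items()
            ]
        ),
        outdir / "truth_fold_changes.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "mirna": v.mirna_id,
                    "position": v.position,
                    "ref": v.ref,
                    "alt": v.alt,
                    "fraction": v.fraction,
                }
                for v in manifest.planted_variants
            ]
        ),
        outdir / "truth_variants.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "mirna": s.mirna_id,
                    "transcript": s.transcript_id,
                    "start": s.start,
                    "designed_score": s.designed_score,
                    "for_variant": s.for_variant,
                }
                for s in manifest.planted_target_sites
            ]
        ),
        outdir / "truth_target_sites.tsv",
    )
    for key in (
        "truth_hairpins",
        "truth_counts",
        "truth_variant_counts",
        "truth_fold_changes",
        "truth_variants",
        "truth_target_sites",
    ):
        paths[key] = str(outdir / f"{key}.tsv")

    # config carries outdir-relative file names so reruns are byte-identical
    rel_paths = {key: Path(p).name for key, p in paths.items()}
    cfg = RunConfig(
        groups=group_design(n_per_group),
        seed=seed,
        paths=rel_paths,
        reference_group="LPSP",
    )
    cfg.to_yaml(outdir / "config.yaml")
    paths["config"] = str(outdir / "config.yaml")
    return {"paths": paths, "manifest": manifest, "transcripts": transcripts}
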