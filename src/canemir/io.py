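"""Standard-format I/O shared by all pipeline stages.

FASTA/FASTQ parsing is delegated to Biopython; this module adds the
error reporting contract used across the package (malformed records are
reported with their record index / line number), small TSV schema checks,
dot-bracket structure files, and the nucleotide-alphabet helpers (U/T
normalisation, reverse complement) every stage relies on.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

__all__ = [
    "RawRead",
    "normalize_t",
    "to_u",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "write_dotbracket",
    "read_dotbracket",
    "FormatError",
]

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed record in an input file."""


@dataclass
class RawRead:
    """A raw sequencer read: sequence plus per-base Phred qualities."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )


def normalize_t(seq: str) -> str:
    """Uppercase and fold U onto T (internal DNA-alphabet convention)."""
    return seq.upper().replace("U", "T")


def to_u(seq: str) -> str:
    """RNA alphabet for user-facing miRNA FASTA output (miRBase convention)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return normalize_t(seq).translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path | _io.TextIOBase) -> dict[str, str]:
    """Parse a FASTA file into an ordered id -> sequence mapping (T alphabet)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path if not isinstance(path, Path) else str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = normalize_t(str(rec.seq))
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    if isinstance(records, dict):
        records = records.items()
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a Phred+33 FASTQ file, naming the record index on parse errors."""
    n_ok = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield RawRead(
                id=rec.id,
                sequence=normalize_t(str(rec.seq)),
                quality=list(rec.letter_annotations["phred_quality"]),
            )
            n_ok += 1
    except ValueError as exc:  # Biopython reports the lengths, we add the index
        raise FormatError(f"malformed FASTQ record at index {n_ok}: {exc}") from exc


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quality)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_tsv(path: str | Path, required_columns: Iterable[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_dotbracket(records: Iterable[tuple[str, str, str, float]], path: str | Path) -> None:
    """Write (id, sequence, structure, energy) records in RNAfold-like layout."""
    with open(path, "w") as fh:
        for name, seq, struct, energy in records:
            fh.write(f">{name}\n{to_u(seq)}\n{struct} ({energy:.2f})\n")


def read_dotbracket(path: str | Path) -> list[tuple[str, str, str, float]]:
    out = []
    lines = Path(path).read_text().splitlines()
    for i in range(0, len(lines), 3):
        name = lines[i][1:]
        seq = lines[i + 1]
        struct, energy = lines[i + 2].rsplit(" ", 1)
        out.append((name, seq, struct, float(energy.strip("()"))))
    return out
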