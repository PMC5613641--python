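"""Run configuration: every pipeline threshold lives here, in one place.

Stage modules take their cutoffs as function arguments whose defaults are
drawn from this module, so a run is fully described by one `RunConfig`.
The defaults are the field-standard parameter set (MIREAP-style hairpin
bounds, the >5 TPM / |log2FC|>1 / p<0.05 / FDR<0.05 DE filter, the six
plant target-prediction rules, the 10-read / 1% variant filters, the Ct
cap of 35).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["HairpinParams", "RunConfig"]

#: Illumina TruSeq small-RNA 3' adapter prefix (kit named by the protocol;
#: sequence is a configurable default, not a published value).
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class HairpinParams:
    """MIREAP-style precursor prediction parameter set.

    All eight values are the standard defaults of the discovery stage.
    ``max_energy`` is in kcal/mol on the scale of whatever folding engine
    is active (the built-in engine by default) and is therefore an
    explicit knob, not a physical constant.
    """

    min_mature: int = 18          # minimal mature miRNA length (nt)
    max_mature: int = 25          # maximal mature miRNA length (nt)
    max_copy: int = 20            # maximal copy number of a read on the reference
    max_energy: float = -18.0     # maximal precursor free energy (kcal/mol)
    max_space: int = 300          # maximal space between mature and star arm (nt)
    min_space: int = 16           # minimal space between mature and star arm (nt)
    max_bulge: int = 4            # maximal bulge in the mature/star duplex (nt)
    flank: int = 20               # flank length added around the arm span (nt)


@dataclass
class RunConfig:
    """Complete configuration for an end-to-end run."""

    # -- sample design: sample id -> group label (exactly two groups) -----
    groups: dict[str, str] = field(default_factory=dict)

    # -- preprocess -------------------------------------------------------
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_len: int = 18             # shortest clean read kept (nt)
    max_len: int = 30             # longest clean read kept (nt)
    min_mean_q: float = 20.0      # mean Phred cutoff defining "low quality"
    adapter_min_overlap: int = 6
    adapter_max_mismatch: int = 1

    # -- discovery --------------------------------------------------------
    max_mismatch: int = 2         # mapping mismatch cap
    hairpin: HairpinParams = field(default_factory=HairpinParams)
    merge_overlap: float = 0.80   # precursors overlapping > this fraction merge
    conserved_min_identity: float = 0.90   # catalog identity must exceed this
    conserved_min_reads: int = 10          # mapped reads must exceed this

    # -- expression -------------------------------------------------------
    count_min_overlap: int = 18   # read/mature overlap must exceed this (nt)
    detect_tpm: float = 1.0       # "detected" means TPM strictly above this
    floor_tpm: float = 5.0        # removed if TPM <= this in all samples

    # -- differential expression ------------------------------------------
    de_min_tpm: float = 5.0       # normalized expression gate (any sample)
    de_min_abs_log2fc: float = 1.0
    de_max_p: float = 0.05
    de_max_fdr: float = 0.05
    de_pseudocount_tpm: float = 0.25   # pseudocount for internal log2FC
    reference_group: str | None = None  # denominator group for log2FC

    # -- target prediction -------------------------------------------------
    target_max_score: float = 3.0      # rule i: mismatch score cap (G:U = 0.5)
    target_mfe_min_ratio: float = 0.75  # rule vi: duplex MFE / perfect MFE
    target_gu_in_adjacency: bool = True

    # -- variants ----------------------------------------------------------
    variant_min_reads: int = 10    # removed if total variant reads < this
    variant_min_ratio: float = 0.01  # removed if variant/(variant+normal) < this

    # -- enrichment ---------------------------------------------------------
    enrich_max_p: float = 0.05
    enrich_max_q: float = 0.05

    # -- qPCR ---------------------------------------------------------------
    ct_cap: float = 35.0           # Ct values greater than this are set to it

    # -- bookkeeping --------------------------------------------------------
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.groups:
            labels = set(self.groups.values())
            if len(labels) != 2:
                raise ValueError(
                    f"sample->group map must define exactly two groups, got {sorted(labels)}"
                )

    def group_labels(self) -> tuple[str, str]:
        """The two group labels, sorted for a deterministic (A, B) order."""
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise ValueError("configuration has no two-group sample map")
        return labels[0], labels[1]

    # -- (de)serialisation --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "hairpin" in data and isinstance(data["hairpin"], dict):
            data["hairpin"] = HairpinParams(**data["hairpin"])
        return cls(**data)
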