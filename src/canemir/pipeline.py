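"""End-to-end pipeline orchestration.

Runs the stages in analysis order -- clean, map/discover, profile, DE,
targets, variants, enrichment -- from a single :class:`RunConfig`,
writing each stage's TSV plus a machine-readable summary.  Any stage
failure aborts with the stage name attached.  Given the same config (and
the same input files) a rerun produces identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diffexp, discovery, enrichment, expression, preprocess, targets, variants
from .config import RunConfig
from .io import read_fasta, read_fastq, to_u, write_dotbracket, write_fasta, write_tsv

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _resolve(config: RunConfig, key: str, base: Path) -> Path:
    if key not in config.paths:
        raise PipelineError(f"config error: missing path {key!r}")
    p = Path(config.paths[key])
    return p if p.is_absolute() else base / p


@_stage("clean")
def _run_clean(config: RunConfig, base: Path):
    clean_per_sample: dict[str, list[str]] = {}
    stats: dict[str, preprocess.CleanStats] = {}
    for sample in config.groups:
        reads = read_fastq(_resolve(config, f"reads_{sample}", base))
        kept, st = preprocess.clean_reads(
            reads,
            adapter=config.adapter,
            min_len=config.min_len,
            max_len=config.max_len,
            min_mean_q=config.min_mean_q,
            adapter_min_overlap=config.adapter_min_overlap,
            adapter_max_mismatch=config.adapter_max_mismatch,
        )
        if not st.conserved():  # pragma: no cover - internal accounting check
            raise RuntimeError(f"count conservation violated in sample {sample}")
        clean_per_sample[sample] = kept
        stats[sample] = st
    return clean_per_sample, stats


@_stage("discover")
def _run_discover(config: RunConfig, collapsed: pd.DataFrame, transcripts, catalog):
    alignments, flagged = discovery.map_reads(
        collapsed.index, transcripts, config.max_mismatch, config.hairpin.max_copy
    )
    read_counts = collapsed.sum(axis=1)
    cands = discovery.predict_hairpins(
        alignments, read_counts, transcripts, config.hairpin, frozenset(flagged)
    )
    merged = discovery.merge_precursors(cands)
    matures = {p.id: (p.mature_seq, p.mature_count) for p in merged}
    labels = discovery.classify_conserved(
        matures, catalog, config.conserved_min_identity, config.conserved_min_reads
    )
    for p in merged:
        p.label, p.best_hit, _ = labels[p.id]
    return merged


def run_pipeline(
    config: RunConfig,
    base_dir: str | Path | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    ``base_dir`` anchors relative paths in ``config.paths`` (default:
    current directory); stage tables are written under ``outdir`` when
    given.
    """
    if not config.groups:
        raise PipelineError("config error: sample->group map is missing")
    base = Path(base_dir) if base_dir is not None else Path.cwd()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    transcripts = read_fasta(_resolve(config, "transcripts", base))
    catalog = read_fasta(_resolve(config, "catalog", base))

    clean_per_sample, stats = _run_clean(config, base)
    collapsed = preprocess.collapse_reads(clean_per_sample)
    pooled = [s for seqs in clean_per_sample.values() for s in seqs]
    lengths = preprocess.length_distribution(pooled, config.min_len, config.max_len)

    precursors = _run_discover(config, collapsed, transcripts, catalog)

    counts, multi = expression.count_mature(collapsed, precursors, config.count_min_overlap)
    totals = {s: st.clean for s, st in stats.items()}
    matrix = expression.tpm_normalize(counts, totals)
    _, presence = expression.presence_sets(matrix.tpm, config.detect_tpm)
    kept = expression.filter_low_tpm(matrix, config.floor_tpm)

    de = diffexp.de_from_counts(
        kept.counts,
        kept.tpm,
        config.groups,
        diffexp.DEThresholds(
            config.de_min_tpm, config.de_min_abs_log2fc, config.de_max_p, config.de_max_fdr
        ),
        pseudocount=config.de_pseudocount_tpm,
        library_sizes={s: float(t) for s, t in totals.items()},
        reference_group=config.reference_group,
    )

    by_id = {p.id: p for p in precursors}
    de_targets: dict[str, set[str]] = {}
    for mid in de.index[de["label"] != "ns"]:
        sites = targets.predict_targets(
            mid,
            by_id[mid].mature_seq,
            transcripts,
            config.target_max_score,
            config.target_mfe_min_ratio,
            config.target_gu_in_adjacency,
        )
        de_targets[mid] = {s.transcript_id for s in sites}
    up_targets = set().union(
        *(de_targets[m] for m in de.index[de["label"] == "up"] if m in de_targets), set()
    )
    down_targets = set().union(
        *(de_targets[m] for m in de.index[de["label"] == "down"] if m in de_targets), set()
    )

    cands, normal = variants.call_variant_mirnas(
        collapsed, precursors, config.count_min_overlap
    )
    kept_vars = variants.filter_variants(
        cands, config.variant_min_reads, config.variant_min_ratio
    )
    var_reports = [
        variants.annotate_variant(
            v,
            by_id[v.mirna_id].mature_seq,
            transcripts,
            config.target_max_score,
            config.target_mfe_min_ratio,
        )
        for v in kept_vars
    ]

    enrich = None
    if "annotation" in config.paths:
        annotation = pd.read_csv(_resolve(config, "annotation", base), sep="\t")
        target_genes = (up_targets | down_targets) & set(annotation["gene"])
        if target_genes:
            enrich = enrichment.enrich_terms(
                target_genes, annotation, max_p=config.enrich_max_p, max_q=config.enrich_max_q
            )

    summary = {
        "samples": {
            s: {"raw": st.raw, "clean": st.clean, "discarded": dict(st.discarded)}
            for s, st in stats.items()
        },
        "length_mode_bins": [int(b) for b in lengths.nlargest(2).index],
        "n_unique_sequences": int(len(collapsed)),
        "n_precursors": len(precursors),
        "n_conserved": sum(p.label == "conserved" for p in precursors),
        "n_novel": sum(p.label == "novel" for p in precursors),
        "n_multi_mapping_reads": int(multi.sum()),
        "presence": presence,
        "n_expressed_after_floor": int(len(kept.counts)),
        "dispersion": float(de.attrs.get("dispersion", 0.0)),
        "n_de_up": int((de["label"] == "up").sum()),
        "n_de_down": int((de["label"] == "down").sum()),
        "n_up_targets": len(up_targets),
        "n_down_targets": len(down_targets),
        "n_shared_targets": len(up_targets & down_targets),
        "n_variant_candidates": len(cands),
        "n_variants_kept": len(kept_vars),
        "variants": [
            {
                "mirna": r["mirna_id"],
                "position": r["position"],
                "ref": r["ref"],
                "alt": r["alt"],
                "in_seed": r["in_seed"],
                "lost": len(r["lost"]),
                "gained": len(r["gained"]),
            }
            for r in var_reports
        ],
        "n_enriched_terms": int(enrich["significant"].sum()) if enrich is not None else 0,
        "seed": config.seed,
    }

    if out is not None:
        write_tsv(collapsed.reset_index(), out / "collapsed.tsv")
        write_tsv(lengths.reset_index(), out / "length_distribution.tsv")
        write_fasta(
            {p.id: to_u(p.sequence) for p in precursors}, out / "precursors.fasta"
        )
        write_fasta(
            {p.id: to_u(p.mature_seq) for p in precursors}, out / "matures.fasta"
        )
        write_dotbracket(
            [(p.id, p.sequence, p.structure, p.energy) for p in precursors],
            out / "precursors.dotbracket",
        )
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "mirna": p.id,
                        "transcript": p.transcript_id,
                        "precursor_start": p.start,
                        "precursor_end": p.end,
                        "mature_start": p.mature[0],
                        "mature_end": p.mature[1],
                        "star_start": p.star[0],
                        "star_end": p.star[1],
                        "arm": p.arm,
                        "energy": p.energy,
                        "label": p.label,
                        "best_hit": p.best_hit,
                    }
                    for p in precursors
                ]
            ),
            out / "loci.tsv",
        )
        write_tsv(matrix.counts.reset_index(), out / "counts.tsv")
        write_tsv(matrix.tpm.round(3).reset_index(), out / "tpm.tsv")
        write_tsv(de.reset_index(names="mirna"), out / "de.tsv")
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "mirna": v.mirna_id,
                        "position": v.position,
                        "ref": v.ref,
                        "alt": v.alt,
                        "total_variant": v.total_variant,
                        "total_normal": v.total_normal,
                        "ratio": v.ratio,
                        "in_seed": v.in_seed,
                        **{f"variant_{s}": c for s, c in v.variant_counts.items()},
                    }
                    for v in kept_vars
                ]
            ),
            out / "variants.tsv",
        )
        if enrich is not None:
            write_tsv(enrich, out / "enrichment.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
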