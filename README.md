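# canemir

Small-RNA sequencing analysis for plant miRNA studies on a transcriptome
reference: hairpin-based miRNA discovery, TPM expression profiling,
exact-test differential expression, rule-based target prediction,
isomiR/SNP scanning, term enrichment, and stem-loop RT-qPCR analysis —
with a synthetic-data generator so the whole pipeline is testable end to
end with known ground truth and no downloads.

## Who this is for

Groups analysing small RNA-seq from organisms without a reference genome
(polyploid crops are the motivating case: the reference is an assembled
transcriptome, not chromosomes). The package re-implements the classic
MIREAP-style discovery workflow and its downstream stages as one tested,
configurable library with a CLI.

## What it computes

- **Discovery** — reads are cleaned (3' adapter, 18–30 nt, mean Phred ≥ 20),
  collapsed, and mapped to transcripts (≤ 2 substitutions, ≤ 20 loci).
  Read-supported arms seed hairpin candidates; the star arm is found by
  reverse-complement scanning within the allowed arm spacing, and the
  precursor is kept only if every bound of the parameter set holds:
  mature length 18–25 nt, arm spacing 16–300 nt, duplex bulge ≤ 4 nt,
  folding energy ≤ −18 kcal/mol, 20-nt flanks. Precursors overlapping
  > 80 % merge; matures are *conserved* if catalog identity > 90 % and
  reads > 10, else *novel*. Folding uses a built-in Nussinov-style
  dynamic program (pair energies G:C −3, A:U −2, G:U −1 kcal/mol;
  a thermodynamic folder can be plugged in).
- **Expression** — a read counts for a mature miRNA iff it matches the
  precursor perfectly and overlaps the mature arm by > 18 nt;
  TPM = 10⁶ · (mapped reads) / (total clean reads).
- **Differential expression** — a conditional negative-binomial exact
  test with method-of-moments common dispersion φ (variance μ + φμ²);
  at φ = 0 it reduces exactly to the conditional binomial test. BH FDR.
  A miRNA is called up/down only if all four gates pass:
  TPM > 5 in ≥ 1 sample, |log2FC| > 1, p < 0.05, FDR < 0.05.
- **Targets** — every transcript window of miRNA length is scored as an
  ungapped antisense duplex (mismatch 1, G:U wobble 0.5) and must pass
  six rules: total score ≤ 3; no > 2 adjacent mismatches; no adjacent
  mismatches in positions 2–12; no mismatch at positions 10–11; ≤ 2.5
  mismatches in positions 1–12; duplex energy ≥ 75 % of the
  perfect-complement energy.
- **Variants** — reads aligning to a precursor with exactly one
  substitution inside the mature arm are isomiR candidates; kept if
  ≥ 10 supporting reads and ≥ 1 % of (variant + normal) reads, dropping
  miRNAs with ≥ 2 surviving substitution positions; seed region =
  positions 2–7; retargeting is reported as shared/lost/gained targets.
- **Enrichment** — upper-tail hypergeometric (≡ one-sided Fisher) per
  term, Storey q-values (BH below 100 terms), significant if p < 0.05
  and q < 0.05.
- **qPCR** — Ct values > 35 capped, replicates averaged,
  RNE = 2^(−ΔΔCt) against a reference assay and calibrator sample, plus
  Pearson correlation with sequencing TPM ratios on log2 scale.

## Worked example

The published DE table ships with the package; applying the four-way
filter reproduces its partition:

```sh
$ canemir de --fixture table2
rows=38 up=25 down=13
```

A full synthetic run (six libraries, two groups of three, 20 planted
hairpins at 20 000 reads per library):

```sh
$ canemir simulate --seed 1 --outdir fx
$ canemir run --config fx/config.yaml --outdir out
```

prints a machine-readable summary; with seed 1 the headline numbers are

```
"length_mode_bins": [21, 24]   # read lengths peak at 21 and 24 nt
"n_precursors": 20             # all 20 planted hairpins recovered
"n_conserved": 10, "n_novel": 10
"n_de_up": 4, "n_de_down": 3   # 4 + 2 planted fold changes (one extra call)
"n_variants_kept": 2           # the two planted isomiRs above the filters
```

and `out/` holds the stage tables (collapsed reads, precursor FASTA and
dot-bracket structures, locus table, counts/TPM, DE table, variant and
enrichment tables, `summary.json`).

As a library:

```python
from canemir import diffexp
table = diffexp.load_table2()
de = diffexp.classify_de(table, ["B1", "B2", "Q2", "Q1", "T1", "T2"])
de["label"].value_counts()      # up 25, down 13
```

## Acceptance script

`scripts/acceptance.py` regenerates the synthetic world at the given
seed and reruns the entire pipeline from scratch:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints the end-to-end run summary and writes the target JSON to
`--out`.

## Layout

```
src/canemir/
  synthetic.py    # generator: planted hairpins, sites, variants, libraries
  preprocess.py   # cleaning, collapsing, length distributions
  discovery.py    # mapping, folding, hairpin prediction, classification
  expression.py   # counting, TPM, presence sets
  diffexp.py      # NB exact test, BH, DE classification (+ table2 fixture)
  targets.py      # six-rule duplex engine, MFE ratio, set comparison
  variants.py     # isomiR calling, filters, retargeting
  enrichment.py   # hypergeometric terms, Storey q-values
  qpcr.py         # -ddCt, platform correlation
  pipeline.py     # orchestration; cli.py  # `canemir` commands
docs/methods.md   # model assumptions, parameter rationale, limitations
```
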