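# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## Read cleaning

The 3' adapter is located as the leftmost position where a prefix of the
adapter matches with at most one substitution and the match extends to
the read's 3' end with at least 6 nt of overlap. Inserts shorter than
18 nt or longer than 30 nt, and reads whose insert mean Phred is below
20, are discarded with per-reason accounting (raw = clean + discarded,
asserted at run time). "Low quality" has no published definition; mean
Phred 20 is this package's explicit default.

Reads with no adapter hit are discarded by default: a short-RNA insert
is always followed by adapter on the sequencer, so an adapterless read
is either contamination or an insert longer than the read. This makes a
literal second cleaning pass destructive, so idempotence is provided by
`require_adapter=False`, which keeps untrimmable reads whole. Tests
exercise both behaviours.

## Folding engine

`discovery.fold_rna` is a Nussinov-style dynamic program: minimum
hairpin loop 3, nested structures only, objective either base-pair
maximisation or minimisation of a per-pair energy (G:C −3, A:U −2,
G:U −1 kcal/mol). This is *not* a nearest-neighbour thermodynamic
model: there is no stacking term, no loop penalties, and the energy
scale is model-relative. Consequences and choices:

- The −18 kcal/mol precursor threshold is interpreted on the active
  engine's scale and is a configurable knob. Any callable
  `seq -> (dot_bracket, energy)` can be plugged in (e.g. an external
  RNAfold wrapper) and the threshold then applies to that engine.
- Without stacking, optimal structures are massively degenerate. The
  traceback breaks ties by leaving a base unpaired when possible and
  otherwise pairing with the *farthest* admissible partner, which
  favours long-range stems (hairpin arms) over incidental pairing with
  nearby loop bases. Tie-breaking affects only the reported structure,
  never the optimal score, which is what the pair-count oracle tests
  verify by exhaustive enumeration for sequences up to 25 nt.

## Hairpin discovery

Candidate mature arms are perfect-match read loci of length 18–25.
The star arm is found by exhaustively scanning both directions at arm
spacings 16–300 nt for the best ungapped reverse-complement window; a
candidate is dropped unless ≥ 85 % of positions match exactly. Because
the scan is ungapped, the reported duplex has bulge 0 (within the ≤ 4 nt
bound by construction) and a genuinely bulged duplex is found only while
its contiguous identity clears 85 %. This is a documented limitation;
the duplex geometry is deliberately *not* taken from the fold, whose
degenerate optima can pair a few mature bases into the loop and corrupt
the inferred star interval. The fold contributes the structure record
and the energy gate.

Precursors on the same transcript overlapping more than 80 % of the
shorter one are merged; the representative has the higher mature read
count (ties: longer precursor, then lexicographically smaller id),
making merging order-invariant and idempotent. A star-seeded candidate
of a real hairpin merges into its mature-seeded twin this way.

Conserved/novel classification uses Levenshtein identity
1 − d/max(len) against the catalog, requiring identity strictly > 0.90
*and* mapped reads strictly > 10. The identity measure is this
package's documented choice; the similarity measure behind the
published "> 90 %" rule is unspecified.

## Expression

A read counts for a mature miRNA iff it matches the precursor with zero
mismatches and overlaps the mature interval by strictly more than 18 nt
(an 18-nt read can therefore never count). Reads matching several
miRNAs count for each and are flagged. TPM divides by *total clean
reads*, not miRNA-mapped reads — the two differ by roughly an order of
magnitude, so the denominator choice matters and follows the stated
normalisation. Detection ("> 1 TPM") and the expression floor
("removed if ≤ 5 TPM in all samples") are both strict comparisons.

## Differential expression

Counts are modelled NB(μ, φ) with variance μ + φμ². The common φ is a
pooled method-of-moments ratio Σ(v − m)/Σm² over gene/group cells,
floored at 0; simulations in the tests show it recovers φ = 0 and
φ = 0.2 within the stated bands. The test conditions the group-A sum on
the pooled sum: for equal per-sample means the conditional law depends
only on the per-group NB sizes n_g/φ, not on μ, giving a parameter-free
exact test given φ. Unequal library sizes are handled by scaling counts
to the mean library size and rounding (φ > 0), or by using the
library-size ratio as the binomial proportion (φ = 0, where the
conditional law is exactly binomial). Two-sidedness doubles the smaller
tail, capped at 1. This mirrors the behaviour of the standard exact
test for count data while being fully specified here; no
empirical-Bayes shrinkage or TMM normalisation is attempted.

log2FC is computed on group-mean TPM with a 0.25-TPM pseudocount
(published tables contain zeros; the pseudocount bounds the fold change
instead of producing infinities). Classification requires all four
gates (TPM > 5 somewhere, |log2FC| > 1, p < 0.05, FDR < 0.05); when a
published table supplies log2FC/p/FDR they are used as-is, which
separates the classification rule (reproducible) from the estimator
(not reproducible without the raw data). Multiple testing is
Benjamini–Hochberg.

## Target prediction

Duplexes are ungapped antisense windows of miRNA length; position 1 is
the miRNA 5' end. States are match, G:U wobble (penalty 0.5) or
mismatch (penalty 1). Rules i (score ≤ 3) and v (score ≤ 2.5 in
positions 1–12) use the half-penalty; the adjacency rules ii/iii and
the cleavage-site rule iv treat any non-match — wobble included — as a
mismatch (conservative literal reading; a flag relaxes ii/iii). The
energy ratio (rule vi) uses the same per-pair energies as the folding
engine with wobbles at −1 and mismatches at 0; the ≥ 0.75 boundary is
inclusive. Target-side bulges are not modelled: the rules are stated
per-position and an ungapped duplex satisfies that framing; this is a
documented limitation, not an inferred intent.

## Variants (isomiRs/SNPs)

Only single substitutions inside the mature arm qualify; 5'/3' length
isomiRs are out of scope. Alignment to precursors allows ≤ 1
substitution (pigeonhole-seeded); counting reuses the > 18 nt overlap
rule. The published removal conditions are "< 10 reads" and "< 1 %", so
exactly 10 reads or exactly 1 % are kept. The ratio denominator pools
variant + normal reads over all samples (a per-sample variant is
ambiguous in the stated rule; pooled is implemented). miRNAs with two
or more surviving substitution positions are excluded entirely.

## Enrichment

Per-term p is the upper-tail hypergeometric, identical to one-sided
Fisher (cross-checked to 1e-12 in tests). q-values follow Storey:
π̂₀(λ) on the grid 0.05–0.95 (step 0.05), smoothed with a cubic
smoothing spline and evaluated at λ = 0.95, clipped to [1/m, 1]; below
100 terms the estimator is unstable and BH is used instead. The
background defaults to all annotated genes and is an input (the original
background — a full transcriptome annotation — is not available).
An optional term blocklist supports removing organism-irrelevant
pathways without hardcoding any list.

## qPCR

Ct values above 35 cycles are set to 35 before replicate averaging
(arithmetic mean of the three replicates; SD reported — the aggregation
is this package's choice). ΔCt subtracts the reference assay within a
sample, ΔΔCt subtracts the calibrator sample, RNE = 2^(−ΔΔCt); the
calibrator's RNE is identically 1 by construction. Cross-platform
correlation is Pearson on log2(RNE) versus log2 of the TPM ratio to the
calibrator (pseudocount 0.25 against zero TPM); a linear-scale option
exists. The published correlation value itself is not recomputable
(the Ct values are unpublished), so the operation is validated against
the direct-formula oracle instead.

## Synthetic world

The generator states one world and the tests measure it; its defaults
are not tuned against outcomes.

- **Design**: six libraries, two groups of three (a leaf-abscission-like
  treatment group versus control), 30 transcripts of 400–900 nt, 20
  planted hairpins (mature + 16–40 nt loop + exact reverse-complement
  star + flanks), 20 000 reads per library by default.
- **Abundance**: per-miRNA baselines are log-uniform over three decades
  (no published per-miRNA abundance law exists; log-uniform reproduces
  the "most miRNAs below 5 TPM" shape qualitatively). Mature lengths
  are tied to abundance rank — dominant products alternate between the
  21-nt and 24-nt classes, minority lengths (20/22/23) fill the
  low-abundance tail — so the pooled read-length histogram peaks at 21
  and 24 nt by construction rather than by chance.
- **Counts**: NB via gamma–Poisson with dispersion φ = 0.1 (Poisson at
  φ = 0); planted fold changes 4.0 (four miRNAs up) and 0.25 (two down)
  on mid-abundance miRNAs so they are detectable but not trivial.
- **Variants**: three planted substitutions on the most abundant
  miRNAs at fractions 0.40, 0.10 and 0.002 — two clear the 10-read/1 %
  filters, one sits well below them; the first is pinned to seed
  position 6 and paired with two engineered target sites (a mismatch at
  position 7 next to the substitution site) so the normal and variant
  forms provably lose and gain one target each.
- **Reads**: every read carries the TruSeq small-RNA 3' adapter and is
  truncated to 36 nt; ~35 % of reads are background transcript
  fragments drawn from hairpin-free transcripts with the same 21/24
  length peaks (they clean up fine but never touch a mature arm, and
  they make total clean reads exceed miRNA-mapped reads as in real
  libraries); ~3 % are junk (10–17 nt inserts or mean Phred 10).
- **Not modelled**: sequencing errors beyond the planted substitutions,
  quality-score realism, bulged hairpins (planted duplexes are exact
  reverse complements), length isomiRs, and polyploid genome structure.

A green recovery test therefore establishes that the pipeline inverts
this generative model exactly (planted objects in, planted objects out)
— not that it would handle degradation products, bulged precursors or
sequencing error the way a thermodynamic, genome-aware pipeline would.

## Numerical notes

- Seeds: every stochastic routine takes or derives from a single integer
  seed; fixture writing is byte-reproducible.
- The folding DP uses exact float arithmetic on small integer-valued
  energies, so traceback equality tests are safe.
- The exact test's conditional weights are computed with log-gamma and
  log-sum-exp; p-values are exactly 1 for balanced data and never 0.
- Coordinates are 1-based closed intervals on transcripts throughout;
  sequences are normalised to the DNA alphabet internally and written
  with U only in user-facing miRNA FASTA output.
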