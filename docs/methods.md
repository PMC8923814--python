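# Methods

This note records the models, conventions, and design choices behind
each stage, in the order the pipeline runs them.

## Coordinates and annotation I/O

All internal intervals are 0-based half-open; GTF files are read and
written 1-based inclusive (Ensembl dialect, `gene_id`/`transcript_id`
attributes on `exon` features). Reading and writing are mutual inverses
on the data model, and all orderings (genes by chrom/start/id,
transcripts by start/id, exons by start) are fixed so parses and outputs
are deterministic and byte-reproducible. Transcript validation enforces
sorted, disjoint exons with introns of at least 1 nt; a transcript
spanning two chromosomes or strands is rejected rather than repaired.

Read 3′-end positions enter as a pre-extracted five-column TSV (chrom,
0-based position, strand, read id, gene id) rather than BAM: the APA
stage consumes exactly this information, and a text input keeps APA
results reproducible from one file. Gene assignment is taken as given;
unknown gene ids are warned about but kept.

## Isoform catalog

Known-isoform status is defined by intron-chain equality, not
exon-boundary equality, so 5′/3′ terminal-end variation — ubiquitous in
long reads — does not demote a transcript. Mono-exon transcripts have no
intron chain; they are known when reciprocal overlap with a same-strand
reference mono-exon transcript is ≥ 0.8 (a conventional
annotation-matching default). Gene assignment for novel isoforms is by
most shared junctions, ties broken by exonic overlap then lexicographic
gene id — deterministic by construction. Novel genes are single-linkage
clusters of leftover transcripts by same-strand exonic overlap, labelled
`NOVELG%06d` in (chrom, start) order so ids are stable across runs and
input orderings.

## Alternative-splicing events

Events are local: every transcript pair of a gene is compared, events
are recorded with a coordinate signature, and the union over pairs is
deduplicated by (gene, type, signature). Duplicated exon chains are
dropped first, so duplicating a transcript never changes event sets.

Naming is strand-aware (the donor is the junction's left edge on `+`,
right edge on `-`), so a given genomic configuration is A5 on one strand
and A3 on the other, and likewise AF/AL. Two coordinate patterns need a
disambiguation rule: a junction pair sharing one edge arises both inside
alternative-splice-site events and at the flanks of ES/MX pairs and
alternative terminal exons. The rule used (splice-site-centric, as in
event-enumeration practice): shared-edge junction pairs whose alternative
flanking exons **overlap** are A5/A3; those whose alternative exons are
disjoint and are both their transcript's terminal exon are AF/AL; other
shared-edge pairs (disjoint internal alternatives) are not events. This
keeps the seven classes mutually exclusive — without the overlap
requirement every ES and MX pair would also register spurious A5/A3
events. MX additionally requires exact sharing of both outer junction
coordinates and non-overlapping middle exons; IR requires the retained
exon to span the two spliced exons exactly.

Signatures are ordered coordinate tuples; for MX the middle-exon
boundary may satisfy `e2 == s3` (abutting middle exons are still
mutually exclusive), and for
AF/AL the terminal exons may abut, so signature coordinates are
non-decreasing with strict increase everywhere a junction intervenes.

The test suite checks the enumeration against an independent brute-force
oracle (a literal transcription of the definitions with naive loops) on
hundreds of random genes, and checks the mirror property: reflecting all
coordinates while keeping the strand label swaps A5↔A3 and AF↔AL,
while reflecting *and* flipping the strand — the same molecule viewed
from the other side — leaves every event type fixed.

## Alternative polyadenylation

Per gene, read 3′-end positions are sorted and clustered by single
linkage with linkage distance ≤ window (default 24 nt); clusters with
fewer than `min_support` reads (default 2) are discarded. Single linkage
rather than fixed-width binning makes the clustering shift-invariant;
the two differ at the margins. The site representative is the
support-weighted (lower) median of member ends, robust to stragglers and
exact when the scatter is zero. The defaults are conventional poly(A)
clustering values and both are exposed in configuration. Note that the
cluster count is monotone non-increasing in the window only *before*
support filtering: two unsupported singletons can merge into one
supported cluster, so the filtered site count can rise with the window.
Genes with ≥ 2 retained sites are APA genes; cross-group overlap reports
Venn regions and the directed shared fraction |X∩Y|/|X|.

## Expression and differential expression

TPM uses union-exon gene length (counts are gene-level, so the union of
exonic sequence is the natural length), and each sample column sums to
10⁶. "Expressed" is the literal TPM > 0 rule — positive in at least one
replicate of the group; stricter replicate thresholds are a parameter.
Activation/silencing are plain set differences of expressed-gene sets,
optionally partitioned by a third set (the two parts always sum to the
total).

The differential test is a negative-binomial Wald test built from
scratch:

* **Size factors** — median-of-ratios over genes positive in every
  sample, rescaled to geometric mean 1; an add-one pseudo-reference
  fallback (with a warning) covers matrices with no all-positive gene.
* **Dispersion** — per gene, a method-of-moments estimate from the
  within-group pooled variance of normalised counts,
  φ̂ = (s² − μ̄)/μ̄² (variance parameterisation var = μ + φμ²). The
  mean–dispersion trend is a log-linear fit to *binned means* of the
  unfloored φ̂: per-gene moment estimates at four residual degrees of
  freedom are individually far too noisy (and often negative) to regress
  in log space, and fitting logs of floored values would bias the trend
  low and the test anticonservative. The working dispersion is
  0.1·max(φ̂, 10⁻⁸) + 0.9·trend. The trend-dominated weight is what
  keeps the test's null behaviour at its nominal level with three
  replicates per group — with the true dispersion plugged in, the Wald
  statistic is almost exactly standard normal, so residual
  miscalibration is dispersion-estimation noise, and the per-gene
  moment estimate contributes little information at this depth. The
  weight is configurable for designs with more replicates or genuinely
  heavy per-gene dispersion variation.
* **Fold change and SE** — log2FC from group means of normalised counts
  with a 0.5 pseudocount (bounds the fold change for zero-containing
  genes); delta-method variance of the log2 mean,
  (1/μ̃ + φ)/(n·ln²2) per group.
* **Inference** — two-sided normal p from the Wald z; BH adjustment over
  tested genes (genes all-zero in both groups are excluded); DEG calls
  at |log2FC| ≥ 1 and padj ≤ 0.001 by default.

This test will not numerically match any particular external DE
implementation; its contract is calibration, verified by simulation in
the acceptance suite: raw P < 0.05 fraction within 0.05 ± 0.02 under the
null (1000 genes, μ ~ logU(10,1000), φ = 0.1, 3 vs 3), and ≥ 90%
recovery of planted 4-fold genes at μ ≥ 100. The power simulation uses
3000 genes with 40% planted effects split evenly up/down — a
parent-vs-parent-scale DE fraction that also keeps median-of-ratios
factors stable.

## In silico hybrid and mid-parent value

The hybrid mixes one replicate pair of parental libraries 1:1: with
n the smaller library total, the larger parent is downsampled to n by a
multivariate-hypergeometric draw (count-level sampling without
replacement), then the vectors are summed, so the hybrid totals 2n.
Equal totals skip the downsampling branch entirely. A read-id-level
variant samples min-n reads from each parent. Both are deterministic
under a seed and order-invariant.

MPV pseudo-replicates pair parental replicates by index,
MPV_i = (A_i + C_i)/2 on normalised expression; unequal replicate counts
are an error rather than silently recycled.

## The twelve expression patterns

Four contrasts per progeny gene — P vs A, P vs C, A vs C, P vs MPV —
are tested at padj ≤ α (default 0.05; deliberately looser than the DEG
rule, as the two thresholds serve different questions). The decision
table, in priority order, assigns:

1. **Transgressive up** — P significantly above both parents (fine
   patterns 7/8/9 by the parental relation A>C, A<C, A≈C);
2. **Transgressive down** — mirror (10/11/12);
3. **ELD-A** — P non-additive (significant vs MPV), not significantly
   different from A, significantly different from C, parents different
   (3/4 by parental relation);
4. **ELD-C** — mirror (5/6);
5. **Additive** — P not significantly different from MPV, significantly
   different from *both* parents (hence intermediate), parents
   different (1/2 by direction);
6. **No change** — no contrast significant;
7. **Ambiguous** — any other signature.

Each pattern demands its complete evidence signature. This matters
because dominance toward the *higher* parent differs from additivity by
only a 1.6-fold expression change at the default 4-fold parental
divergence — frequently undetectable at three replicates — and any rule
that forces such genes into a pattern misassigns them systematically.
Genes whose contrasts cannot distinguish their pattern are reported as
ambiguous, and pattern proportions are computed over confidently
classified genes (unclassified counts are still reported). The
additivity definition (between the parents and distinct from both, with
the MPV test as the operational non-additivity criterion) follows the
standard twelve-pattern scheme; the 2+2+2+3+3 fine-pattern numbering
above is this package's fixed mapping.

Swapping the parental inputs swaps ELD-A↔ELD-C exactly and leaves the
additive and transgressive groups fixed; this symmetry is asserted in
the tests. On the standard noisy simulation the classifier recovers
≥ 95% of classified genes' planted groups; per-class, transgressive and
dominance classes sit near 1.0 while the additive diagonal is bounded
near 0.9 by the power limit above — an identifiability property of the
design (effect size, replicates, dispersion), not of the implementation.

## Synthetic data generator

The generator emulates the targeted study design: 19 chromosomes
(A01–A10, C01–C09), four count groups (A, C, RAC, NAC) at three
replicates, gene models with planted AS events, NB counts with planted
expression classes, and read 3′ ends scattered around planted poly(A)
sites. Specifics:

* **Annotation** — each planted AS gene carries exactly two transcripts
  realising exactly one local event of the requested mode (the
  construction is verified at generation time by running the enumerator);
  remaining genes are single-transcript. Strands are random; templates
  are mirrored appropriately so the named mode is realised on either
  strand.
* **Counts** — parental means μ_A ~ logU over the configured range
  (default 10–1000); the second parent differs 4-fold (log2 effect 2.0,
  the default chosen so three-replicate tests at the configured
  thresholds recover planted classes reliably) in a random direction;
  progeny means follow the planted class (additive (μ_A+μ_C)/2,
  dominance μ_A or μ_C, transgressive max·4 / min/4, silenced exactly 0
  in progeny, activated exactly 0 in both parents — exact zeros match
  the TPM > 0 operational rule). Counts are NB with var = μ + φμ²
  (φ default 0.1); φ = 0 degenerates to deterministic rounding of the
  mean for zero-noise tests. Default class proportions (additive 0.15,
  ELD-A 0.15, ELD-C 0.20, up 0.12, down 0.08, silenced 0.05, activated
  0.05, null 0.20) mirror the qualitative findings for allopolyploid
  expression — more ELD-C than ELD-A, more transgressive up than down —
  with a null class for calibration.
* **Read ends** — 1–3 poly(A) sites per gene (probabilities 0.30 /
  0.525 / 0.175, so three quarters of multi-site genes have two sites),
  separated by 100 nt (safely above both 3× the end scatter and the
  clustering window), each emitting 10–30 reads at Normal(site, 5 nt)
  rounded to integers.

What the generator does **not** emulate: library-size variation between
samples (all counts are on a common scale, so unit size factors are the
ground truth), homoeolog mapping ambiguity between subgenomes,
sequencing error, transcript-level (as opposed to gene-level)
quantification, and genomic A-rich internal-priming artefacts. Passing
tests therefore demonstrate the correctness and calibration of the
statistics and event logic under the stated noise model — not robustness
to alignment or normalisation pathologies of real long-read data. One
consequence is visible in the zero-noise end-to-end check: because true
factors are unity by construction, that check runs the classifier
without size-factor estimation (estimated factors deviate by a few
percent under the strongly non-null gene composition, which is noise at
φ = 0.1 but dominates a near-zero SE); the noisy simulations keep the
full estimated-factor path. The zero-noise scenario also plants means at
μ ≥ 100: at zero dispersion a 16-fold change planted below ~5 reads
(1 vs 4 counts) is unrecoverable by any test through the Poisson floor
of the SE.

## Numerical and degenerate-input conventions

* BH adjustment enforces monotonicity and padj ≥ p; out-of-range
  p-values are errors.
* A degenerate dispersion-trend fit (e.g. all-identical replicates)
  falls back to unshrunk floored moment estimates with a warning.
* All-zero samples yield zero TPM columns with a warning; all-zero genes
  are excluded from testing, never called.
* Empty catalogs, empty pattern tables, empty Venn inputs, non-positive
  clustering windows, and parents with zero reads are errors.
* Every stochastic component takes a seed; pipeline outputs are
  byte-identical under a fixed config.

## Problem sizes

The test-suite and acceptance simulations use 1000 genes for the null
calibration, 3000 for DEG power, 2000 for pattern recovery, 200 genes
for APA recovery, and 150 for the zero-noise end-to-end run — sizes at
which the binomial error of each measured rate is well inside the
asserted bounds while the whole suite runs in a few seconds.

## Known limitations

* The NB Wald test is calibrated for the simulated conditions; for
  n = 2 replicates or strongly gene-specific dispersion the
  trend-dominated shrinkage will understate per-gene variability.
* Pattern classification inherits the identifiability limits discussed
  above; reported pattern proportions depend on the ambiguity rate,
  which rises as effect sizes shrink.
* The isoform catalog matches on exact junction coordinates; it does not
  model small alignment wobble at splice sites (upstream tools are
  expected to have produced consistent junctions).
* APA calling does not filter internal priming (needs genome sequence)
  and does not estimate poly(A)-tail lengths.
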