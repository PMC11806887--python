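# Methods

This note documents the models and procedures implemented in `snpfunnel`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmark does and does not establish.

## The funnel

The pipeline turns two traits' GWAS summary statistics into a short list of
candidate risk-SNPs with target genes. All stages are deterministic given
their inputs and a single seed, which is fanned out to named child streams
(`panel`, `genes`, `truth`, `stats-<trait>`, `tracks`, `ctrl-<trait>`, model
seeds), so any stage can be re-run in isolation and reproduce its bytes.

**p-value filter.** SNPs with p > 5 × 10⁻⁴ are discarded. The comparison is
inclusive: p exactly at the threshold is retained. p = 0 is treated as
malformed at parse time (downstream work is on a log scale) and the row is
rejected rather than clamped.

**Association blocks.** Greedy: the unconsumed SNP with the globally lowest
p-value becomes a lead unless it lies within 1 Mb of an existing lead on the
same chromosome, in which case it is dropped ("consumed-as-skipped" — it can
neither lead nor join a later block). A block is the lead plus its 30 most
significant still-free SNPs within ±500 kb. The 500 kb window is half the
lead separation, so adjacent blocks' windows cannot overlap; both the window
and the separation are parameters. Ties in p-value break by lower position,
then SNP id. Blocks with fewer than 31 members are kept and zero-padded
downstream.

**Feature maps.** A SNP's feature vector has a 1 for every track with an
interval covering its (0-based) position; a block becomes a 31 × F binary
matrix, rows in genomic-position order, padded rows flagged by an explicit
mask that the model receives. Control (label-0) maps permute each feature
column independently across the valid rows of the block: every per-column
marginal is preserved exactly while the association between a SNP and its
feature combination is destroyed. Shuffling is within-block; cross-block
shuffling would change column marginals and make controls trivially
separable by prevalence alone.

## The prioritizer

A small convolutional network over the SNP axis: two convolution layers
(kernels span all F feature columns) followed by a per-row dense head
emitting a score in [0, 1] per SNP slot. Defaults: 16+16 channels, 16 dense
units, kernel height 1. Kernel height 1 is deliberate: candidate selection
is per SNP, so a SNP's score should be attributable to its own annotations;
with taller kernels a non-causal neighbor of a feature-dense SNP inherits
its convolutional response and can steal the block-top. Height is
configurable for users who want neighborhood context.

**Multiple-instance training with uncertain labels.** Only blocks carry
labels, yet per-SNP scores are needed, so the block score is a pooling of
row scores over valid rows. The default pooling is a smooth maximum
(softmax-weighted mean with sharpness β = 8); exact `max`, `mean` and
`noisy-or` are available. The smooth maximum matters for calibration: with a
hard max only the argmax row receives gradient, so independently trained
networks saturate *different* rows of the same block and their averaged
per-SNP scores collapse toward the middle — below the fixed 0.5 candidate
threshold — even when every network separates blocks perfectly. The smooth
maximum supervises every high row, the ensemble members agree, and absolute
scores remain meaningful. The loss is binary cross-entropy of the block
score against *soft* targets, 0.9 for real blocks and 0.05 for controls,
reflecting that a positive block contains at most one truly causal SNP
among up to 31 (and that an occasional block is pure statistical noise);
with targets 1/0 the loss reduces exactly to hard-label cross-entropy.

**Monotonicity.** By default the score is constrained to be non-decreasing
in every feature (all weight matrices are projected to be non-negative after
each optimizer step; biases are free). The rationale is scientific and
practical: the features are positive regulatory evidence, and without the
constraint the real-vs-shuffled objective admits degenerate solutions — for
example, real blocks contain occasional near-empty rows that column-shuffled
controls almost never produce, so an *anti-density* detector separates the
classes while scoring sparse SNPs highest, which ruins per-SNP attribution.
Monotone networks cannot express that family. The constraint is a flag.

**Regularization and ensembling.** Training data are a few dozen maps, so
three controls against overfitting are on by default: inverted input
dropout (rate 0.25 — no idiosyncratic column combination is reliable, which
pushes the head toward pooled-evidence solutions), decoupled weight decay
(10⁻⁴), and an ensemble: 7 networks are trained from different
initializations (each with its own autoencoder pretraining), and the up to 3
members whose validation loss is within 0.2 of the best are kept; their row
scores are averaged. Validation-based member selection is the main
generalization control; per-epoch validation restoring is also applied
within each member.

**Autoencoder pretraining.** The convolutional stack is pretrained to
reconstruct the valid rows of the training maps (sigmoid decoder, masked
binary cross-entropy), then transferred to the classifier. With zero
pretraining epochs the seeded random initialization is returned unchanged.

**Chromosome splits and evaluation.** Maps are partitioned by chromosome
into train/validation/test; a control always follows its source block's
chromosome, so no chromosome leaks between partitions. Performance is the
block-level ROC AUC (Mann–Whitney; ties count ½) of positive vs control on
the test partition. Per-SNP scores, candidate selection (strictly > 0.5)
and block-top selection (ties by lower p-value, position, id) are computed
on all real blocks.

## Gene assignment and LD sharing

A SNP is linked to a gene by: body (1-based inclusive bounds), promoter
(strand-aware half-open 3 kb window immediately upstream of the TSS — the
TSS base itself belongs to the body: on + the window is [TSS−3000, TSS), on
− it is (TSS, TSS+3000]), or enhancer (precomputed interval-to-gene links;
enhancer calling is upstream of this package). A SNP may collect several
genes and evidence classes; none outranks another. Assignments are monotone
in the promoter width and mirror exactly under coordinate reflection with
strand flipping.

LD is computed from phased haplotypes: r² is the squared Pearson correlation
of the two allele-indicator vectors and D′ = |D|/D_max with the classical
frequency bound. Monomorphic sites are an error, unphased input is rejected
(expectation-maximization phasing would make the arithmetic approximate),
and cross-chromosome pairs are defined as r² = 0. The cross-trait filter
keeps a primary-trait block-top candidate iff one of its genes is in the
shared set and some secondary-trait block-top linked to a shared gene has
r² ≥ 0.8 with it; a SNP that is a candidate for both traits supports itself
(r² = 1). The 0.8 cut is the conventional strong-LD threshold and is a
parameter. Both sides of the filter use block-top candidates, keeping the
two traits symmetric.

## The synthetic benchmark

The generator's defaults are the package's reference study conditions; they
were chosen to reproduce, at desk scale, the statistical structure the
method assumes, and each choice has a mechanical reason:

* **Genome**: 6 chromosomes × 7 Mb with 2,000 SNPs each (~3.5 kb spacing).
* **Haplotype panel**: 200 phased haplotypes. Within 100 kb LD blocks each
  SNP's column copies the previous column and redraws 0.4% of entries
  (minor-allele frequencies rejection-sampled into [0.05, 0.5]); columns are
  independent across block boundaries. This yields adjacent r² ≈ 0.97 and
  r² ≥ 0.8 over roughly ±10–15 SNPs — enough strong-LD partners that a
  causal locus produces a realistically sized association block. A
  coalescent simulator would be more faithful but adds nothing the funnel
  consumes beyond r² structure.
* **Genes**: 60 non-overlapping gene bodies of 40–80 kb, one per 0.7 Mb
  slot, near-centered with ±30 kb jitter; strands random; 0–2 enhancer
  links within 10–150 kb of each gene.
* **Causal architecture**: 18 causal genes per trait with half shared
  (rounded half up → 9 shared, 27 distinct loci). Loci are tiled over
  chromosomes — balanced counts, pairwise ≥ 1.3 Mb within a chromosome via
  maximal spaced chains — for two reasons: every chromosome carries signal
  for both traits (chromosome-holdout evaluation stays well defined), and
  nearly every stray null SNP that survives the p-value filter lands within
  1 Mb of a causal lead, where the block builder drops it, so blocks with no
  signal (pure label noise) are rare. Each causal gene carries a cluster of
  5 causal SNPs from the single LD block holding most of its body SNPs,
  emulating a compact regulatory causal locus; the clustering also means
  both traits' block-tops at a shared gene are in strong mutual LD, which
  the cross-trait filter requires.
* **p-values**: null SNPs draw i.i.d. Uniform(0, 1); causal SNPs and their
  panel partners at r² ≥ 0.8 draw Beta(0.1, 20), putting about two thirds of
  causal-locus SNPs below the 5 × 10⁻⁴ filter — large meta-analyses put
  genome-wide-significant loci far below that cut, so this is conservative.
  Effect sizes are not modeled: the funnel consumes only p-values.
* **Feature tracks**: 4 categories × 8 tracks (F = 32). Null-SNP overlap is
  15% per track in every category, but not independently: a latent per-SNP
  regulatory-activity state (10% of SNPs) raises the open-chromatin and
  histone categories to 50% for active SNPs, with the inactive rate
  compensating so the marginal stays 15%. Causal SNPs draw every track
  independently at the rate implied by a per-track odds ratio of 9
  (≈ 61%). Real annotations co-occur this way — generic regulatory elements
  are dense in DHS/histone signal everywhere in the genome — and the
  consequence is what makes the learning problem honest: a shuffled control
  differs from a real block in row coherence, not just in a single summary,
  and only truly causal SNPs are dense across all four categories, so the
  model must separate them from ordinary active elements to place the
  block-top correctly. Intervals are 150–300 bp windows containing the SNP,
  far smaller than the SNP spacing, so a track hit marks one SNP.

**What passing tests on this benchmark do and do not show.** They show the
machinery is correct and that, when feature enrichment of the assumed
structure exists, the funnel recovers it: held-out AUC ≥ 0.8, ≥ 80% of
planted shared causal genes recovered across seeds, chance-level AUC on
label-permuted data, and exact agreement of the combinatorial stages with
brute-force oracles. They do not show that real GWAS of any disease pair
contains such signal, and several properties of real data are deliberately
absent: realistic allele-frequency spectra and population structure,
imputation error, correlated null test statistics along LD (nulls here are
i.i.d.), continuous-valued or cell-type-resolved annotation, genes spanning
many LD blocks, and real-genome coordinates. Reported AUC/recall therefore
characterize the implementation, not any disease biology.

## Numerical and procedural choices

* The network is plain numpy (manual backprop, Adam, β₁ = 0.9, β₂ = 0.999)
  with all randomness from explicit seeds; runs are bit-reproducible.
  Sigmoids are computed in the numerically stable split form; probabilities
  are clipped at 10⁻⁷ inside cross-entropies.
* Ties: block leads and block-tops break deterministically (p-value,
  position, id); AUC ties count ½.
* Degenerate inputs: empty filtered tables produce empty block lists, not
  errors; an evaluation partition with a single class raises; a candidate
  SNP missing from the LD panel is excluded with a warning rather than
  aborting the run; a training partition lacking either class raises.
* Coordinates: summary statistics and gene bodies are 1-based; BED
  intervals and enhancer links are 0-based half-open; VCF positions are
  1-based. Conversions happen at the interfaces, and the interval tests pin
  the conventions.
* Scale: the default benchmark (12,000 SNPs per trait, ~19 blocks per
  trait, 7-member ensembles) runs the full two-trait funnel in a few
  seconds on one CPU, so the test suite and the acceptance script rerun
  everything from scratch rather than caching artifacts.

## Known limitations

* Per-SNP scores are calibrated only relative to the training conditions;
  the 0.5 candidate cut is the upstream convention, not an estimated
  operating point.
* The LD-sharing filter requires the same SNP identifiers in the panel and
  the summary statistics; no positional matching or liftover is attempted.
* The monotonicity constraint, appropriate for presence/absence evidence,
  would be wrong for signed features (e.g., conservation deltas); disable it
  if such columns are introduced.
* With very small validation partitions (one sparse chromosome), ensemble
  member selection degrades toward keeping everything; supplying at least
  one signal-bearing validation chromosome is the user's responsibility.
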