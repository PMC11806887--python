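# snpfunnel

Cross-trait post-GWAS prioritization of functional risk-SNPs from summary
statistics and epigenomic annotation.

Genome-wide association studies localize disease signal to loci, not to
variants: the lead SNP of an associated region is usually a proxy in linkage
disequilibrium (LD) with the functional variant, which often sits in
non-coding regulatory sequence. `snpfunnel` implements a staged funnel that
narrows a trait's summary statistics down to a short list of candidate
risk-SNPs and their target genes, borrowing strength from a second,
genetically correlated trait:

1. **Filter** — discard SNPs with association p-value > 5 × 10⁻⁴.
2. **Association blocks** — greedily pick the unconsumed SNP with the lowest
   p-value as a lead (leads ≥ 1 Mb apart on a chromosome) and group it with
   its 30 most significant neighbors within ±500 kb.
3. **Feature maps** — annotate every SNP with binary epigenomic features
   (DNase hypersensitivity, histone modifications, TF binding sites,
   target-gene-function tracks), giving each block a 31 × F binary matrix
   with a validity mask.
4. **Uncertain-label CNN** — label real blocks 1 and shuffled-feature
   controls 0 (per-column permutation within the block, preserving feature
   prevalences), split by chromosome into train/validation/test, pretrain
   the convolutional stack as an autoencoder, and train with soft targets
   (0.9 / 0.05) because a positive block contains at most one causal SNP.
   The network scores each SNP row in [0, 1]; a smooth-maximum
   (multiple-instance) pooling of row scores gives the block score the loss
   is taken against. Performance is reported as block-level ROC AUC on the
   held-out chromosomes.
5. **Candidates** — SNPs with prediction score strictly above 0.5 are
   initial candidates; the best-scoring candidate of each block is its
   block-top.
6. **Target genes** — each block-top is assigned genes by gene body, by the
   3 kb strand-aware window upstream of the TSS (promoter), and by
   precomputed enhancer–gene links.
7. **Cross-trait LD sharing** — intersect both traits' target-gene sets;
   keep a primary-trait candidate only if some second-trait candidate
   linked to a shared gene is in strong LD with it (haplotype r² ≥ 0.8 from
   a phased reference panel; r² is the squared Pearson correlation of
   allele-indicator vectors, D′ = |D|/D_max is also reported).

Because the method's real inputs (large GWAS meta-analyses and epigenome
compendia) cannot be bundled, the package ships a first-class synthetic-data
generator (`snpfunnel.simulate`) that emulates their statistical structure —
LD-block haplotype panels, two traits with partially shared causal genes,
p-value signal concentrated at causal SNPs and their strong-LD partners, and
feature tracks enriched at causal SNPs — together with a truth manifest, so
every stage of the funnel is testable and its recovery of planted truth is
measurable.

## Worked example

```python
from snpfunnel import SimulationConfig, simulate_and_run

truth, manifest, recovery = simulate_and_run(SimulationConfig(seed=7))
```

prints nothing by itself; `examples/04_cross_trait_funnel.py` formats the
result and produces:

```
funnel counts
  trait1: 12000 SNPs -> 312 filtered -> 19 blocks -> 56 candidates -> 18 block-tops  (test AUC 0.867)
  trait2: 12000 SNPs -> 303 filtered -> 19 blocks -> 61 candidates -> 17 block-tops  (test AUC 0.906)
  shared genes: 8; final: 8 SNPs / 8 genes

truth recovery
  planted shared causal genes : 9
  recall    : 0.89
  precision : 1.00
  final SNPs that are causal  : 1.00
  hypergeometric overlap p    : 3.52e-09
```

Reading this: of 12,000 simulated SNPs per trait, ~300 survive the p-value
filter and form 19 association blocks each; the CNN separates real from
shuffled blocks on held-out chromosomes (AUC 0.87/0.91); 8 target genes are
shared between the traits' block-top candidates; after LD-sharing filtering,
8 SNPs mapping to 8 genes remain. Eight of the nine planted shared causal
genes are recovered (recall 0.89), every reported gene was planted
(precision 1.00), every final SNP is a truly causal variant, and the overlap
is far beyond chance (hypergeometric p ≈ 4 × 10⁻⁹).

The other scripts in `examples/` walk through the individual capabilities:
dataset simulation and writers (`01`), block construction and feature/control
maps (`02`), CNN training, evaluation, and candidate selection (`03`).

A thin command-line interface covers the shell-level workflow:

```bash
snpfunnel simulate --seed 7 --out data/          # write a synthetic dataset
snpfunnel run --config pipeline.yaml             # run the funnel on files
snpfunnel simulate-run --seed 7 --out run/       # both, with recovery report
```

## Layout

```
src/snpfunnel/
  simulate.py   synthetic two-trait benchmark + truth manifest
  gwas.py       summary-statistics reading, validation, p-value filter
  blocks.py     association-block construction
  features.py   epigenomic annotation, block feature maps, shuffled controls
  model.py      uncertain-label CNN prioritizer (numpy), selection, AUC
  genes.py      SNP -> target-gene assignment (body / promoter / enhancer)
  ld.py         haplotype LD (r², D′), shared genes, LD-sharing filter
  pipeline.py   end-to-end orchestration, run manifest
  cli.py        thin click front end
docs/methods.md model and generator documentation
examples/       one narrative script per capability
```
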