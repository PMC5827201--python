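# Methods

This document records the statistical model, the conventions and
parameter defaults the package uses, the rationale behind them, and the
known limits of what the synthetic-data machinery can reproduce.

## Genome model and functional regions

Coordinates are 1-based on a 16,569 bp circular genome with the rCRS
coordinate structure. The forward sequence is the light (L) strand; the
heavy (H) strand is its reverse complement. The packaged FASTA is a
deterministic synthetic surrogate: gene boundaries, orientations,
overlaps and reading frames match the real annotation (protein genes
start with ATG, contain no internal stop codons under the vertebrate
mitochondrial code, and reproduce the real incomplete-stop padding),
but the intergenic and intragenic sequence content is generated. This
keeps the package free of third-party data while preserving every
coordinate-level property the algorithms depend on.

The seven functional regions follow the remainder convention: each of
rRNA, tRNA and complexes I/III/IV/V is the union of its genes' spans
counted once (overlapping genes such as ATP8/ATP6 at 8,527–8,572 do not
double-count), and non-coding is whatever is left, giving lengths
1,153 / 2,513 / 1,508 / 6,356 / 1,141 / 3,010 / 888 summing to 16,569.
Positions inside a gene overlap are annotated with both genes and take
the more severe consequence; region assignment uses the first-listed
(most severe) gene.

Consequence annotation uses the vertebrate mitochondrial genetic code
(TGA=Trp, AGA/AGG=stop, ATA=Met) with A-padding of incomplete terminal
codons; genes on the reverse strand are translated from the reverse
complement.

## Variant calling

Input is per-position, strand-split allele counts (parsed from
samtools mpileup text with a base-quality floor, default BAQ ≥ 20, or
read directly as TSV).

A constitutional variant call requires all of:

1. site depth ≥ 100;
2. variant allele fraction VAF ≥ 0.02;
3. variant allele count VAC ≥ 10;
4. the lower bound of the exact (Clopper–Pearson) 99.999% binomial
   confidence interval for the VAF strictly above 0;
5. ≥ 5 variant reads on each strand.

Calls with VAF in [0.02, 0.98] are heteroplasmies, above 0.98
homoplasmies. Threshold comparisons use exact rational arithmetic
(`fractions.Fraction`), so a site at exactly the boundary (e.g. VAC
40 / depth 2000 against VAF ≥ 0.02) passes deterministically with no
floating-point edge behaviour; the test suite pins these boundaries.

A somatic call additionally requires, against the matched normal:

* normal depth ≥ 100;
* tumour−normal VAC difference ≥ 10, by default with the normal count
  rescaled to tumour depth (computed by exact integer
  cross-multiplication); a raw-difference mode is available;
* tumour−normal VAF difference ≥ 0.02;
* the normal VAF outside the tumour's Clopper–Pearson interval.

Linked-artefact flagging takes read-level observations of candidate
variant pairs and flags a pair when the co-occurrence fraction among
reads covering both positions exceeds 0.95; flagged alleles are removed
from both call sets by the pipeline.

## Haplogroups and private variants

The phylotree is a rooted TSV (haplogroup, parent, defining variants);
the packaged tree is a small illustrative subtree. A sample is scored
against every node by |path ∩ sample| − |path \ sample|, matching on
(position, alt); ties prefer the deeper node, then the
lexicographically smallest label, making assignment deterministic.
Constitutional variants then partition exactly into hotspot
(A16182C, A16183C, T16519C by default), global (on the assigned path)
and private.

## Heteroplasmy dynamics

For every normal-tissue heteroplasmy, the tumour VAF at the same
position and allele is looked up **threshold-free** from the raw tumour
counts (a drifted allele must not be censored by the calling cascade;
tumour depth < 100 only sets a low-confidence flag). With
HF = min(VAF, 1 − VAF), the shift report runs two paired t-tests over
pairs:

* ΔHF = normal HF − tumour HF: positive mean under symmetric drift
  toward loss or fixation;
* ΔVAF = tumour VAF − normal VAF: centred at zero under neutral drift,
  displaced only by directional selection.

Pairs drifted beyond the heteroplasmy band are counted as fixed
(> 0.98) or lost (< 0.02).

## Mutational spectra

The 96-bin spectrum is the standard pyrimidine-collapsed convention:
purine-reference substitutions are complemented together with their
trinucleotide context, bins are labelled `5'[class]3'` and ordered
class-major. The strand-resolved spectrum records each variant both as
seen on the L strand and as its complement on the H strand, so the
identity H[X] = L[complement(X)] holds exactly by construction and is
asserted on all inputs; replication-linked deamination of the H strand
predicts elevated H-strand C>T and A>G (forward G>A and T>C).

## Cohort statistics

Region placement is tested with a Pearson goodness-of-fit chi-square
against expected counts proportional to region lengths (df = 6;
regions with expected count < 5 are flagged). Two variant sets are
compared with a 2×7 chi-square of homogeneity. The burden screen runs
a two-sample t-test for binary phenotypes and Pearson correlation for
continuous ones, with Benjamini–Hochberg correction across phenotypes;
zero-variance groups with unequal means are reported as skipped rather
than given a misleading p = 1.

## Simulator

Each tumour–normal pair is generated from an independent seeded stream
(`default_rng([seed, pair_index])`), so pairs are reproducible in
isolation and cohorts are embarrassingly parallel.

* **Haplogroup and variants.** A tree node is drawn per pair; its path
  variants are planted as homoplasmies in both tissues. Private
  variant counts are Poisson (mean 3.0), placed with 4-fold D-Loop
  enrichment, 70% homoplasmic. Normal heteroplasmies (Poisson mean
  1.5) draw VAFs from Beta(1, 15) floored at 0.03. Somatic mutations
  (Poisson mean 1.5) first draw a substitution class from a
  strand-asymmetric weight table (G>A 0.35, T>C 0.25, C>T 0.12, …),
  then a uniform position among matching reference bases, with tumour
  VAF uniform on [0.03, 0.95] and normal VAF 0.
* **Drift.** Normal heteroplasmies drift in the tumour under a
  Wright–Fisher bottleneck with N_seg segregating units for g
  generations (variance p(1−p)(1−(1−1/N_seg)^g), verified against the
  closed form); a directional mode adds a clipped shift.
* **Reads.** Per-sample depth is lognormal around the configured mean
  (sd ≈ 0.5 × mean), per-site depth negative-binomial-dispersed;
  allele counts are binomial in the true VAF with symmetric sequencing
  error e = 5 × 10⁻⁴ (each wrong base at e/3), split binomially across
  strands. The expected observed VAF is therefore
  v′ = v(1 − e) + (1 − v)e/3, the quantity used in recovery checks.
* **Artefacts.** Optionally a linked read-chimera pair is injected
  with read-level observations so the flagging path is testable end to
  end.

### Drift defaults and their calibration

The default bottleneck is **N_seg = 1000, g = 20**. The choice was made
a priori from two requirements: (i) visible HF attrition over a
tumour's mitotic history (effective drift time t = g/N_seg = 0.02,
VAF drift sd ≈ 0.04 at p = 0.3), and (ii) the neutral-drift null must
actually be null for the ΔVAF paired t-test — with violent drift most
heteroplasmies fix or are lost, ΔVAF becomes strongly non-normal and
the nominal 0.05 test anti-conserves (measured type-I ≈ 0.09 at
N_seg = 10, g = 50). Under the defaults the measured type-I over 500
cohorts of 40 pairs is ≈ 0.05–0.07, inside the binomial 3σ band
[0.021, 0.079]. The strong-fixation regime (N_seg = 10, g = 50)
remains available explicitly and is what the power checks use: the
ΔHF test detects planted symmetric fixation with power 1.0 at n = 40.

### Simulator limitations

* Reads are independent binomial draws: no alignment artefacts, indels,
  mapping bias, NUMT contamination or base-quality structure beyond a
  single error rate.
* A normal heteroplasmy that drifts strongly in the tumour can
  legitimately satisfy the somatic contrast filters; truth tables
  record origin classes so evaluations match calls to planted truth by
  position and allele rather than by caller label.
* The phylotree is a toy subtree; haplogroup labels are illustrative,
  not nomenclature-complete.
* The synthetic genome preserves coordinate structure, not real
  sequence, so site-specific annotations of real published mutations
  cannot be reproduced against it (see below).

## Numerical choices

* Exact rational arithmetic for every filter predicate; Clopper–Pearson
  bounds from beta-distribution quantiles (cross-checked against
  statsmodels to 10⁻¹²).
* t-tests and chi-squares delegate to scipy; BH correction is
  cross-checked against statsmodels.
* All randomness flows from explicit `numpy.random.SeedSequence`-style
  integer lists; no global RNG state is used anywhere.

## Unreproducible published results

The package models the analysis of a 2018 study of somatic mtDNA
mutations in diffuse large B-cell lymphoma. Its cohort-scale numbers
derive from controlled-access (dbGaP) sequence data and external
annotation services, and are deliberately **not** reproduced here:

* Table-1-scale cohort counts, the paired t statistics (3.815 on ΔHF,
  −2.898 reported for the VAF comparison), GenBank novelty fractions
  and MutPred median scores (0.72 vs 0.49) all require the primary
  data or external services. The procedures that produce them are
  instead validated on synthetic data (acceptance criteria 3–6).
* **Supplementary annotation (acceptance criterion 2, RED by
  design).** Re-annotating the study's 60 listed somatic mutations to
  the published split (40 protein-coding: 13 synonymous /
  26 non-synonymous / 1 stop-gain; codon positions 35%/27.5%/37.5%)
  requires the supplementary mutation list and the true rCRS sequence.
  Neither ships with this package, and against the synthetic surrogate
  genome the per-site codon content differs, so the criterion cannot
  pass. It is kept as a failing test rather than skipped, so the gap
  is visible.
* **Chi-square discrepancy.** The published per-region counts *are*
  printed and can be recomputed. For the 108 private constitutional
  variants (30/12/7/35/4/15/5 across non-coding, rRNA, tRNA, complexes
  I/III/IV/V), the standard Pearson goodness-of-fit statistic against
  length-proportional expectation is **73.036** (df = 6,
  p ≈ 1 × 10⁻¹³), not the published **68.628**. The difference is not
  explained by rounding; plausible causes include a slightly different
  region-length table or a continuity adjustment, neither of which is
  specified in print. The qualitative conclusion — strongly
  non-proportional placement, driven by non-coding excess — is
  unchanged. For the 60 somatic mutations (4/13/3/21/2/13/4) the same
  formula gives 4.660 (p = 0.588), i.e. no significant departure,
  consistent with the published reading. Both recomputations are
  frozen in `tests/test_acceptance.py` and emitted by
  `scripts/acceptance.py`.
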