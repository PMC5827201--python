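# mitovar

Strand-aware mitochondrial DNA variant analysis for matched
tumour–normal sample pairs: constitutional and somatic variant calling
from per-position allele counts, haplogroup assignment with
private-variant derivation, heteroplasmy-shift statistics, trinucleotide
mutational spectra with strand (replication) asymmetry, cohort-level
region statistics, and a fully seeded synthetic-data generator that
makes every one of those procedures testable without access to
controlled sequencing data.

## Scientific background

Human mitochondrial DNA (mtDNA) is a circular 16,569 bp genome present
in hundreds to thousands of copies per cell. A variant can therefore be
*heteroplasmic* — carried by only a fraction of the molecules — and that
fraction (the variant allele fraction, VAF) is measurable from deep
sequencing as an almost ideal binomial sampling problem. Three
biological layers are distinguished here:

* **Global (haplogroup) variants** — inherited differences from the
  reference that define the sample's branch of the human mtDNA
  phylogeny.
* **Private constitutional variants** — germline variants not explained
  by the assigned haplogroup and not known mutational hotspots.
* **Somatic mutations** — present in the tumour but absent from the
  matched normal tissue.

Tumour expansion acts as a population bottleneck on the mtDNA pool, so
normal-tissue heteroplasmies drift toward loss or fixation in the
tumour: the heteroplasmic fraction HF = min(VAF, 1 − VAF) decreases on
average even when the VAF shows no directional change. mtDNA mutations
also show strong replication-linked strand asymmetry — an excess of
C>T and A>G changes on the heavy (H) strand, attributed to deamination
of the transiently single-stranded parental H-strand — which the
spectrum module quantifies.

## Package layout

| module | contents |
|---|---|
| `mitovar.reference` | mitochondrial genome model, gene table, 7-region functional partition (remainder convention), trinucleotide contexts, vertebrate-mitochondrial-code consequence annotation |
| `mitovar.calling` | mpileup parsing to strand-split allele counts; constitutional filter cascade (depth ≥ 100, VAF ≥ 0.02, VAC ≥ 10, 99.999% Clopper–Pearson lower bound > 0, ≥ 5 reads per strand); somatic caller with tumour-normal contrast filters; linked-artefact flagging |
| `mitovar.haplogroups` | phylotree loading, maximum-agreement haplogroup assignment, hotspot/global/private partition of constitutional variants |
| `mitovar.dynamics` | normal–tumour heteroplasmy pairing, paired t-tests on ΔHF and ΔVAF, shift report |
| `mitovar.spectrum` | 96-bin pyrimidine-collapsed spectrum, L/H strand-resolved substitution spectrum, strand-asymmetry consequence/pathogenicity comparisons |
| `mitovar.cohort` | cohort summary tables, chi-square region-distribution and homogeneity tests, burden association screen with Benjamini–Hochberg correction |
| `mitovar.simulate` | seeded tumour–normal cohort generator: haplogroups from the packaged tree, private/heteroplasmic/somatic planting, Wright–Fisher bottleneck drift, strand-split binomial read counts with sequencing error, linked-artefact injection |
| `mitovar.pipeline` / `mitovar.cli` | end-to-end orchestration, TSV/VCF/JSON output, `mitovar` command-line tool |

The packaged reference sequence is a deterministic synthetic surrogate
with the real rCRS coordinate structure (gene boundaries, lengths,
overlaps, reading frames, 16,569 bp total) but generated sequence
content, so the package ships no third-party data. All coordinates are
1-based rCRS; the forward sequence is the light (L) strand.

## Worked example

Simulate a three-pair cohort and run the full pipeline:

```
$ mitovar all --seed 7 --n-pairs 3 demo
{
  "pairs": 3,
  "sites_read": 99414,
  "constitutional_calls": 27,
  "somatic_calls": 6,
  "private_variants": 13,
  "heteroplasmy_pairs": 6,
  "artefact_flagged": 0
}
```

`demo/data/` holds the count tables, truth tables and manifest;
`demo/results/` holds `calls.tsv`, `calls.vcf`, `haplogroups.tsv`,
`heteroplasmy_pairs.tsv`, `cohort_summary.tsv` and `summary.json`:

```
$ head -4 demo/results/haplogroups.tsv
sample_id  pair_id  haplogroup  score
P000N      P000     U5a         6
P001N      P001     U5          4
P002N      P002     HV          4
```

Individual stages are available as `mitovar simulate`, `call`,
`somatic`, `private`, `shifts`, `spectrum`, `regions` and `report`;
every stage reads and writes plain TSV so they compose with standard
tools. Exit codes: 0 success, 2 input/contract error, 3 internal
invariant violation.

Library use mirrors the CLI:

```python
from mitovar.calling import call_constitutional, call_somatic, read_count_table

normal = read_count_table("demo/data/P000N.tsv")
tumour = read_count_table("demo/data/P000T.tsv")
constitutional = call_constitutional(normal)
somatic = call_somatic(tumour, normal)
```

## Testing and acceptance

```
python -m pytest -q tests/
```

The suite verifies each module against independent oracles (exact
Fraction-arithmetic reimplementation of the filter cascade,
Biopython translation for consequence calls, scipy/statsmodels for the
statistics, exhaustive search for haplogroup assignment).
`tests/test_acceptance.py` holds one test per release criterion;
criterion 2 **fails by design** because it needs an external annotation
table and the true rCRS sequence — see `docs/methods.md` for the
analysis. All other tests pass.

The headline quantities (filter-oracle agreement, simulator parameter
recovery, drift-test type-I error and power, spectrum recovery, and the
frozen recomputation of published region chi-squares) can be computed
for any seed:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Methods, parameter defaults and their rationale, simulator limitations
and known discrepancies with published values are documented in
`docs/methods.md`.
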