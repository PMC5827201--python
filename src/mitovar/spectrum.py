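"""Trinucleotide mutational spectra and strand-asymmetry analyses.

Substitutions are summarised three ways:

* a 96-bin pyrimidine-collapsed spectrum (six substitution classes
  C>A, C>G, C>T, T>A, T>C, T>G by 5'/3' flanking base), the convention
  used for mutational-signature analysis; purine-reference variants are
  complemented -- substitution *and* context -- before binning;
* a strand-resolved tally: each variant is recorded as seen on the light
  strand (forward rCRS) and as its complement on the heavy strand, so
  e.g. forward G>A is C>T on the H-strand and forward T>C is A>G on the
  H-strand.  Asymmetric deamination of the transiently single-stranded
  parental H-strand during replication predicts an excess of H-strand
  C>T and A>G;
* a consequence/pathogenicity comparison of C>T-and-A>G variants grouped
  by the strand on which the pyrimidine-context change occurred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reference import (COMPLEMENT, MitoGenome, RegionMap,
                        ReferenceMismatchError, consequence,
                        revcomp, strand_class, trinucleotide_context)

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: All 12 substitution labels in forward (L-strand) notation.
SUBSTITUTIONS = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)


def complement_substitution(label: str) -> str:
    r, a = label.split(">")
    return f"{COMPLEMENT[r]}>{COMPLEMENT[a]}"


def context_labels() -> list[str]:
    """The 96 bin labels, ordered class-major then 5' then 3' base."""
    out = []
    for cls in PYRIMIDINE_CLASSES:
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{cls}]{three}")
    return out


_LABELS = context_labels()
_LABEL_INDEX = {lab: i for i, lab in enumerate(_LABELS)}


def collapse_to_pyrimidine(ref: str, alt: str,
                           context: str) -> tuple[str, str]:
    """Pyrimidine-centred (class, context) for one substitution.

    Purine-reference substitutions are reverse-complemented together
    with their trinucleotide context; the mapping is idempotent on
    already-pyrimidine input.
    """
    if context[1] != ref:
        raise ValueError("context centre does not match the ref allele")
    if ref in ("C", "T"):
        return f"{ref}>{alt}", context
    return complement_substitution(f"{ref}>{alt}"), revcomp(context)


@dataclass
class SpectrumMatrix:
    """96-bin pyrimidine-collapsed trinucleotide spectrum."""

    counts: np.ndarray  # shape (96,), integer
    set_label: str = ""
    labels: tuple[str, ...] = tuple(_LABELS)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray | None:
        """Counts normalised to sum 1; None for an empty spectrum."""
        if self.total == 0:
            return None
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies
        return pd.DataFrame({
            "context": self.labels,
            "count": self.counts,
            "frequency": np.zeros(96) if freq is None else freq,
        })

    def class_frequencies(self) -> dict[str, float]:
        """Frequency per six-class pyrimidine substitution."""
        freq = self.frequencies
        out = {}
        for i, cls in enumerate(PYRIMIDINE_CLASSES):
            block = slice(i * 16, (i + 1) * 16)
            out[cls] = 0.0 if freq is None else float(freq[block].sum())
        return out


def build_96_spectrum(variants: pd.DataFrame, genome: MitoGenome,
                      set_label: str = "") -> SpectrumMatrix:
    """Bin SNVs (columns pos/ref/alt) into the 96 trinucleotide contexts.

    Contexts wrap circularly at the genome origin.  An empty variant set
    yields all-zero counts with undefined (None) frequencies.
    """
    counts = np.zeros(96, dtype=np.int64)
    for rec in variants.itertuples():
        pos, ref, alt = int(rec.pos), rec.ref, rec.alt
        if genome.base(pos) != ref:
            raise ReferenceMismatchError(
                f"ref {ref} does not match genome at {pos}")
        ctx = trinucleotide_context(pos, genome)
        cls, pctx = collapse_to_pyrimidine(ref, alt, ctx)
        counts[_LABEL_INDEX[f"{pctx[0]}[{cls}]{pctx[2]}"]] += 1
    if counts.sum() == 0:
        warnings.warn("empty variant set: spectrum frequencies undefined",
                      stacklevel=2)
    return SpectrumMatrix(counts=counts, set_label=set_label)


@dataclass
class StrandSpectrum:
    """Per-strand tallies of the 12 substitution labels.

    Every variant appears once on each strand: as its forward label on L
    and as the complementary label on H, so the H tally of class X
    always equals the L tally of complement(X) and each strand's tally
    sums to the total variant count.
    """

    l_counts: dict[str, int] = field(default_factory=dict)
    h_counts: dict[str, int] = field(default_factory=dict)
    set_label: str = ""

    @property
    def total(self) -> int:
        return sum(self.l_counts.values())

    def frequencies(self, strand: str) -> dict[str, float]:
        counts = self.l_counts if strand == "L" else self.h_counts
        n = self.total
        return {k: (v / n if n else 0.0) for k, v in counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand, counts in (("L", self.l_counts), ("H", self.h_counts)):
            for sub in SUBSTITUTIONS:
                rows.append({"strand": strand, "substitution": sub,
                             "count": counts[sub],
                             "frequency": counts[sub] / self.total
                             if self.total else 0.0})
        return pd.DataFrame(rows)


def build_strand_spectrum(variants: pd.DataFrame,
                          set_label: str = "") -> StrandSpectrum:
    """Tally substitutions as seen on each strand (columns ref/alt)."""
    l_counts = {s: 0 for s in SUBSTITUTIONS}
    h_counts = {s: 0 for s in SUBSTITUTIONS}
    for rec in variants.itertuples():
        l_label, h_label = strand_class(rec.ref, rec.alt)
        l_counts[l_label] += 1
        h_counts[h_label] += 1
    return StrandSpectrum(l_counts=l_counts, h_counts=h_counts,
                          set_label=set_label)


# ---------------------------------------------------------------------------
# Strand asymmetry of C>T / A>G consequences and pathogenicity
# ---------------------------------------------------------------------------

#: Forward substitutions whose pyrimidine change lies on the H strand
#: (forward G>A is H-strand C>T; forward T>C is H-strand A>G).
H_STRAND_TRANSITIONS = frozenset({"G>A", "T>C"})
#: Forward substitutions whose pyrimidine change lies on the L strand.
L_STRAND_TRANSITIONS = frozenset({"C>T", "A>G"})

_FIG_CLASSES = ("non-coding", "synonymous", "non-synonymous")


def _collapse_consequence(cons: str) -> str:
    """Collapse the six consequence classes to the three-way grouping.

    tRNA/rRNA variants are non-protein-coding and group with non-coding;
    a stop-gain changes the protein and groups with non-synonymous.
    """
    if cons in ("non-coding", "tRNA", "rRNA"):
        return "non-coding"
    if cons == "stop-gain":
        return "non-synonymous"
    return cons


@dataclass
class StrandConsequenceTable:
    counts: pd.DataFrame        # index strand {H,L}, columns the 3 classes
    proportions: pd.DataFrame
    score_summary: pd.DataFrame  # mean/median/n pathogenicity per strand
    score_test: "TwoSampleTestResult | None"
    notice: str | None = None


@dataclass(frozen=True)
class TwoSampleTestResult:
    t: float
    p: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


def frequency_group_test(values_a, values_b,
                         welch: bool = False) -> TwoSampleTestResult:
    """Two-tailed two-sample t-test (pooled variance; Welch optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group requires n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TwoSampleTestResult(0.0, 1.0, a.size, b.size,
                                       float(a.mean()), float(b.mean()))
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TwoSampleTestResult(float(t), float(p), a.size, b.size,
                               float(a.mean()), float(b.mean()))


def strand_asymmetry_analysis(
    annotated: pd.DataFrame,
    score_column: str = "pathogenicity",
    welch: bool = False,
) -> StrandConsequenceTable:
    """Compare C>T/A>G variants between strands (consequences, scores).

    ``annotated`` needs columns pos/ref/alt/consequence and optionally a
    pathogenicity-score column (NaN = unscored; unscored variants are
    excluded from the score test).  A variant joins the H group iff its
    forward label is G>A or T>C (i.e. H-strand C>T or A>G) and the L
    group iff its forward label is C>T or A>G.
    """
    labels = annotated["ref"] + ">" + annotated["alt"]
    groups = {
        "H": annotated.loc[labels.isin(H_STRAND_TRANSITIONS)],
        "L": annotated.loc[labels.isin(L_STRAND_TRANSITIONS)],
    }
    counts = pd.DataFrame(0, index=["H", "L"], columns=list(_FIG_CLASSES))
    for strand, sub in groups.items():
        collapsed = sub["consequence"].map(_collapse_consequence)
        for cls, n in collapsed.value_counts().items():
            counts.loc[strand, cls] = int(n)
    totals = counts.sum(axis=1)
    proportions = counts.div(totals.replace(0, np.nan), axis=0)

    score_rows = []
    scored: dict[str, np.ndarray] = {}
    for strand, sub in groups.items():
        if score_column in sub.columns:
            nonsyn = sub.loc[
                sub["consequence"].map(_collapse_consequence)
                == "non-synonymous"]
            vals = nonsyn[score_column].dropna().to_numpy(dtype=float)
        else:
            vals = np.array([])
        scored[strand] = vals
        score_rows.append({
            "strand": strand, "n_scored": vals.size,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "median": float(np.median(vals)) if vals.size else np.nan,
        })
    score_summary = pd.DataFrame(score_rows).set_index("strand")

    notice = None
    score_test = None
    if scored["H"].size >= 2 and scored["L"].size >= 2:
        score_test = frequency_group_test(scored["H"], scored["L"],
                                          welch=welch)
    else:
        notice = ("score test skipped: fewer than 2 scored non-synonymous "
                  "variants in a strand group")
    return StrandConsequenceTable(
        counts=counts, proportions=proportions,
        score_summary=score_summary, score_test=score_test, notice=notice)


def annotate_variants(variants: pd.DataFrame, region_map: RegionMap,
                      genome: MitoGenome,
                      scores: pd.DataFrame | None = None,
                      frequencies: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join consequence/region/gene annotation onto a variant table.

    ``scores``/``frequencies`` are optional side tables keyed on
    pos/ref/alt with a ``pathogenicity`` / ``population_frequency``
    column; these values are always supplied as inputs, never computed.
    """
    out = variants.copy()
    cons, genes, regions, codon_pos = [], [], [], []
    for rec in out.itertuples():
        call = consequence(int(rec.pos), rec.ref, rec.alt, region_map, genome)
        cons.append(call.consequence)
        genes.append(",".join(call.genes) if call.genes else "")
        hits = region_map.locate(int(rec.pos))
        if call.gene_calls:
            best = max(call.gene_calls,
                       key=lambda gc: _severity_index(gc.consequence))
            regions.append(best.gene.region)
        else:
            regions.append(hits[0][0])
        codon_pos.append(call.codon_position)
    out["consequence"] = cons
    out["gene"] = genes
    out["region"] = regions
    out["codon_position"] = codon_pos
    for table, col in ((scores, "pathogenicity"),
                       (frequencies, "population_frequency")):
        if table is not None:
            out = out.merge(table[["pos", "ref", "alt", col]],
                            on=["pos", "ref", "alt"], how="left")
    return out


def _severity_index(cons: str) -> int:
    from .reference import CONSEQUENCE_SEVERITY
    return CONSEQUENCE_SEVERITY.index(cons)


# ---------------------------------------------------------------------------
# Nuclear variant contexts (linear contigs)
# ---------------------------------------------------------------------------

def nuclear_context_annotation(variants: pd.DataFrame,
                               reference_fasta) -> pd.DataFrame:
    """Attach 3-mer contexts to nuclear SNVs from a linear reference.

    ``variants`` needs chrom/pos/ref/alt.  Variants at contig edges
    (no 5' or 3' base) are dropped with a notice; a chromosome missing
    from the reference is an error.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(reference_fasta), as_raw=True, sequence_always_upper=True)
    rows = []
    dropped = 0
    for rec in variants.itertuples():
        chrom = str(rec.chrom)
        if chrom not in fa:
            raise KeyError(f"chromosome {chrom!r} absent from reference")
        pos = int(rec.pos)
        if pos < 2 or pos > len(fa[chrom]) - 1:
            dropped += 1
            continue
        ctx = fa[chrom][pos - 2:pos + 1]
        if ctx[1] != rec.ref:
            raise ReferenceMismatchError(
                f"ref {rec.ref} does not match reference at {chrom}:{pos}")
        cls, pctx = collapse_to_pyrimidine(rec.ref, rec.alt, ctx)
        rows.append({"chrom": chrom, "pos": pos, "ref": rec.ref,
                     "alt": rec.alt, "context": ctx,
                     "pyrimidine_class": cls, "pyrimidine_context": pctx})
    if dropped:
        warnings.warn(f"{dropped} variant(s) at contig edges dropped",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "context", "pyrimidine_class",
                                       "pyrimidine_context"])
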