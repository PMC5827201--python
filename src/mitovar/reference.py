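"""Circular human mitochondrial reference model and functional annotation.

Coordinates throughout are 1-based inclusive on the 16,569-bp rCRS
(revised Cambridge Reference Sequence), matching variant nomenclature such
as ``G11711A``.  The forward rCRS sequence is the light (L) strand; the
heavy (H) strand is its reverse complement.

The packaged reference (``data/rcrs_synthetic.fasta``) carries the
*authentic* rCRS gene coordinates -- they reproduce the canonical
functional-region lengths exactly -- but a **synthetic** nucleotide
sequence generated by :func:`synthetic_rcrs_sequence` (the real sequence
is not redistributed with this package).  Users with the real rCRS FASTA
can point every entry point at it; the coordinate annotation is identical.

The genome is partitioned into seven functional regions: non-coding
(control region plus intergenic gaps), rRNA, tRNA, and the mtDNA-encoded
subunits of OxPhos complexes I, III, IV and V.  Because three gene pairs
overlap (ATP8/ATP6, ND4L/ND4, tRNA-Cys/tRNA-Tyr and tRNA-Ile/tRNA-Gln),
the non-coding length is defined as the remainder ``16569 - sum(gene
lengths)`` so that the seven region lengths always total 16,569.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

GENOME_LENGTH = 16569

#: The seven functional-region labels, in canonical reporting order.
REGIONS = (
    "non-coding",
    "rRNA",
    "tRNA",
    "complex I",
    "complex III",
    "complex IV",
    "complex V",
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Consequence classes ordered by increasing severity.
CONSEQUENCE_SEVERITY = (
    "non-coding",
    "tRNA",
    "rRNA",
    "synonymous",
    "non-synonymous",
    "stop-gain",
)

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class ReferenceMismatchError(ValueError):
    """Raised when a stated reference allele contradicts the genome."""


@dataclass(frozen=True)
class MitoGenome:
    """A circular mitochondrial genome sequence."""

    sequence: str
    name: str = "chrM"

    def __post_init__(self) -> None:
        if len(self.sequence) != GENOME_LENGTH:
            raise ValueError(
                f"mitochondrial genome must be {GENOME_LENGTH} bp, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("genome alphabet must be within {A,C,G,T,N}")

    def base(self, position: int) -> str:
        """Base at a 1-based position with circular wrap-around."""
        return self.sequence[(position - 1) % GENOME_LENGTH]

    def __len__(self) -> int:
        return GENOME_LENGTH


@dataclass(frozen=True)
class GeneRecord:
    """One annotated mitochondrial gene (1-based inclusive coordinates)."""

    name: str
    start: int
    end: int
    kind: str  # protein | tRNA | rRNA
    orientation: str  # forward | reverse
    complex: str  # I | III | IV | V | none

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "tRNA", "rRNA"):
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def region(self) -> str:
        if self.kind == "protein":
            return f"complex {self.complex}"
        return self.kind


@dataclass
class RegionMap:
    """Seven-region functional partition of the mitochondrial genome.

    ``lengths`` follows the remainder convention: each region's length is
    the sum of its gene lengths (overlapping positions counted once per
    gene) and the non-coding length is ``genome_length`` minus the grand
    total, so the seven lengths always sum to ``genome_length``.
    """

    genes: tuple[GeneRecord, ...]
    genome_length: int = GENOME_LENGTH
    lengths: dict[str, int] = field(default_factory=dict)
    _index: list[tuple[int, ...]] = field(default_factory=list, repr=False)

    def locate(self, position: int) -> list[tuple[str, GeneRecord | None]]:
        """All (region, gene) assignments covering a 1-based position.

        Positions in no gene map to ``("non-coding", None)``; overlap
        positions return one entry per covering gene.
        """
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside [1, {self.genome_length}]"
            )
        hits = self._index[position - 1]
        if not hits:
            return [("non-coding", None)]
        return [(self.genes[i].region, self.genes[i]) for i in hits]

    def genes_at(self, position: int) -> list[GeneRecord]:
        return [g for _, g in self.locate(position) if g is not None]


def build_region_map(
    genes: Iterable[GeneRecord], genome_length: int = GENOME_LENGTH
) -> RegionMap:
    """Partition the genome into the seven functional regions.

    Region lengths are sums of gene lengths per class; the non-coding
    length is the remainder ``genome_length - sum(all gene lengths)``,
    which absorbs the double-counted gene overlaps.
    """
    genes = tuple(genes)
    seen: set[tuple] = set()
    for g in genes:
        if g.end > genome_length:
            raise ValueError(f"gene {g.name} extends beyond the genome")
        key = (g.name, g.start, g.end, g.kind)
        if key in seen:
            raise ValueError(f"duplicate gene record {g.name}")
        seen.add(key)

    lengths = {r: 0 for r in REGIONS}
    for g in genes:
        lengths[g.region] += g.length
    coding_total = sum(g.length for g in genes)
    if coding_total > genome_length:
        raise ValueError("gene lengths exceed the genome length")
    lengths["non-coding"] = genome_length - coding_total

    index: list[tuple[int, ...]] = [()] * genome_length
    for i, g in enumerate(genes):
        for p in range(g.start - 1, g.end):
            index[p] = index[p] + (i,)
    return RegionMap(genes=genes, genome_length=genome_length,
                     lengths=lengths, _index=index)


# ---------------------------------------------------------------------------
# Packaged annotation and reference loading
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("mitovar").joinpath("data", name))


def load_gene_table(path: str | Path | None = None) -> list[GeneRecord]:
    """Read a gene-annotation TSV (name, start, end, kind, orientation, complex)."""
    path = _data_path("rcrs_genes.tsv") if path is None else Path(path)
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                GeneRecord(
                    name=row["name"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    kind=row["kind"],
                    orientation=row["orientation"],
                    complex=row["complex"],
                )
            )
    return records


def load_reference(path: str | Path | None = None) -> MitoGenome:
    """Load a single-record mitochondrial FASTA (default: packaged synthetic rCRS)."""
    path = _data_path("rcrs_synthetic.fasta") if path is None else Path(path)
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    raise ValueError("reference FASTA must contain one record")
                name = line[1:].split()[0]
            elif line:
                chunks.append(line.upper())
    if name is None:
        raise ValueError(f"no FASTA record in {path}")
    return MitoGenome(sequence="".join(chunks), name=name)


def default_region_map() -> RegionMap:
    return build_region_map(load_gene_table())


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

class GeneticCode:
    """Vertebrate mitochondrial genetic code (NCBI translation table 2).

    Distinctive reassignments relative to the standard code: TGA->Trp,
    AGA/AGG->Stop, ATA->Met.  Stops are represented as ``"*"``.
    """

    def __init__(self) -> None:
        self.table: dict[str, str] = dict(_MITO_TABLE.forward_table)
        for codon in _MITO_TABLE.stop_codons:
            self.table[codon] = "*"
        assert len(self.table) == 64

    def translate(self, codon: str) -> str:
        return self.table[codon.upper()]


VERTEBRATE_MITO_CODE = GeneticCode()


# ---------------------------------------------------------------------------
# Per-variant annotation
# ---------------------------------------------------------------------------

def trinucleotide_context(position: int, genome: MitoGenome) -> str:
    """3-mer centred on a position, wrapping circularly at the origin."""
    if not 1 <= position <= GENOME_LENGTH:
        raise ValueError(f"position {position} outside the genome")
    return genome.base(position - 1) + genome.base(position) + genome.base(position + 1)


def strand_class(ref: str, alt: str) -> tuple[str, str]:
    """Substitution labels as seen on the L strand and on the H strand.

    The L label records the change on the forward rCRS sequence; the H
    label is its complement (forward G>A is C>T on the heavy strand,
    forward T>C is A>G on the heavy strand).
    """
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"non-nucleotide allele {b!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    return f"{ref}>{alt}", f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


@dataclass(frozen=True)
class GeneConsequence:
    gene: GeneRecord
    consequence: str
    codon_position: int | None = None  # 1..3, protein genes only
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


@dataclass(frozen=True)
class ConsequenceCall:
    position: int
    ref: str
    alt: str
    consequence: str  # most severe across covering genes
    gene_calls: tuple[GeneConsequence, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(gc.gene.name for gc in self.gene_calls)

    @property
    def codon_position(self) -> int | None:
        """Codon position of the most severe protein-gene call."""
        best = None
        for gc in self.gene_calls:
            if gc.codon_position is None:
                continue
            if best is None or (CONSEQUENCE_SEVERITY.index(gc.consequence)
                                > CONSEQUENCE_SEVERITY.index(best.consequence)):
                best = gc
        return None if best is None else best.codon_position


def _codon_at(gene: GeneRecord, position: int, genome: MitoGenome) -> tuple[str, int, int]:
    """Reference codon, 0-based in-codon offset, codon start offset.

    Codons are read on the coding strand (reverse complement for
    reverse-orientation genes).  Genes with incomplete terminal stop
    codons (length not a multiple of 3; completed by polyadenylation in
    vivo) are padded with ``A``.
    """
    if gene.orientation == "forward":
        offset = position - gene.start
    else:
        offset = gene.end - position
    codon_index, in_codon = divmod(offset, 3)
    bases = []
    for k in range(3):
        o = codon_index * 3 + k
        if gene.orientation == "forward":
            p = gene.start + o
            if p > gene.end:
                bases.append("A")  # polyadenylation-completed stop
            else:
                bases.append(genome.base(p))
        else:
            p = gene.end - o
            if p < gene.start:
                bases.append("A")
            else:
                bases.append(COMPLEMENT[genome.base(p)])
    return "".join(bases), in_codon, codon_index


def consequence(
    position: int,
    ref: str,
    alt: str,
    region_map: RegionMap,
    genome: MitoGenome,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> ConsequenceCall:
    """Functional consequence of a single-nucleotide substitution.

    Every gene covering the position is evaluated; the primary call is
    the most severe (stop-gain > non-synonymous > synonymous).  Positions
    outside all genes are non-coding.
    """
    ref, alt = ref.upper(), alt.upper()
    if genome.base(position) != ref:
        raise ReferenceMismatchError(
            f"reference allele {ref} does not match the genome "
            f"({genome.base(position)}) at position {position}"
        )
    strand_class(ref, alt)  # validates alleles

    gene_calls: list[GeneConsequence] = []
    for region, gene in region_map.locate(position):
        if gene is None:
            continue
        if gene.kind in ("tRNA", "rRNA"):
            gene_calls.append(GeneConsequence(gene=gene, consequence=gene.kind))
            continue
        ref_codon, in_codon, _ = _codon_at(gene, position, genome)
        coding_alt = alt if gene.orientation == "forward" else COMPLEMENT[alt]
        alt_codon = (
            ref_codon[:in_codon] + coding_alt + ref_codon[in_codon + 1:]
        )
        ref_aa = code.translate(ref_codon)
        alt_aa = code.translate(alt_codon)
        if alt_aa == ref_aa:
            cls = "synonymous"
        elif alt_aa == "*" and ref_aa != "*":
            cls = "stop-gain"
        else:
            cls = "non-synonymous"
        gene_calls.append(
            GeneConsequence(
                gene=gene, consequence=cls, codon_position=in_codon + 1,
                ref_codon=ref_codon, alt_codon=alt_codon,
                ref_aa=ref_aa, alt_aa=alt_aa,
            )
        )
    if not gene_calls:
        primary = "non-coding"
    else:
        primary = max(
            (gc.consequence for gc in gene_calls),
            key=CONSEQUENCE_SEVERITY.index,
        )
    return ConsequenceCall(
        position=position, ref=ref, alt=alt,
        consequence=primary, gene_calls=tuple(gene_calls),
    )


# ---------------------------------------------------------------------------
# Synthetic reference sequence (packaged stand-in)
# ---------------------------------------------------------------------------

# L-strand base composition of human mtDNA (approximate published values).
_BASE_FREQS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}
_STOPS = set(_MITO_TABLE.stop_codons)

#: Seed used to generate the packaged synthetic reference.
PACKAGED_SEQUENCE_SEED = 20180226


def synthetic_rcrs_sequence(
    genes: Sequence[GeneRecord] | None = None,
    seed: int = PACKAGED_SEQUENCE_SEED,
) -> str:
    """Deterministic synthetic stand-in for the rCRS nucleotide sequence.

    The generated sequence is *not* the rCRS.  It shares its length, its
    overall L-strand base composition, its first seven bases (GATCACA)
    and -- through the authentic gene coordinate table -- its gene
    structure: protein genes are codon-structured open reading frames on
    the correct strand (ATG start, no internal stop where the frame is
    unconstrained by an overlapping gene, terminal TAA or an incomplete
    T/TA stop completed by A-padding).  The ND4 codon covering position
    11711 is fixed to GCC so the recurrent-variant example G11711A is a
    non-synonymous Ala->Thr change, as in the real genome.
    """
    if genes is None:
        genes = load_gene_table()
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_BASE_FREQS))
    probs = np.array(list(_BASE_FREQS.values()))
    probs = probs / probs.sum()

    seq: list[str | None] = [None] * GENOME_LENGTH

    def draw(n: int) -> list[str]:
        return list(rng.choice(alphabet, size=n, p=probs))

    def genome_pos(gene: GeneRecord, coding_offset: int) -> int:
        # 0-based genome index for a 0-based coding-strand offset
        if gene.orientation == "forward":
            return gene.start - 1 + coding_offset
        return gene.end - 1 - coding_offset

    proteins = sorted((g for g in genes if g.kind == "protein"),
                      key=lambda g: g.start)
    # start codons first so ATG wins inside gene overlaps (ATP8/ATP6, ND4L/ND4)
    for g in proteins:
        for k, b in enumerate("ATG"):
            p = genome_pos(g, k)
            if seq[p] is None:
                seq[p] = b if g.orientation == "forward" else COMPLEMENT[b]
    for g in proteins:
        n = g.length
        n_full, tail = divmod(n, 3)
        for ci in range(n_full):
            pos3 = [genome_pos(g, ci * 3 + k) for k in range(3)]
            fixed = [seq[p] for p in pos3]
            if g.orientation == "reverse":
                fixed = [None if b is None else COMPLEMENT[b] for b in fixed]
            if ci == n_full - 1 and tail == 0 and all(b is None for b in fixed):
                codon = list("TAA")
            else:
                codon = list(fixed)
                # avoid in-frame stops wherever at least one base is free
                for _ in range(100):
                    codon = [b if b is not None else draw(1)[0] for b in fixed]
                    if "".join(codon) not in _STOPS or None not in fixed:
                        break
                if ci == n_full - 1 and tail == 0:
                    # terminal stop: force where free
                    codon = [f if f is not None else t
                             for f, t in zip(fixed, "TAA")]
            for p, b in zip(pos3, codon):
                if seq[p] is None:
                    seq[p] = b if g.orientation == "forward" else COMPLEMENT[b]
        if tail:  # incomplete terminal stop: T or TA, A-padded in vivo
            partial = "T" if tail == 1 else "TA"
            for k, b in enumerate(partial):
                p = genome_pos(g, n_full * 3 + k)
                if seq[p] is None:
                    seq[p] = b if g.orientation == "forward" else COMPLEMENT[b]

    # fix the ND4 codon covering 11711 (codon 318 of ND4) to GCC
    nd4 = next(g for g in proteins if g.name == "ND4")
    ci = (11711 - nd4.start) // 3
    for k, b in enumerate("GCC"):
        seq[nd4.start - 1 + ci * 3 + k] = b

    for i, b in enumerate("GATCACA"):
        seq[i] = b
    free = [i for i in range(GENOME_LENGTH) if seq[i] is None]
    fill = draw(len(free))
    for i, b in zip(free, fill):
        seq[i] = b
    return "".join(seq)  # type: ignore[arg-type]


def write_fasta(sequence: str, path: str | Path, name: str = "chrM",
                description: str = "", width: int = 70) -> None:
    with open(path, "w") as fh:
        header = f">{name} {description}".rstrip()
        fh.write(header + "\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")
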