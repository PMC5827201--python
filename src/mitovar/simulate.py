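"""Seeded tumour-normal mitochondrial data generator with known truth.

Each simulated pair carries four planted variant classes on top of the
packaged reference:

* **global** haplogroup variants -- the defining variants of a node drawn
  from the phylotree, homoplasmic in both tissues;
* **private** constitutional variants -- placed with D-Loop enrichment,
  mostly homoplasmic with a low-heteroplasmy minority;
* constitutional **heteroplasmies** -- low VAF in the normal (most mass
  below 0.10), transformed in the tumour by a drift model;
* **somatic** mutations -- uniform positions, substitution class drawn
  from strand-labelled spectrum weights with H-strand C>T and A>G
  elevated, present only in the tumour.

Read counts are emitted per position: depth is overdispersed around the
target mean (a between-sample lognormal factor times a within-sample
negative binomial, reflecting that mtDNA coverage varies far more
between samples than along the genome), allele counts are binomial in
the true VAF, strands split 50/50, and a per-base error process
scatters reference reads onto the three other alleles.  Heteroplasmy
drift uses an explicit Wright-Fisher bottleneck (repeated binomial
resampling of ``n_seg`` segregating units), which is mean-preserving --
neutral -- with variance ``p(1-p)(1-(1-1/N)^g)``.

All randomness flows from ``(seed, pair_index)`` sub-streams so any
single pair is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import haplogroups as hg
from .calling import ALLELES, COUNT_COLUMNS
from .reference import GENOME_LENGTH, MitoGenome, RegionMap, load_reference
from .reference import default_region_map, strand_class

_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Default strand-labelled somatic substitution weights (forward
#: notation).  G>A (H-strand C>T) and T>C (H-strand A>G) carry the
#: deamination excess; L-strand C>T/A>G and the ROS class C>A are minor;
#: the remaining transversions share a small uniform floor.
DEFAULT_SOMATIC_WEIGHTS = {
    "G>A": 0.35, "T>C": 0.25, "C>T": 0.12, "A>G": 0.08,
    "C>A": 0.05, "G>T": 0.03,
    "T>A": 0.02, "A>T": 0.02, "C>G": 0.02, "G>C": 0.02,
    "T>G": 0.02, "A>C": 0.02,
}

#: D-Loop / control region span (wraps the origin).
DLOOP_START, DLOOP_END = 16024, 576


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the generator."""

    seed: int = 0
    n_pairs: int = 20
    mean_depth: float = 2000.0
    sample_depth_sigma: float = 0.5      # between-sample lognormal sigma
    position_dispersion: float = 50.0    # within-sample NB size parameter
    error_rate: float = 5e-4
    n_private_mean: float = 3.0          # Poisson means (per-sample draws)
    n_het_mean: float = 1.5
    n_somatic_mean: float = 1.5
    n_private_per_sample: int | None = None  # fixed counts override Poisson
    n_het_per_sample: int | None = None
    n_somatic_per_sample: int | None = None
    private_homoplasmy_prob: float = 0.7
    het_vaf_beta: tuple[float, float] = (1.0, 15.0)
    het_vaf_floor: float = 0.03
    somatic_vaf_range: tuple[float, float] = (0.03, 0.95)
    somatic_spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOMATIC_WEIGHTS))
    private_dloop_enrichment: float = 4.0
    drift_model: str = "neutral_bottleneck"  # or "directional"
    n_seg: int = 1000
    generations: int = 20
    directional_shift: float = 0.2
    artefact_pair_rate: float = 0.0

    def __post_init__(self) -> None:
        w = np.array(list(self.somatic_spectrum_weights.values()))
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("somatic_spectrum_weights must sum to 1")
        for name in ("error_rate", "artefact_pair_rate",
                     "private_homoplasmy_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_depth <= 0 or self.n_seg < 1:
            raise ValueError("depths positive, n_seg >= 1 required")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


TRUTH_COLUMNS = (
    "pair_id", "pos", "ref", "alt", "variant_class",
    "normal_vaf", "tumour_vaf", "l_label", "h_label", "region",
)


@dataclass
class SimulatedPair:
    pair_id: str
    normal_sample: str
    tumour_sample: str
    haplogroup: str
    normal_counts: pd.DataFrame
    tumour_counts: pd.DataFrame
    truth: pd.DataFrame
    read_observations: pd.DataFrame  # empty unless artefacts injected
    artefact_pairs: list[tuple[tuple[int, str], tuple[int, str]]]


# ---------------------------------------------------------------------------
# Drift models
# ---------------------------------------------------------------------------

def neutral_bottleneck_drift(vaf, n_seg: int, generations: int,
                             rng: np.random.Generator):
    """Wright-Fisher bottleneck drift of heteroplasmy fractions.

    Repeated binomial resampling of ``n_seg`` segregating mtDNA units
    for ``generations`` rounds; 0 and 1 are absorbing and the
    expectation is preserved (neutrality).
    """
    x = np.atleast_1d(np.asarray(vaf, dtype=float)).copy()
    for _ in range(generations):
        x = rng.binomial(n_seg, x) / n_seg
    return x if np.ndim(vaf) else float(x[0])


def directional_drift(vaf, shift: float):
    """Deterministic directional selection: VAF shifted toward fixation."""
    return np.clip(np.asarray(vaf, dtype=float) + shift, 0.0, 1.0)


def _apply_drift(vaf: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.drift_model == "neutral_bottleneck":
        return np.atleast_1d(
            neutral_bottleneck_drift(vaf, config.n_seg,
                                     config.generations, rng))
    if config.drift_model == "directional":
        return directional_drift(vaf, config.directional_shift)
    raise ValueError(f"unknown drift model {config.drift_model!r}")


# ---------------------------------------------------------------------------
# Planted-variant placement
# ---------------------------------------------------------------------------

def _dloop_mask() -> np.ndarray:
    mask = np.zeros(GENOME_LENGTH, dtype=bool)
    mask[DLOOP_START - 1:] = True
    mask[:DLOOP_END] = True
    return mask


_DLOOP = _dloop_mask()


def _draw_count(rng, fixed: int | None, mean: float) -> int:
    return fixed if fixed is not None else int(rng.poisson(mean))


def _draw_positions(rng: np.random.Generator, n: int, used: set[int],
                    weights: np.ndarray | None = None) -> list[int]:
    avail = np.array([p for p in range(1, GENOME_LENGTH + 1)
                      if p not in used])
    if n > avail.size:
        raise ValueError("more planted variants than genome positions")
    if weights is None:
        w = None
    else:
        w = weights[avail - 1]
        w = w / w.sum()
    chosen = rng.choice(avail, size=n, replace=False, p=w)
    used.update(int(p) for p in chosen)
    return [int(p) for p in chosen]


def _het_vaf(rng: np.random.Generator, config: SimulationConfig,
             size: int) -> np.ndarray:
    a, b = config.het_vaf_beta
    floor = config.het_vaf_floor
    return floor + (1.0 - floor) * rng.beta(a, b, size=size)


def _constitutional_alt(rng: np.random.Generator, ref: str) -> str:
    # transitions dominate constitutional variation
    if rng.random() < 0.8:
        return _TRANSITION[ref]
    choices = [a for a in ALLELES if a != ref and a != _TRANSITION[ref]]
    return choices[rng.integers(len(choices))]


# ---------------------------------------------------------------------------
# Count emission
# ---------------------------------------------------------------------------

def _depths(rng: np.random.Generator, config: SimulationConfig,
            size: int) -> np.ndarray:
    sigma = config.sample_depth_sigma
    sample_mean = config.mean_depth * rng.lognormal(-sigma ** 2 / 2, sigma)
    r = config.position_dispersion
    p = r / (r + sample_mean)
    return rng.negative_binomial(r, p, size=size)


def _emit_counts(rng: np.random.Generator, config: SimulationConfig,
                 genome: MitoGenome, sample_id: str,
                 planted: dict[int, tuple[str, float]]) -> pd.DataFrame:
    """Per-position strand-split counts for one sample.

    ``planted`` maps position -> (alt allele, true VAF).
    """
    L = GENOME_LENGTH
    depth = _depths(rng, config, L).astype(np.int64)
    ref_idx = np.fromiter((_ALLELE_INDEX[genome.base(p)]
                           for p in range(1, L + 1)), dtype=np.int64,
                          count=L)
    counts = np.zeros((L, 4), dtype=np.int64)
    counts[np.arange(L), ref_idx] = depth
    for pos, (alt, vaf) in planted.items():
        i = pos - 1
        vac = int(rng.binomial(depth[i], vaf))
        counts[i, _ALLELE_INDEX[alt]] += vac
        counts[i, ref_idx[i]] -= vac
    if config.error_rate > 0:
        ref_counts = counts[np.arange(L), ref_idx]
        err = rng.binomial(ref_counts, config.error_rate)
        e1 = rng.binomial(err, 1 / 3)
        e2 = rng.binomial(err - e1, 1 / 2)
        e3 = err - e1 - e2
        counts[np.arange(L), ref_idx] -= err
        splits = np.column_stack([e1, e2, e3])
        others = np.array([[j for j in range(4) if j != r]
                           for r in range(4)])  # non-ref allele indices
        per_pos_others = others[ref_idx]  # (L, 3)
        for k in range(3):
            np.add.at(counts, (np.arange(L), per_pos_others[:, k]),
                      splits[:, k])
    fwd = rng.binomial(counts, 0.5)
    rev = counts - fwd
    data = {"sample_id": sample_id,
            "pos": np.arange(1, L + 1),
            "ref": [genome.base(p) for p in range(1, L + 1)]}
    for a, i in _ALLELE_INDEX.items():
        data[f"{a}_fwd"] = fwd[:, i]
        data[f"{a}_rev"] = rev[:, i]
    return pd.DataFrame(data, columns=list(COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# Artefact injection
# ---------------------------------------------------------------------------

def inject_artefact_pair(counts: pd.DataFrame,
                         positions: tuple[int, int],
                         alts: tuple[str, str],
                         n_linked: int,
                         n_covering: int,
                         rng: np.random.Generator,
                         read_prefix: str = "art") -> tuple[pd.DataFrame,
                                                            pd.DataFrame]:
    """Add a perfectly read-linked alt pair to a count table.

    Emits ``n_covering`` synthetic reads spanning both positions;
    ``n_linked`` of them carry both alternate alleles, the remainder the
    reference at both.  Returns the modified counts and the read-level
    observations for artefact flagging.
    """
    p1, p2 = positions
    if p1 == p2:
        raise ValueError("artefact pair positions must differ")
    a1, a2 = alts
    counts = counts.copy()
    obs = []
    refs = {}
    for p in (p1, p2):
        row = counts.index[counts["pos"] == p]
        if len(row) != 1:
            raise ValueError(f"position {p} absent from count table")
        refs[p] = counts.loc[row[0], "ref"]
    for i in range(n_covering):
        read_id = f"{read_prefix}_{p1}_{p2}_{i}"
        linked = i < n_linked
        for p, a in ((p1, a1), (p2, a2)):
            allele = a if linked else refs[p]
            obs.append({"read_id": read_id, "pos": p, "allele": allele})
            row = counts.index[counts["pos"] == p][0]
            strand = "fwd" if rng.random() < 0.5 else "rev"
            counts.loc[row, f"{allele}_{strand}"] += 1
    return counts, pd.DataFrame(obs, columns=["read_id", "pos", "allele"])


# ---------------------------------------------------------------------------
# Pair and cohort simulation
# ---------------------------------------------------------------------------

def simulate_pair(config: SimulationConfig, pair_index: int,
                  genome: MitoGenome | None = None,
                  region_map: RegionMap | None = None,
                  tree: hg.Phylotree | None = None) -> SimulatedPair:
    """Simulate one tumour-normal pair; deterministic in (seed, pair_index)."""
    genome = genome or load_reference()
    region_map = region_map or default_region_map()
    tree = tree or hg.load_phylotree()
    rng = np.random.default_rng([config.seed, pair_index])

    pair_id = f"P{pair_index:03d}"
    used: set[int] = set()
    truth_rows: list[dict] = []

    def plant(pos, ref, alt, cls, nvaf, tvaf):
        l_label, h_label = strand_class(ref, alt)
        truth_rows.append({
            "pair_id": pair_id, "pos": pos, "ref": ref, "alt": alt,
            "variant_class": cls, "normal_vaf": nvaf, "tumour_vaf": tvaf,
            "l_label": l_label, "h_label": h_label,
            "region": region_map.locate(pos)[0][0],
        })

    # 1. haplogroup backbone: homoplasmic in both tissues
    labels = sorted(tree.nodes)
    haplogroup = labels[rng.integers(len(labels))]
    for pos, ref, alt in tree.path_variants(haplogroup):
        if genome.base(pos) != ref:
            raise ValueError(f"tree variant ref mismatch at {pos}")
        used.add(pos)
        plant(pos, ref, alt, "global", 1.0, 1.0)

    # 2. private constitutional variants, D-Loop enriched
    dloop_weights = np.where(_DLOOP, config.private_dloop_enrichment, 1.0)
    n_priv = _draw_count(rng, config.n_private_per_sample,
                         config.n_private_mean)
    for pos in _draw_positions(rng, n_priv, used, dloop_weights):
        ref = genome.base(pos)
        alt = _constitutional_alt(rng, ref)
        if rng.random() < config.private_homoplasmy_prob:
            nvaf = tvaf = 1.0
        else:
            nvaf = float(_het_vaf(rng, config, 1)[0])
            tvaf = float(_apply_drift(np.array([nvaf]), config, rng)[0])
        plant(pos, ref, alt, "private", nvaf, tvaf)

    # 3. constitutional heteroplasmies that drift in the tumour
    n_het = _draw_count(rng, config.n_het_per_sample, config.n_het_mean)
    het_pos = _draw_positions(rng, n_het, used, dloop_weights)
    nvafs = _het_vaf(rng, config, n_het)
    tvafs = _apply_drift(nvafs, config, rng) if n_het else np.array([])
    for pos, nvaf, tvaf in zip(het_pos, nvafs, tvafs):
        ref = genome.base(pos)
        plant(pos, ref, _constitutional_alt(rng, ref), "heteroplasmy",
              float(nvaf), float(tvaf))

    # 4. somatic mutations: uniform positions, strand-asymmetric classes
    weights = config.somatic_spectrum_weights
    subs = list(weights)
    probs = np.array([weights[s] for s in subs])
    probs = probs / probs.sum()
    n_som = _draw_count(rng, config.n_somatic_per_sample,
                        config.n_somatic_mean)
    # class first, then a uniform position among sites with that reference
    # base: this realises the spectrum weights exactly
    by_base = {a: np.array([p for p in range(1, GENOME_LENGTH + 1)
                            if genome.base(p) == a]) for a in ALLELES}
    for _ in range(n_som):
        sub = subs[rng.choice(len(subs), p=probs)]
        ref, alt = sub.split(">")
        avail = np.array([p for p in by_base[ref] if p not in used])
        if avail.size == 0:
            raise ValueError("could not place somatic variants")
        pos = int(rng.choice(avail))
        used.add(pos)
        tvaf = float(rng.uniform(*config.somatic_vaf_range))
        plant(pos, ref, alt, "somatic", 0.0, tvaf)

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))

    normal_planted = {
        r["pos"]: (r["alt"], r["normal_vaf"]) for r in truth_rows
        if r["normal_vaf"] > 0}
    tumour_planted = {
        r["pos"]: (r["alt"], r["tumour_vaf"]) for r in truth_rows
        if r["tumour_vaf"] > 0}
    normal_counts = _emit_counts(rng, config, genome, f"{pair_id}N",
                                 normal_planted)
    tumour_counts = _emit_counts(rng, config, genome, f"{pair_id}T",
                                 tumour_planted)

    observations = pd.DataFrame(columns=["read_id", "pos", "allele"])
    artefact_pairs: list[tuple[tuple[int, str], tuple[int, str]]] = []
    if rng.random() < config.artefact_pair_rate:
        p1, p2 = _draw_positions(rng, 2, used)
        a1 = _TRANSITION[genome.base(p1)]
        a2 = _TRANSITION[genome.base(p2)]
        depth_here = int(max(100, config.mean_depth * 0.05))
        n_linked = max(10, int(depth_here * 0.5))
        for tissue in ("normal", "tumour"):
            counts = normal_counts if tissue == "normal" else tumour_counts
            counts, obs = inject_artefact_pair(
                counts, (p1, p2), (a1, a2), n_linked, depth_here, rng,
                read_prefix=f"{pair_id}{tissue[0].upper()}")
            if tissue == "normal":
                normal_counts = counts
            else:
                tumour_counts = counts
            observations = pd.concat([observations, obs],
                                     ignore_index=True)
        artefact_pairs.append(((p1, a1), (p2, a2)))

    return SimulatedPair(
        pair_id=pair_id, normal_sample=f"{pair_id}N",
        tumour_sample=f"{pair_id}T", haplogroup=haplogroup,
        normal_counts=normal_counts, tumour_counts=tumour_counts,
        truth=truth, read_observations=observations,
        artefact_pairs=artefact_pairs)


def simulate_cohort(config: SimulationConfig,
                    genome: MitoGenome | None = None,
                    region_map: RegionMap | None = None,
                    tree: hg.Phylotree | None = None) -> list[SimulatedPair]:
    genome = genome or load_reference()
    region_map = region_map or default_region_map()
    tree = tree or hg.load_phylotree()
    return [simulate_pair(config, i, genome, region_map, tree)
            for i in range(config.n_pairs)]


def cohort_manifest(pairs: list[SimulatedPair]) -> pd.DataFrame:
    return pd.DataFrame([
        {"pair_id": p.pair_id, "normal_sample": p.normal_sample,
         "tumour_sample": p.tumour_sample} for p in pairs])


# ---------------------------------------------------------------------------
# Lightweight heteroplasmy-pair simulation for drift statistics
# ---------------------------------------------------------------------------

def simulate_heteroplasmy_pairs(config: SimulationConfig, n: int,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Paired-heteroplasmy table without full-genome count emission.

    Normal and tumour VAFs include binomial read-sampling noise at the
    configured depth; the tumour truth is the configured drift transform
    of the normal truth.  Used for calibration/power studies where
    per-position count tables are unnecessary.
    """
    true_normal = _het_vaf(rng, config, n)
    true_tumour = _apply_drift(true_normal, config, rng)
    depth_n = _depths(rng, config, n)
    depth_t = _depths(rng, config, n)
    depth_n = np.maximum(depth_n, 1)
    depth_t = np.maximum(depth_t, 1)
    obs_n = rng.binomial(depth_n, true_normal) / depth_n
    obs_t = rng.binomial(depth_t, true_tumour) / depth_t
    hf_n = np.minimum(obs_n, 1 - obs_n)
    hf_t = np.minimum(obs_t, 1 - obs_t)
    return pd.DataFrame({
        "pair_id": [f"sim{i}" for i in range(n)],
        "pos": np.arange(1, n + 1), "ref": "C", "alt": "T",
        "normal_vaf": obs_n, "tumour_vaf": obs_t,
        "normal_hf": hf_n, "tumour_hf": hf_t,
        "delta_hf": hf_n - hf_t, "delta_vaf": obs_t - obs_n,
        "low_confidence": False,
    })


# ---------------------------------------------------------------------------
# Pileup emission (exercises the text-pileup input path)
# ---------------------------------------------------------------------------

def counts_to_pileup(counts: pd.DataFrame, chrom: str = "chrM",
                     qual_char: str = "I") -> str:
    """Render a count table as text pileup (all bases above the BAQ floor)."""
    lines = []
    for rec in counts.itertuples():
        bases = []
        ref = rec.ref
        for a in ALLELES:
            fwd = getattr(rec, f"{a}_fwd")
            rev = getattr(rec, f"{a}_rev")
            if a == ref:
                bases.append("." * fwd + "," * rev)
            else:
                bases.append(a * fwd + a.lower() * rev)
        base_str = "".join(bases)
        lines.append("\t".join([
            chrom, str(rec.pos), ref, str(len(base_str)), base_str,
            qual_char * len(base_str)]))
    return "\n".join(lines) + "\n"
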