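"""Strand-aware mitochondrial variant calling with a cascade of filters.

The calling substrate is a per-sample, per-position table of strand-split
allele counts (``SiteCounts`` layout below), produced either from a text
pileup (:func:`parse_pileup`) or loaded from a TSV count table.  Counts
are held in a pandas DataFrame rather than per-site objects so the filter
cascade can run vectorised over the whole genome.

Constitutional calls in the normal tissue require, at every position:
depth >= 100, VAF >= 0.02, VAC >= 10, a 99.999% exact binomial
(Clopper-Pearson) confidence interval for the variant fraction excluding
zero, and >= 5 variant reads on each strand.  Somatic calls additionally
require the tumour-normal difference to be >= 10 in allele count and
>= 0.02 in allele fraction, and the normal VAF to fall outside the
99.999% binomial interval of the tumour variant fraction.

VAF thresshold comparisons are performed in exact rational arithmetic
(``vac * q >= p * depth`` for a threshold ``p/q``) so that boundary cases
such as ``vac=40, depth=2000`` at a 0.02 floor are never decided by
floating-point rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALLELES = ("A", "C", "G", "T")

#: Column layout of a strand-split count table.
COUNT_COLUMNS = (
    "sample_id", "pos", "ref",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
)

#: Column layout of a call table.
CALL_COLUMNS = (
    "sample_id", "tissue", "pos", "ref", "alt",
    "vac", "depth", "vaf", "fwd_vac", "rev_vac", "zygosity", "origin",
)


@dataclass(frozen=True)
class CallingThresholds:
    """Filter-cascade thresholds.

    ``min_mq`` is declarative: mapping quality cannot be recovered from a
    plain pileup or count table, so it documents the contract of upstream
    pileup generation rather than being enforced here.
    """

    min_baq: int = 20
    min_mq: int = 20
    min_depth: int = 100
    min_vaf: float = 0.02
    min_vac: int = 10
    ci_confidence: float = 0.99999
    min_per_strand: int = 5
    somatic_min_vac_diff: int = 10
    somatic_min_vaf_diff: float = 0.02
    het_lower: float = 0.02
    het_upper: float = 0.98

    def __post_init__(self) -> None:
        if not 0 < self.ci_confidence < 1:
            raise ValueError("ci_confidence must be in (0, 1)")
        for name in ("min_baq", "min_mq", "min_depth", "min_vac",
                     "min_per_strand", "somatic_min_vac_diff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_vaf", "somatic_min_vaf_diff"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")

    def with_overrides(self, **kwargs) -> "CallingThresholds":
        return replace(self, **kwargs)


def depth_of(counts: pd.DataFrame) -> np.ndarray:
    """Total post-filter depth per row (sum of the eight strand counts)."""
    cols = [f"{a}_{s}" for a in ALLELES for s in ("fwd", "rev")]
    return counts[cols].to_numpy(dtype=np.int64).sum(axis=1)


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ref": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    return df


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False, columns=list(COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# Pileup parsing
# ---------------------------------------------------------------------------

class PileupError(ValueError):
    pass


def _parse_base_string(bases: str, quals: str, ref: str, min_baq: int,
                       lineno: int) -> dict[str, list[int]]:
    """Decode one pileup base string into per-allele strand counts.

    Returns ``{allele: [fwd, rev]}``.  Read starts (``^X``), read ends
    (``$``) and indel runs (``+n``/``-n`` plus the inserted sequence) are
    consumed without emitting a base; ``*`` (deletion placeholder) and
    ``N`` consume a quality character but never contribute to counts or
    depth.
    """
    out: dict[str, list[int]] = {a: [0, 0] for a in ALLELES}
    i = 0  # base-string cursor
    q = 0  # quality cursor
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            j = i
            while j < n and bases[j].isdigit():
                j += 1
            run = int(bases[i:j])
            i = j + run
            continue
        if q >= len(quals):
            raise PileupError(
                f"line {lineno}: base/quality string length mismatch"
            )
        baq = ord(quals[q]) - 33
        q += 1
        i += 1
        if c == "*":
            continue
        if baq < min_baq:
            continue
        if c == ".":
            out[ref][0] += 1
        elif c == ",":
            out[ref][1] += 1
        else:
            allele = c.upper()
            if allele == "N":
                continue
            if allele not in ALLELES:
                raise PileupError(f"line {lineno}: unexpected symbol {c!r}")
            out[allele][0 if c.isupper() else 1] += 1
    if q != len(quals):
        raise PileupError(f"line {lineno}: base/quality string length mismatch")
    return out


def parse_pileup(lines: Iterable[str], min_baq: int = 20,
                 sample_id: str = "sample") -> pd.DataFrame:
    """Parse a text pileup stream into a strand-split count table.

    Bases below ``min_baq`` are dropped from both counts and depth;
    strand is inferred from symbol case ('.'/uppercase forward,
    ','/lowercase reverse).
    """
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupError(f"line {lineno}: expected >=6 columns")
        _, pos, ref, _, bases, quals = fields[:6]
        ref = ref.upper()
        counts = _parse_base_string(bases, quals, ref, min_baq, lineno)
        row = {"sample_id": sample_id, "pos": int(pos), "ref": ref}
        for a in ALLELES:
            row[f"{a}_fwd"], row[f"{a}_rev"] = counts[a]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# Binomial confidence interval
# ---------------------------------------------------------------------------

def binomial_interval(count: int, depth: int,
                      confidence: float = 0.99999) -> tuple[float, float]:
    """Exact two-sided Clopper-Pearson interval for a binomial proportion."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= count <= depth:
        raise ValueError("count must be within [0, depth]")
    alpha = 1.0 - confidence
    lower = 0.0 if count == 0 else stats.beta.ppf(alpha / 2, count,
                                                  depth - count + 1)
    upper = 1.0 if count == depth else stats.beta.ppf(1 - alpha / 2,
                                                      count + 1, depth - count)
    return float(lower), float(upper)


def _cp_bounds(vac: np.ndarray, depth: np.ndarray,
               confidence: float) -> tuple[np.ndarray, np.ndarray]:
    alpha = 1.0 - confidence
    vac = vac.astype(np.float64)
    depth = depth.astype(np.float64)
    with np.errstate(all="ignore"):
        lower = stats.beta.ppf(alpha / 2, vac, depth - vac + 1)
        upper = stats.beta.ppf(1 - alpha / 2, vac + 1, depth - vac)
    lower = np.where(vac == 0, 0.0, lower)
    upper = np.where(vac == depth, 1.0, upper)
    return lower, upper


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def _frac(x: float) -> Fraction:
    return Fraction(str(x))


def classify_zygosity(vaf: float, het_lower: float = 0.02,
                      het_upper: float = 0.98) -> str:
    """Heteroplasmy iff ``het_lower <= vaf <= het_upper`` (inclusive)."""
    return "heteroplasmy" if het_lower <= vaf <= het_upper else "homoplasmy"


def _long_counts(sites: pd.DataFrame) -> pd.DataFrame:
    """One row per (site, non-reference allele) with vac/strand/depth."""
    depth = depth_of(sites)
    frames = []
    for a in ALLELES:
        mask = sites["ref"].to_numpy() != a
        if not mask.any():
            continue
        sub = sites.loc[mask, ["sample_id", "pos", "ref"]].copy()
        sub["alt"] = a
        sub["fwd_vac"] = sites.loc[mask, f"{a}_fwd"].to_numpy(np.int64)
        sub["rev_vac"] = sites.loc[mask, f"{a}_rev"].to_numpy(np.int64)
        sub["vac"] = sub["fwd_vac"] + sub["rev_vac"]
        sub["depth"] = depth[mask]
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["sample_id", "pos", "ref", "alt",
                                     "fwd_vac", "rev_vac", "vac", "depth"])
    return pd.concat(frames, ignore_index=True)


def _constitutional_mask(long: pd.DataFrame,
                         t: CallingThresholds) -> np.ndarray:
    vac = long["vac"].to_numpy(np.int64)
    depth = long["depth"].to_numpy(np.int64)
    fwd = long["fwd_vac"].to_numpy(np.int64)
    rev = long["rev_vac"].to_numpy(np.int64)
    p = _frac(t.min_vaf)
    ok = (
        (depth >= t.min_depth)
        & (vac >= t.min_vac)
        & (vac * p.denominator >= p.numerator * depth)  # exact VAF >= min_vaf
        & (fwd >= t.min_per_strand)
        & (rev >= t.min_per_strand)
    )
    if ok.any():
        lower, _ = _cp_bounds(vac[ok], depth[ok], t.ci_confidence)
        ok_idx = np.flatnonzero(ok)
        ok[ok_idx] = lower > 0.0
    return ok


def _finalize_calls(long: pd.DataFrame, tissue: str, origin: str,
                    t: CallingThresholds) -> pd.DataFrame:
    calls = long.copy()
    calls["tissue"] = tissue
    calls["origin"] = origin
    with np.errstate(invalid="ignore"):
        calls["vaf"] = calls["vac"] / calls["depth"]
    calls["zygosity"] = [
        classify_zygosity(v, t.het_lower, t.het_upper)
        for v in calls["vaf"]
    ]
    calls = calls[list(CALL_COLUMNS)]
    return calls.sort_values(["sample_id", "pos", "alt"],
                             ignore_index=True)


def call_constitutional(sites: pd.DataFrame,
                        thresholds: CallingThresholds | None = None,
                        tissue: str = "normal") -> pd.DataFrame:
    """Apply the constitutional filter cascade to one sample's count table.

    Multiple alternate alleles at one site are each filtered
    independently against the full site depth.
    """
    t = thresholds or CallingThresholds()
    long = _long_counts(sites)
    if long.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    keep = _constitutional_mask(long, t)
    return _finalize_calls(long.loc[keep], tissue, "constitutional", t)


def call_somatic(tumour_sites: pd.DataFrame, normal_sites: pd.DataFrame,
                 thresholds: CallingThresholds | None = None,
                 normalize_vac_diff: bool = True) -> pd.DataFrame:
    """Call tumour-specific variants against the matched normal.

    A tumour allele is somatic iff it passes the constitutional-style
    cascade in the tumour and, versus the normal at the same position:
    the allele-count difference is >= ``somatic_min_vac_diff`` (with the
    normal count rescaled to tumour depth by default, so unequal depths
    do not bias the comparison), the VAF difference is >=
    ``somatic_min_vaf_diff``, and the normal VAF lies outside the
    Clopper-Pearson interval of the tumour variant fraction.  Tumour
    positions absent from the normal table are skipped with a warning.
    """
    t = thresholds or CallingThresholds()
    long = _long_counts(tumour_sites)
    if long.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    keep = _constitutional_mask(long, t)
    cand = long.loc[keep].copy()
    if cand.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))

    ndepth_all = depth_of(normal_sites)
    nidx = pd.DataFrame({
        "pos": normal_sites["pos"].to_numpy(),
        "n_depth": ndepth_all,
    })
    for a in ALLELES:
        nidx[f"n_{a}"] = (normal_sites[f"{a}_fwd"].to_numpy(np.int64)
                          + normal_sites[f"{a}_rev"].to_numpy(np.int64))
    merged = cand.merge(nidx, on="pos", how="left", validate="many_to_one")
    unmatched = merged["n_depth"].isna()
    if unmatched.any():
        warnings.warn(
            f"{int(unmatched.sum())} candidate somatic site(s) had no "
            "matched normal counts and were skipped",
            stacklevel=2,
        )
        merged = merged.loc[~unmatched]
    if merged.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))

    t_vac = merged["vac"].to_numpy(np.int64)
    t_depth = merged["depth"].to_numpy(np.int64)
    n_depth = merged["n_depth"].to_numpy(np.int64)
    n_vac = np.zeros(len(merged), dtype=np.int64)
    for a in ALLELES:
        n_vac = np.where(merged["alt"].to_numpy() == a,
                         merged[f"n_{a}"].to_numpy(np.int64), n_vac)

    ok = n_depth >= t.min_depth  # matched depth required in both tissues
    # VAC difference, exact integer arithmetic
    if normalize_vac_diff:
        # t_vac - n_vaf * t_depth >= diff   (x n_depth)
        ok &= (t_vac * n_depth - n_vac * t_depth
               >= t.somatic_min_vac_diff * n_depth)
    else:
        ok &= (t_vac - n_vac) >= t.somatic_min_vac_diff
    # VAF difference, exact rational arithmetic
    q = _frac(t.somatic_min_vaf_diff)
    ok &= ((t_vac * n_depth - n_vac * t_depth) * q.denominator
           >= q.numerator * t_depth * n_depth)
    # normal VAF outside the tumour Clopper-Pearson interval
    lower, upper = _cp_bounds(t_vac, t_depth, t.ci_confidence)
    n_vaf = n_vac / n_depth
    ok &= (n_vaf < lower) | (n_vaf > upper)

    return _finalize_calls(merged.loc[ok, list(cand.columns)],
                           "tumour", "somatic", t)


# ---------------------------------------------------------------------------
# Read-linked artefact flagging
# ---------------------------------------------------------------------------

def flag_linked_artefacts(
    observations: pd.DataFrame,
    candidate_pairs: Sequence[tuple[tuple[int, str], tuple[int, str]]],
    cooccurrence_min: float = 0.95,
) -> pd.DataFrame:
    """Flag variant pairs that always co-occur on the same reads.

    ``observations`` has one row per read-base (read_id, pos, allele).
    For each candidate pair, among reads covering both positions: the
    co-occurrence fraction is (reads carrying both alts) / (reads
    carrying either); a pair is flagged iff that fraction reaches
    ``cooccurrence_min`` and the partner allele never appears on a read
    lacking the first allele.  Pairs with no co-covering reads are
    reported as untestable.
    """
    results = []
    for (pos1, alt1), (pos2, alt2) in candidate_pairs:
        at1 = observations.loc[observations["pos"] == pos1]
        at2 = observations.loc[observations["pos"] == pos2]
        cover = set(at1["read_id"]) & set(at2["read_id"])
        rec = {"pos1": pos1, "alt1": alt1, "pos2": pos2, "alt2": alt2,
               "n_covering": len(cover)}
        if not cover:
            rec.update(fraction=np.nan, flagged=False, untestable=True)
            results.append(rec)
            continue
        has1 = set(at1.loc[at1["allele"] == alt1, "read_id"]) & cover
        has2 = set(at2.loc[at2["allele"] == alt2, "read_id"]) & cover
        both = has1 & has2
        either = has1 | has2
        fraction = len(both) / len(either) if either else 0.0
        partner_alone = len(has2 - has1)
        rec.update(
            fraction=fraction,
            flagged=bool(either) and fraction >= cooccurrence_min
            and partner_alone == 0,
            untestable=False,
        )
        results.append(rec)
    return pd.DataFrame(
        results, columns=["pos1", "alt1", "pos2", "alt2", "n_covering",
                          "fraction", "flagged", "untestable"])
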