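"""Cohort-level variant summaries and distribution tests.

Covers the cohort summary table (per-class totals, unique variants,
carrier counts and depth statistics), the chi-square comparison of a
variant set's placement across the seven functional regions against the
length-proportional expectation, and a simple clinical-association
screen of per-sample mutational burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import REGIONS, RegionMap

VARIANT_CLASSES = ("total_constitutional", "private_constitutional",
                   "heteroplasmic_constitutional", "somatic")


def summarize_cohort(calls: pd.DataFrame,
                     manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-class cohort summary.

    ``calls`` is a call table with origin/zygosity columns and, for
    constitutional calls, an optional boolean ``private`` column.  Rows:
    one per variant class; columns: total and unique (distinct
    pos/ref/alt) variant counts, number of samples carrying >= 1, and
    mean +/- sd of read depth at called variants.
    """
    class_masks = {
        "total_constitutional": calls["origin"] == "constitutional",
        "private_constitutional": (
            (calls["origin"] == "constitutional")
            & calls.get("private", pd.Series(False, index=calls.index))
            .fillna(False).astype(bool)),
        "heteroplasmic_constitutional": (
            (calls["origin"] == "constitutional")
            & (calls["zygosity"] == "heteroplasmy")),
        "somatic": calls["origin"] == "somatic",
    }
    rows = []
    for cls, mask in class_masks.items():
        sub = calls.loc[mask]
        undefined_depth = sub.empty
        if undefined_depth:
            warnings.warn(f"no {cls} variants: depth statistics undefined",
                          stacklevel=2)
        rows.append({
            "variant_class": cls,
            "total_variants": len(sub),
            "unique_variants": len(sub[["pos", "ref", "alt"]]
                                   .drop_duplicates()),
            "n_samples": sub["sample_id"].nunique(),
            "mean_depth": float(sub["depth"].mean()) if not sub.empty
            else np.nan,
            "sd_depth": float(sub["depth"].std(ddof=1))
            if len(sub) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("variant_class")


@dataclass
class RegionDistribution:
    observed: pd.Series           # counts per region, canonical order
    expected_proportions: pd.Series
    chi2: float
    df: int
    p: float
    low_expected_regions: tuple[str, ...]  # expected count < 5

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.to_dict(),
            "expected_proportions": self.expected_proportions.to_dict(),
            "chi2": self.chi2, "df": self.df, "p": self.p,
            "low_expected_regions": list(self.low_expected_regions),
        }


def region_distribution_test(variants: pd.DataFrame,
                             region_map: RegionMap) -> RegionDistribution:
    """Goodness-of-fit chi-square of variant placement across regions.

    Expected counts are proportional to region lengths (remainder
    convention).  ``variants`` must carry a ``region`` column (primary
    region; overlap variants contribute their most severe gene's
    region).  Regions with expected count < 5 are flagged.
    """
    if len(variants) == 0:
        raise ValueError("region test requires >= 1 variant")
    observed = pd.Series(
        [int((variants["region"] == r).sum()) for r in REGIONS],
        index=list(REGIONS))
    if observed.sum() != len(variants):
        unknown = sorted(set(variants["region"]) - set(REGIONS))
        raise ValueError(f"unknown region labels {unknown}")
    total_len = sum(region_map.lengths.values())
    props = pd.Series(
        [region_map.lengths[r] / total_len for r in REGIONS],
        index=list(REGIONS))
    nonzero = props > 0  # toy maps may leave some regions empty
    if (observed[~nonzero] > 0).any():
        raise ValueError("variants observed in a zero-length region")
    expected = props * observed.sum()
    chi2, p = stats.chisquare(observed[nonzero], f_exp=expected[nonzero])
    return RegionDistribution(
        observed=observed, expected_proportions=props,
        chi2=float(chi2), df=int(nonzero.sum()) - 1, p=float(p),
        low_expected_regions=tuple(expected.index[nonzero & (expected < 5)]))


def region_homogeneity_test(variants_a: pd.DataFrame,
                            variants_b: pd.DataFrame) -> tuple[float, int, float]:
    """Two-sample chi-square comparing two variant sets' region profiles."""
    table = np.array([
        [int((v["region"] == r).sum()) for r in REGIONS]
        for v in (variants_a, variants_b)])
    keep = table.sum(axis=0) > 0
    chi2, p, df, _ = stats.chi2_contingency(table[:, keep])
    return float(chi2), int(df), float(p)


def burden_association(burden: pd.DataFrame, phenotypes: pd.DataFrame,
                       bh_correction: bool = True) -> pd.DataFrame:
    """Screen per-sample variant burden against clinical phenotypes.

    ``burden`` has columns sample_id/burden; ``phenotypes`` has
    sample_id plus one column per phenotype.  Binary phenotypes (two
    distinct non-null values) get a two-sample t-test of burden between
    groups; numeric phenotypes a Pearson correlation test.  Raw p-values
    are always reported; Benjamini-Hochberg adjusted p-values are added
    across the tested phenotypes by default.
    """
    merged = phenotypes.merge(burden, on="sample_id", how="inner")
    rows = []
    for col in phenotypes.columns:
        if col == "sample_id":
            continue
        sub = merged[[col, "burden"]].dropna()
        values = sub[col]
        levels = values.unique()
        if len(levels) < 2:
            rows.append({"phenotype": col, "test": "skipped",
                         "statistic": np.nan, "p": np.nan,
                         "note": "fewer than two groups/values"})
            continue
        if len(levels) == 2:
            g1 = sub.loc[values == levels[0], "burden"]
            g2 = sub.loc[values == levels[1], "burden"]
            if len(g1) < 2 or len(g2) < 2:
                rows.append({"phenotype": col, "test": "skipped",
                             "statistic": np.nan, "p": np.nan,
                             "note": "a group has fewer than 2 samples"})
                continue
            if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
                if not np.isclose(g1.mean(), g2.mean()):
                    rows.append({"phenotype": col, "test": "skipped",
                                 "statistic": np.nan, "p": np.nan,
                                 "note": "zero within-group variance"})
                    continue
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(g1, g2)
            rows.append({"phenotype": col, "test": "two-sample t",
                         "statistic": float(t_stat), "p": float(p),
                         "note": ""})
        else:
            r, p = stats.pearsonr(sub[col].astype(float), sub["burden"])
            rows.append({"phenotype": col, "test": "pearson",
                         "statistic": float(r), "p": float(p), "note": ""})
    out = pd.DataFrame(rows)
    if bh_correction and not out.empty:
        tested = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if tested.any():
            adj[tested.to_numpy()] = stats.false_discovery_control(
                out.loc[tested, "p"].to_numpy(), method="bh")
        out["p_adjusted"] = adj
    return out
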