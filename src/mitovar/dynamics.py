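"""Heteroplasmy shifts between matched normal and tumour tissue.

Each constitutional heteroplasmy called in the normal sample is paired
with the raw tumour counts at the same position, *without* re-applying
calling thresholds: loss of heteroplasmy drives the tumour allele below
the calling floor, so threshold-free lookup is required to observe it.
Two paired quantities are tracked per variant:

* VAF, the variant allele fraction (variant count / depth), whose shift
  is directional with respect to the variant allele; and
* HF, the heteroplasmic fraction ``min(VAF, 1 - VAF)``, the minor-allele
  fraction, whose decrease indicates movement toward fixation or loss of
  *either* allele.

A paired t-test on (normal, tumour) HF detects a trend toward loss of
heteroplasmy regardless of which allele wins; the same test on VAF asks
whether the variant allele specifically is favoured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ALLELES, CallingThresholds, depth_of

PAIR_COLUMNS = (
    "pair_id", "pos", "ref", "alt",
    "normal_vaf", "tumour_vaf", "normal_hf", "tumour_hf",
    "delta_hf", "delta_vaf", "low_confidence",
)


def heteroplasmic_fraction(vaf: float) -> float:
    """Minor-allele fraction of a biallelic site: ``min(vaf, 1 - vaf)``."""
    return min(vaf, 1.0 - vaf)


def pair_heteroplasmies(normal_calls: pd.DataFrame,
                        tumour_sites: pd.DataFrame,
                        thresholds: CallingThresholds | None = None,
                        pair_id: str | None = None) -> pd.DataFrame:
    """Pair each normal heteroplasmy with the raw tumour counts.

    Tumour VAF is recomputed directly from the tumour count table with no
    calling thresholds (an allele lost from the tumour yields VAF 0).
    Pairs whose tumour depth falls below ``min_depth`` are retained but
    flagged ``low_confidence``.  Third alleles at the site are ignored
    for HF (biallelic ref/alt convention) with a logged warning.
    """
    t = thresholds or CallingThresholds()
    hets = normal_calls.loc[normal_calls["zygosity"] == "heteroplasmy"]
    tdepth = depth_of(tumour_sites)
    tidx: dict[int, int] = {
        int(p): i for i, p in enumerate(tumour_sites["pos"].to_numpy())
    }
    tcounts = {
        a: (tumour_sites[f"{a}_fwd"].to_numpy(np.int64)
            + tumour_sites[f"{a}_rev"].to_numpy(np.int64))
        for a in ALLELES
    }
    rows = []
    third_allele_sites = 0
    for rec in hets.itertuples():
        pos = int(rec.pos)
        i = tidx.get(pos)
        if i is None:
            warnings.warn(f"no tumour counts at position {pos}; pair skipped",
                          stacklevel=2)
            continue
        depth = int(tdepth[i])
        vac = int(tcounts[rec.alt][i])
        ref_count = int(tcounts[rec.ref][i])
        if depth > vac + ref_count:
            third_allele_sites += 1
        tumour_vaf = vac / depth if depth > 0 else 0.0
        normal_hf = heteroplasmic_fraction(rec.vaf)
        tumour_hf = heteroplasmic_fraction(tumour_vaf)
        rows.append({
            "pair_id": pair_id or rec.sample_id,
            "pos": pos, "ref": rec.ref, "alt": rec.alt,
            "normal_vaf": rec.vaf, "tumour_vaf": tumour_vaf,
            "normal_hf": normal_hf, "tumour_hf": tumour_hf,
            "delta_hf": normal_hf - tumour_hf,  # positive = loss of het.
            "delta_vaf": tumour_vaf - rec.vaf,
            "low_confidence": depth < t.min_depth,
        })
    if third_allele_sites:
        warnings.warn(
            f"{third_allele_sites} paired site(s) carried third alleles, "
            "ignored for HF (biallelic convention)", stacklevel=2)
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    n: int
    mean_difference: float


def paired_t_test(values_a, values_b) -> PairedTestResult:
    """Two-tailed paired t-test on matched samples (differences a - b).

    ``t = mean(d) / (sd(d) / sqrt(n))`` with the sample (n-1) standard
    deviation; p from the t distribution with n - 1 degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), p=float(p), n=n,
                            mean_difference=float(d.mean()))


@dataclass(frozen=True)
class ShiftReport:
    hf_test: PairedTestResult
    vaf_test: PairedTestResult
    n_pairs: int
    n_fixed: int  # tumour VAF crossed above the heteroplasmy band
    n_lost: int   # tumour VAF fell below the heteroplasmy band

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_fixed": self.n_fixed,
            "n_lost": self.n_lost,
            "hf_test": vars(self.hf_test),
            "vaf_test": vars(self.vaf_test),
        }


def shift_report(pairs: pd.DataFrame,
                 thresholds: CallingThresholds | None = None) -> ShiftReport:
    """Directional-shift summary over a set of paired heteroplasmies.

    The HF test is paired (normal HF, tumour HF), so a positive t means a
    trend toward loss of heteroplasmy; the VAF test is paired
    (tumour VAF, normal VAF), so a positive t means the variant allele is
    preferentially amplified.
    """
    t = thresholds or CallingThresholds()
    if len(pairs) < 2:
        raise ValueError("shift_report requires >= 2 pairs")
    hf = paired_t_test(pairs["normal_hf"], pairs["tumour_hf"])
    vaf = paired_t_test(pairs["tumour_vaf"], pairs["normal_vaf"])
    tumour_vaf = pairs["tumour_vaf"].to_numpy()
    return ShiftReport(
        hf_test=hf, vaf_test=vaf, n_pairs=len(pairs),
        n_fixed=int((tumour_vaf > t.het_upper).sum()),
        n_lost=int((tumour_vaf < t.het_lower).sum()),
    )
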