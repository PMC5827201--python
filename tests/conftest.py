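"""Shared fixtures: packaged reference, annotation and tree, plus helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitovar.calling import ALLELES, COUNT_COLUMNS
from mitovar.haplogroups import load_phylotree
from mitovar.reference import build_region_map, load_gene_table, load_reference


@pytest.fixture(scope="session")
def genome():
    return load_reference()


@pytest.fixture(scope="session")
def genes():
    return load_gene_table()


@pytest.fixture(scope="session")
def region_map(genes):
    return build_region_map(genes)


@pytest.fixture(scope="session")
def tree():
    return load_phylotree()


def make_sites(rows, sample_id="S1"):
    """Build a strand-split count table from sparse row dicts.

    Each row: {"pos": p, "ref": r, "<allele>_fwd": n, ...}; unspecified
    allele counts default to zero.
    """
    out = []
    for row in rows:
        rec = {"sample_id": sample_id, "pos": row["pos"], "ref": row["ref"]}
        for a in ALLELES:
            for s in ("fwd", "rev"):
                rec[f"{a}_{s}"] = row.get(f"{a}_{s}", 0)
        out.append(rec)
    return pd.DataFrame(out, columns=list(COUNT_COLUMNS))


def ref_site(pos, ref, depth, alt=None, alt_fwd=0, alt_rev=0):
    """One site with the reference carrying all non-alt depth, split evenly."""
    rem = depth - alt_fwd - alt_rev
    row = {"pos": pos, "ref": ref,
           f"{ref}_fwd": rem - rem // 2, f"{ref}_rev": rem // 2}
    if alt is not None:
        row[f"{alt}_fwd"] = alt_fwd
        row[f"{alt}_rev"] = alt_rev
    return row


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
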