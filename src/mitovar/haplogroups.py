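"""Haplogroup assignment and private constitutional variant derivation.

A sample's constitutional mtDNA variants are a mixture of haplogroup-
defining ("global") polymorphisms, hypervariable hotspot alleles, and
genuinely private variants.  This module assigns a haplogroup by simple
match-minus-mismatch scoring against a phylotree-style table of defining
variants (a deliberately lighter scheme than HaploGrep's weighted ranks;
externally produced haplogroup calls can be supplied instead) and then
derives the private set by exact (position, alt) subtraction of the
haplogroup path variants and the mutational super-hotspots
A16182C / A16183C / T16519C.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

#: Mutational super-hotspots excluded from the private set by default.
DEFAULT_HOTSPOTS = frozenset({(16182, "A", "C"), (16183, "A", "C"),
                              (16519, "T", "C")})

_VARIANT_TOKEN = re.compile(r"^([ACGT])(\d+)([ACGT])$")

Variant = tuple[int, str, str]  # (position, ref, alt)


def parse_variant_token(token: str) -> Variant:
    """Parse nomenclature like ``T16519C`` into (position, ref, alt)."""
    m = _VARIANT_TOKEN.match(token.strip().upper())
    if not m:
        raise ValueError(f"malformed variant token {token!r}")
    ref, pos, alt = m.groups()
    if ref == alt:
        raise ValueError(f"ref equals alt in {token!r}")
    return int(pos), ref, alt


def format_variant(variant: Variant) -> str:
    pos, ref, alt = variant
    return f"{ref}{pos}{alt}"


@dataclass
class PhylotreeNode:
    haplogroup: str
    parent: str | None
    defining_variants: tuple[Variant, ...]


@dataclass
class Phylotree:
    """A rooted haplogroup tree with per-node defining variants."""

    nodes: dict[str, PhylotreeNode]
    root: str
    _paths: dict[str, tuple[Variant, ...]] = field(default_factory=dict,
                                                   repr=False)

    def __post_init__(self) -> None:
        if not self._paths:
            for label in self.nodes:
                self._paths[label] = self._compute_path(label)

    def _compute_path(self, label: str) -> tuple[Variant, ...]:
        variants: list[Variant] = []
        chain = []
        node = self.nodes[label]
        while node is not None:
            chain.append(node)
            node = self.nodes.get(node.parent) if node.parent else None
        for n in reversed(chain):
            variants.extend(n.defining_variants)
        # the path variant *set*; preserve order, drop duplicates
        seen: set[Variant] = set()
        out = []
        for v in variants:
            if v not in seen:
                seen.add(v)
                out.append(v)
        return tuple(out)

    def path_variants(self, label: str) -> tuple[Variant, ...]:
        return self._paths[label]

    def depth(self, label: str) -> int:
        d = 0
        node = self.nodes[label]
        while node.parent:
            d += 1
            node = self.nodes[node.parent]
        return d


def load_phylotree(path: str | Path | None = None) -> Phylotree:
    """Load a tree TSV (haplogroup, parent, defining_variants).

    ``defining_variants`` is a comma-separated list of tokens such as
    ``T16519C``; the root row has an empty parent.  Defaults to the
    packaged toy tree (sized for tests; supply a full phylotree-format
    table for real data).
    """
    if path is None:
        path = Path(resources.files("mitovar").joinpath(
            "data", "toy_phylotree.tsv"))
    nodes: dict[str, PhylotreeNode] = {}
    roots = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            label = row["haplogroup"].strip()
            parent = row["parent"].strip() or None
            tokens = [t for t in row["defining_variants"].split(",")
                      if t.strip()]
            nodes[label] = PhylotreeNode(
                haplogroup=label, parent=parent,
                defining_variants=tuple(parse_variant_token(t)
                                        for t in tokens))
            if parent is None:
                roots.append(label)
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {roots}")
    # cycle / dangling-parent check
    for label, node in nodes.items():
        seen = {label}
        cur = node
        while cur.parent is not None:
            if cur.parent not in nodes:
                raise ValueError(f"unknown parent {cur.parent!r} of {label}")
            if cur.parent in seen:
                raise ValueError(f"cycle through {label}")
            seen.add(cur.parent)
            cur = nodes[cur.parent]
    return Phylotree(nodes=nodes, root=roots[0])


@dataclass(frozen=True)
class HaplogroupCall:
    haplogroup: str
    score: int  # matched minus mismatched path-defining variants
    path_variants: tuple[Variant, ...]


def _match_key(variant: Variant) -> tuple[int, str]:
    pos, _ref, alt = variant
    return pos, alt


def assign_haplogroup(constitutional_variants: Iterable[Variant],
                      tree: Phylotree) -> HaplogroupCall:
    """Best-scoring haplogroup for a set of constitutional variants.

    The score of a node is ``|path & sample| - |path \\ sample|`` over
    the defining variants on the root-to-node path, matched exactly on
    (position, alt allele).  Ties break to the deepest node, then to the
    lexicographically smallest label.
    """
    if not tree.nodes:
        raise ValueError("empty tree")
    sample_keys = {_match_key(v) for v in constitutional_variants}
    best: tuple[int, int, list[str]] | None = None  # (score, depth, [labels])
    best_label = None
    for label in tree.nodes:
        path = tree.path_variants(label)
        matched = sum(1 for v in path if _match_key(v) in sample_keys)
        score = matched - (len(path) - matched)
        key = (score, tree.depth(label))
        if best is None or key > best[:2] or (
                key == best[:2] and label < best_label):
            best = (score, key[1], [label])
            best_label = label
    assert best_label is not None
    return HaplogroupCall(
        haplogroup=best_label, score=best[0],
        path_variants=tree.path_variants(best_label))


def derive_private(
    constitutional_variants: Iterable[Variant],
    call: HaplogroupCall,
    hotspots: frozenset[Variant] | set[Variant] = DEFAULT_HOTSPOTS,
) -> list[Variant]:
    """Constitutional variants not explained by haplogroup or hotspots.

    Subtraction matches exactly on (position, alt allele): a variant at
    a haplogroup-path position but with a different alternate allele is
    retained as private.
    """
    path_keys = {_match_key(v) for v in call.path_variants}
    hotspot_keys = {_match_key(v) for v in hotspots}
    return [v for v in constitutional_variants
            if _match_key(v) not in path_keys
            and _match_key(v) not in hotspot_keys]


def partition_constitutional(
    constitutional_variants: Iterable[Variant],
    call: HaplogroupCall,
    hotspots: frozenset[Variant] | set[Variant] = DEFAULT_HOTSPOTS,
) -> Mapping[str, list[Variant]]:
    """Split the constitutional set into hotspot / global / private.

    Hotspots take precedence over path membership for reporting, so the
    three parts are pairwise disjoint and their union is the input.
    """
    path_keys = {_match_key(v) for v in call.path_variants}
    hotspot_keys = {_match_key(v) for v in hotspots}
    parts: dict[str, list[Variant]] = {"hotspot": [], "global": [],
                                       "private": []}
    for v in constitutional_variants:
        k = _match_key(v)
        if k in hotspot_keys:
            parts["hotspot"].append(v)
        elif k in path_keys:
            parts["global"].append(v)
        else:
            parts["private"].append(v)
    return parts
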