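"""Comparison of map content against other gene-set resources.

Set arithmetic on gene symbols and annotation PMIDs: what fraction of the
map's genes appears in each external resource, which genes are exclusive to
the map, which modules are enriched in those exclusive genes
(hypergeometric test with Benjamini–Hochberg correction over the map
universe), and how recent the map's literature body is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hierarchy import GeneSetCollection, Level, MapHierarchy, read_gmt


def _canonical(genes: Iterable[str]) -> frozenset[str]:
    out = frozenset(g.strip().upper() for g in genes if g.strip())
    return out


@dataclass(frozen=True)
class ResourceSet:
    """One external resource: its gene symbols and (optionally) its literature."""

    name: str
    genes: frozenset[str]
    pmids: frozenset[str] = field(default_factory=frozenset)
    pub_years: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _canonical(self.genes))
        object.__setattr__(self, "pmids", frozenset(self.pmids))
        object.__setattr__(self, "pub_years", dict(self.pub_years))

    @classmethod
    def from_symbol_file(cls, name: str, path: str | Path) -> "ResourceSet":
        """One gene symbol per line."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(name=name, genes=_canonical(lines))

    @classmethod
    def from_gmt(cls, name: str, path: str | Path) -> "ResourceSet":
        """Union of all gene sets of a GMT file."""
        collection = read_gmt(path)
        genes = frozenset(g for s in collection for g in s.genes)
        return cls(name=name, genes=_canonical(genes))


@dataclass(frozen=True)
class OverlapResult:
    n_common: int
    pct_of_map: float  # |map ∩ other| / |map|, one-decimal percent
    jaccard: float


def overlap_fraction(map_genes: Iterable[str], other: ResourceSet | Iterable[str]) -> OverlapResult:
    """Fraction of the map's genes present in the other resource.

    The denominator is the map set (so "61% overlap with resource X" reads
    "61% of the map is in X"); the symmetric Jaccard index is reported
    alongside. Raises on an empty map set.
    """
    map_set = _canonical(map_genes)
    if not map_set:
        raise ValueError("empty map gene set")
    other_set = other.genes if isinstance(other, ResourceSet) else _canonical(other)
    common = map_set & other_set
    union = map_set | other_set
    return OverlapResult(
        n_common=len(common),
        pct_of_map=round(100.0 * len(common) / len(map_set), 1),
        jaccard=len(common) / len(union) if union else 0.0,
    )


def unique_genes(
    map_genes: Iterable[str], others: Sequence[ResourceSet | Iterable[str]]
) -> frozenset[str]:
    """Genes on the map and in none of the other resources."""
    map_set = _canonical(map_genes)
    pooled: frozenset[str] = frozenset()
    for other in others:
        pooled |= other.genes if isinstance(other, ResourceSet) else _canonical(other)
    return map_set - pooled


def module_unique_enrichment(
    hierarchy: MapHierarchy,
    unique_set: Iterable[str],
    level: Level = "module",
) -> pd.DataFrame:
    """Which containers are enriched in map-exclusive genes.

    For each gene set at ``level``: the hypergeometric tail probability of
    drawing ≥ k exclusive genes among its n members, from the map universe
    with ``|unique_set|`` exclusive genes overall; Benjamini–Hochberg
    adjustment across the sets. Returns columns ``name, k_unique, n_genes,
    p, q``.
    """
    unique = _canonical(unique_set)
    universe = _canonical(hierarchy.all_genes)
    if not unique <= universe:
        raise ValueError("unique_set must be a subset of the hierarchy's genes")
    big_m, big_k = len(universe), len(unique)
    rows = []
    for name in hierarchy.names(level):
        members = _canonical(hierarchy.genes(level, name))
        n = len(members)
        k = len(members & unique)
        p = float(stats.hypergeom.sf(k - 1, big_m, big_k, n)) if k > 0 else 1.0
        rows.append({"name": name, "k_unique": k, "n_genes": n, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class LiteratureStats:
    n_unique: int
    n_shared: int
    recent_fraction: float | None  # None when no publication year is known


def literature_stats(
    map_pmids: Iterable[str],
    others: Sequence[Iterable[str]],
    pub_years: Mapping[str, int] | None = None,
    since_year: int = 2010,
) -> LiteratureStats:
    """Uniqueness and recency of the map's annotation literature.

    ``n_unique``/``n_shared`` split the map PMIDs against the union of the
    other resources' PMID sets; ``recent_fraction`` is the share of map
    papers with a known year ≥ ``since_year`` (``None``, not 0, when no year
    is known — missing data is not evidence of old literature).
    """
    map_set = frozenset(map_pmids)
    pooled: frozenset[str] = frozenset()
    for other in others:
        pooled |= frozenset(other.pmids if isinstance(other, ResourceSet) else other)
    shared = map_set & pooled
    years = {p: y for p, y in (pub_years or {}).items() if p in map_set}
    recent = sum(1 for y in years.values() if y >= since_year)
    return LiteratureStats(
        n_unique=len(map_set - pooled),
        n_shared=len(shared),
        recent_fraction=recent / len(years) if years else None,
    )
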