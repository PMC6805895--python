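"""Reaction confidence scores.

Two integer scores on a 0–5 scale, 0 meaning "undefined confidence":

* the reference score (REF) weighs the publications annotating a reaction —
  experimental papers from the relevant immune cell type count full weight,
  reviews and experimental papers from non-immune cells count half;
* the functional proximity score (FUNC) measures how close the reaction's
  protein participants sit in an external protein–protein interaction (PPI)
  network, via the average shortest-path distance over all participant pairs.

Both weightings are declared conventions and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import floor
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .entities import MapEntity, MapReaction

REFERENCE_CATEGORIES: frozenset[str] = frozenset(
    {"experimental_immune", "review", "experimental_nonimmune"}
)

#: publication weights: five directly supporting experimental papers saturate the scale
DEFAULT_REF_WEIGHTS: Mapping[str, float] = {
    "experimental_immune": 1.0,
    "review": 0.5,
    "experimental_nonimmune": 0.5,
}

#: (distance threshold, score) pairs, unit-distance bins; distances above the
#: last threshold score 1, an undefined distance scores 0
DEFAULT_FUNC_BINS: tuple[tuple[float, int], ...] = ((1.0, 5), (2.0, 4), (3.0, 3), (4.0, 2))


@dataclass(frozen=True)
class ReferenceRecord:
    """One publication annotating a reaction, with its evidence category."""

    pmid: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in REFERENCE_CATEGORIES:
            raise ValueError(
                f"unknown reference category {self.category!r}; expected one of "
                f"{sorted(REFERENCE_CATEGORIES)}"
            )


@dataclass(frozen=True)
class ConfidenceScores:
    ref_score: int
    func_score: int

    def __post_init__(self) -> None:
        for name in ("ref_score", "func_score"):
            v = getattr(self, name)
            if not (0 <= v <= 5):
                raise ValueError(f"{name} must be in [0, 5], got {v}")


class PPIGraph:
    """Undirected protein–protein interaction graph over gene/protein symbols."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r} not allowed")
            g.add_edge(a, b)
        self._g = g

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "PPIGraph":
        return cls(graph.nodes, graph.edges)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PPIGraph":
        """Read a SIF-like edge list: two tab-separated symbol columns; a third
        interaction-type column, if present, is ignored."""
        edges = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"PPI edge line needs at least two columns: {line!r}")
            edges.append((fields[0], fields[1]))
        return cls(edges=edges)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self._g.edges)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __repr__(self) -> str:
        return f"PPIGraph({self._g.number_of_nodes()} nodes, {self._g.number_of_edges()} edges)"


def ref_score(
    references: Iterable[ReferenceRecord],
    weights: Mapping[str, float] | None = None,
    cap: int = 5,
) -> int:
    """Publication-based confidence: ``min(cap, floor(Σ weight(category)))``.

    An empty reference list yields 0 (undefined confidence); an unknown
    category raises (already at :class:`ReferenceRecord` construction, and
    again here for raw mappings passed in ``weights``).
    """
    weights = DEFAULT_REF_WEIGHTS if weights is None else weights
    total = 0.0
    for rec in references:
        if rec.category not in weights:
            raise ValueError(f"no weight for reference category {rec.category!r}")
        total += weights[rec.category]
    return min(cap, floor(total))


def avg_pairwise_distance(graph: PPIGraph, proteins: Iterable[str]) -> float | None:
    """Mean breadth-first shortest-path length over all unordered protein pairs.

    Returns ``None`` (an undefined distance, not an error) when fewer than two
    proteins are given, when any protein is absent from the graph, or when any
    pair is disconnected.
    """
    symbols = sorted(set(proteins))
    if len(symbols) < 2:
        return None
    g = graph._g
    if any(s not in g for s in symbols):
        return None
    total = 0
    n_pairs = 0
    for i, source in enumerate(symbols[:-1]):
        lengths = nx.single_source_shortest_path_length(g, source)
        for target in symbols[i + 1 :]:
            if target not in lengths:
                return None  # disconnected pair
            total += lengths[target]
            n_pairs += 1
    return total / n_pairs


def func_score(
    graph: PPIGraph,
    reaction: MapReaction,
    entities: Mapping[str, MapEntity],
    bins: Sequence[tuple[float, int]] = DEFAULT_FUNC_BINS,
) -> int:
    """Functional proximity confidence of a reaction from PPI distances.

    Participants are the symbols of all protein-class reactants, products and
    regulators. The average pairwise distance d̄ is binned: with the default
    bins, d̄ ≤ 1 → 5, ≤ 2 → 4, ≤ 3 → 3, ≤ 4 → 2, larger → 1; an undefined d̄
    (single participant, absent protein, disconnected pair) → 0.
    """
    participants = {
        entities[eid].symbol
        for eid in reaction.participant_ids()
        if eid in entities and entities[eid].entity_class == "protein"
    }
    d = avg_pairwise_distance(graph, participants)
    return score_from_distance(d, bins)


def score_from_distance(
    distance: float | None, bins: Sequence[tuple[float, int]] = DEFAULT_FUNC_BINS
) -> int:
    """Map an average PPI distance to the 0–5 FUNC scale (``None`` → 0)."""
    if distance is None:
        return 0
    for threshold, score in sorted(bins):
        if distance <= threshold:
            return score
    return 1


def score_reactions(
    graph: PPIGraph,
    reactions: Iterable[MapReaction],
    entities: Mapping[str, MapEntity],
    references: Mapping[str, Sequence[ReferenceRecord]] | None = None,
    ref_weights: Mapping[str, float] | None = None,
    func_bins: Sequence[tuple[float, int]] = DEFAULT_FUNC_BINS,
) -> "pd.DataFrame":
    """Score a batch of reactions; returns a reaction × (ref, func) table.

    ``references`` maps reaction id to its :class:`ReferenceRecord` list; a
    reaction absent from it gets REF 0.
    """
    import pandas as pd

    references = references or {}
    rows = []
    for rxn in reactions:
        rows.append(
            {
                "reaction": rxn.id,
                "ref_score": ref_score(references.get(rxn.id, ()), weights=ref_weights),
                "func_score": func_score(graph, rxn, entities, bins=func_bins),
            }
        )
    return pd.DataFrame(rows).set_index("reaction")
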