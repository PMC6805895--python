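"""Molecular entities and biochemical reactions of a signalling map.

Entities are the map nodes (proteins, genes, RNAs, antisense RNAs, simple
molecules, ions, drugs, phenotypes and complexes); reactions connect them and
may carry regulators (catalysis, inhibition, modulation, trigger, physical
stimulation) as well as publication references and the two 0–5 confidence
scores computed in :mod:`immunemap.confidence`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hierarchy import MapHierarchy
from .tags import TagSet, parse_tags

ENTITY_CLASSES: frozenset[str] = frozenset(
    {"protein", "gene", "rna", "asrna", "simple_molecule", "ion", "drug", "phenotype", "complex"}
)
#: classes for which a non-empty symbol is mandatory
_SYMBOL_REQUIRED = frozenset({"protein", "gene", "rna", "asrna"})

REGULATION_TYPES: frozenset[str] = frozenset(
    {"catalysis", "inhibition", "modulation", "trigger", "physical_stimulation"}
)

# Table-1-style column order for content summaries
_CLASS_COLUMNS = (
    "protein",
    "gene",
    "rna",
    "asrna",
    "simple_molecule",
    "ion",
    "drug",
    "phenotype",
    "complex",
)


@dataclass(frozen=True)
class MapEntity:
    """One molecular object on the map."""

    id: str
    symbol: str
    entity_class: str
    tags: TagSet = field(default_factory=TagSet)
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(
                f"unknown entity_class {self.entity_class!r}; expected one of "
                f"{sorted(ENTITY_CLASSES)}"
            )
        if self.entity_class in _SYMBOL_REQUIRED and not self.symbol:
            raise ValueError(f"entity {self.id!r} of class {self.entity_class!r} needs a symbol")
        object.__setattr__(self, "references", tuple(self.references))


@dataclass(frozen=True)
class MapReaction:
    """One biochemical reaction: reactants → products, with optional regulators."""

    id: str
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    regulators: tuple[tuple[str, str], ...] = ()  # (entity id, regulation type)
    references: tuple[str, ...] = ()
    ref_score: int | None = None
    func_score: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "regulators", tuple((e, t) for e, t in self.regulators))
        object.__setattr__(self, "references", tuple(self.references))
        for _, rtype in self.regulators:
            if rtype not in REGULATION_TYPES:
                raise ValueError(
                    f"unknown regulation type {rtype!r}; expected one of "
                    f"{sorted(REGULATION_TYPES)}"
                )
        for score_name in ("ref_score", "func_score"):
            score = getattr(self, score_name)
            if score is not None and not (0 <= int(score) <= 5):
                raise ValueError(f"{score_name} must be in [0, 5], got {score}")

    def participant_ids(self) -> tuple[str, ...]:
        """Entity ids of reactants, products and regulators, in that order."""
        return self.reactants + self.products + tuple(e for e, _ in self.regulators)


def check_reaction_entities(
    reactions: Iterable[MapReaction], entities: Mapping[str, MapEntity]
) -> None:
    """Verify every entity id referenced by a reaction exists; raise otherwise."""
    for rxn in reactions:
        missing = [e for e in rxn.participant_ids() if e not in entities]
        if missing:
            raise ValueError(f"reaction {rxn.id!r} references unknown entities {missing}")


def content_summary(entities: Iterable[MapEntity], hierarchy: MapHierarchy) -> pd.DataFrame:
    """Per-module species counts broken down by entity class.

    Returns a table with one row per hierarchy module (in hierarchy order),
    an ``untagged`` row for entities whose tags resolve to no module, and a
    ``total`` row counting each entity once. Columns: ``species`` plus one per
    entity class; in every row ``species`` equals the sum over the class
    columns. An entity tagged with several modules is counted in each.
    """
    modules = list(hierarchy.names("module"))
    rows = {m: dict.fromkeys(("species", *_CLASS_COLUMNS), 0) for m in modules}
    untagged = dict.fromkeys(("species", *_CLASS_COLUMNS), 0)
    total = dict.fromkeys(("species", *_CLASS_COLUMNS), 0)

    for ent in entities:
        targets = [m for m in ent.tags.modules if m in hierarchy.modules]
        buckets = [rows[m] for m in targets] if targets else [untagged]
        for bucket in buckets + [total]:
            bucket["species"] += 1
            bucket[ent.entity_class] += 1

    index = modules + ["untagged", "total"]
    data = [rows[m] for m in modules] + [untagged, total]
    return pd.DataFrame(data, index=pd.Index(index, name="module"))


def write_entities_csv(entities: Iterable[MapEntity], path: str | Path) -> None:
    """Write entities as CSV (id, symbol, entity_class, tags, references)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "symbol", "entity_class", "tags", "references"])
        for ent in entities:
            writer.writerow(
                [ent.id, ent.symbol, ent.entity_class, ent.tags.to_text(), ";".join(ent.references)]
            )


def read_entities_csv(path: str | Path) -> list[MapEntity]:
    """Read entities written by :func:`write_entities_csv`."""
    out: list[MapEntity] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MapEntity(
                    id=row["id"],
                    symbol=row["symbol"],
                    entity_class=row["entity_class"],
                    tags=parse_tags(row.get("tags", "") or ""),
                    references=tuple(p for p in (row.get("references", "") or "").split(";") if p),
                )
            )
    return out
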