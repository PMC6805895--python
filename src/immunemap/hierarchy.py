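"""The four-level map hierarchy and its GMT gene-set representation.

An integrated signalling map is organized into nested containers: two
polarization *zones* (anti-tumor vs pro-tumor) partition the biological
processes (*meta-modules*), which partition the functional *modules*, which
partition the signalling *pathways*; a pathway is a set of gene symbols.
Containers partition containers — every pathway has exactly one parent module
and so on — but a *gene* may appear in many pathways, so gene sets of sibling
containers can overlap.

The gene set of any container is defined bottom-up as the union of its
children's gene sets, and every level can be exported to (and re-imported
from) the tab-separated GMT gene-set exchange format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

Level = str
LEVELS: tuple[Level, ...] = ("pathway", "module", "meta_module", "zone")


@dataclass(frozen=True)
class GeneSet:
    """A named, described, ordered set of gene symbols (one GMT line)."""

    name: str
    description: str
    genes: tuple[str, ...]


class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets = tuple(sets)
        names = [s.name for s in self._sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dup}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, i: int) -> GeneSet:
        return self._sets[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self._sets)

    def by_name(self, name: str) -> GeneSet:
        for s in self._sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self._sets)} sets)"


class MapHierarchy:
    """Validated zones → meta-modules → modules → pathways partition.

    Construct via :func:`build_hierarchy`, which checks the partition
    properties and raises on violations. Gene sets at every level are derived
    bottom-up; ``gene_index`` maps each gene symbol to the containers holding
    it at each level.
    """

    def __init__(
        self,
        zones: Mapping[str, Iterable[str]],
        meta_modules: Mapping[str, Iterable[str]],
        modules: Mapping[str, Iterable[str]],
        pathways: Mapping[str, Iterable[str]],
    ):
        self.zones = {z: frozenset(v) for z, v in zones.items()}
        self.meta_modules = {m: frozenset(v) for m, v in meta_modules.items()}
        self.modules = {m: frozenset(v) for m, v in modules.items()}
        self.pathways = {p: frozenset(v) for p, v in pathways.items()}
        self._validate()

        # parent pointers (exist and are unique after validation)
        self.module_of_pathway = {p: m for m, ps in self.modules.items() for p in ps}
        self.meta_module_of_module = {m: mm for mm, ms in self.meta_modules.items() for m in ms}
        self.zone_of_meta_module = {mm: z for z, mms in self.zones.items() for mm in mms}

        self._genes: dict[Level, dict[str, frozenset[str]]] = {"pathway": dict(self.pathways)}
        self._genes["module"] = {
            m: frozenset().union(*(self.pathways[p] for p in ps)) for m, ps in self.modules.items()
        }
        self._genes["meta_module"] = {
            mm: frozenset().union(*(self._genes["module"][m] for m in ms))
            for mm, ms in self.meta_modules.items()
        }
        self._genes["zone"] = {
            z: frozenset().union(*(self._genes["meta_module"][mm] for mm in mms))
            if mms
            else frozenset()
            for z, mms in self.zones.items()
        }

        self.gene_index: dict[str, dict[Level, frozenset[str]]] = {}
        for level in LEVELS:
            for name, genes in self._genes[level].items():
                for g in genes:
                    entry = self.gene_index.setdefault(g, {lv: frozenset() for lv in LEVELS})
                    entry[level] = entry[level] | {name}

    def _validate(self) -> None:
        for level_name, parents, child_names in (
            ("meta_module", self.zones, set(self.meta_modules)),
            ("module", self.meta_modules, set(self.modules)),
            ("pathway", self.modules, set(self.pathways)),
        ):
            seen: dict[str, str] = {}
            for parent, children in parents.items():
                for child in children:
                    if child in seen:
                        raise ValueError(
                            f"{level_name} {child!r} assigned to two parents: "
                            f"{seen[child]!r} and {parent!r}"
                        )
                    if child not in child_names:
                        raise ValueError(f"dangling {level_name} name {child!r} under {parent!r}")
                    seen[child] = parent
            orphans = child_names - set(seen)
            if orphans:
                raise ValueError(f"{level_name}(s) with no parent: {sorted(orphans)}")
        for p, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"empty pathway {p!r}")

    def names(self, level: Level) -> tuple[str, ...]:
        self._check_level(level)
        return tuple(self._genes[level])

    def genes(self, level: Level, name: str) -> frozenset[str]:
        """Gene set of one container (union of its descendants' pathways)."""
        self._check_level(level)
        return self._genes[level][name]

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(self.gene_index)

    def ancestry(self, level: Level, name: str) -> tuple[str, ...]:
        """Path from the enclosing zone down to (and including) ``name``."""
        self._check_level(level)
        if name not in self._genes[level]:
            raise KeyError(f"no {level} named {name!r}")
        chain = [name]
        if level == "pathway":
            chain.insert(0, self.module_of_pathway[name])
        if level in ("pathway", "module"):
            chain.insert(0, self.meta_module_of_module[chain[0]])
        if level in ("pathway", "module", "meta_module"):
            chain.insert(0, self.zone_of_meta_module[chain[0]])
        return tuple(chain)

    @staticmethod
    def _check_level(level: Level) -> None:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")

    def __repr__(self) -> str:
        return (
            f"MapHierarchy({len(self.zones)} zones, {len(self.meta_modules)} meta-modules, "
            f"{len(self.modules)} modules, {len(self.pathways)} pathways, "
            f"{len(self.gene_index)} genes)"
        )


def build_hierarchy(
    zone_defs: Mapping[str, Iterable[str]],
    meta_module_defs: Mapping[str, Iterable[str]],
    module_defs: Mapping[str, Iterable[str]],
    pathway_defs: Mapping[str, Iterable[str]],
) -> MapHierarchy:
    """Assemble and validate a :class:`MapHierarchy` from per-level definitions.

    Each mapping sends a container name to its child names (gene symbols for
    ``pathway_defs``). Raises ``ValueError`` on a child with two parents, a
    dangling or orphaned child name, or an empty pathway.
    """
    return MapHierarchy(zone_defs, meta_module_defs, module_defs, pathway_defs)


def to_gene_sets(hierarchy: MapHierarchy, level: Level) -> GeneSetCollection:
    """Export one level of the hierarchy as a gene-set collection.

    One set per container at ``level``; the description records the ancestry
    path ``zone/meta_module/.../name`` (readers must not rely on it); genes
    are ordered lexicographically for reproducible output.
    """
    sets = [
        GeneSet(
            name=name,
            description="/".join(hierarchy.ancestry(level, name)),
            genes=tuple(sorted(hierarchy.genes(level, name))),
        )
        for name in hierarchy.names(level)
    ]
    return GeneSetCollection(sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, genes.

    Blank lines and trailing empty fields are ignored; a line with fewer than
    three tab-separated fields raises ``ValueError``.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 gene "
                    f"(got {len(fields)} fields)"
                )
            name, description, *genes = fields
            sets.append(GeneSet(name=name, description=description, genes=tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in the GMT dialect read by :func:`read_gmt`.

    Raises ``ValueError`` on an empty gene set (a gene-less GMT line is
    unreadable by construction).
    """
    lines = []
    for s in collection:
        if not s.genes:
            raise ValueError(f"refusing to write empty gene set {s.name!r}")
        lines.append("\t".join([s.name, s.description, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
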