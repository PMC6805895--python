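"""Entity annotation tags.

Every molecular entity on a signalling map carries free-text annotation in
which membership in map sub-structures is declared with ``PREFIX:NAME``
tokens: ``MODULE:<NAME>`` for functional modules, ``PATHWAY:<NAME>`` for
signalling pathways and ``MAP:<NAME>`` for cell-type-specific maps. The
grammar is deliberately simple so that tags survive round trips through
plain-text annotation fields: ``NAME`` is the maximal run of non-whitespace
characters after the colon, matching is case-sensitive, and unknown prefixes
are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_PREFIXES = {"MODULE": "modules", "PATHWAY": "pathways", "MAP": "cell_maps"}


@dataclass(frozen=True)
class TagSet:
    """Parsed tags of one entity, grouped by prefix."""

    modules: frozenset[str] = field(default_factory=frozenset)
    pathways: frozenset[str] = field(default_factory=frozenset)
    cell_maps: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for group in ("modules", "pathways", "cell_maps"):
            names = frozenset(getattr(self, group))
            object.__setattr__(self, group, names)
            for name in names:
                if not name or any(ch.isspace() for ch in name):
                    raise ValueError(f"invalid tag name {name!r}: empty or contains whitespace")

    def __bool__(self) -> bool:
        return bool(self.modules or self.pathways or self.cell_maps)

    def to_text(self) -> str:
        """Serialize back to the textual ``PREFIX:NAME`` form (sorted, space-separated)."""
        tokens = (
            [f"MODULE:{n}" for n in sorted(self.modules)]
            + [f"PATHWAY:{n}" for n in sorted(self.pathways)]
            + [f"MAP:{n}" for n in sorted(self.cell_maps)]
        )
        return " ".join(tokens)


def parse_tags(annotation_text: str) -> TagSet:
    """Extract all ``MODULE:``/``PATHWAY:``/``MAP:`` tags from free annotation text.

    Tokens are whitespace-delimited; a token of the form ``PREFIX:NAME`` with a
    recognized prefix and non-empty name contributes one tag. Anything else,
    including unknown prefixes, is silently ignored, so arbitrary prose yields
    an empty :class:`TagSet` rather than an error.
    """
    groups: dict[str, set[str]] = {"modules": set(), "pathways": set(), "cell_maps": set()}
    for token in annotation_text.split():
        prefix, sep, name = token.partition(":")
        if sep and name and prefix in _PREFIXES:
            groups[_PREFIXES[prefix]].add(name)
    return TagSet(
        modules=frozenset(groups["modules"]),
        pathways=frozenset(groups["pathways"]),
        cell_maps=frozenset(groups["cell_maps"]),
    )
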