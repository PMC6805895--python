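"""Single-cell expression container and preprocessing.

The analysis pipeline works on a genes × cells matrix of log-scale expression
that has been mean-centred per gene. :func:`preprocess` takes either already
log-transformed (normalized) data or raw non-negative values and produces a
centred :class:`ExpressionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

_CENTER_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Genes × cells log-expression with explicit centering state."""

    values: np.ndarray
    genes: tuple[str, ...]
    cells: tuple[str, ...]
    centered: bool = False
    _gene_pos: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.genes = tuple(self.genes)
        self.cells = tuple(self.cells)
        if self.values.ndim != 2 or self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes × {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")
        if self.centered and self.values.size:
            drift = np.abs(self.values.mean(axis=1)).max()
            if drift > _CENTER_TOL:
                raise ValueError(f"matrix marked centered but max row-mean is {drift:.3g}")
        self._gene_pos = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, centered: bool = False) -> "ExpressionMatrix":
        """Build from a DataFrame with genes as index and cells as columns."""
        return cls(
            values=frame.to_numpy(dtype=np.float64),
            genes=tuple(map(str, frame.index)),
            cells=tuple(map(str, frame.columns)),
            centered=centered,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.cells))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_pos[gene]]

    def gene_positions(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes`` (all must be present)."""
        return np.array([self._gene_pos[g] for g in genes], dtype=np.intp)

    def present_genes(self, genes) -> list[str]:
        """Subset of ``genes`` measured in this matrix, in sorted order."""
        return sorted(g for g in set(genes) if g in self._gene_pos)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: j for j, c in enumerate(self.cells)}
        idx = np.array([pos[c] for c in cells], dtype=np.intp)
        # column subsetting preserves row means only in expectation, so the
        # centered flag is dropped
        return ExpressionMatrix(self.values[:, idx], self.genes, tuple(cells), centered=False)


def preprocess(
    data: pd.DataFrame | ExpressionMatrix,
    already_log: bool = True,
) -> ExpressionMatrix:
    """Log-transform (if needed) and mean-centre each gene across cells.

    Parameters
    ----------
    data:
        Genes × cells values, as a DataFrame (index genes, columns cells) or
        an :class:`ExpressionMatrix`.
    already_log:
        When False the input must be non-negative raw values and is
        transformed with ``log2(x + 1)`` first.

    Raises on NaN anywhere, and on negative values when ``already_log`` is
    False.
    """
    if isinstance(data, pd.DataFrame):
        matrix = ExpressionMatrix.from_frame(data)
    elif isinstance(data, ExpressionMatrix):
        matrix = data
    else:
        raise TypeError(f"expected DataFrame or ExpressionMatrix, got {type(data).__name__}")

    values = matrix.values
    if not already_log:
        if (values < 0).any():
            raise ValueError("raw expression must be non-negative before log transform")
        values = np.log2(values + 1.0)
    centered = values - values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(centered, matrix.genes, matrix.cells, centered=True)
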