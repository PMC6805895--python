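"""Module activity scores and group comparison.

A gene set's activity in a cell is the mean log-expression of the set's most
variant half (genes above the median variability, computed across all cells
so that both groups see the same selection). Group activity is the mean of
the per-cell scores, and groups are compared with a two-sided Welch t-test;
p values are reported with the standard significance code
(*** p < 0.001, ** p < 0.01, * p < 0.05, · p < 0.1).

The same rule applies at every hierarchy level — pathway, module,
meta-module and the two polarization zones, where the container's gene set
is the union over its members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .hierarchy import MapHierarchy, Level
from .ranking import CellGroups

#: minimum pathway size ("more than 10 molecules") for the pathway heatmap
DEFAULT_MIN_PATHWAY_GENES = 11


def significance_code(p: float) -> str:
    """Standard code: *** < 0.001, ** < 0.01, * < 0.05, · < 0.1, else ''."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "·"
    return ""


@dataclass(frozen=True)
class ModuleScoreRow:
    """One gene set's group comparison."""

    name: str
    level: str
    mean_group1: float
    mean_group2: float
    t: float
    p: float
    code: str
    direction: str  # which group scores higher ("" on an exact tie)
    n_genes: int
    skipped: bool = False


def select_variant_genes(matrix: ExpressionMatrix, gene_set: Iterable[str]) -> list[str]:
    """The top ``ceil(n/2)`` most variant genes of the set.

    Genes absent from the matrix are dropped first; variance is the sample
    variance (n−1 denominator) across *all* cells; ties are broken
    lexicographically by symbol. Raises when no set gene is measured.
    """
    present = matrix.present_genes(gene_set)
    if not present:
        raise ValueError("gene set has no genes in the expression matrix")
    variances = matrix.values[matrix.gene_positions(present)].var(axis=1, ddof=1)
    ranked = sorted(zip(present, variances), key=lambda gv: (-gv[1], gv[0]))
    keep = math.ceil(len(ranked) / 2)
    return [g for g, _ in ranked[:keep]]


def module_score(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    cells: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-cell mean over the (already selected) genes, and its group mean.

    Returns the per-cell scores over *all* cells of the matrix as a Series,
    and the mean over ``cells`` (default: all cells).
    """
    if not genes:
        raise ValueError("empty gene selection")
    scores = pd.Series(
        matrix.values[matrix.gene_positions(list(genes))].mean(axis=0),
        index=list(matrix.cells),
    )
    group = scores.loc[list(cells)] if cells is not None else scores
    return scores, float(group.mean())


def compare_groups(
    matrix: ExpressionMatrix,
    gene_set: Iterable[str],
    groups: CellGroups,
    name: str = "",
    level: str = "",
    equal_var: bool = False,
) -> ModuleScoreRow:
    """Welch (default) two-sided t-test of group1 vs group2 activity scores.

    Variance selection is applied internally on the full matrix. Raises when
    a group has fewer than 2 cells or when both groups have zero score
    variance. ``equal_var=True`` switches to the pooled-variance Student test.
    """
    if tuple(groups.cells) != matrix.cells:
        raise ValueError("groups and matrix refer to different cells")
    selected = select_variant_genes(matrix, gene_set)
    scores, _ = module_score(matrix, selected)
    g1 = scores.to_numpy()[groups.mask("group1")]
    g2 = scores.to_numpy()[groups.mask("group2")]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 cells for a t-test")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if np.isclose(g1.mean(), g2.mean()):
            # identical constants: no evidence of difference
            t_stat, p_val = 0.0, 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        t_stat, p_val = stats.ttest_ind(g1, g2, equal_var=equal_var)
    m1, m2 = float(g1.mean()), float(g2.mean())
    direction = "group1" if m1 > m2 else "group2" if m2 > m1 else ""
    return ModuleScoreRow(
        name=name,
        level=level,
        mean_group1=m1,
        mean_group2=m2,
        t=float(t_stat),
        p=float(p_val),
        code=significance_code(float(p_val)),
        direction=direction,
        n_genes=len(selected),
    )


def score_all(
    matrix: ExpressionMatrix,
    hierarchy: MapHierarchy,
    groups: CellGroups,
    level: Level,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Group comparison for every gene set at one hierarchy level.

    Sets without any measured gene are reported with ``skipped=True`` and NaN
    statistics rather than dropped. Returns a DataFrame of
    :class:`ModuleScoreRow` fields.
    """
    rows = []
    for name in hierarchy.names(level):
        gene_set = hierarchy.genes(level, name)
        if not matrix.present_genes(gene_set):
            rows.append(
                ModuleScoreRow(
                    name=name,
                    level=level,
                    mean_group1=float("nan"),
                    mean_group2=float("nan"),
                    t=float("nan"),
                    p=float("nan"),
                    code="",
                    direction="",
                    n_genes=0,
                    skipped=True,
                )
            )
            continue
        rows.append(
            compare_groups(matrix, gene_set, groups, name=name, level=level, equal_var=equal_var)
        )
    return pd.DataFrame([asdict(r) for r in rows])


def polarization_scores(
    matrix: ExpressionMatrix,
    hierarchy: MapHierarchy,
    groups: CellGroups,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Anti-tumor vs pro-tumor zone activity of the two cell groups.

    The zone-level case of :func:`score_all`; requires exactly two zones.
    """
    if len(hierarchy.zones) != 2:
        raise ValueError(f"polarization needs exactly 2 zones, got {len(hierarchy.zones)}")
    return score_all(matrix, hierarchy, groups, level="zone", equal_var=equal_var)


def staining_table(table: pd.DataFrame) -> pd.DataFrame:
    """Map-staining export: one row per (set, group) with a red/green color.

    Red marks the group whose mean activity exceeds the other's, green the
    lower one; exact ties are neutral (empty color). Skipped sets are
    omitted.
    """
    rows = []
    for rec in table.itertuples(index=False):
        if getattr(rec, "skipped", False):
            continue
        colors = {"group1": "", "group2": ""}
        if rec.mean_group1 > rec.mean_group2:
            colors = {"group1": "red", "group2": "green"}
        elif rec.mean_group2 > rec.mean_group1:
            colors = {"group1": "green", "group2": "red"}
        for group, mean in (("group1", rec.mean_group1), ("group2", rec.mean_group2)):
            rows.append(
                {
                    "set": rec.name,
                    "level": rec.level,
                    "group": group,
                    "mean": mean,
                    "t": rec.t,
                    "p": rec.p,
                    "code": rec.code,
                    "color": colors[group],
                }
            )
    return pd.DataFrame(rows)


def pathway_heatmap_matrix(
    matrix: ExpressionMatrix,
    hierarchy: MapHierarchy,
    groups: CellGroups,
    min_genes: int = DEFAULT_MIN_PATHWAY_GENES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Group-mean activity of the larger pathways, for heatmap plotting.

    Only pathways with at least ``min_genes`` measured genes are kept — the
    default 11 implements "more than 10 molecules". Returns the pathways ×
    groups score matrix and the per-pathway significance codes.
    """
    table = score_all(matrix, hierarchy, groups, level="pathway")
    measured = {
        name: len(matrix.present_genes(hierarchy.genes("pathway", name)))
        for name in hierarchy.names("pathway")
    }
    keep = table[~table["skipped"] & (table["name"].map(measured) >= min_genes)]
    scores = keep.set_index("name")[["mean_group1", "mean_group2"]]
    scores.columns = ["group1", "group2"]
    codes = keep.set_index("name")["code"]
    return scores, codes
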