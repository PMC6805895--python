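"""Survival z-score enrichment of map gene content.

The input is a per-gene table of survival z-scores from a pan-cancer
meta-analysis (columns ``gene``, ``z``, ``p``), with the convention that
z < 0 marks a positive association with patient survival. The map's gene
content is tested for enrichment in survival-significant genes against the
genome-wide significant fraction with a 1-df χ² test, and each meta-module is
summarized by its mean z and its counts of significant genes on either side
of zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import MapHierarchy

_REQUIRED_COLUMNS = ("gene", "z", "p")

ENRICHMENT_ALPHA = 0.001  # χ² significance threshold for map-level enrichment


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survival table lacks columns {missing}")
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene symbols in survival table: {dup[:5]}")
    return table


@dataclass(frozen=True)
class EnrichmentResult:
    """Map-level survival enrichment against the genome-wide fraction."""

    k_significant: int
    n_scored: int
    fraction: float
    chi2: float
    p: float
    significant: bool  # at the 0.001 threshold


def significant_genes(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with p strictly below ``alpha``."""
    table = _check_table(table)
    return table[table["p"] < alpha]


def map_overlap_enrichment(
    map_genes: Iterable[str],
    table: pd.DataFrame,
    background_fraction: float,
    alpha: float = 0.05,
    method: str = "goodness_of_fit",
    background_n: int | None = None,
) -> EnrichmentResult:
    """χ² test of the map's survival-significant fraction vs the genome.

    ``background_fraction`` is the genome-wide significant fraction (an input
    by design: whether it is taken over all genes or all scored genes is a
    choice of the reference study). The default is a 1-df Pearson
    goodness-of-fit of the observed (significant, non-significant) counts
    among the n map genes found in the table against expectations
    ``(n·f, n·(1−f))``; cells with zero expectation are skipped, which keeps
    the degenerate f → 0/1 edges finite. ``method="contingency"`` instead
    runs a 2×2 map-vs-genome test and needs ``background_n`` scored genome
    genes. Raises when no map gene is scored.
    """
    table = _check_table(table)
    if not 0.0 < background_fraction < 1.0 and method == "contingency":
        raise ValueError("background_fraction must be in (0, 1)")
    map_genes = set(map_genes)
    scored = table[table["gene"].isin(map_genes)]
    n = len(scored)
    if n == 0:
        raise ValueError("no map gene is present in the survival table")
    k = int((scored["p"] < alpha).sum())
    fraction = k / n

    if method == "goodness_of_fit":
        observed = np.array([k, n - k], dtype=float)
        expected = np.array([n * background_fraction, n * (1.0 - background_fraction)])
        keep = expected > 0
        chi2 = float((((observed - expected) ** 2)[keep] / expected[keep]).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "contingency":
        if background_n is None:
            raise ValueError("contingency method needs background_n")
        bg_k = int(round(background_fraction * background_n))
        contingency = np.array([[k, n - k], [bg_k, background_n - bg_k]])
        chi2, p, _, _ = stats.chi2_contingency(contingency, correction=False)
        chi2, p = float(chi2), float(p)
    else:
        raise ValueError(f"unknown method {method!r}")

    return EnrichmentResult(
        k_significant=k,
        n_scored=n,
        fraction=fraction,
        chi2=chi2,
        p=p,
        significant=p < ENRICHMENT_ALPHA,
    )


def meta_module_summary(
    hierarchy: MapHierarchy, table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-meta-module mean z and significant-gene counts by sign.

    The mean is over *all* scored member genes; the counts are over the
    significant ones (p < alpha) split into positive association with
    survival (z < 0) and negative (z > 0). Genes absent from the table are
    excluded throughout; a meta-module with no scored gene is flagged
    ``skipped``. Genes in several meta-modules contribute to each. Rows are
    sorted by mean z, descending (most survival-adverse first).
    """
    table = _check_table(table)
    indexed = table.set_index("gene")
    rows = []
    for meta in hierarchy.names("meta_module"):
        members = sorted(hierarchy.genes("meta_module", meta))
        scored = indexed.loc[[g for g in members if g in indexed.index]]
        if scored.empty:
            rows.append(
                {
                    "meta_module": meta,
                    "mean_z": float("nan"),
                    "n_scored": 0,
                    "n_positive_survival": 0,
                    "n_negative_survival": 0,
                    "skipped": True,
                }
            )
            continue
        sig = scored[scored["p"] < alpha]
        rows.append(
            {
                "meta_module": meta,
                "mean_z": float(scored["z"].mean()),
                "n_scored": len(scored),
                "n_positive_survival": int((sig["z"] < 0).sum()),
                "n_negative_survival": int((sig["z"] > 0).sum()),
                "skipped": False,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("mean_z", ascending=False, na_position="last").reset_index(drop=True)
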