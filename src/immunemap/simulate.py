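"""Synthetic inputs with known ground truth.

Every external input of the pipeline is generated here with planted structure
so that downstream recovery can be scored exactly:

* :func:`generate_map` — a regular two-zone hierarchy (zones → meta-modules →
  modules → pathways) with synthetic gene symbols and tagged protein entities;
* :func:`generate_cells` — a log-scale genes × cells matrix
  ``x_gc = s_g · t_c + ε_gc`` with a one-dimensional non-Gaussian latent
  polarization gradient ``t`` loading (±a) on the genes of the planted active
  modules, emulating normalized single-cell RNA-seq of immune cells along an
  anti-tumor ↔ pro-tumor axis;
* :func:`generate_ppi` — an Erdős–Rényi background densified within pathways,
  for exercising the functional proximity score;
* :func:`generate_survival_zscores` — per-gene survival z-scores drawn around
  planted per-meta-module means (z < 0 = positive association with survival).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .confidence import PPIGraph
from .entities import MapEntity
from .expression import ExpressionMatrix
from .hierarchy import MapHierarchy, build_hierarchy
from .tags import TagSet

ANTI_TUMOR_ZONE = "Anti-tumor"
PRO_TUMOR_ZONE = "Pro-tumor"


@dataclass(frozen=True)
class SimulationSpec:
    """Shape and noise parameters of the synthetic study.

    Defaults give 2 zones × 2 meta-modules × 3 modules × 3 pathways ×
    15 genes = 540 genes and 200 cells, a bimodal latent gradient with unit
    loading magnitude and Gaussian noise of sd 0.5, and half of the modules
    in each zone carrying signal.
    """

    n_zones: int = 2
    meta_modules_per_zone: int = 2
    modules_per_meta_module: int = 3
    pathways_per_module: int = 3
    genes_per_pathway: int = 15
    n_cells: int = 200
    latent_distribution: str = "bimodal"  # or "uniform"
    loading_magnitude: float = 1.0
    noise_sd: float = 0.5
    fraction_active_modules: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_zones",
            "meta_modules_per_zone",
            "modules_per_meta_module",
            "pathways_per_module",
            "genes_per_pathway",
            "n_cells",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.loading_magnitude <= 0:
            raise ValueError("loading_magnitude must be > 0")
        if not 0.0 <= self.fraction_active_modules <= 1.0:
            raise ValueError("fraction_active_modules must be in [0, 1]")
        if self.latent_distribution not in ("bimodal", "uniform"):
            raise ValueError("latent_distribution must be 'bimodal' or 'uniform'")

    @property
    def n_genes(self) -> int:
        return (
            self.n_zones
            * self.meta_modules_per_zone
            * self.modules_per_meta_module
            * self.pathways_per_module
            * self.genes_per_pathway
        )


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    latent: np.ndarray  # t_c per cell
    groups: np.ndarray  # 1 where t > 0 (anti-tumor side), else 2
    active_modules: frozenset[str]
    loadings: pd.Series  # s_g per gene, +a anti-tumor / −a pro-tumor / 0 inactive


def _zone_names(n_zones: int) -> list[str]:
    if n_zones == 2:
        return [ANTI_TUMOR_ZONE, PRO_TUMOR_ZONE]
    return [f"Zone{i + 1}" for i in range(n_zones)]


def generate_map(spec: SimulationSpec) -> tuple[MapHierarchy, list[MapEntity]]:
    """Build the regular synthetic hierarchy and its tagged protein entities.

    Gene symbols are ``G0001 …``; container names encode their ancestry
    (e.g. ``Anti-tumor_MM1_M2_P3``). Deterministic: the structure involves no
    randomness beyond the spec counts.
    """
    zones: dict[str, list[str]] = {}
    meta_modules: dict[str, list[str]] = {}
    modules: dict[str, list[str]] = {}
    pathways: dict[str, list[str]] = {}
    entities: list[MapEntity] = []

    gene_no = 0
    for zone in _zone_names(spec.n_zones):
        zones[zone] = []
        for i in range(spec.meta_modules_per_zone):
            meta = f"{zone}_MM{i + 1}"
            zones[zone].append(meta)
            meta_modules[meta] = []
            for j in range(spec.modules_per_meta_module):
                module = f"{meta}_M{j + 1}"
                meta_modules[meta].append(module)
                modules[module] = []
                for k in range(spec.pathways_per_module):
                    pathway = f"{module}_P{k + 1}"
                    modules[module].append(pathway)
                    genes = []
                    for _ in range(spec.genes_per_pathway):
                        gene_no += 1
                        genes.append(f"G{gene_no:04d}")
                    pathways[pathway] = genes
                    tags = TagSet(
                        modules=frozenset({module}),
                        pathways=frozenset({pathway}),
                        cell_maps=frozenset({"SYNTHETIC"}),
                    )
                    entities.extend(
                        MapEntity(id=g, symbol=g, entity_class="protein", tags=tags)
                        for g in genes
                    )

    hierarchy = build_hierarchy(zones, meta_modules, modules, pathways)
    return hierarchy, entities


def _planted_loadings(
    hierarchy: MapHierarchy, spec: SimulationSpec, rng: np.random.Generator
) -> tuple[pd.Series, frozenset[str]]:
    """Pick active modules per zone and assign ±a loadings to their genes."""
    genes = sorted(hierarchy.all_genes)
    loadings = pd.Series(0.0, index=genes)
    active: set[str] = set()
    for zone in hierarchy.names("zone"):
        zone_modules = sorted(
            m
            for mm in hierarchy.zones[zone]
            for m in hierarchy.meta_modules[mm]
        )
        n_active = int(round(spec.fraction_active_modules * len(zone_modules)))
        chosen = rng.choice(zone_modules, size=n_active, replace=False) if n_active else []
        sign = 1.0 if zone == ANTI_TUMOR_ZONE else -1.0
        for module in chosen:
            active.add(module)
            for g in hierarchy.genes("module", module):
                loadings[g] = sign * spec.loading_magnitude
    return loadings, frozenset(active)


def generate_cells(
    hierarchy: MapHierarchy, spec: SimulationSpec
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the log-expression matrix with the planted latent gradient.

    ``x_gc = s_g t_c + ε_gc`` with ``ε ~ N(0, σ²)``; the latent ``t`` is
    bimodal (±1 plus N(0, 0.1²) jitter — non-Gaussian, as the independent
    component model assumes) or uniform(−1, 1). Cells with ``t > 0`` are the
    planted anti-tumor group (label 1), the rest label 2. The matrix is
    returned uncentred, on log scale.
    """
    rng = np.random.default_rng(spec.seed)
    loadings, active = _planted_loadings(hierarchy, spec, rng)

    if spec.latent_distribution == "bimodal":
        t = rng.choice([-1.0, 1.0], size=spec.n_cells) + rng.normal(0.0, 0.1, size=spec.n_cells)
    else:
        t = rng.uniform(-1.0, 1.0, size=spec.n_cells)
    groups = np.where(t > 0, 1, 2)

    s = loadings.to_numpy()
    noise = rng.normal(0.0, spec.noise_sd, size=(len(s), spec.n_cells))
    values = np.outer(s, t) + noise

    cells = tuple(f"C{j + 1:04d}" for j in range(spec.n_cells))
    matrix = ExpressionMatrix(values, tuple(loadings.index), cells, centered=False)
    truth = GroundTruth(latent=t, groups=groups, active_modules=active, loadings=loadings)
    return matrix, truth


def generate_ppi(
    entities: list[MapEntity],
    intra_reaction_edge_prob: float = 0.8,
    background_edge_prob: float = 0.01,
    seed: int = 1,
) -> PPIGraph:
    """Random PPI graph: dense within pathways, sparse Erdős–Rényi elsewhere.

    A protein pair sharing at least one pathway tag is joined with probability
    ``intra_reaction_edge_prob``; every other pair with
    ``background_edge_prob``. Deterministic per seed.
    """
    proteins = sorted(
        {e.symbol for e in entities if e.entity_class == "protein"},
    )
    n = len(proteins)
    pathway_names = sorted({p for e in entities for p in e.tags.pathways})
    pathway_pos = {p: i for i, p in enumerate(pathway_names)}
    membership = np.zeros((n, len(pathway_names)), dtype=bool)
    symbol_pos = {s: i for i, s in enumerate(proteins)}
    for e in entities:
        if e.entity_class != "protein":
            continue
        for p in e.tags.pathways:
            membership[symbol_pos[e.symbol], pathway_pos[p]] = True

    shares_pathway = membership @ membership.T > 0 if pathway_names else np.zeros((n, n), bool)
    prob = np.where(shares_pathway, intra_reaction_edge_prob, background_edge_prob)

    rng = np.random.default_rng(seed)
    draws = rng.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    adj = upper & (draws < prob)
    edges = [(proteins[i], proteins[j]) for i, j in zip(*np.nonzero(adj))]
    return PPIGraph(nodes=proteins, edges=edges)


def generate_survival_zscores(
    hierarchy: MapHierarchy,
    mu: Mapping[str, float] | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Per-gene survival z-score table around planted per-meta-module means.

    ``mu`` maps meta-module name to its planted mean z (missing meta-modules
    default to 0); a gene in several meta-modules uses the mean of their
    planted values. ``z_g ~ N(μ, 1)``, ``p_g`` is the two-sided standard
    normal tail probability. Returns a DataFrame with columns ``gene``, ``z``,
    ``p`` — the z < 0 rows are the genes positively associated with survival.
    """
    mu = dict(mu or {})
    unknown = set(mu) - set(hierarchy.names("meta_module"))
    if unknown:
        raise ValueError(f"planted means for unknown meta-modules: {sorted(unknown)}")
    genes = sorted(hierarchy.all_genes)
    means = np.array(
        [
            np.mean([mu.get(mm, 0.0) for mm in hierarchy.gene_index[g]["meta_module"]])
            for g in genes
        ]
    )
    rng = np.random.default_rng(seed)
    z = rng.normal(means, 1.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"gene": genes, "z": z, "p": p})
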