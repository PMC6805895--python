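"""Cell ranking along the most stable independent component.

Single cells are ordered along a latent polarization axis by independent
component analysis (ICA) of the centred genes × cells matrix. Cells play the
role of observations: each component is a latent signal evaluated per cell
(the projections, which are non-Gaussian across cells — e.g. bimodal for a
two-state polarization), and the associated gene-space pattern (the
loadings) says which genes carry it.

The estimation is a fixed-point iteration with the log-cosh contrast and
symmetric decorrelation on SVD-whitened data, repeated from many random
starts on bootstrap-resampled cells. Components pooled across runs are
clustered by the absolute Pearson correlation of their cell projections; a
cluster's *stability index* is its mean within-cluster correlation minus its
mean correlation to everything else, scaled by how many of the restarts the
cluster draws from, so a component reproduced in every resample scores near
1 while a one-off local optimum of a fixed noise realization scores low. The representative of the most stable cluster is
IC1. Because an independent component's sign is unidentifiable,
:func:`orient_component` fixes it against the hierarchy's anti-tumor zone so
that "group 1" is reproducibly the anti-tumor side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import linalg

from .expression import ExpressionMatrix
from .hierarchy import MapHierarchy
from .simulate import ANTI_TUMOR_ZONE

logger = logging.getLogger(__name__)

#: below this stability index the top component is logged as unreliable
DEFAULT_STABILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class ComponentResult:
    """Estimated components, sorted by stability; index 0 is IC1."""

    projections: np.ndarray  # cells × components
    loadings: np.ndarray  # genes × components
    stability: np.ndarray  # per component, non-increasing
    genes: tuple[str, ...]
    cells: tuple[str, ...]
    selected: int = 0
    cluster_sizes: tuple[int, ...] = ()
    n_runs: int = 0
    n_converged: int = 0

    def ic1_projection(self) -> np.ndarray:
        return self.projections[:, self.selected]

    def ic1_loading(self) -> np.ndarray:
        return self.loadings[:, self.selected]


@dataclass(frozen=True)
class CellGroups:
    """Cell partition into group1 / group2 / unassigned."""

    cells: tuple[str, ...]
    labels: np.ndarray  # array of "group1" | "group2" | "unassigned"

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(c for c, l in zip(self.cells, self.labels) if l == label)

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def swapped(self) -> "CellGroups":
        """Exchange the two group labels (unassigned cells unchanged)."""
        swap = {"group1": "group2", "group2": "group1"}
        return CellGroups(
            self.cells, np.array([swap.get(l, l) for l in self.labels], dtype=object)
        )


class ConvergenceError(RuntimeError):
    """No ICA restart converged within the iteration budget."""


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W ← (W Wᵀ)^(−1/2) W, making the rows an orthonormal system."""
    vals, vecs = linalg.eigh(w @ w.T)
    vals = np.clip(vals, 1e-12, None)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T @ w


def _fastica_once(
    z: np.ndarray, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, bool]:
    """One fixed-point run on whitened data z (observations × k).

    Returns the unmixing matrix (k × k, orthonormal rows) and whether the
    iteration converged (maximal change of any row direction below tol).
    """
    n, k = z.shape
    w = _sym_decorrelate(rng.normal(size=(k, k)))
    converged = False
    for _ in range(max_iter):
        wz = z @ w.T  # n × k source estimates
        g = np.tanh(wz)
        g_prime_mean = (1.0 - g**2).mean(axis=0)  # per component
        w_new = (g.T @ z) / n - g_prime_mean[:, None] * w
        w_new = _sym_decorrelate(w_new)
        # rows are unit norm: |cos| of the angle between old and new row
        lim = np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
        w = w_new
        if lim < tol:
            converged = True
            break
    return w, converged


def _greedy_cluster(corr: np.ndarray, threshold: float) -> list[list[int]]:
    """Greedy single-seed clustering on an absolute-correlation matrix.

    Repeatedly seeds a cluster at the unassigned component with the most
    unassigned neighbours at |r| ≥ threshold and absorbs those neighbours.
    """
    m = corr.shape[0]
    unassigned = set(range(m))
    clusters: list[list[int]] = []
    while unassigned:
        members = sorted(unassigned)
        sub = corr[np.ix_(members, members)] >= threshold
        counts = sub.sum(axis=1)  # includes self
        seed_local = int(np.argmax(counts))
        cluster = [members[i] for i in np.nonzero(sub[seed_local])[0]]
        clusters.append(sorted(cluster))
        unassigned -= set(cluster)
    return clusters


def run_ica(
    matrix: ExpressionMatrix,
    n_components: int | None = None,
    n_runs: int = 20,
    seed: int = 1,
    tol: float = 1e-4,
    max_iter: int = 200,
    corr_threshold: float = 0.85,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
    run_seeds: Sequence[int] | None = None,
    bootstrap: bool = True,
) -> ComponentResult:
    """Estimate independent components with stability-based selection.

    Per restart: whiten the cell-observation view of the matrix to
    ``n_components`` dimensions by truncated SVD, then fixed-point iterate
    the log-cosh contrast with symmetric decorrelation from a seeded random
    orthogonal start; with ``bootstrap`` (the default) each restart
    additionally fits on a resampled-with-replacement set of cells,
    re-whitened, so that a component must be a feature of the population and
    not of one fixed noise realization to recur across restarts. Across
    restarts, pooled components are clustered at
    ``corr_threshold`` on the absolute Pearson correlation of their cell
    projections; a cluster's stability is its mean within-cluster |r| minus
    its mean |r| to everything outside, scaled by its occupancy (cluster size
    over the number of pooled restarts, capped at 1). Each cluster
    contributes its member closest to the cluster centroid, and clusters are
    sorted by stability (ties broken by cluster size). ``run_seeds`` overrides the per-run seeds (mostly for testing).

    Raises :class:`ConvergenceError` when no restart yields usable
    components; logs a warning when the top stability falls below
    ``stability_threshold`` (no sufficiently stable component in the data).
    """
    if not matrix.centered:
        raise ValueError("run_ica requires a mean-centred matrix (see preprocess)")
    n_genes, n_cells = matrix.values.shape
    if n_components is None:
        n_components = min(10, n_cells - 1, n_genes)
    if not 1 <= n_components <= min(n_genes, n_cells):
        raise ValueError(f"n_components must be in [1, {min(n_genes, n_cells)}]")
    if n_runs < 2:
        raise ValueError("n_runs must be ≥ 2 for a stability estimate")

    # cells are the observations; the gene variables are zero-mean because
    # the matrix is gene-centred
    data = matrix.values.T  # cells × genes
    u, _, _ = np.linalg.svd(data, full_matrices=False)
    z = u[:, :n_components] * np.sqrt(n_cells)  # whitened: zᵀz / n_cells = I

    if run_seeds is None:
        run_seeds = np.random.SeedSequence(seed).generate_state(n_runs).tolist()
    elif len(run_seeds) != n_runs:
        raise ValueError("run_seeds must have length n_runs")

    # Pool components from every restart that terminates with finite results,
    # whether it met tol or stopped at max_iter: a noisy subspace may never
    # settle below tol, and discounting its wandering components is precisely
    # the job of the stability clustering below. n_converged reports how many
    # restarts met the tol criterion.
    pooled_loadings: list[np.ndarray] = []
    pooled_projections: list[np.ndarray] = []
    n_converged = 0
    n_usable = 0
    for run_seed in run_seeds:
        rng = np.random.default_rng(run_seed)
        if bootstrap:
            idx = rng.integers(0, n_cells, size=n_cells)
            z_fit = z[idx] - z[idx].mean(axis=0, keepdims=True)
            # re-whiten the bootstrap sample (its covariance is only
            # approximately the identity)
            vals, vecs = linalg.eigh(z_fit.T @ z_fit / n_cells)
            whitener = (vecs / np.sqrt(np.clip(vals, 1e-12, None))) @ vecs.T
            z_fit = z_fit @ whitener
        else:
            z_fit = z
            whitener = np.eye(n_components)
        w, converged = _fastica_once(z_fit, rng, tol, max_iter)
        w = w @ whitener  # back to the common whitened basis of z
        if not np.isfinite(w).all():
            continue
        n_usable += 1
        n_converged += converged
        sources = z @ w.T  # cells × k: the per-cell projections
        mixing, *_ = np.linalg.lstsq(sources, data, rcond=None)  # k × genes
        for c in range(n_components):
            pooled_projections.append(sources[:, c])
            pooled_loadings.append(mixing[c])
    if n_usable == 0:
        raise ConvergenceError(
            f"none of {n_runs} ICA restarts produced finite components "
            f"within {max_iter} iterations"
        )
    if n_converged == 0:
        logger.warning(
            "no ICA restart met tol=%.1e within %d iterations; "
            "pooling max_iter-terminated runs",
            tol,
            max_iter,
        )

    proj = np.asarray(pooled_projections)  # m × cells
    corr = np.abs(np.corrcoef(proj))
    np.nan_to_num(corr, copy=False)
    clusters = _greedy_cluster(corr, corr_threshold)

    reps, stabilities, sizes = [], [], []
    all_idx = np.arange(corr.shape[0])
    for cluster in clusters:
        members = np.asarray(cluster)
        sub = corr[np.ix_(members, members)]
        if len(members) > 1:
            intra = (sub.sum() - len(members)) / (len(members) * (len(members) - 1))
        else:
            # a component recovered in a single run has no within-cluster
            # agreement to show: zero reproducibility evidence
            intra = 0.0
        outside = np.setdiff1d(all_idx, members)
        out = corr[np.ix_(members, outside)].mean() if outside.size else 0.0
        # occupancy: a stable component recurs once per restart, so a cluster
        # drawn from only a few restarts cannot score high however tight it is
        occupancy = min(1.0, len(members) / n_usable)
        stabilities.append(max(0.0, (intra - out) * occupancy))
        sizes.append(len(members))
        # representative: member most correlated with the rest of its cluster
        rep_local = int(np.argmax(sub.mean(axis=1)))
        reps.append(members[rep_local])

    order = sorted(
        range(len(clusters)), key=lambda i: (stabilities[i], sizes[i]), reverse=True
    )
    reps = [reps[i] for i in order]
    stability = np.array([stabilities[i] for i in order])
    sizes = tuple(sizes[i] for i in order)

    projections = np.column_stack([pooled_projections[r] for r in reps])
    loadings = np.column_stack([pooled_loadings[r] for r in reps])

    if stability[0] < stability_threshold:
        logger.warning(
            "top component stability %.3f below the %.2f threshold: "
            "no sufficiently stable independent component",
            stability[0],
            stability_threshold,
        )

    return ComponentResult(
        projections=projections,
        loadings=loadings,
        stability=stability,
        genes=matrix.genes,
        cells=matrix.cells,
        selected=0,
        cluster_sizes=sizes,
        n_runs=n_runs,
        n_converged=n_converged,
    )


def orient_component(
    result: ComponentResult,
    hierarchy: MapHierarchy,
    zone: str = ANTI_TUMOR_ZONE,
) -> ComponentResult:
    """Fix IC1's sign so the mean loading over the anti-tumor zone is ≥ 0.

    Idempotent; a mean of exactly zero leaves the component unchanged.
    Raises when no gene of the zone is present among the component genes.
    """
    zone_genes = hierarchy.genes("zone", zone)
    idx = [i for i, g in enumerate(result.genes) if g in zone_genes]
    if not idx:
        raise ValueError(f"no gene of zone {zone!r} present in the component result")
    mean_loading = result.loadings[idx, result.selected].mean()
    if mean_loading >= 0:
        return result
    projections = result.projections.copy()
    loadings = result.loadings.copy()
    projections[:, result.selected] *= -1.0
    loadings[:, result.selected] *= -1.0
    return replace(result, projections=projections, loadings=loadings)


def split_by_sign(result: ComponentResult) -> CellGroups:
    """Group 1 = cells with positive IC1 projection, group 2 = negative.

    A projection of exactly zero is left unassigned. Raises when either group
    would be empty.
    """
    proj = result.ic1_projection()
    labels = np.where(proj > 0, "group1", np.where(proj < 0, "group2", "unassigned"))
    labels = labels.astype(object)
    for group in ("group1", "group2"):
        if not (labels == group).any():
            raise ValueError(f"sign split leaves {group} empty")
    return CellGroups(result.cells, labels)


def split_by_quartiles(result: ComponentResult, max_group_fraction: float = 0.4) -> CellGroups:
    """Keep only the extreme cells: group 2 ≤ Q1, group 1 ≥ Q3 of IC1.

    Quartiles use the linear-interpolation convention; after orientation,
    group 1 is the anti-tumor side. Middle cells are unassigned. Raises when
    ties at a quartile boundary push a group above ``max_group_fraction`` of
    the cells (degenerate, e.g. all-equal projections).
    """
    proj = result.ic1_projection()
    n = proj.size
    if n < 8:
        raise ValueError("quartile split needs at least 8 cells")
    q1, q3 = np.quantile(proj, [0.25, 0.75])
    labels = np.full(n, "unassigned", dtype=object)
    labels[proj >= q3] = "group1"
    labels[proj <= q1] = "group2"
    for group in ("group1", "group2"):
        if (labels == group).sum() > max_group_fraction * n:
            raise ValueError(
                f"quartile boundary ties make {group} exceed "
                f"{max_group_fraction:.0%} of cells"
            )
    return CellGroups(result.cells, labels)


def pca_coordinates(matrix: ExpressionMatrix, k: int = 2) -> np.ndarray:
    """Cells × k principal-component coordinates of the centred matrix.

    Cells are the samples (gene-centred rows make the gene variables
    zero-mean). Components are ordered by singular value; each is signed so
    its largest-magnitude gene loading is positive.
    """
    if not matrix.centered:
        raise ValueError("pca_coordinates requires a mean-centred matrix")
    if k > min(matrix.n_genes, matrix.n_cells):
        raise ValueError(f"k={k} exceeds min(genes, cells)={min(matrix.values.shape)}")
    x = matrix.values.T  # cells × genes, columns zero-mean
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] *= -1.0
    return coords
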