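"""Within-position 3D placement of mapped cells.

Three placement modes of increasing structure:

* ``uniform_fill`` — i.i.d. uniform points over the position's interior
  region (the default rendering of cells mapped to a position);
* ``gradient_sort`` — keep the point set but reassign cells to points so
  that a supplied per-cell gradient value (a graded gene's expression or
  a signalling readout) is monotone along a chosen axis;
* ``optimal_spatial_distribution`` — a constrained least-squares
  embedding: pairwise transcriptomic Euclidean distances are rescaled so
  the largest equals the region's maximum interior chord, then cell
  coordinates are optimized to reproduce them (stress minimization)
  subject to staying inside the region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance
from sklearn.decomposition import PCA

from .geometry import PositionRegion

__all__ = [
    "PlacementSet",
    "DistanceMatrices",
    "OSDParams",
    "uniform_fill",
    "gradient_sort",
    "select_input_genes",
    "stress",
    "optimal_spatial_distribution",
]


@dataclass
class PlacementSet:
    """Cell coordinates inside one position's region."""

    cell_ids: list[str]
    coordinates: np.ndarray  # (n, 3)
    region: PositionRegion
    provenance: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(self.cell_ids) != len(self.coordinates):
            raise ValueError("one coordinate per cell required")
        for p in self.coordinates:
            if not self.region.contains(p, tol=1e-9):
                raise ValueError(f"coordinate {tuple(p)} outside the placement region")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, columns=["x", "y", "z"], index=pd.Index(self.cell_ids, name="cell")
        )


@dataclass
class DistanceMatrices:
    """Transcriptomic distances and their region-scaled counterpart."""

    d_edm: np.ndarray
    d_norm: np.ndarray
    max_length: float

    def __post_init__(self) -> None:
        for name, m in (("d_edm", self.d_edm), ("d_norm", self.d_norm)):
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 0.0, atol=1e-9):
                raise ValueError(f"{name} must have a zero diagonal")
        if self.d_edm.max() > 0 and abs(self.d_norm.max() - self.max_length) > 1e-9:
            raise ValueError("max of d_norm must equal max_length")


@dataclass(frozen=True)
class OSDParams:
    """Optimizer settings for the constrained embedding."""

    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-8
    n_input_genes: int = 100


def uniform_fill(region: PositionRegion, n: int, seed: int = 0) -> PlacementSet:
    """n points i.i.d. uniform over the region volume (seeded)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pts = region.sample(n, rng) if n else np.empty((0, 3))
    return PlacementSet(
        cell_ids=[f"cell_{i}" for i in range(n)],
        coordinates=pts,
        region=region,
        provenance="uniform_fill",
    )


def _axis_key(coords: np.ndarray, axis: str, region: PositionRegion) -> np.ndarray:
    if axis == "x":
        return coords[:, 0]
    if axis == "y":
        return coords[:, 1]
    if axis == "z":
        return coords[:, 2]
    if axis == "radial":
        return np.hypot(coords[:, 0], coords[:, 1])
    if axis == "angular":
        theta = np.arctan2(coords[:, 1], coords[:, 0]) - region.theta_center
        return np.mod(theta + math.pi, 2.0 * math.pi) - math.pi
    raise ValueError(f"unknown axis {axis!r} (expected x, y, z, radial or angular)")


def gradient_sort(
    placements: PlacementSet,
    gradient_values: Sequence[float],
    axis: str = "z",
    increasing: bool = True,
) -> PlacementSet:
    """Reassign cells to the existing coordinates so the gradient values
    are monotone along ``axis`` (a quicksort-style reordering: the point
    multiset is untouched, only the cell-to-point assignment changes).

    ``increasing=True`` puts the largest value at the largest axis
    coordinate.  Stable for ties: cells with equal values keep their
    relative axis order, so a constant gradient is the identity.
    """
    values = np.asarray(gradient_values, dtype=float)
    if len(values) != len(placements.cell_ids):
        raise ValueError("one gradient value per cell required")
    key = _axis_key(placements.coordinates, axis, placements.region)
    slot_order = np.argsort(key, kind="stable")  # slots by ascending axis coordinate
    vals_in_slot_order = values[slot_order]
    sign = 1.0 if increasing else -1.0
    cell_order = slot_order[np.argsort(sign * vals_in_slot_order, kind="stable")]
    new_coords = np.empty_like(placements.coordinates)
    new_coords[cell_order] = placements.coordinates[slot_order]
    return PlacementSet(
        cell_ids=list(placements.cell_ids),
        coordinates=new_coords,
        region=placements.region,
        provenance=f"gradient_sort({axis})",
    )


def select_input_genes(matrix: pd.DataFrame, n_genes: int = 100, n_pcs: int = 5) -> list[str]:
    """Top PC-loading genes of the cells' own PCA (genes x cells input).

    Genes are scored by the explained-variance-weighted absolute loading
    over the first ``n_pcs`` components; ties break by gene label.
    """
    X = matrix.to_numpy(dtype=float).T  # cells x genes
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if n_comp < 1 or np.allclose(X.var(axis=0), 0.0):
        return sorted(str(g) for g in matrix.index)[:n_genes]
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X)
    score = (pca.explained_variance_ratio_[:, None] * np.abs(pca.components_)).sum(axis=0)
    genes = matrix.index.to_list()
    order = sorted(range(len(genes)), key=lambda i: (-score[i], str(genes[i])))
    return [str(genes[i]) for i in order[:n_genes]]


def stress(coords: np.ndarray, target: np.ndarray) -> float:
    """Raw stress sum_i sum_j (||x_i - x_j|| - d_ij)^2 over ordered pairs."""
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(coords))
    return float(((d - target) ** 2).sum())


def _stress_gradient(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(d, 1.0)
    # coincident points contribute no usable direction; floor the distance
    d = np.maximum(d, 1e-12)
    factor = 4.0 * (d - target) / d
    np.fill_diagonal(factor, 0.0)
    return (factor[:, :, None] * diff).sum(axis=1)


def _classical_mds(target: np.ndarray, dim: int = 3) -> np.ndarray:
    """Torgerson scaling of a distance matrix (embedding initializer)."""
    n = target.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (target**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[idx], 0.0, None)
    coords = v[:, idx] * np.sqrt(lam)
    if coords.shape[1] < dim:
        coords = np.pad(coords, ((0, 0), (0, dim - coords.shape[1])))
    return coords


def _project_all(coords: np.ndarray, region: PositionRegion) -> np.ndarray:
    return np.array([region.clamp(p) for p in coords])


def _projected_descent(
    coords: np.ndarray,
    target: np.ndarray,
    region: PositionRegion,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float]:
    x = _project_all(coords, region)
    f = stress(x, target)
    step = 0.05 * region.max_chord() / max(target.max(), 1e-12)
    for _ in range(max_iter):
        g = _stress_gradient(x, target)
        g_norm = np.linalg.norm(g)
        if g_norm < tol:
            break
        improved = False
        for _ in range(25):
            x_new = _project_all(x - step * (g / g_norm), region)
            f_new = stress(x_new, target)
            if f_new < f - 1e-15:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if (f - f_new) < tol * max(f, 1.0):
            x, f = x_new, f_new
            break
        x, f = x_new, f_new
        step *= 1.3
    return x, f


def optimal_spatial_distribution(
    cells_submatrix: pd.DataFrame,
    region: PositionRegion,
    params: OSDParams = OSDParams(),
    seed: int = 0,
    input_genes: Sequence[str] | None = None,
) -> tuple[PlacementSet, DistanceMatrices, float]:
    """Constrained least-squares embedding of the cells mapped to one
    position (genes x cells input, log-space values).

    Pipeline: (1) Euclidean distance matrix over the input gene set (top
    PC-loading genes by default); (2) rescale so the largest distance
    equals the region's maximum interior chord; (3) minimize the raw
    stress between spatial and rescaled distances over coordinates
    constrained to the region, by projected gradient descent from a
    classical-MDS start plus seeded random restarts; best stress kept.

    Returns ``(placement, matrices, final_stress)``.
    """
    if cells_submatrix.shape[1] < 2:
        raise ValueError("need at least 2 cells to embed")
    if input_genes is None:
        input_genes = select_input_genes(cells_submatrix, params.n_input_genes)
    sub = cells_submatrix.loc[list(input_genes)]
    X = sub.to_numpy(dtype=float).T  # cells x genes
    d_edm = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(X))
    max_length = region.max_chord()
    d_max = d_edm.max()
    cell_ids = [str(c) for c in cells_submatrix.columns]
    if d_max == 0.0:
        # transcriptomically identical cells: co-locate, jitter for rendering
        rng = np.random.default_rng(seed)
        base = np.array(region.centroid())
        coords = base + 1e-6 * max_length * rng.standard_normal((len(cell_ids), 3))
        coords = _project_all(coords, region)
        matrices = DistanceMatrices(d_edm=d_edm, d_norm=d_edm.copy(), max_length=max_length)
        placement = PlacementSet(cell_ids, coords, region, "optimal_spatial_distribution")
        return placement, matrices, stress(coords, d_edm)
    d_norm = d_edm * (max_length / d_max)
    matrices = DistanceMatrices(d_edm=d_edm, d_norm=d_norm, max_length=max_length)
    rng = np.random.default_rng(seed)
    centroid = np.array(region.centroid())
    inits: list[np.ndarray] = []
    mds = _classical_mds(d_norm)
    inits.append(mds - mds.mean(axis=0) + centroid)
    # chord-aligned start: spread cells along the longest interior segment
    # in their leading-MDS-coordinate order (helps elongated configurations
    # reach the full normalized scale)
    p, q = region.max_chord_endpoints()
    lead = mds[:, 0]
    span = lead.max() - lead.min()
    frac = (lead - lead.min()) / span if span > 0 else np.linspace(0, 1, len(lead))
    inits.append(p[None, :] + frac[:, None] * (q - p)[None, :])
    for _ in range(max(0, params.n_restarts - 2)):
        inits.append(region.sample(len(cell_ids), rng))
    best: tuple[np.ndarray, float] | None = None
    for init in inits:
        x, f = _projected_descent(init, d_norm, region, params.max_iter, params.tol)
        if best is None or f < best[1]:
            best = (x, f)
    coords, final_stress = best
    placement = PlacementSet(cell_ids, coords, region, "optimal_spatial_distribution")
    return placement, matrices, final_stress
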