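"""Spatial reference atlas and derivation of position-specific marker
genes ("zipcodes").

Two routes are provided, matching how sparse early-stage references and
richer later-stage references behave in practice:

* the clustering route — k-means over positions with the cluster number
  chosen by a Bayesian information criterion (spherical-Gaussian model),
  then one-vs-rest differential expression per spatial domain;
* the PCA-loading route — restrict to the most variable genes, run PCA,
  and take the extreme positive and negative loading genes of the leading
  components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .geometry import PositionalAddress

__all__ = [
    "ReferenceAtlas",
    "DomainModelFit",
    "detect_spatial_domains",
    "kmeans_bic",
    "domain_zipcodes",
    "differential_genes",
    "pca_zipcodes",
]


@dataclass
class ReferenceAtlas:
    """A spatially registered reference: positions x genes log-expression
    joined to positional addresses.

    ``expression`` rows align with ``addresses``; values are log-space
    (log2(x+1) by convention).  ``zipcodes`` holds the marker set used
    for single-cell mapping; ``spatial_domains`` an optional per-position
    domain label.
    """

    expression: pd.DataFrame
    addresses: list[PositionalAddress]
    zipcodes: list[str] = field(default_factory=list)
    spatial_domains: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.expression) != len(self.addresses):
            raise ValueError(
                f"{len(self.expression)} expression rows vs {len(self.addresses)} addresses"
            )
        values = self.expression.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("reference expression contains non-finite values")
        unknown = set(self.zipcodes) - set(self.expression.columns)
        if unknown:
            raise ValueError(f"zipcodes not in gene labels: {sorted(unknown)[:10]}")

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    @property
    def position_names(self) -> list[str]:
        return [a.name for a in self.addresses]

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinate for a in self.addresses])

    @property
    def layers(self) -> np.ndarray:
        return np.array([a.layer for a in self.addresses])

    def address_by_name(self, name: str) -> PositionalAddress:
        for a in self.addresses:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass
class DomainModelFit:
    """Result of BIC-guided k-means over reference positions."""

    k: int
    labels: np.ndarray
    bic: dict[int, float]
    inertia: dict[int, float]
    labels_by_k: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if self.k != min(self.bic, key=self.bic.get):
            raise ValueError("chosen k does not minimize the BIC curve")


def kmeans_bic(X: np.ndarray, labels: np.ndarray, inertia: float) -> float:
    """BIC of a fitted k-means partition under spherical Gaussians with a
    shared variance: -2 log L + p log n with p = k*d + 1 free parameters
    (k centroids of dimension d plus the common variance)."""
    n, d = X.shape
    k = len(np.unique(labels))
    sigma2 = max(inertia / (n * d), 1e-300)
    log_l = -0.5 * n * d * (np.log(2.0 * np.pi * sigma2) + 1.0)
    n_params = k * d + 1
    return -2.0 * log_l + n_params * np.log(n)


def detect_spatial_domains(
    atlas: ReferenceAtlas,
    k_candidates: Sequence[int],
    seed: int = 0,
    n_restarts: int = 25,
) -> DomainModelFit:
    """Partition reference positions into spatial domains by k-means,
    selecting k by minimum BIC over ``k_candidates``.

    Each candidate k is fit with ``n_restarts`` seeded restarts and the
    best-inertia solution kept; the BIC uses a spherical-Gaussian cluster
    model with shared variance.
    """
    X = atlas.expression.to_numpy()
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 positions to detect domains")
    if np.allclose(X, X[0]):
        raise ValueError("expression matrix is constant across positions; no domain structure")
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("no candidate cluster numbers given")
    if k_candidates[0] < 2 or k_candidates[-1] > n - 1:
        raise ValueError(f"k candidates must lie in [2, {n - 1}]")
    bic: dict[int, float] = {}
    inertia: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        bic[k] = kmeans_bic(X, labels, km.inertia_)
        inertia[k] = float(km.inertia_)
        labels_by_k[k] = labels
    best_k = min(bic, key=bic.get)
    return DomainModelFit(
        k=best_k,
        labels=labels_by_k[best_k],
        bic=bic,
        inertia=inertia,
        labels_by_k=labels_by_k,
    )


def differential_genes(
    expression: pd.DataFrame,
    group_mask: np.ndarray,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    top_n: int | None = 50,
    bh_correct: bool = False,
) -> list[str]:
    """Genes up in ``group_mask`` rows vs the rest, by Welch t-test on
    log-space values (p < ``p_threshold``) and linear-scale fold change
    (2**mean-log-difference > ``fc_threshold``), ranked by p value; ties
    broken by larger fold change, then gene label."""
    in_group = expression.to_numpy()[group_mask]
    out_group = expression.to_numpy()[~group_mask]
    if len(in_group) < 2 or len(out_group) < 2:
        warnings.warn("group with fewer than 2 members; differential test skipped")
        return []
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, pvals = scipy.stats.ttest_ind(in_group, out_group, equal_var=False, axis=0)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    if bh_correct:
        pvals = scipy.stats.false_discovery_control(pvals, method="bh")
    log_fc = in_group.mean(axis=0) - out_group.mean(axis=0)
    fold_change = np.power(2.0, log_fc)
    keep = (pvals < p_threshold) & (fold_change > fc_threshold)
    genes = expression.columns.to_numpy()
    order = sorted(
        np.flatnonzero(keep), key=lambda i: (pvals[i], -fold_change[i], str(genes[i]))
    )
    if top_n is not None:
        order = order[:top_n]
    return [str(genes[i]) for i in order]


def domain_zipcodes(
    atlas: ReferenceAtlas,
    domains: np.ndarray | None = None,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    top_n: int = 50,
    bh_correct: bool = False,
) -> list[str]:
    """Zipcodes by the clustering route: per spatial domain, the top
    ``top_n`` one-vs-rest differential genes (defaults p < 0.05, fold
    change > 1.5, top 50); the union over domains is returned, sorted for
    determinism.
    """
    if domains is None:
        domains = atlas.spatial_domains
    if domains is None:
        raise ValueError("no domain labels: run detect_spatial_domains first")
    domains = np.asarray(domains)
    uniq = np.unique(domains)
    if len(uniq) < 2:
        raise ValueError("need at least 2 domains for differential expression")
    selected: set[str] = set()
    for dom in uniq:
        mask = domains == dom
        if mask.sum() < 2:
            warnings.warn(f"domain {dom!r} has a single member; skipped")
            continue
        selected.update(
            differential_genes(
                atlas.expression, mask, p_threshold, fc_threshold, top_n, bh_correct
            )
        )
    return sorted(selected)


def pca_zipcodes(
    atlas: ReferenceAtlas,
    n_variable: int = 6000,
    pcs: Sequence[int] = (1, 2, 3, 4, 5),
    top_loadings: int = 50,
) -> list[str]:
    """Zipcodes by the loading route: restrict to the ``n_variable`` most
    variable genes, run PCA over positions, and per selected component
    (1-based indices) take the ``top_loadings`` highest- and lowest-loading
    genes; the union is returned sorted.

    Ties in variance or loading rank are broken by gene label.
    """
    expr = atlas.expression
    if n_variable > expr.shape[1]:
        n_variable = expr.shape[1]
    variances = expr.var(axis=0, ddof=1)
    order = sorted(expr.columns, key=lambda g: (-variances[g], str(g)))
    var_genes = order[:n_variable]
    sub = expr[var_genes]
    n_comp = min(len(sub) - 1, len(var_genes))
    if not pcs:
        raise ValueError("no principal components selected")
    if max(pcs) > n_comp:
        raise ValueError(f"component {max(pcs)} exceeds the {n_comp} available")
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(sub.to_numpy())
    selected: set[str] = set()
    for pc in pcs:
        loadings = pca.components_[pc - 1]
        ranked_hi = sorted(range(len(var_genes)), key=lambda i: (-loadings[i], str(var_genes[i])))
        ranked_lo = sorted(range(len(var_genes)), key=lambda i: (loadings[i], str(var_genes[i])))
        selected.update(var_genes[i] for i in ranked_hi[:top_loadings])
        selected.update(var_genes[i] for i in ranked_lo[:top_loadings])
    return sorted(selected)
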