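"""Multi-dimension single-cell (MDSC) mapping.

Each dissociated cell is matched against every position of a spatially
registered reference by Spearman rank correlation (SRCC) over the
position-specific marker genes ("zipcodes"), then assigned a position by
a spatial-smoothing step: unless the top correlation clearly dominates
(relative gap > 0.1), the top-ranked positions are merged into a
consensus point — the SRCC-weighted geometric median of their
coordinates — and the cell is assigned to the reference position nearest
that point.

The version-2 rules refine this: (1) the germ layer is fixed by the
global best-correlated position and the remaining top positions are
drawn from that layer; (2) when the top-3 positions are dispersed over
different parts of the structure, the top-5 are used instead; (3) when
the smoothed assignment lands more than 3 sections from the
best-correlated position, the latter wins; (4) SRCC values weight the
consensus point throughout.  Version 1 (rules 1-3 disabled) is retained
for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .geometry import PositionalAddress
from .zipcodes import ReferenceAtlas

__all__ = [
    "MappingParams",
    "MappingResult",
    "srcc_profile",
    "weighted_geometric_median",
    "smooth_position",
    "map_cell_v2",
    "map_cells",
]


@dataclass(frozen=True)
class MappingParams:
    """Tunable parameters of the mapping pipeline.

    Defaults are the published operating point: gate 0.1 on the relative
    SRCC gap, 3-section override distance, top-3 smoothing with top-5
    dispersion fallback.
    ``version=1`` disables the layer rule, the dispersion fallback and the
    section override (smoothing and SRCC weighting only).
    """

    gate_threshold: float = 0.1
    top_k: int = 3
    fallback_top_k: int = 5
    section_override: float = 3.0
    dispersion_section_gap: float = 3.0
    dispersion_angle: float = math.pi / 2.0
    version: int = 2

    def __post_init__(self) -> None:
        if self.version not in (1, 2):
            raise ValueError("version must be 1 or 2")


@dataclass
class MappingResult:
    """Outcome of mapping one cell."""

    cell_id: str
    srcc: pd.Series
    top_positions: list[tuple[PositionalAddress, float]]
    smoothed_point: tuple[float, float, float] | None
    assigned: PositionalAddress | None
    delta_srcc: float | None
    rule_trace: list[str] = field(default_factory=list)
    error: str | None = None


def srcc_profile(
    cell_expression: pd.Series,
    atlas: ReferenceAtlas,
    zipcodes: Sequence[str] | None = None,
) -> pd.Series:
    """Spearman correlation of one cell against every reference position
    over the zipcode gene intersection.

    Ranks use average tie handling.  Positions whose zipcode vector is
    constant (correlation undefined) are returned as NaN; a constant cell
    vector makes the whole profile NaN.
    """
    genes = list(zipcodes) if zipcodes is not None else list(atlas.zipcodes)
    shared = [g for g in genes if g in cell_expression.index and g in atlas.genes]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} zipcode genes shared between cell and atlas (need >= 3)"
        )
    cell = cell_expression[shared].to_numpy(dtype=float)
    ref = atlas.expression[shared].to_numpy(dtype=float)
    cell_rank = scipy.stats.rankdata(cell)
    ref_rank = scipy.stats.rankdata(ref, axis=1)
    cr = cell_rank - cell_rank.mean()
    rr = ref_rank - ref_rank.mean(axis=1, keepdims=True)
    cell_norm = np.linalg.norm(cr)
    ref_norm = np.linalg.norm(rr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rr @ cr) / (ref_norm * cell_norm)
    rho[ref_norm == 0] = np.nan
    if cell_norm == 0:
        rho[:] = np.nan
    return pd.Series(rho, index=atlas.position_names, name=str(cell_expression.name))


def weighted_geometric_median(
    anchors: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> np.ndarray:
    """Minimizer of f(x) = sum_i w_i * ||x - a_i|| by Weiszfeld iteration
    with the Vardi-Zhang rule at anchor coincidences.

    Initialized at the weighted centroid; weights must be positive.
    """
    anchors = np.asarray(anchors, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if len(anchors) == 1:
        return anchors[0].copy()
    x = np.average(anchors, axis=0, weights=weights)
    for _ in range(max_iter):
        d = np.linalg.norm(anchors - x, axis=1)
        at_anchor = d < tol
        if at_anchor.any():
            i = int(np.argmax(at_anchor))
            others = ~at_anchor
            if not others.any():
                return anchors[i].copy()
            r_vec = np.sum(
                (weights[others, None] * (anchors[others] - x)) / d[others, None], axis=0
            )
            r_norm = np.linalg.norm(r_vec)
            if r_norm <= weights[i] + tol:
                return x  # the anchor itself is the median
            denom = np.sum(weights[others] / d[others])
            x_new = x + (1.0 - weights[i] / r_norm) * (r_vec / denom)
        else:
            inv = weights / d
            x_new = (inv @ anchors) / inv.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def _sort_key(entry: tuple[PositionalAddress, float]):
    addr, s = entry
    return (-s, addr.section, addr.sector)


def smooth_position(
    top_positions: Sequence[tuple[PositionalAddress, float]],
    gate_threshold: float = 0.1,
    candidates: Sequence[tuple[PositionalAddress, float]] | None = None,
) -> tuple[tuple[float, float, float], PositionalAddress, float | None, list[str]]:
    """Spatial smoothing over ranked (address, SRCC) pairs.

    If the relative gap (SRCC_top1 - SRCC_top2) / SRCC_top1 exceeds
    ``gate_threshold``, the top-1 address is returned unsmoothed
    (high-confidence gate).  Otherwise the consensus point P0 is the
    SRCC-weighted geometric median of the top coordinates and the
    assigned address is the candidate nearest P0 (ties broken by higher
    SRCC, then lower section).  A zero or negative top SRCC leaves the
    gap undefined and smoothing is applied; if no anchor has positive
    SRCC the top-1 is returned with a warning.

    Returns ``(P0, assigned, delta_srcc, trace)``.
    """
    if not top_positions:
        raise ValueError("no ranked positions to smooth")
    ranked = sorted(top_positions, key=_sort_key)
    if candidates is None:
        candidates = ranked
    top1_addr, top1_srcc = ranked[0]
    delta: float | None = None
    if top1_srcc > 0 and len(ranked) > 1:
        delta = (top1_srcc - ranked[1][1]) / top1_srcc
    elif top1_srcc > 0:
        delta = 1.0
    if delta is not None and delta > gate_threshold:
        return top1_addr.coordinate, top1_addr, delta, ["high_confidence"]
    positive = [(a, s) for a, s in ranked if s > 0]
    if not positive:
        warnings.warn("no positive SRCC among top positions; falling back to top-1")
        return top1_addr.coordinate, top1_addr, delta, ["nonpositive_fallback"]
    anchors = np.array([a.coordinate for a, _ in positive])
    weights = np.array([s for _, s in positive])
    p0 = weighted_geometric_median(anchors, weights)
    dists = np.linalg.norm(np.array([a.coordinate for a, _ in candidates]) - p0, axis=1)
    best = sorted(
        range(len(candidates)),
        key=lambda i: (round(dists[i], 12), -candidates[i][1], candidates[i][0].section),
    )[0]
    assigned = candidates[best][0]
    return tuple(p0), assigned, delta, ["smoothed"]


def _dispersed(
    top: Sequence[tuple[PositionalAddress, float]],
    section_gap: float,
    angle_threshold: float,
) -> bool:
    """Top positions span different parts of the structure: at least two
    of the pairwise section gaps exceed ``section_gap``, or the positions
    occupy >= 3 distinct sectors with some pair separated by more than
    ``angle_threshold`` around the axis."""
    addrs = [a for a, _ in top]
    if len(addrs) < 3:
        return False
    gaps = [
        abs(a.section - b.section)
        for i, a in enumerate(addrs)
        for b in addrs[i + 1 :]
    ]
    if sum(g > section_gap for g in gaps) >= 2:
        return True
    if len({a.sector for a in addrs}) >= 3:
        angles = []
        for a in addrs:
            x, y, _ = a.coordinate
            if math.hypot(x, y) > 1e-12:
                angles.append(math.atan2(y, x))
        for i, t1 in enumerate(angles):
            for t2 in angles[i + 1 :]:
                d = abs(t1 - t2) % (2.0 * math.pi)
                if min(d, 2.0 * math.pi - d) > angle_threshold:
                    return True
    return False


def map_cell_v2(
    cell_expression: pd.Series,
    atlas: ReferenceAtlas,
    params: MappingParams = MappingParams(),
    zipcodes: Sequence[str] | None = None,
) -> MappingResult:
    """Map one cell to its best-inferred positional address.

    Runs the SRCC profile, applies the germ-layer rule, the
    high-confidence gate, dispersion-triggered top-5 fallback, weighted
    smoothing, and the 3-section override (see module docstring); with
    ``params.version == 1`` only gate + smoothing run, over all layers.
    """
    profile = srcc_profile(cell_expression, atlas, zipcodes)
    valid = [
        (atlas.addresses[i], float(profile.iloc[i]))
        for i in range(len(profile))
        if np.isfinite(profile.iloc[i])
    ]
    if not valid:
        return MappingResult(
            cell_id=str(cell_expression.name),
            srcc=profile,
            top_positions=[],
            smoothed_point=None,
            assigned=None,
            delta_srcc=None,
            error="no position with a defined SRCC",
        )
    ranked_all = sorted(valid, key=_sort_key)
    argmax_addr, _ = ranked_all[0]
    trace: list[str] = []
    if params.version >= 2:
        pool = [(a, s) for a, s in ranked_all if a.layer == argmax_addr.layer]
        trace.append(f"layer:{argmax_addr.layer}")
    else:
        pool = ranked_all
    top = pool[: params.top_k]
    # the dispersion fallback only matters when the gate will not bypass
    # smoothing, so check the relative SRCC gap first
    s1 = pool[0][1]
    gate_fires = s1 > 0 and (len(pool) < 2 or (s1 - pool[1][1]) / s1 > params.gate_threshold)
    if (
        params.version >= 2
        and not gate_fires
        and _dispersed(top, params.dispersion_section_gap, params.dispersion_angle)
    ):
        top = pool[: params.fallback_top_k]
        trace.append("top5_fallback")
    p0, assigned, delta, smooth_trace = smooth_position(
        top, params.gate_threshold, candidates=pool
    )
    trace.extend(smooth_trace)
    if (
        params.version >= 2
        and abs(assigned.section - argmax_addr.section) > params.section_override
    ):
        assigned = argmax_addr
        trace.append("section_override")
    return MappingResult(
        cell_id=str(cell_expression.name),
        srcc=profile,
        top_positions=top,
        smoothed_point=p0,
        assigned=assigned,
        delta_srcc=delta,
        rule_trace=trace,
    )


def map_cells(
    matrix: pd.DataFrame,
    atlas: ReferenceAtlas,
    params: MappingParams = MappingParams(),
    zipcodes: Sequence[str] | None = None,
) -> list[MappingResult]:
    """Map every column (cell) of a genes x cells matrix; per-cell
    failures are recorded on the result, not raised."""
    results = []
    for cell_id in matrix.columns:
        try:
            results.append(map_cell_v2(matrix[cell_id], atlas, params, zipcodes))
        except ValueError as exc:
            results.append(
                MappingResult(
                    cell_id=str(cell_id),
                    srcc=pd.Series(dtype=float),
                    top_positions=[],
                    smoothed_point=None,
                    assigned=None,
                    delta_srcc=None,
                    error=str(exc),
                )
            )
    return results


def mapping_table(results: Sequence[MappingResult]) -> pd.DataFrame:
    """Flatten mapping results to the interchange TSV layout."""
    rows = []
    for r in results:
        a = r.assigned
        rows.append(
            {
                "cell": r.cell_id,
                "stage": a.stage if a else None,
                "section": a.section if a else None,
                "sector": a.sector if a else None,
                "layer": a.layer if a else None,
                "x0": r.smoothed_point[0] if r.smoothed_point else None,
                "y0": r.smoothed_point[1] if r.smoothed_point else None,
                "z0": r.smoothed_point[2] if r.smoothed_point else None,
                "srcc_top1": r.top_positions[0][1] if r.top_positions else None,
                "delta_srcc": r.delta_srcc,
                "rule_trace": ";".join(r.rule_trace),
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)
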