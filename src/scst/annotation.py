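"""Cell-identity annotation by correlation transfer.

A mapped query cell inherits the label of the most-correlated single
cell already resident at its inferred position: Pearson correlation is
computed over the position's cell-type differential genes (one-vs-rest,
same test and thresholds as zipcode derivation) and the argmax resident
cell's type is transferred.  Labels follow the "X->Y" (transitional
state from layer X toward fate Y) and "X(Y)" (precursor of type Y within
layer X) nomenclature, but any string label works.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .zipcodes import differential_genes

__all__ = ["AnnotationResult", "position_celltype_degs", "annotate_cell"]


@dataclass
class AnnotationResult:
    """Label transfer outcome for one query cell."""

    cell_id: str
    address_name: str
    matched_cell: str
    label: str
    pcc: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.pcc <= 1.0 + 1e-9:
            raise ValueError("PCC outside [-1, 1]")


def position_celltype_degs(
    atlas_cells: pd.DataFrame,
    labels: Mapping[str, str],
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    top_n: int = 50,
) -> tuple[list[str], bool]:
    """Union of per-type one-vs-rest differential genes among the cells
    resident at one position (genes x cells input; ``labels`` maps cell
    id -> type).

    With fewer than two types present no within-position contrast exists;
    all genes are returned and the fallback flag set (callers typically
    substitute the layer-level union).  Returns ``(genes, fallback)``.
    """
    cell_ids = list(atlas_cells.columns)
    types = {labels[c] for c in cell_ids}
    if len(types) < 2:
        warnings.warn("single cell type at position; falling back to the full gene set")
        return sorted(str(g) for g in atlas_cells.index), True
    expr = atlas_cells.T  # cells x genes
    selected: set[str] = set()
    for t in sorted(types):
        mask = np.array([labels[c] == t for c in cell_ids])
        if mask.sum() < 2:
            warnings.warn(f"cell type {t!r} has a single cell; skipped")
            continue
        selected.update(differential_genes(expr, mask, p_threshold, fc_threshold, top_n))
    return sorted(selected), False


def annotate_cell(
    query: pd.Series,
    atlas_cells_at_position: pd.DataFrame,
    deg_set: Sequence[str],
    labels: Mapping[str, str],
    address_name: str = "",
    fallback: bool = False,
) -> AnnotationResult:
    """Transfer the label of the maximum-PCC resident cell to the query.

    Correlations are computed over ``deg_set`` (log2-space values;
    >= 3 shared genes required); residents with a constant vector are
    excluded.  Ties in the maximum PCC break toward the more frequent
    resident type, then the lexicographically smaller label, then the
    resident cell id.
    """
    shared = [g for g in deg_set if g in query.index and g in atlas_cells_at_position.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} DEGs shared with the resident cells (need >= 3)")
    q = query[shared].to_numpy(dtype=float)
    R = atlas_cells_at_position.loc[shared].to_numpy(dtype=float).T  # residents x genes
    qc = q - q.mean()
    rc = R - R.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(qc)
    rn = np.linalg.norm(rc, axis=1)
    if qn == 0:
        raise ValueError("query expression is constant over the DEG set")
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (rc @ qc) / (rn * qn)
    pcc[rn == 0] = np.nan
    if not np.isfinite(pcc).any():
        raise ValueError("no resident cell with a defined correlation")
    resident_ids = [str(c) for c in atlas_cells_at_position.columns]
    type_freq = Counter(labels[c] for c in resident_ids)
    best = max(
        (i for i in range(len(resident_ids)) if np.isfinite(pcc[i])),
        key=lambda i: (
            round(float(pcc[i]), 12),
            type_freq[labels[resident_ids[i]]],
            # negated label sorts reversed strings; use tuple trick instead
        ),
    )
    # resolve remaining exact ties deterministically by label then cell id
    top_val = round(float(pcc[best]), 12)
    tied = [
        i
        for i in range(len(resident_ids))
        if np.isfinite(pcc[i]) and round(float(pcc[i]), 12) == top_val
    ]
    best = min(
        tied,
        key=lambda i: (
            -type_freq[labels[resident_ids[i]]],
            str(labels[resident_ids[i]]),
            resident_ids[i],
        ),
    )
    return AnnotationResult(
        cell_id=str(query.name),
        address_name=address_name,
        matched_cell=resident_ids[best],
        label=str(labels[resident_ids[best]]),
        pcc=float(np.clip(pcc[best], -1.0, 1.0)),
        fallback=fallback,
    )
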