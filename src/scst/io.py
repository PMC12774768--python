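"""Readers and writers for the interchange formats.

Expression matrices travel as dense TSV/CSV (genes as rows, samples as
columns) or as MatrixMarket triplets with ``features.tsv`` /
``barcodes.tsv`` sidecars (1-based indices, the common droplet-pipeline
dialect).  Positional-address tables, mapping tables and lineage edge
lists are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .geometry import EmbryoModelConfig, PositionalAddress

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_address_table",
    "write_address_table",
    "read_gene_list",
    "write_gene_list",
    "corn_plot_table",
    "load_geometry_config",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    log1p: bool = False,
) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    ``fmt`` is 'tsv', 'csv' or 'mtx'; inferred from the suffix when None.
    For MTX, ``features.tsv`` and ``barcodes.tsv`` sidecars are looked up
    next to the matrix file (gene and sample labels, one per line, first
    column used).  ``log1p`` applies log2(x + 1) after reading.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise FormatError(f"not a readable MatrixMarket file: {path}: {exc}") from exc
        mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        genes = _read_sidecar(path.parent / "features.tsv", mat.shape[0], "features")
        cells = _read_sidecar(path.parent / "barcodes.tsv", mat.shape[1], "barcodes")
        frame = pd.DataFrame(mat, index=genes, columns=cells)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        if path.stat().st_size == 0:
            raise FormatError(f"empty expression file: {path}")
        frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if frame.shape[1] == 0:
            raise FormatError(f"no sample columns found in {path}")
        if not all(np.issubdtype(d, np.number) for d in frame.dtypes):
            raise FormatError(f"non-numeric values (ragged rows?) in {path}")
        if frame.isna().any().any():
            bad = frame.index[frame.isna().any(axis=1)].tolist()
            raise FormatError(f"missing values (ragged rows?) in {path}: rows {bad[:10]}")
    else:
        raise FormatError(f"unknown expression format {fmt!r}")
    for axis, kind in ((frame.index, "gene"), (frame.columns, "sample")):
        dup = axis[axis.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate {kind} labels: {dup[:10]}")
    if log1p:
        frame = np.log2(frame + 1.0)
    return frame


def _read_sidecar(path: Path, expect: int, kind: str) -> list[str]:
    if not path.exists():
        return [f"{kind[:-1]}_{i + 1}" for i in range(expect)]
    labels = [line.split("\t")[0] for line in path.read_text().splitlines() if line]
    if len(labels) != expect:
        raise FormatError(f"{path} has {len(labels)} entries, matrix expects {expect}")
    return labels


def write_expression(frame: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a genes x samples matrix as dense TSV/CSV or MTX + sidecars."""
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower(), "tsv")
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(frame.to_numpy()))
        (path.parent / "features.tsv").write_text("\n".join(map(str, frame.index)) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(map(str, frame.columns)) + "\n")
    else:
        frame.to_csv(path, sep="\t" if fmt == "tsv" else ",")


_ADDRESS_COLUMNS = ["stage", "section", "sector", "layer", "x", "y", "z"]


def write_address_table(addresses: Sequence[PositionalAddress], path: str | Path) -> None:
    rows = [
        [a.stage, a.section, a.sector, a.layer, *a.coordinate] for a in addresses
    ]
    pd.DataFrame(rows, columns=_ADDRESS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_address_table(path: str | Path) -> list[PositionalAddress]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _ADDRESS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"address table {path} lacks columns {missing}")
    return [
        PositionalAddress(
            stage=str(r.stage),
            section=int(r.section),
            sector=str(r.sector),
            layer=str(r.layer),
            coordinate=(float(r.x), float(r.y), float(r.z)),
        )
        for r in frame.itertuples()
    ]


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def corn_plot_table(
    addresses: Sequence[PositionalAddress], values: Sequence[float]
) -> pd.DataFrame:
    """Long-format (address, value) table for corn-plot rendering."""
    if len(addresses) != len(values):
        raise ValueError("one value per address required")
    return pd.DataFrame(
        {
            "address": [a.name for a in addresses],
            "layer": [a.layer for a in addresses],
            "x": [a.coordinate[0] for a in addresses],
            "y": [a.coordinate[1] for a in addresses],
            "z": [a.coordinate[2] for a in addresses],
            "value": list(values),
        }
    )


def load_geometry_config(path: str | Path) -> EmbryoModelConfig:
    """Load a geometry config from JSON (or YAML when PyYAML is present)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return EmbryoModelConfig.from_json(json.dumps(yaml.safe_load(text)))
    return EmbryoModelConfig.from_json(text)
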