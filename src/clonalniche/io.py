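"""Readers and writers for the tabular/matrix formats the pipeline touches.

Every reader validates into the domain types and is the exact inverse of the
corresponding writer on valid data.  Row order is always input order; readers
never silently reorder.  Writers emit byte-stable output for identical input:
JSON keys are sorted and floats are formatted to 6 significant digits.

Delimiters are auto-detected from the extension (``.tsv`` -> tab, ``.csv`` ->
comma) and overridable with the ``delimiter`` argument, because both dialects
occur in VDJ exports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Point, Polygon, mapping as geom_mapping, shape as geom_shape

from .errors import ConfigurationError, ValidationError
from .types import (
    CellTable,
    CellType,
    CountMatrix,
    Lineage,
    RepertoireTable,
    VesselGeometry,
)

#: default lineage value sets; source files encode Foxp3 status heterogeneously,
#: so these are configurable via ``lineage_values``
DEFAULT_LINEAGE_VALUES: dict[Lineage, tuple[str, ...]] = {
    Lineage.TREG: ("treg", "foxp3+"),
    Lineage.TCONV: ("tconv", "foxp3-"),
}

REPERTOIRE_ROLES = ("cell_id", "subject_id", "clone_id", "lineage")
CELL_ROLES = ("cell_id", "x", "y", "cell_type")


def _detect_sep(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _fmt6(x: float) -> float:
    """Round a float to 6 significant digits for byte-stable output."""
    return float(f"{x:.6g}")


def read_repertoire(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    lineage_values: Optional[Mapping[Lineage, tuple[str, ...]]] = None,
) -> RepertoireTable:
    """Read a per-cell clonotype table from delimited text.

    ``column_map`` maps the required roles (cell_id, subject_id, clone_id,
    lineage; optionally timepoint) to the file's column names, so 10x-VDJ-style
    exports (``barcode``, ``raw_clonotype_id``) load without renaming upstream.
    Rows with an empty clone_id are dropped and counted in ``n_dropped``.
    Lineage labels are parsed case-insensitively from ``lineage_values``
    (default: "Treg"/"Foxp3+" -> TREG, "Tconv"/"Foxp3-" -> TCONV).
    """
    path = Path(path)
    column_map = dict(column_map or {r: r for r in (*REPERTOIRE_ROLES, "timepoint")})
    raw = pd.read_csv(path, sep=_detect_sep(path, delimiter), dtype=str)

    for role in REPERTOIRE_ROLES:
        if role not in column_map:
            raise ConfigurationError(f"column_map missing required role '{role}'")
        if column_map[role] not in raw.columns:
            raise ConfigurationError(
                f"column '{column_map[role]}' for role '{role}' not found in {path.name}"
            )

    df = pd.DataFrame(
        {role: raw[column_map[role]].astype(str) for role in REPERTOIRE_ROLES}
    )
    tp_col = column_map.get("timepoint")
    if tp_col is not None and tp_col in raw.columns:
        df["timepoint"] = raw[tp_col].astype(str)
    else:
        df["timepoint"] = ""

    empty = df["clone_id"].isna() | df["clone_id"].str.strip().isin(("", "nan", "None"))
    n_dropped = int(empty.sum())
    df = df[~empty].reset_index(drop=True)

    values = lineage_values or DEFAULT_LINEAGE_VALUES
    lookup = {
        v.lower(): lin.value for lin, vals in values.items() for v in vals
    }
    lookup.update({lin.value.lower(): lin.value for lin in Lineage})
    parsed = df["lineage"].str.lower().map(lookup)
    if parsed.isna().any():
        bad = parsed[parsed.isna()].index.tolist()
        raise ValidationError(
            f"unparseable lineage value(s) at row index {bad}: "
            f"{df.loc[bad, 'lineage'].unique().tolist()}"
        )
    df["lineage"] = parsed
    df = df[["cell_id", "subject_id", "timepoint", "clone_id", "lineage"]]
    return RepertoireTable(df=df, n_dropped=n_dropped)


def write_repertoire(rep: RepertoireTable, path: str | Path) -> None:
    path = Path(path)
    rep.df.to_csv(path, sep=_detect_sep(path, None), index=False)


def read_cell_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
) -> CellTable:
    """Read a typed cell point pattern (cell_id, x, y, cell_type) from text.

    Unknown cell_type strings map to OTHER; the number of such rows is
    reported in ``n_unknown_type``.
    """
    path = Path(path)
    column_map = dict(column_map or {r: r for r in CELL_ROLES})
    raw = pd.read_csv(path, sep=_detect_sep(path, delimiter), dtype=str)

    for role in CELL_ROLES:
        if role not in column_map:
            raise ConfigurationError(f"column_map missing required role '{role}'")
        if column_map[role] not in raw.columns:
            raise ConfigurationError(
                f"column '{column_map[role]}' for role '{role}' not found in {path.name}"
            )

    df = pd.DataFrame({role: raw[column_map[role]] for role in CELL_ROLES})
    for axis in ("x", "y"):
        coerced = pd.to_numeric(df[axis], errors="coerce")
        if coerced.isna().any():
            bad = coerced[coerced.isna()].index.tolist()
            raise ValidationError(f"non-numeric {axis} coordinate at row index {bad}")
        df[axis] = coerced.astype(float)

    known = {t.value for t in CellType}
    types = df["cell_type"].astype(str)
    unknown = ~types.isin(known)
    n_unknown = int(unknown.sum())
    df["cell_type"] = types.where(~unknown, CellType.OTHER.value)
    df["cell_id"] = df["cell_id"].astype(str)
    return CellTable(df=df, n_unknown_type=n_unknown)


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    path = Path(path)
    out = cells.df.copy()
    out["x"] = out["x"].map(lambda v: f"{v:.6g}")
    out["y"] = out["y"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep=_detect_sep(path, None), index=False)


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CountMatrix:
    """Read a MatrixMarket triplet count matrix with gene/cell name lists."""
    M = scipy.io.mmread(str(matrix_path))
    genes = Path(genes_path).read_text().splitlines()
    cells = Path(cells_path).read_text().splitlines()
    if M.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"dimension mismatch: matrix {M.shape}, "
            f"{len(genes)} genes, {len(cells)} cells"
        )
    return CountMatrix(genes=genes, cells=cells, X=sp.csr_matrix(M))


def write_counts_mtx(
    counts: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    X = sp.coo_matrix(counts.X)
    scipy.io.mmwrite(str(matrix_path), X.astype(np.int64), field="integer")
    Path(genes_path).write_text("\n".join(counts.genes) + "\n")
    Path(cells_path).write_text("\n".join(counts.cells) + "\n")


def read_vessels(path: str | Path) -> VesselGeometry:
    """Read vessel features from GeoJSON-style JSON or a two-column point CSV.

    JSON accepts a GeoJSON FeatureCollection or a bare ``{"features": [...]}``
    list of Point/Polygon geometries.  CSV input is interpreted as one vessel
    point per row (columns x, y).  An empty feature list is valid: downstream
    the parenchymal fraction is then 1.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        doc = json.loads(path.read_text())
        feats = doc.get("features", doc if isinstance(doc, list) else [])
        geoms = []
        for i, feat in enumerate(feats):
            g = feat.get("geometry", feat)
            try:
                geom = geom_shape(g)
            except Exception as exc:
                raise ValidationError(f"unparseable vessel feature {i}: {exc}") from exc
            geoms.append(geom)
        return VesselGeometry(features=geoms)
    df = pd.read_csv(path, sep=_detect_sep(path, None))
    if not {"x", "y"} <= set(df.columns):
        raise ConfigurationError("vessel point CSV requires columns x, y")
    return VesselGeometry(
        features=[Point(float(r.x), float(r.y)) for r in df.itertuples()]
    )


def write_vessels(vessels: VesselGeometry, path: str | Path) -> None:
    def _round_coords(obj):
        if isinstance(obj, (list, tuple)):
            return [_round_coords(v) for v in obj]
        if isinstance(obj, float):
            return _fmt6(obj)
        return obj

    feats = []
    for geom in vessels.features:
        m = geom_mapping(geom)
        feats.append(
            {
                "geometry": {
                    "coordinates": _round_coords(m["coordinates"]),
                    "type": m["type"],
                },
                "type": "Feature",
            }
        )
    doc = {"features": feats, "type": "FeatureCollection"}
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
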