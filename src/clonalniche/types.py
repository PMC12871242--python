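"""Core domain types shared across the pipeline.

Coordinates are micrometers with an arbitrary origin; all spatial statistics
are invariant under translation and rotation, so the y-axis orientation of the
imaging platform is irrelevant.  Clone identity is the ``clone_id`` string
exactly as provided by the upstream VDJ caller: the package treats clonotype
definition (nucleotide vs. amino-acid level) as upstream and opaque.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.geometry import Point, Polygon

from .errors import ValidationError


class Lineage(str, Enum):
    """Foxp3 lineage of a CD4 T cell: regulatory (TREG) or conventional (TCONV)."""

    TREG = "TREG"
    TCONV = "TCONV"


class CellType(str, Enum):
    """Cell-type label of a cell in tissue space."""

    DC = "DC"
    T_CONV = "T_CONV"
    T_REG = "T_REG"
    OTHER = "OTHER"


T_CELL_TYPES = frozenset({CellType.T_CONV, CellType.T_REG})


class CloneCategory(str, Enum):
    """Lineage composition of a clone: pure Treg, pure Tconv, or shared."""

    TREG_ONLY = "TREG_ONLY"
    TCONV_ONLY = "TCONV_ONLY"
    SHARED = "SHARED"


REPERTOIRE_COLUMNS = ["cell_id", "subject_id", "timepoint", "clone_id", "lineage"]
CELL_TABLE_COLUMNS = ["cell_id", "x", "y", "cell_type"]


@dataclass
class RepertoireTable:
    """Per-cell clonotype table: one row per sequenced T cell.

    Columns: ``cell_id`` (unique), ``subject_id``, ``timepoint`` (free-text
    label, e.g. "PND7"), ``clone_id`` (non-empty), ``lineage`` ("TREG"/"TCONV").
    ``n_dropped`` counts input rows discarded for an empty clone_id.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in REPERTOIRE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"repertoire table missing columns: {missing}")
        dup = self.df["cell_id"][self.df["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate cell_id values: {sorted(dup.unique().tolist())}"
            )
        if (self.df["clone_id"].astype(str) == "").any():
            raise ValidationError("empty clone_id present after filtering")
        bad = set(self.df["lineage"].unique()) - {l.value for l in Lineage}
        if bad:
            raise ValidationError(f"unknown lineage values: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def subjects(self) -> list[str]:
        return list(pd.unique(self.df["subject_id"]))


@dataclass
class CellTable:
    """Typed cell point pattern from imaging / in-situ transcriptomics.

    Columns: ``cell_id`` (unique), ``x``/``y`` (µm, finite), ``cell_type``
    (one of the :class:`CellType` values).  ``n_unknown_type`` counts input
    rows whose type label was not recognised and mapped to OTHER.
    Optionally linked to a :class:`CountMatrix` whose columns match cell_ids.
    """

    df: pd.DataFrame
    counts: Optional["CountMatrix"] = None
    n_unknown_type: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CELL_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"cell table missing columns: {missing}")
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad_rows = np.where(~np.isfinite(xy).all(axis=1))[0].tolist()
            raise ValidationError(f"non-finite coordinates at rows {bad_rows}")
        dup = self.df["cell_id"][self.df["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate cell_id values: {sorted(dup.unique().tolist())}"
            )
        bad = set(self.df["cell_type"].unique()) - {t.value for t in CellType}
        if bad:
            raise ValidationError(f"unknown cell_type values: {sorted(bad)}")
        if self.counts is not None:
            if list(self.counts.cells) != list(self.df["cell_id"]):
                raise ValidationError(
                    "linked count matrix columns do not match cell_ids one-to-one"
                )

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer counts."""

    genes: list[str]
    cells: list[str]
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene names")
        data = self.X.data
        if len(data) and (data < 0).any():
            raise ValidationError("negative count entries")
        if len(data) and np.any(data != np.floor(data)):
            raise ValidationError("fractional count entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


@dataclass
class VesselGeometry:
    """Vessel features: shapely Points and/or closed Polygons, in µm."""

    features: list  # shapely Point | Polygon

    def __post_init__(self) -> None:
        for i, geom in enumerate(self.features):
            if isinstance(geom, Point):
                if not (np.isfinite(geom.x) and np.isfinite(geom.y)):
                    raise ValidationError(f"non-finite vessel point at index {i}")
            elif isinstance(geom, Polygon):
                n_vertices = len(geom.exterior.coords) - 1
                if n_vertices < 3:
                    raise ValidationError(
                        f"vessel polygon {i} has fewer than 3 vertices"
                    )
                if geom.area == 0:
                    raise ValidationError(f"vessel polygon {i} has zero area")
                if not np.isfinite(np.asarray(geom.exterior.coords)).all():
                    raise ValidationError(f"non-finite vessel polygon at index {i}")
            else:
                raise ValidationError(
                    f"vessel feature {i} is neither point nor polygon"
                )

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class CloneRecord:
    """Per-clone aggregate: size, lineage composition and sharing category."""

    clone_id: str
    size: int
    n_treg: int
    n_tconv: int
    category: CloneCategory

    def __post_init__(self) -> None:
        if self.size != self.n_treg + self.n_tconv or self.size < 1:
            raise ValidationError(
                f"clone {self.clone_id}: size {self.size} != "
                f"{self.n_treg} Treg + {self.n_tconv} Tconv"
            )

    @property
    def expanded(self) -> bool:
        return self.size > 1

    @staticmethod
    def categorize(n_treg: int, n_tconv: int) -> CloneCategory:
        if n_treg >= 1 and n_tconv >= 1:
            return CloneCategory.SHARED
        return CloneCategory.TREG_ONLY if n_tconv == 0 else CloneCategory.TCONV_ONLY


@dataclass
class RepertoireSummary:
    """Per-subject clonal-architecture summary."""

    subject_id: str
    n_cells: int
    n_clones: int
    r20: float
    expanded_fraction: float
    expanded_category_fractions: dict[CloneCategory, float]
    shared_clone_count: int
    monoclonal: bool = False  # degenerate single-clone repertoire (r20 = 1 by formula)


@dataclass
class NicheParams:
    """Density-based microniche detection parameters.

    ``eps`` (µm) and ``min_samples`` follow DBSCAN semantics (a core point has
    >= min_samples points within eps, itself included).  A cluster is retained
    as a niche only if it contains >= ``min_dc`` dendritic cells and
    >= ``min_t`` T cells (conventional + regulatory combined).
    Defaults: eps 30 µm (~2-3 hepatocyte diameters), min_samples 5 (the
    2*dim + 1 heuristic), min_dc 1, min_t 3.
    """

    eps: float = 30.0
    min_samples: int = 5
    min_dc: int = 1
    min_t: int = 3
    included_types: frozenset = frozenset(
        {CellType.DC, CellType.T_CONV, CellType.T_REG}
    )

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValidationError("eps must be > 0")
        if self.min_samples < 2:
            raise ValidationError("min_samples must be >= 2")
        if self.min_dc < 1 or self.min_t < 1:
            raise ValidationError("min_dc and min_t must be >= 1")


@dataclass
class Niche:
    """One detected DC-T cell microcluster."""

    niche_id: str
    member_cell_ids: list[str]
    centroid: tuple[float, float]
    composition: dict[CellType, int]
    is_parenchymal: Optional[bool] = None
    area_proxy: Optional[float] = None  # convex-hull area, µm²; None if collinear
    hull_degenerate: bool = False

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)

    @property
    def n_dc(self) -> int:
        return self.composition.get(CellType.DC, 0)

    @property
    def n_t(self) -> int:
        return self.composition.get(CellType.T_CONV, 0) + self.composition.get(
            CellType.T_REG, 0
        )


@dataclass
class SlideStats:
    """Whole-slide spatial statistics."""

    mean_nearest_dc_distance: float  # µm
    foci_density: float  # niches per mm²
    tissue_area: float  # mm²
    parenchymal_fraction: Optional[float] = None  # only defined if vessels given
    n_niches: int = 0
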