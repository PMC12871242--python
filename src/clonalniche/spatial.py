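"""Microniche detection and whole-slide spatial statistics.

Niches are detected with DBSCAN semantics on the typed cell point pattern:
a core point has at least ``min_samples`` points (itself included) within
``eps`` µm; clusters are connected components of core points plus reachable
border points; everything else is noise.  Classic DBSCAN assigns a border
point reachable from several clusters to whichever cluster is visited first,
which makes the output depend on input row order.  Here border points are
instead assigned to the cluster containing their nearest core point, with
exact-distance ties going to the lower-ranked cluster (clusters ranked by the
lexicographically smallest (x, y, cell_id) of their core members), so the
output is deterministic and invariant under row permutation and rigid motion.

Detected clusters are kept as niches only when they satisfy a composition
rule — at least ``min_dc`` dendritic cells and ``min_t`` T cells — which
operationalises "DC-T cell cluster" while excluding pure-T clumps.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import Point, Polygon

from .errors import (
    DegenerateGeometryError,
    DomainError,
    ValidationError,
)
from .types import (
    CellTable,
    CellType,
    Niche,
    NicheParams,
    SlideStats,
    T_CELL_TYPES,
    VesselGeometry,
)

NO_NICHE = "NONE"


def _hull_area(xy: np.ndarray) -> Optional[float]:
    """Convex-hull area in µm², or None for < 3 points / collinear members."""
    if len(xy) < 3:
        return None
    try:
        return float(ConvexHull(xy).volume)  # in 2D, .volume is the area
    except QhullError:
        return None


def detect_microclusters(
    cells: CellTable, params: Optional[NicheParams] = None
) -> list[Niche]:
    """Detect DC-T cell microniches by density-based clustering.

    Only cells of ``params.included_types`` participate in clustering.
    Returns niches sorted by descending member count, ties broken by centroid
    x then y; niche ids are assigned in that order ("N000", "N001", ...).
    An empty cell table yields an empty list.
    """
    params = params or NicheParams()
    included = {t.value for t in params.included_types}
    sub = cells.df[cells.df["cell_type"].isin(included)].reset_index(drop=True)
    if sub.empty:
        return []

    xy = sub[["x", "y"]].to_numpy(dtype=float)
    ids = sub["cell_id"].to_numpy()
    types = sub["cell_type"].to_numpy()
    n = len(sub)

    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, params.eps)
    core = np.array([len(nb) >= params.min_samples for nb in neighbors])
    core_idx = np.flatnonzero(core)
    if core_idx.size == 0:
        return []

    # connected components over core points linked within eps
    core_pos = {int(i): j for j, i in enumerate(core_idx)}
    rows, cols = [], []
    for i in core_idx:
        for j in neighbors[i]:
            if core[j]:
                rows.append(core_pos[int(i)])
                cols.append(core_pos[int(j)])
    graph = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(core_idx.size, core_idx.size)
    )
    n_comp, comp = connected_components(graph, directed=False)

    # canonical cluster ranks: lexicographic min (x, y, cell_id) of core members
    rank_key = {}
    for c in range(n_comp):
        members = core_idx[comp == c]
        keys = sorted((xy[i, 0], xy[i, 1], str(ids[i])) for i in members)
        rank_key[c] = keys[0]
    order = sorted(range(n_comp), key=lambda c: rank_key[c])
    rank = {c: r for r, c in enumerate(order)}

    labels = np.full(n, -1, dtype=int)  # cluster rank, -1 = noise
    for j, i in enumerate(core_idx):
        labels[i] = rank[comp[j]]

    # border points: non-core with >= 1 core neighbor; assign to the cluster
    # of the nearest core point, ties to the lower cluster rank
    for i in np.flatnonzero(~core):
        core_nb = [j for j in neighbors[i] if core[j]]
        if not core_nb:
            continue
        dists = np.hypot(*(xy[core_nb] - xy[i]).T)
        best = min(
            range(len(core_nb)), key=lambda k: (dists[k], labels[core_nb[k]])
        )
        labels[i] = labels[core_nb[best]]

    niches = []
    for r in range(n_comp):
        member_mask = labels == r
        comp_counts = {
            t: int((types[member_mask] == t.value).sum()) for t in CellType
        }
        n_t = comp_counts[CellType.T_CONV] + comp_counts[CellType.T_REG]
        if comp_counts[CellType.DC] < params.min_dc or n_t < params.min_t:
            continue
        member_xy = xy[member_mask]
        area = _hull_area(member_xy)
        niches.append(
            Niche(
                niche_id="",  # assigned after the final sort
                member_cell_ids=[str(i) for i in ids[member_mask]],
                centroid=(float(member_xy[:, 0].mean()), float(member_xy[:, 1].mean())),
                composition={t: c for t, c in comp_counts.items() if c > 0},
                area_proxy=area,
                hull_degenerate=area is None,
            )
        )

    niches.sort(key=lambda nc: (-nc.size, nc.centroid[0], nc.centroid[1]))
    for i, nc in enumerate(niches):
        nc.niche_id = f"N{i:03d}"
    return niches


def nearest_dc_distance(cells: CellTable) -> tuple[list[str], np.ndarray, float]:
    """Per-T-cell Euclidean distance to the nearest DC, and the mean (µm).

    Returns (T-cell ids in input order, distances, mean).  Requires at least
    one DC (the reference population) and one T cell.
    """
    df = cells.df
    t_mask = df["cell_type"].isin({t.value for t in T_CELL_TYPES})
    dc_mask = df["cell_type"] == CellType.DC.value
    if not dc_mask.any():
        raise DomainError("distance undefined without reference population (no DC)")
    if not t_mask.any():
        raise DomainError("no T cells present")
    t_xy = df.loc[t_mask, ["x", "y"]].to_numpy(dtype=float)
    dc_xy = df.loc[dc_mask, ["x", "y"]].to_numpy(dtype=float)
    dists, _ = cKDTree(dc_xy).query(t_xy, k=1)
    dists = np.atleast_1d(dists)
    return (
        df.loc[t_mask, "cell_id"].tolist(),
        dists,
        float(dists.mean()),
    )


def foci_density(niches: Sequence[Niche], tissue_area: float) -> float:
    """Niches per mm² of tissue."""
    if not tissue_area > 0:
        raise ValidationError("tissue_area must be > 0")
    return len(niches) / tissue_area


def _vessel_distance(centroid: tuple[float, float], vessels: VesselGeometry) -> float:
    """Distance (µm) from a point to the nearest vessel feature.

    Point features use plain Euclidean distance; polygon features use the
    distance to the polygon boundary, 0 if the point lies inside.
    """
    pt = Point(*centroid)
    best = np.inf
    for geom in vessels.features:
        if isinstance(geom, Polygon):
            d = 0.0 if geom.covers(pt) else geom.exterior.distance(pt)
        else:
            d = geom.distance(pt)
        best = min(best, d)
    return best


def classify_parenchymal(
    niches: Sequence[Niche],
    vessels: VesselGeometry,
    proximity_radius: float = 50.0,
) -> tuple[list[Niche], Optional[float]]:
    """Flag each niche as parenchymal and return the parenchymal fraction.

    A niche is parenchymal iff its centroid is farther than
    ``proximity_radius`` from every vessel feature; with no vessel features
    every niche is parenchymal.  The fraction is None (undefined) when there
    are no niches.
    """
    if not proximity_radius > 0:
        raise ValidationError("proximity_radius must be > 0")
    out = list(niches)
    for nc in out:
        nc.is_parenchymal = (
            len(vessels) == 0
            or _vessel_distance(nc.centroid, vessels) > proximity_radius
        )
    if not out:
        return out, None
    return out, sum(nc.is_parenchymal for nc in out) / len(out)


def tissue_area_estimate(
    cells: CellTable, method: str = "CONVEX_HULL", grid_step: float = 100.0
) -> float:
    """Estimate the imaged tissue area in mm² from the cell point pattern.

    CONVEX_HULL uses the hull of all cells regardless of type (tight for
    convex sections, an underestimate of lobular tissue with bays).
    ALPHA_GRID counts grid cells of side ``grid_step`` µm containing >= 1
    cell; coarse steps overestimate.  A user-supplied tissue mask, when
    available, should be preferred over either.
    """
    xy = cells.coords()
    if method == "CONVEX_HULL":
        if len(xy) < 3:
            raise DegenerateGeometryError(
                "convex hull needs >= 3 cells; try ALPHA_GRID"
            )
        try:
            hull = ConvexHull(xy)
        except QhullError as exc:
            raise DegenerateGeometryError(
                "collinear cells: convex hull degenerate; try ALPHA_GRID"
            ) from exc
        return float(hull.volume) / 1e6
    if method == "ALPHA_GRID":
        if not grid_step > 0:
            raise ValidationError("grid_step must be > 0")
        occupied = {
            (int(np.floor(x / grid_step)), int(np.floor(y / grid_step)))
            for x, y in xy
        }
        return len(occupied) * grid_step**2 / 1e6
    raise ValidationError(f"unknown area method '{method}'")


def assign_niche_membership(
    cells: CellTable, niches: Sequence[Niche]
) -> pd.Series:
    """Per-cell niche label: the niche_id for member cells, NONE otherwise.

    Membership is by clustering, not geometry: a cell physically inside a
    niche's hull but not clustered into it stays NONE.
    """
    labels = pd.Series(NO_NICHE, index=cells.df["cell_id"], name="niche_id")
    known = set(labels.index)
    for nc in niches:
        for cid in nc.member_cell_ids:
            if cid not in known:
                raise ValidationError(
                    f"niche {nc.niche_id} member '{cid}' absent from cell table"
                )
            labels.loc[cid] = nc.niche_id
    return labels


def slide_stats(
    cells: CellTable,
    niches: Sequence[Niche],
    vessels: Optional[VesselGeometry] = None,
    tissue_area: Optional[float] = None,
    area_method: str = "CONVEX_HULL",
    proximity_radius: float = 50.0,
) -> SlideStats:
    """Whole-slide summary: mean nearest-DC distance, focus density and, when
    vessel geometry is available, the parenchymal niche fraction."""
    if tissue_area is None:
        tissue_area = tissue_area_estimate(cells, method=area_method)
    _, _, mean_dist = nearest_dc_distance(cells)
    frac = None
    if vessels is not None:
        _, frac = classify_parenchymal(niches, vessels, proximity_radius)
    return SlideStats(
        mean_nearest_dc_distance=mean_dist,
        foci_density=foci_density(niches, tissue_area),
        tissue_area=tissue_area,
        parenchymal_fraction=frac,
        n_niches=len(niches),
    )
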