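"""Synthetic repertoires and tissues with known ground truth.

The generators emulate the structure of the study inputs so that every
pipeline stage is testable without any download: per-cell clonotype tables
with tunable clonal expansion and cross-lineage sharing, and tissue cell maps
with planted DC-T microniches over a background point field, vessels, and
niche-conditional gene effects.

Repertoires: clone sizes are drawn from a configurable law (power law,
geometric, or uniform) until the target cell count is reached (the last clone
is truncated so cell counts stay exact for closed-form checks).  Lineage is
drawn once per clone — mirroring biological clonal coherence — except for a
controlled fraction of expanded clones that are forced to contain both
lineages, making shared clones a planted, not incidental, event.

Tissues: background cells follow homogeneous Poisson processes per type;
niche members are placed uniformly in discs around centers accepted by
rejection sampling under a minimum-separation constraint; vessels are points
placed uniformly at random; gene counts are Poisson with a fold-change
multiplier applied to niche members of the matching type.  Counts carry no
overdispersion knob: the downstream test is rank-based and robust to the
marginal distribution.

All generators are bit-reproducible given (params, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from shapely.geometry import Point

from .errors import ConfigurationError, GenerationError, ValidationError
from .io import (
    write_cell_table,
    write_counts_mtx,
    write_repertoire,
    write_vessels,
)
from .types import (
    CellTable,
    CellType,
    CloneRecord,
    CountMatrix,
    Lineage,
    RepertoireTable,
    VesselGeometry,
)

CLONE_SIZE_LAWS = ("POWER_LAW", "GEOMETRIC", "UNIFORM")


def _check_keys(doc: dict, allowed: set[str], what: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {what} parameter keys: {sorted(unknown)}")


@dataclass
class RepertoireSimParams:
    """Parameters for the repertoire generator.

    ``clone_size_law`` is one of POWER_LAW (Zipf with ``exponent`` > 1),
    GEOMETRIC (success probability ``p``; mean size 1/p) or UNIFORM (every
    clone of size ``uniform_size``).  ``p_treg`` is the marginal Treg
    probability; ``sharing_rate`` is the fraction of expanded clones forced to
    contain both lineages.
    """

    n_cells: int = 1000
    clone_size_law: str = "GEOMETRIC"
    exponent: float = 2.5
    p: float = 0.5
    uniform_size: int = 1
    p_treg: float = 0.5
    sharing_rate: float = 0.1
    subject_id: str = "sim"
    timepoint: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if self.clone_size_law not in CLONE_SIZE_LAWS:
            raise ValidationError(
                f"clone_size_law must be one of {CLONE_SIZE_LAWS}"
            )
        if self.clone_size_law == "POWER_LAW" and not self.exponent > 1:
            raise ValidationError("power-law exponent must be > 1")
        if self.clone_size_law == "GEOMETRIC" and not 0 < self.p <= 1:
            raise ValidationError("geometric p must be in (0, 1]")
        if self.clone_size_law == "UNIFORM" and self.uniform_size < 1:
            raise ValidationError("uniform_size must be >= 1")
        if not 0 <= self.p_treg <= 1:
            raise ValidationError("p_treg must be in [0, 1]")
        if not 0 <= self.sharing_rate <= 1:
            raise ValidationError("sharing_rate must be in [0, 1]")

    @classmethod
    def from_json(cls, doc: dict) -> "RepertoireSimParams":
        _check_keys(doc, set(cls.__dataclass_fields__), "repertoire")
        return cls(**doc)


def _draw_clone_sizes(params: RepertoireSimParams, rng: np.random.Generator):
    sizes: list[int] = []
    total = 0
    while total < params.n_cells:
        if params.clone_size_law == "POWER_LAW":
            s = int(
                scipy.stats.zipf(params.exponent).rvs(random_state=rng)
            )
        elif params.clone_size_law == "GEOMETRIC":
            s = int(rng.geometric(params.p))
        else:
            s = params.uniform_size
        sizes.append(s)
        total += s
    sizes[-1] -= total - params.n_cells  # truncate last clone to hit n_cells
    if sizes[-1] == 0:
        sizes.pop()
    return sizes


def simulate_repertoire(
    params: RepertoireSimParams,
) -> tuple[RepertoireTable, list[CloneRecord]]:
    """Generate a per-cell clonotype table plus its ground-truth clone list."""
    rng = np.random.default_rng(params.seed)
    sizes = _draw_clone_sizes(params, rng)
    n_clones = len(sizes)

    expanded_idx = [i for i, s in enumerate(sizes) if s > 1]
    n_forced = int(round(params.sharing_rate * len(expanded_idx)))
    forced = set(
        rng.choice(expanded_idx, size=n_forced, replace=False).tolist()
        if n_forced
        else []
    )

    rows = []
    records = []
    cell_counter = 0
    for i, size in enumerate(sizes):
        clone_id = f"clone{i:05d}"
        if i in forced:
            # draw size-1 cells i.i.d., then force one cell of the minority
            # (or absent) lineage so both lineages are guaranteed present
            draws = rng.random(size - 1) < params.p_treg
            n_treg = int(draws.sum())
            n_tconv = (size - 1) - n_treg
            if n_treg <= n_tconv:
                lineages = ["TREG"] + ["TREG"] * n_treg + ["TCONV"] * n_tconv
            else:
                lineages = ["TCONV"] + ["TREG"] * n_treg + ["TCONV"] * n_tconv
        else:
            # clonal lineage coherence: one draw for the whole clone
            lin = "TREG" if rng.random() < params.p_treg else "TCONV"
            lineages = [lin] * size
        n_treg = lineages.count("TREG")
        n_tconv = size - n_treg
        records.append(
            CloneRecord(
                clone_id=clone_id,
                size=size,
                n_treg=n_treg,
                n_tconv=n_tconv,
                category=CloneRecord.categorize(n_treg, n_tconv),
            )
        )
        for lin in lineages:
            rows.append(
                {
                    "cell_id": f"{params.subject_id}_c{cell_counter:06d}",
                    "subject_id": params.subject_id,
                    "timepoint": params.timepoint,
                    "clone_id": clone_id,
                    "lineage": lin,
                }
            )
            cell_counter += 1
    table = RepertoireTable(df=pd.DataFrame(rows))
    assert table.n_cells == params.n_cells
    return table, records


@dataclass
class PlantedNiche:
    """Ground truth for one planted microniche."""

    center: tuple[float, float]
    radius: float
    member_cell_ids: list[str]
    composition: dict[str, int]


@dataclass
class TissueSimParams:
    """Parameters for the tissue generator.

    ``field_size`` is (width, height) in µm.  ``background_intensity`` maps
    cell-type name to cells/mm².  Niche type counts are Poisson with means
    ``niche_mean_dc`` and ``niche_mean_t`` (T cells split Treg/Tconv by
    ``t_reg_fraction``); members are uniform in a disc of ``niche_radius``.
    ``niche_effects`` maps (cell-type name, gene) to a fold change applied to
    the Poisson mean of niche members of that type.
    """

    field_size: tuple[float, float] = (2000.0, 2000.0)
    background_intensity: dict = dc_field(
        default_factory=lambda: {"DC": 30.0, "T_CONV": 40.0, "T_REG": 20.0, "OTHER": 10.0}
    )
    n_niches: int = 5
    niche_radius: float = 15.0
    niche_mean_dc: float = 4.0
    niche_mean_t: float = 10.0
    t_reg_fraction: float = 0.4
    min_niche_separation: float = 300.0
    n_vessels: int = 3
    n_genes: int = 30
    baseline_expression: float = 1.0
    gene_names: Optional[list[str]] = None
    niche_effects: dict = dc_field(default_factory=dict)  # (type, gene) -> fold
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.background_intensity.values()):
            raise ValidationError("background intensities must be >= 0")
        if not self.niche_radius > 0:
            raise ValidationError("niche_radius must be > 0")
        if self.min_niche_separation < 2 * self.niche_radius:
            raise ValidationError(
                "min_niche_separation must be >= 2 * niche_radius"
            )
        if any(f <= 0 for f in self.niche_effects.values()):
            raise ValidationError("niche-effect fold changes must be > 0")
        if self.gene_names is None:
            self.gene_names = [f"g{i:03d}" for i in range(self.n_genes)]
        if len(self.gene_names) != self.n_genes:
            raise ValidationError("gene_names length must equal n_genes")
        for (ct, gene) in self.niche_effects:
            if gene not in self.gene_names:
                raise ValidationError(f"niche effect on unknown gene '{gene}'")
            CellType(ct)  # raises on unknown type name

    @classmethod
    def from_json(cls, doc: dict) -> "TissueSimParams":
        doc = dict(doc)
        _check_keys(doc, set(cls.__dataclass_fields__), "tissue")
        if "field_size" in doc:
            doc["field_size"] = tuple(doc["field_size"])
        if "niche_effects" in doc:  # JSON encodes keys as "TYPE:gene"
            doc["niche_effects"] = {
                tuple(k.split(":", 1)): v for k, v in doc["niche_effects"].items()
            }
        return cls(**doc)


def _sample_niche_centers(
    params: TissueSimParams, rng: np.random.Generator, max_attempts: int = 10_000
) -> np.ndarray:
    w, h = params.field_size
    r = params.niche_radius
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < params.n_niches:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not place {params.n_niches} niches with separation "
                f"{params.min_niche_separation} in {max_attempts} attempts; "
                "reduce n_niches or enlarge the field"
            )
        attempts += 1
        c = np.array([rng.uniform(r, w - r), rng.uniform(r, h - r)])
        if all(
            np.hypot(*(c - prev)) >= params.min_niche_separation for prev in centers
        ):
            centers.append(c)
    return np.array(centers)


def simulate_tissue(
    params: TissueSimParams,
) -> tuple[CellTable, CountMatrix, VesselGeometry, list[PlantedNiche]]:
    """Generate a tissue cell map, gene counts, vessels and planted niches."""
    rng = np.random.default_rng(params.seed)
    w, h = params.field_size
    area_mm2 = w * h / 1e6

    centers = (
        _sample_niche_centers(params, rng)
        if params.n_niches
        else np.empty((0, 2))
    )

    rows = []
    planted: list[PlantedNiche] = []
    counter = 0

    def _add_cell(x: float, y: float, ct: str) -> str:
        nonlocal counter
        cid = f"c{counter:06d}"
        rows.append({"cell_id": cid, "x": x, "y": y, "cell_type": ct})
        counter += 1
        return cid

    for center in centers:
        n_dc = int(rng.poisson(params.niche_mean_dc))
        n_t = int(rng.poisson(params.niche_mean_t))
        n_treg = int(rng.binomial(n_t, params.t_reg_fraction))
        members = []
        comp: dict[str, int] = {}
        for ct, count in (
            ("DC", n_dc),
            ("T_REG", n_treg),
            ("T_CONV", n_t - n_treg),
        ):
            for _ in range(count):
                rho = params.niche_radius * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                members.append(
                    _add_cell(
                        center[0] + rho * np.cos(theta),
                        center[1] + rho * np.sin(theta),
                        ct,
                    )
                )
            if count:
                comp[ct] = count
        planted.append(
            PlantedNiche(
                center=(float(center[0]), float(center[1])),
                radius=params.niche_radius,
                member_cell_ids=members,
                composition=comp,
            )
        )

    for ct in sorted(params.background_intensity):
        lam = params.background_intensity[ct] * area_mm2
        for _ in range(int(rng.poisson(lam))):
            _add_cell(rng.uniform(0, w), rng.uniform(0, h), ct)

    cells = CellTable(df=pd.DataFrame(rows, columns=["cell_id", "x", "y", "cell_type"]))

    vessels = VesselGeometry(
        features=[
            Point(rng.uniform(0, w), rng.uniform(0, h))
            for _ in range(params.n_vessels)
        ]
    )

    # genes x cells Poisson counts; niche members of a matching type get the
    # fold-change multiplier on their mean
    n_cells = cells.n_cells
    lam = np.full((params.n_genes, n_cells), params.baseline_expression, dtype=float)
    gene_index = {g: i for i, g in enumerate(params.gene_names)}
    cell_index = {cid: j for j, cid in enumerate(cells.df["cell_id"])}
    cell_types = cells.df["cell_type"].to_numpy()
    for niche in planted:
        for cid in niche.member_cell_ids:
            j = cell_index[cid]
            for (ct, gene), fold in params.niche_effects.items():
                if cell_types[j] == ct:
                    lam[gene_index[gene], j] *= fold
    counts = CountMatrix(
        genes=list(params.gene_names),
        cells=list(cells.df["cell_id"]),
        X=sp.csr_matrix(rng.poisson(lam)),
    )
    return cells, counts, vessels, planted


# --- fixture suite -----------------------------------------------------------

#: repertoire conditions mimicking the postnatal trajectory: sparse clonality
#: just after birth, a strong expansion-and-sharing wave at PND7, and a
#: near-fully polyclonal adult repertoire
FIXTURE_REPERTOIRES = {
    "pnd4": dict(n_cells=800, p=0.92, sharing_rate=0.05, p_treg=0.45),
    "pnd7": dict(n_cells=800, p=0.55, sharing_rate=0.30, p_treg=0.50),
    "adult": dict(n_cells=800, p=0.96, sharing_rate=0.02, p_treg=0.30),
}

#: panel genes whose niche-conditional effects mirror the study's qualitative
#: findings: niche DCs up for Ccr7/Cd80/Pdcd1lg2/Cd274, niche T cells up for
#: Ikzf2 (Helios) and Cxcr3, niche DCs also up for the Cxcr3 ligand Cxcl10
FIXTURE_GENES = ["Ccr7", "Cd80", "Pdcd1lg2", "Cd274", "Ikzf2", "Cxcr3", "Cxcl10"]
FIXTURE_EFFECTS = {
    ("DC", "Ccr7"): 4.0,
    ("DC", "Cd80"): 3.0,
    ("DC", "Pdcd1lg2"): 3.0,
    ("DC", "Cd274"): 4.0,
    ("T_REG", "Ikzf2"): 3.0,
    ("T_CONV", "Ikzf2"): 3.0,
    ("T_REG", "Cxcr3"): 2.5,
    ("T_CONV", "Cxcr3"): 2.5,
    ("DC", "Cxcl10"): 3.0,
}


def _fixture_gene_panel(n_filler: int = 23) -> list[str]:
    return FIXTURE_GENES + [f"g{i:03d}" for i in range(n_filler)]


def _tissue_params(seed: int, n_niches: int) -> TissueSimParams:
    genes = _fixture_gene_panel()
    return TissueSimParams(
        field_size=(2000.0, 2000.0),
        n_niches=n_niches,
        niche_radius=15.0,
        niche_mean_dc=5.0,
        niche_mean_t=12.0,
        min_niche_separation=300.0,
        n_vessels=0,  # vessel layout is fixture-specific, added below
        n_genes=len(genes),
        gene_names=genes,
        niche_effects=dict(FIXTURE_EFFECTS),
        seed=seed,
    )


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Write the fixed fixture set and return a {filename: sha256} manifest.

    Three repertoires mimic the PND4 -> PND7 -> adult trajectory (increasing
    then collapsing expansion/sharing); a "neonatal-like" tissue has niches
    in vessel-free parenchyma, an "adult-like" tissue has every niche within
    close vessel proximity.  Byte-stable given the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    truth: dict = {"seed": seed, "repertoires": {}, "tissues": {}}
    files: list[Path] = []

    for name, cfg in FIXTURE_REPERTOIRES.items():
        sub_seed = int(master.integers(0, 2**31 - 1))
        params = RepertoireSimParams(
            clone_size_law="GEOMETRIC",
            subject_id=f"{name}_m1",
            timepoint=name.upper() if name != "adult" else "adult",
            seed=sub_seed,
            **cfg,
        )
        table, records = simulate_repertoire(params)
        path = out_dir / f"repertoire_{name}.tsv"
        write_repertoire(table, path)
        files.append(path)
        truth["repertoires"][name] = {
            "seed": sub_seed,
            "n_cells": params.n_cells,
            "n_clones": len(records),
            "n_expanded": sum(r.size > 1 for r in records),
            "n_shared": sum(r.category.value == "SHARED" for r in records),
        }

    for name, n_niches in (("neonatal", 8), ("adult", 4)):
        sub_seed = int(master.integers(0, 2**31 - 1))
        params = _tissue_params(sub_seed, n_niches)
        cells, counts, _, planted = simulate_tissue(params)
        rng = np.random.default_rng(sub_seed + 1)
        centers = np.array([p.center for p in planted])
        if name == "neonatal":
            # a few vessels, rejected within 250 µm of any niche center:
            # niches sit in parenchyma
            feats = []
            while len(feats) < 3:
                pt = np.array([rng.uniform(0, 2000), rng.uniform(0, 2000)])
                if np.hypot(*(centers - pt).T).min() > 250:
                    feats.append(Point(*pt))
        else:
            # adult-like: one vessel 20 µm from every niche center (within
            # the default 50 µm proximity radius)
            feats = [Point(c[0] + 20.0, c[1]) for c in centers]
        vessels = VesselGeometry(features=feats)

        stem = out_dir / f"tissue_{name}"
        paths = {
            "cells": Path(f"{stem}_cells.csv"),
            "mtx": Path(f"{stem}_counts.mtx"),
            "genes": Path(f"{stem}_genes.txt"),
            "cell_names": Path(f"{stem}_cellnames.txt"),
            "vessels": Path(f"{stem}_vessels.json"),
        }
        write_cell_table(cells, paths["cells"])
        write_counts_mtx(counts, paths["mtx"], paths["genes"], paths["cell_names"])
        write_vessels(vessels, paths["vessels"])
        files.extend(paths.values())
        truth["tissues"][name] = {
            "seed": sub_seed,
            "n_cells": cells.n_cells,
            "n_planted_niches": len(planted),
            "planted": [
                {
                    "center": [p.center[0], p.center[1]],
                    "composition": p.composition,
                    "n_members": len(p.member_cell_ids),
                }
                for p in planted
            ],
        }

    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, sort_keys=True, indent=1) + "\n")
    files.append(truth_path)

    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(files)
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest
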