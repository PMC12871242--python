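from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonalniche.types import CellTable, RepertoireTable


def make_repertoire(cells, subject_id="s1", timepoint="PND7") -> RepertoireTable:
    """Build a RepertoireTable from (cell_id, clone_id, lineage) triples."""
    return RepertoireTable(
        df=pd.DataFrame(
            [
                {
                    "cell_id": cid,
                    "subject_id": subject_id,
                    "timepoint": timepoint,
                    "clone_id": clone,
                    "lineage": lin,
                }
                for cid, clone, lin in cells
            ]
        )
    )


def random_repertoire(
    rng: np.random.Generator,
    max_clones: int = 50,
    max_size: int = 30,
    subject_id: str = "s1",
) -> RepertoireTable:
    """Random repertoire with i.i.d. clone sizes and lineage labels."""
    n_clones = int(rng.integers(1, max_clones + 1))
    rows = []
    counter = 0
    for c in range(n_clones):
        size = int(rng.integers(1, max_size + 1))
        for _ in range(size):
            rows.append(
                (f"cell{counter:05d}", f"cl{c:04d}", rng.choice(["TREG", "TCONV"]))
            )
            counter += 1
    return make_repertoire(rows, subject_id=subject_id)


def make_cells(points) -> CellTable:
    """Build a CellTable from (x, y, cell_type) triples or 4-tuples with id."""
    rows = []
    for i, p in enumerate(points):
        if len(p) == 4:
            cid, x, y, ct = p
        else:
            x, y, ct = p
            cid = f"c{i:05d}"
        rows.append({"cell_id": cid, "x": x, "y": y, "cell_type": ct})
    return CellTable(df=pd.DataFrame(rows))


def random_cells(
    rng: np.random.Generator, n: int, field: float = 1000.0, types=("DC", "T_CONV", "T_REG")
) -> CellTable:
    return make_cells(
        [
            (rng.uniform(0, field), rng.uniform(0, field), rng.choice(types))
            for _ in range(n)
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
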