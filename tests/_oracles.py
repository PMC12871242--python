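"""Independent reference implementations used as test oracles.

These are deliberately naive (brute force, exhaustive, closed form) and share
no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def brute_r20(sizes, fraction_threshold=Fraction(1, 5)):
    """Cumulative-sum R20 oracle with exact rational threshold arithmetic."""
    ordered = sorted(sizes, reverse=True)
    n_cells = sum(ordered)
    threshold = Fraction(fraction_threshold) * n_cells
    cum = 0
    for k, s in enumerate(ordered, start=1):
        cum += s
        if cum >= threshold:
            return k / len(ordered)
    raise AssertionError("unreachable: cumulative sum always reaches total")


def groupby_clones(cell_rows):
    """Brute-force clone aggregation: rows of (clone_id, lineage)."""
    out = {}
    for clone_id, lineage in cell_rows:
        rec = out.setdefault(clone_id, {"TREG": 0, "TCONV": 0})
        rec[lineage] += 1
    result = {}
    for cid, rec in out.items():
        if rec["TREG"] and rec["TCONV"]:
            cat = "SHARED"
        elif rec["TCONV"] == 0:
            cat = "TREG_ONLY"
        else:
            cat = "TCONV_ONLY"
        result[cid] = (rec["TREG"] + rec["TCONV"], rec["TREG"], rec["TCONV"], cat)
    return result


def reference_dbscan(xy, cell_ids, eps, min_samples):
    """Naive O(n^2) DBSCAN with the deterministic border tie rule.

    Returns a list of member-id sets, ordered by the canonical cluster rank
    (lexicographic min (x, y, cell_id) over core members).  Border points go
    to the cluster of their nearest core neighbor, distance ties to the
    lower-ranked cluster.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n == 0:
        return []
    D = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    adj = D <= eps
    core = adj.sum(axis=1) >= min_samples

    # BFS connected components over core points
    comp = [-1] * n
    n_comp = 0
    for start in range(n):
        if not core[start] or comp[start] != -1:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            i = stack.pop()
            for j in range(n):
                if core[j] and adj[i, j] and comp[j] == -1:
                    comp[j] = n_comp
                    stack.append(j)
        n_comp += 1

    def rank_key(c):
        return min(
            (xy[i, 0], xy[i, 1], str(cell_ids[i]))
            for i in range(n)
            if core[i] and comp[i] == c
        )

    order = sorted(range(n_comp), key=rank_key)
    rank = {c: r for r, c in enumerate(order)}

    clusters = [set() for _ in range(n_comp)]
    for i in range(n):
        if core[i]:
            clusters[rank[comp[i]]].add(cell_ids[i])
    for i in range(n):
        if core[i]:
            continue
        candidates = [
            (D[i, j], rank[comp[j]]) for j in range(n) if core[j] and adj[i, j]
        ]
        if candidates:
            _, r = min(candidates)
            clusters[r].add(cell_ids[i])
    return clusters


def brute_nearest(query_xy, ref_xy):
    """All-pairs minimum distance from each query point to the reference set."""
    out = []
    for q in query_xy:
        out.append(min(np.hypot(q[0] - r[0], q[1] - r[1]) for r in ref_xy))
    return np.array(out)


def point_in_polygon(pt, vertices):
    """Ray-casting point-in-polygon test (vertices as (x, y) list, open ring)."""
    x, y = pt
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_cross > x:
                inside = not inside
    return inside


def shoelace(vertices):
    """Polygon area by the shoelace formula."""
    s = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2


def bh_stepup(pvals):
    """Hand-rolled Benjamini-Hochberg step-up, preserving input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
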