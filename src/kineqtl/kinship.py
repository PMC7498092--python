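"""Pedigree-based additive relationship (numerator) matrix.

The scan uses the A-matrix of the study samples as the error covariance of
the association model. The pedigree is truncated to a fixed number of
ancestral generations (default 4) before the tabular recursion: ancestors
beyond the horizon are treated as unknown founders. Because the scan's
statistics are invariant to a global rescaling of the covariance, the
conventional A (diagonal >= 1) is returned rather than the kinship
coefficient matrix A/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNKNOWN = "0"


def _as_str(ped: pd.DataFrame) -> pd.DataFrame:
    ped = ped[["animal", "sire", "dam"]].copy()
    for c in ped.columns:
        ped[c] = ped[c].astype(str)
    return ped


def truncate_pedigree(ped: pd.DataFrame, focal_ids: list[str],
                      n_gen: int = 4) -> pd.DataFrame:
    """Keep each focal animal plus ancestors within ``n_gen`` parent steps.

    The horizon is counted per focal animal (parent steps, not calendar
    generations). Ancestors sitting exactly at the horizon become founders:
    their own parents are recoded unknown. Animals reachable only beyond the
    horizon are dropped.

    Returns a pedigree with one row per retained animal.
    """
    ped = _as_str(ped)
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples()}
    missing = [f for f in focal_ids if str(f) not in parents]
    if missing:
        raise ValueError(f"focal ids not in pedigree: {missing[:5]}")

    # depth = minimal parent-step distance from any focal animal
    depth: dict[str, int] = {}
    frontier = [str(f) for f in focal_ids]
    for f in frontier:
        depth[f] = 0
    d = 0
    while frontier and d < n_gen:
        nxt = []
        for a in frontier:
            for p in parents.get(a, (UNKNOWN, UNKNOWN)):
                if p != UNKNOWN and p in parents and p not in depth:
                    depth[p] = d + 1
                    nxt.append(p)
        frontier = nxt
        d += 1

    rows = []
    for a, dep in depth.items():
        s, dm = parents.get(a, (UNKNOWN, UNKNOWN))
        if dep >= n_gen:  # horizon: founderize
            s = dm = UNKNOWN
        else:
            if s not in depth:
                s = UNKNOWN
            if dm not in depth:
                dm = UNKNOWN
        rows.append((a, s, dm))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


def _topological_order(ped: pd.DataFrame) -> list[str]:
    """Parents before offspring; raises on cycles, naming one member."""
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples()}
    order: list[str] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    for root in parents:
        if state.get(root) == 1:
            continue
        stack = [(root, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise ValueError(f"pedigree cycle detected involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for p in parents.get(node, (UNKNOWN, UNKNOWN)):
                if p != UNKNOWN and p in parents:
                    if state.get(p) == 0:
                        raise ValueError(
                            f"pedigree cycle detected involving {p!r}")
                    if state.get(p) != 1:
                        stack.append((p, False))
    return order


def a_matrix(ped: pd.DataFrame, focal_ids: list[str]) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    a(i,i) = 1 + a(sire_i, dam_i)/2; a(i,j) = (a(j,sire_i) + a(j,dam_i))/2
    for previously processed j; unknown parents contribute 0. Returns the
    focal x focal submatrix as a DataFrame indexed by focal ids.
    """
    ped = _as_str(ped)
    order = _topological_order(ped)
    idx = {a: i for i, a in enumerate(order)}
    parents = {r.animal: (r.sire, r.dam) for r in ped.itertuples()}
    n = len(order)
    A = np.zeros((n, n))
    for i, a in enumerate(order):
        s, d = parents[a]
        si = idx.get(s, -1) if s != UNKNOWN else -1
        di = idx.get(d, -1) if d != UNKNOWN else -1
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            row /= 2.0
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (A[si, di] / 2.0 if si >= 0 and di >= 0 else 0.0)
    focal = [str(f) for f in focal_ids]
    missing = [f for f in focal if f not in idx]
    if missing:
        raise ValueError(f"focal ids not in pedigree: {missing[:5]}")
    sel = [idx[f] for f in focal]
    return pd.DataFrame(A[np.ix_(sel, sel)], index=focal, columns=focal)


def kinship_from_pedigree(ped: pd.DataFrame, focal_ids: list[str],
                          n_gen: int = 4) -> pd.DataFrame:
    """Truncate to ``n_gen`` ancestral generations, then build A."""
    return a_matrix(truncate_pedigree(ped, list(focal_ids), n_gen), focal_ids)
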