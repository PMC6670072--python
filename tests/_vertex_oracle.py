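"""Exhaustive vertex-enumeration oracle for tiny flux polytopes.

Independent of the solver path under test: vertices of
{v : S v = 0, lb <= v <= ub, (optional linear inequalities)} are enumerated
by brute force over active-constraint subsets and solved with numpy.  Because
sum(|v|) is piecewise linear, its minimum over the polytope is attained at a
vertex of the arrangement obtained by adding the v_i = 0 hyperplanes, which
are included in the candidate set.  FVA bounds (linear objectives) are
attained at polytope vertices; the total-flux lock sum(v) <= T is only valid
as a linear facet for irreversible networks, so use the oracle's FVA mode on
networks with lb >= 0.
"""

from __future__ import annotations

import itertools

import numpy as np

_TOL = 1e-9


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       ineq: list[tuple[np.ndarray, float]] | None = None
                       ) -> np.ndarray:
    """All vertices of {S v = 0, lb <= v <= ub, a.v <= b for (a, b) in ineq},
    augmented with the coordinate hyperplanes v_i = 0."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    ineq = ineq or []

    candidates: list[tuple[np.ndarray, float]] = []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        for val in {lb[i], ub[i], 0.0} if lb[i] < 0.0 < ub[i] else {lb[i], ub[i]}:
            if np.isfinite(val):
                candidates.append((e.copy(), float(val)))
    for a, bval in ineq:
        candidates.append((np.asarray(a, dtype=float), float(bval)))

    rank_S = np.linalg.matrix_rank(S) if S.size else 0
    need = n - rank_S
    verts: list[np.ndarray] = []
    for combo in itertools.combinations(range(len(candidates)), need):
        A = np.vstack([S] + [candidates[i][0][None, :] for i in combo])
        b = np.concatenate([np.zeros(S.shape[0]),
                            [candidates[i][1] for i in combo]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > 1e-7:
            continue
        if np.any(v < lb - _TOL) or np.any(v > ub + _TOL):
            continue
        if any(a @ v > bval + _TOL for a, bval in ineq):
            continue
        if not any(np.allclose(v, w, atol=1e-7) for w in verts):
            verts.append(v)
    return np.array(verts)


def oracle_pfba(S, lb, ub) -> tuple[float, np.ndarray]:
    """Minimum of sum(|v|) over the flux polytope and one attaining vertex."""
    verts = enumerate_vertices(S, lb, ub)
    if len(verts) == 0:
        raise ValueError("infeasible or unbounded tiny network")
    sums = np.abs(verts).sum(axis=1)
    k = int(np.argmin(sums))
    return float(sums[k]), verts[k]


def oracle_fva(S, lb, ub, total_flux_cap: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction min/max over the polytope cut by sum(v) <= cap.

    Only valid for irreversible networks (lb >= 0), where total flux is
    linear.
    """
    lb = np.asarray(lb, dtype=float)
    if np.any(lb < 0):
        raise ValueError("FVA oracle requires an irreversible network")
    n = np.atleast_2d(S).shape[1]
    verts = enumerate_vertices(S, lb, ub,
                               ineq=[(np.ones(n), total_flux_cap)])
    if len(verts) == 0:
        raise ValueError("infeasible under the total-flux cap")
    return verts.min(axis=0), verts.max(axis=0)
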