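"""Independent brute-force oracles used to cross-check the LP path.

The enumerator never calls scipy.optimize: it enumerates basic solutions of
{S v = 0, lb <= v <= ub} directly (every vertex of a bounded polyhedron has
at least n - rank(S) variables pinned at a bound), so LP results can be
checked against an exhaustive search on small models.

For the minimal-total-|flux| check the candidate set is enlarged: sum|v| is
linear only per sign-orthant, so its minimum over the optimal face sits at a
basic point of the arrangement that also includes the hyperplanes v_j = 0.
Passing ``fix_zero=True`` therefore pins variables at lb, 0, or ub.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_basic_points(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    extra_eq: tuple[np.ndarray, np.ndarray] | None = None,
    fix_zero: bool = False,
    tol: float = 1e-9,
) -> np.ndarray:
    """All basic feasible points of {v : S v = 0, [extra_eq], lb <= v <= ub}.

    Only usable for small n (combinatorial). Bounds must be finite.
    """
    A = np.atleast_2d(S)
    b = np.zeros(A.shape[0])
    if extra_eq is not None:
        rows, rhs = extra_eq
        A = np.vstack([A, np.atleast_2d(rows)])
        b = np.concatenate([b, np.atleast_1d(rhs)])
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    n_fixed = n - rank
    levels = (0, 1, 2) if fix_zero else (0, 1)
    points: list[np.ndarray] = []
    seen: set[tuple] = set()
    for fixed in itertools.combinations(range(n), n_fixed):
        fixed = list(fixed)
        free = [j for j in range(n) if j not in fixed]
        A_free = A[:, free]
        A_fixed = A[:, fixed]
        for choice in itertools.product(levels, repeat=n_fixed):
            v = np.empty(n)
            v[fixed] = [
                (lb[j], ub[j], 0.0)[c] for j, c in zip(fixed, choice)
            ]
            if free:
                rhs = b - A_fixed @ v[fixed]
                sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(A @ v - b)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            key = tuple(np.round(v, 8))
            if key not in seen:
                seen.add(key)
                points.append(v)
    return np.array(points)


def fba_oracle(model) -> float:
    """Max objective flux by exhaustive vertex enumeration."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    verts = enumerate_basic_points(S, lb, ub)
    idx = model.reaction_ids.index(model.objective_id)
    return float(verts[:, idx].max())


def pfba_oracle(model, z_star: float) -> float:
    """Exact min sum|v| over the face {objective flux = z*}, by enumerating
    basic points of the face arrangement including the v_j = 0 hyperplanes."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    idx = model.reaction_ids.index(model.objective_id)
    row = np.zeros(len(model.reactions))
    row[idx] = 1.0
    pts = enumerate_basic_points(
        S, lb, ub, extra_eq=(row, np.array([z_star])), fix_zero=True
    )
    return float(np.abs(pts).sum(axis=1).min())


def pfba_vertex_oracle(model, z_star: float) -> float:
    """Min sum|v| over face *vertices* only: an upper bound on the true
    parsimonious total (cheaper; exact when flux signs are fixed on the face)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    idx = model.reaction_ids.index(model.objective_id)
    row = np.zeros(len(model.reactions))
    row[idx] = 1.0
    pts = enumerate_basic_points(S, lb, ub, extra_eq=(row, np.array([z_star])))
    return float(np.abs(pts).sum(axis=1).min())
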