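"""Flux computation: FBA, parsimonious FBA, and alternative-optima sampling.

All linear programs are solved through a single backend contract,
:func:`solve_lp`, currently backed by HiGHS via :func:`scipy.optimize.linprog`.

``fba`` maximizes the objective (biomass) flux subject to steady state
``S v = 0`` and the flux bounds. ``pfba_flux`` then fixes the objective at
its optimum and minimizes the total absolute flux, the standard parsimonious
second stage, via the usual split into non-negative forward and backward
components. ``sample_alternative_optima`` characterizes the optimal face by
repeatedly maximizing random (seeded, i.i.d. standard normal) objective
vectors at fixed biomass, yielding per-reaction means and standard
deviations over the alternative optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .model import MetabolicModel

__all__ = [
    "FluxDistribution",
    "AltOptimaSample",
    "solve_lp",
    "fba",
    "pfba_flux",
    "sample_alternative_optima",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS_MAP = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class FluxDistribution:
    """Reaction fluxes (mmol gDW^-1 h^-1) with the achieved objective."""

    fluxes: dict[str, float]
    objective_value: float
    status: str

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def total_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


@dataclass
class AltOptimaSample:
    """A set of alternative optimal flux distributions and their moments."""

    samples: list[FluxDistribution]
    mean: dict[str, float]
    sd: dict[str, float]
    n: int
    seed: int


def solve_lp(
    c: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    maximize: bool = True,
) -> tuple[str, np.ndarray | None, float]:
    """Solve max (or min) c.v s.t. S v = 0, A_ub v <= b_ub, lb <= v <= ub.

    Returns (status, solution vector or None, objective value in the
    requested sense; nan unless optimal).
    """
    sign = -1.0 if maximize else 1.0
    res = scipy.optimize.linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    status = _STATUS_MAP.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return status, None, float("nan")
    return status, res.x, float(sign * res.fun)


def _distribution(model: MetabolicModel, x: np.ndarray, status: str) -> FluxDistribution:
    fluxes = dict(zip(model.reaction_ids, (float(v) for v in x)))
    return FluxDistribution(fluxes, fluxes[model.objective_id], status)


def fba(model: MetabolicModel) -> FluxDistribution:
    """Maximize the objective reaction's flux at steady state."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_id)] = 1.0
    status, x, _ = solve_lp(c, S, lb, ub)
    if status != OPTIMAL:
        return FluxDistribution({}, float("nan"), status)
    return _distribution(model, x, status)


def _objective_floor(z_star: float, tolerance: float) -> float:
    # keep the floor strictly attainable whatever the sign of the optimum
    return (1.0 - tolerance) * z_star if z_star >= 0 else (1.0 + tolerance) * z_star


def pfba_flux(model: MetabolicModel, tolerance: float = 1e-7) -> FluxDistribution:
    """Parsimonious FBA: minimal total |flux| among (near-)optimal solutions.

    Stage 1 obtains the FBA optimum z*; stage 2 requires the objective flux
    to stay >= (1 - tolerance) z* and minimizes sum_r |v_r| using the split
    v = f - b with f, b >= 0.
    """
    stage1 = fba(model)
    if stage1.status != OPTIMAL:
        return stage1
    z_star = stage1.objective_value

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    obj_idx = model.reaction_ids.index(model.objective_id)

    # variables: [f; b], v = f - b
    S2 = np.hstack([S, -S])
    eye = np.eye(n)
    rows = [np.hstack([eye, -eye]), np.hstack([-eye, eye])]
    rhs = [ub, -lb]
    floor_row = np.zeros(2 * n)
    floor_row[obj_idx] = -1.0
    floor_row[n + obj_idx] = 1.0
    rows.append(floor_row[None, :])
    rhs.append(np.array([-_objective_floor(z_star, tolerance)]))
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)

    c = np.ones(2 * n)
    bound_mag = np.maximum(np.abs(lb), np.abs(ub))
    status, x, _ = solve_lp(
        c, S2,
        lb=np.zeros(2 * n),
        ub=np.concatenate([bound_mag, bound_mag]),
        A_ub=A_ub, b_ub=b_ub,
        maximize=False,
    )
    if status != OPTIMAL:
        return FluxDistribution({}, float("nan"), status)
    v = x[:n] - x[n:]
    return _distribution(model, v, OPTIMAL)


def sample_alternative_optima(
    model: MetabolicModel,
    n: int = 100,
    seed: int = 0,
    tolerance: float = 1e-7,
) -> AltOptimaSample:
    """Sample vertices of the optimal face under random objective vectors.

    With the biomass flux pinned at its optimum, each draw maximizes a
    random linear objective (i.i.d. standard normal coefficients), landing
    on a vertex of the face of alternative optima. Identical seeds give
    bit-identical output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    stage1 = fba(model)
    if stage1.status != OPTIMAL:
        raise ValueError(f"model is {stage1.status}; cannot sample alternative optima")
    z_star = stage1.objective_value

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n_rxn = len(model.reactions)
    obj_idx = model.reaction_ids.index(model.objective_id)
    floor_row = np.zeros((1, n_rxn))
    floor_row[0, obj_idx] = -1.0
    b_floor = np.array([-_objective_floor(z_star, tolerance)])

    rng = np.random.default_rng(seed)
    samples: list[FluxDistribution] = []
    for _ in range(n):
        c = rng.standard_normal(n_rxn)
        status, x, _ = solve_lp(c, S, lb, ub, A_ub=floor_row, b_ub=b_floor)
        if status != OPTIMAL:
            raise RuntimeError(f"alternative-optima subproblem {status}")
        samples.append(_distribution(model, x, OPTIMAL))

    matrix = np.array([[s.fluxes[r] for r in model.reaction_ids] for s in samples])
    mean = dict(zip(model.reaction_ids, matrix.mean(axis=0)))
    ddof = 1 if n > 1 else 0
    sd = dict(zip(model.reaction_ids, matrix.std(axis=0, ddof=ddof)))
    return AltOptimaSample(samples, mean, sd, n, seed)
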