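"""Expression-proportional flux bounds (the ``fullconstrain`` transform).

Every gene-associated reaction receives a flux capacity proportional to the
RPKM of its highest-expressed gene: the expression is rounded up to the next
multiple of the granularity and scaled by the proportionality constant ``k``
(mmol gDW^-1 h^-1 per RPKM). Irreversible reactions are capped in their
allowed direction; reversible reactions are capped symmetrically in both
directions, reading the expression level as an enzyme-capacity ceiling.
Capacities never widen pre-existing bounds, and reactions without any gene
association keep their bounds untouched. A reaction whose genes are all
silent (0 RPKM) is closed outright.

``calibrate_k`` inverts the transform: it finds by bisection the constant
``k`` at which the constrained model's optimal growth matches an observed
growth rate, exploiting that optimal growth is non-decreasing in ``k``.
"""

from __future__ import annotations

import logging

from .config import PyTargConfig
from .expression import ExpressionProfile, reaction_expression, round_up_to_granularity
from .model import MetabolicModel
from .solver import OPTIMAL, fba

logger = logging.getLogger(__name__)

__all__ = ["fullconstrain", "calibrate_k", "CalibrationError"]


class CalibrationError(RuntimeError):
    """The observed growth rate cannot be reached for any k in range."""


def fullconstrain(
    model: MetabolicModel,
    profile: ExpressionProfile,
    config: PyTargConfig | None = None,
) -> MetabolicModel:
    """Return a copy of ``model`` with expression-derived flux capacities."""
    config = config or PyTargConfig()
    out = model.copy()
    for r in out.reactions:
        if not r.genes:
            continue
        expr = round_up_to_granularity(
            reaction_expression(r, profile), config.granularity
        )
        cap = config.k * expr
        if r.lower_bound >= 0:  # irreversible, forward
            r.lower_bound, r.upper_bound = 0.0, min(r.upper_bound, cap)
        elif r.upper_bound <= 0:  # irreversible, backward
            r.lower_bound, r.upper_bound = max(r.lower_bound, -cap), 0.0
        else:  # reversible: capacity limits both directions
            r.lower_bound = max(r.lower_bound, -cap)
            r.upper_bound = min(r.upper_bound, cap)
    return out


def calibrate_k(
    model: MetabolicModel,
    profile: ExpressionProfile,
    observed_growth: float,
    config: PyTargConfig | None = None,
    k_min: float = 1e-6,
    k_max: float = 1.0,
    max_iter: int = 80,
) -> float:
    """Bisect for the k reproducing an observed growth rate (h^-1)."""
    config = config or PyTargConfig()
    tol = config.solver_tolerance

    def growth(k: float) -> float:
        sol = fba(fullconstrain(model, profile, config.replace(k=k)))
        return sol.objective_value if sol.status == OPTIMAL else 0.0

    if observed_growth <= 0:
        logger.warning(
            "observed growth %g <= 0; returning the lower search bound k=%g",
            observed_growth, k_min,
        )
        return k_min
    hi_growth = growth(k_max)
    if hi_growth < observed_growth - tol:
        raise CalibrationError(
            f"growth at k={k_max} is {hi_growth:.6g} < observed {observed_growth:.6g}; "
            "the observed rate is unreachable under these constraints"
        )
    lo, hi = k_min, k_max
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = growth(mid)
        if abs(g - observed_growth) <= tol:
            return mid
        if g < observed_growth:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)
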