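"""Reaction-targeting analyses: block ratios, group screens, and the greedy
personalized target-set search.

``block`` emulates strong but incomplete inhibition of one or more reactions:
each targeted reaction is throttled to a fraction (default 10%) of its
baseline parsimonious flux, the model is re-solved, and the objective ratio
after/before is reported. A ratio equal to the fraction means growth is
fully coupled to a targeted reaction; a ratio of 1 means alternative
pathways fully compensate.

``personal`` searches for a small reaction set whose simultaneous throttling
halves the target cell's predicted growth while sparing a reference cell.
Candidates are ranked once, by decreasing difference in baseline flux usage
between the two cells, then tried greedily: a candidate is kept only when
the target's cumulative relative growth falls below ``single_threshold``
and exceeds the reference's by more than ``selectivity_margin``; the search
stops when the target's relative growth reaches ``stop_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PyTargConfig
from .model import MetabolicModel, Reaction
from .solver import OPTIMAL, FluxDistribution, pfba_flux

__all__ = ["BlockResult", "TraceRecord", "TargetSet", "block", "screen_targets", "personal"]


@dataclass
class BlockResult:
    """Outcome of throttling a reaction set."""

    targeted: list[str]
    ratio: float
    baseline_objective: float
    blocked_objective: float


@dataclass
class TraceRecord:
    """One candidate decision in the greedy search."""

    reaction_id: str
    target_ratio_after: float
    reference_ratio_after: float
    accepted: bool


@dataclass
class TargetSet:
    """Accepted reactions, in acceptance order, with the full decision trace."""

    accepted: list[str]
    trace: list[TraceRecord] = field(default_factory=list)
    final_target_ratio: float = 1.0
    final_reference_ratio: float = 1.0
    converged: bool = False


def _throttle(reaction: Reaction, baseline_flux: float, fraction: float) -> None:
    """Constrain a reaction to ``fraction`` times its baseline flux, in place."""
    v = baseline_flux
    if v > 0:
        reaction.upper_bound = fraction * v
        reaction.lower_bound = min(reaction.lower_bound, fraction * v)
    elif v < 0:
        reaction.lower_bound = fraction * v
        reaction.upper_bound = max(reaction.upper_bound, fraction * v)
    else:
        reaction.lower_bound = reaction.upper_bound = 0.0


def _blocked_model(
    model: MetabolicModel,
    baseline: FluxDistribution,
    targets: list[str],
    fraction: float,
) -> MetabolicModel:
    out = model.copy()
    for t in targets:
        _throttle(out.reaction(t), baseline.fluxes[t], fraction)
    return out


def block(
    model: MetabolicModel,
    baseline: FluxDistribution,
    targets: list[str],
    fraction: float = 0.1,
    tolerance: float = 1e-7,
) -> BlockResult:
    """Throttle ``targets`` to ``fraction`` of baseline flux and re-solve.

    ``baseline`` must be the parsimonious flux distribution of ``model``;
    the ratio is the re-solved objective over the baseline objective. A
    blocked model that cannot grow at all yields ratio 0.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if baseline.status != OPTIMAL:
        raise ValueError("baseline distribution is not optimal")
    known = set(model.reaction_ids)
    unknown = [t for t in targets if t not in known]
    if unknown:
        raise ValueError(f"unknown target reaction(s): {unknown}")

    blocked = pfba_flux(_blocked_model(model, baseline, list(targets), fraction),
                        tolerance=tolerance)
    blocked_obj = blocked.objective_value if blocked.status == OPTIMAL else 0.0
    ratio = blocked_obj / baseline.objective_value if baseline.objective_value > 0 else 0.0
    return BlockResult(list(targets), ratio, baseline.objective_value, blocked_obj)


def screen_targets(
    target_models: list[tuple[str, MetabolicModel]],
    reference_models: list[tuple[str, MetabolicModel]],
    reactions: list[str],
    config: PyTargConfig | None = None,
):
    """Per-reaction block ratios across two model groups, with a Welch test.

    Each model (already expression-constrained) contributes one block ratio
    per reaction; reactions are compared between groups by a Welch t-test on
    the ratio vectors and the table is sorted by ascending p-value.

    Returns a :class:`pandas.DataFrame` with one ratio column per model id,
    group means, mean difference (reference - target; positive = stronger
    effect on the target group), t and p.
    """
    import pandas as pd

    from .diffstats import welch_t

    config = config or PyTargConfig()
    if len(target_models) < 2 or len(reference_models) < 2:
        raise ValueError("need at least 2 models per group for the screen")

    baselines = {
        mid: pfba_flux(m, tolerance=config.solver_tolerance)
        for mid, m in [*target_models, *reference_models]
    }
    bad = [mid for mid, b in baselines.items() if b.status != OPTIMAL]
    if bad:
        raise ValueError(f"models with non-optimal baseline: {bad}")

    rows = []
    for rxn in reactions:
        ratios = {}
        for mid, m in [*target_models, *reference_models]:
            ratios[mid] = block(
                m, baselines[mid], [rxn],
                fraction=config.block_fraction,
                tolerance=config.solver_tolerance,
            ).ratio
        tgt = [ratios[mid] for mid, _ in target_models]
        ref = [ratios[mid] for mid, _ in reference_models]
        t, p = welch_t(tgt, ref)
        rows.append(
            {
                "reaction_id": rxn,
                **ratios,
                "mean_target": sum(tgt) / len(tgt),
                "mean_reference": sum(ref) / len(ref),
                "mean_difference": sum(ref) / len(ref) - sum(tgt) / len(tgt),
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def _rank_candidates(
    target: MetabolicModel,
    v_target: FluxDistribution,
    v_reference: FluxDistribution,
    reference_ids: set[str],
    config: PyTargConfig,
) -> list[str]:
    def score(rid: str) -> float:
        vt, vr = v_target.fluxes[rid], v_reference.fluxes[rid]
        return (vt - vr) if config.signed_ranking else (abs(vt) - abs(vr))

    candidates = [
        r.id
        for r in target.reactions
        if r.id in reference_ids
        and r.id != target.objective_id
        and not (v_target.fluxes[r.id] == 0.0 and v_reference.fluxes[r.id] == 0.0)
    ]
    return sorted(candidates, key=lambda rid: (-score(rid), rid))


def personal(
    target: MetabolicModel,
    reference: MetabolicModel,
    config: PyTargConfig | None = None,
) -> TargetSet:
    """Greedy search for a selective growth-halving reaction set.

    Both models must already be expression-constrained and able to grow.
    Throttling always refers to each model's own *initial* parsimonious
    flux; kept constraints accumulate, and relative growth is cumulative.
    Candidates with zero baseline flux in both models are skipped (they
    cannot change either ratio).
    """
    config = config or PyTargConfig()
    tol = config.solver_tolerance
    base_t = pfba_flux(target, tolerance=tol)
    base_r = pfba_flux(reference, tolerance=tol)
    if base_t.status != OPTIMAL or base_t.objective_value <= 0:
        raise ValueError("target model is infeasible or cannot grow")
    if base_r.status != OPTIMAL or base_r.objective_value <= 0:
        raise ValueError("reference model is infeasible or cannot grow")

    ranked = _rank_candidates(target, base_t, base_r, set(reference.reaction_ids), config)

    kept: list[str] = []
    trace: list[TraceRecord] = []
    cur_t_ratio, cur_r_ratio = 1.0, 1.0

    def ratios_with(targets: list[str]) -> tuple[float, float]:
        rt = block(target, base_t, targets, config.block_fraction, tol)
        rr = block(reference, base_r, targets, config.block_fraction, tol)
        return rt.ratio, rr.ratio

    converged = False
    for rid in ranked:
        t_ratio, r_ratio = ratios_with(kept + [rid])
        accept = (
            t_ratio < config.single_threshold
            and (r_ratio - t_ratio) > config.selectivity_margin
        )
        trace.append(TraceRecord(rid, t_ratio, r_ratio, accept))
        if accept:
            kept.append(rid)
            cur_t_ratio, cur_r_ratio = t_ratio, r_ratio
            if cur_t_ratio <= config.stop_ratio:
                converged = True
                break
    return TargetSet(kept, trace, cur_t_ratio, cur_r_ratio, converged)
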