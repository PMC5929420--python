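"""Deterministic toy metabolic networks and matched expression profiles.

These fixtures stand in for a genome-scale human reconstruction plus
measured RNA-seq profiles, at desk scale. Each named scenario isolates one
coupling regime the targeting analyses distinguish:

* ``CHAIN3`` — a linear uptake -> conversion -> biomass chain: growth fully
  coupled to the single gene-associated reaction.
* ``PARALLEL`` — two redundant gene-associated routes under a shared uptake
  limit: alternative optima, full compensation when one route is throttled.
* ``SELECTIVE`` — biomass needs two precursors; one can be imported by a
  transporter or synthesized internally. A target cell that does not express
  the transporter gene is fully dependent on synthesis, while the reference
  cell can import — the minimal mechanism behind a therapeutic window (as
  with cholesterol uptake versus biosynthesis in cells lacking a functional
  sterol transporter).
* ``CYCLE`` — PARALLEL plus a stoichiometrically balanced futile cycle that
  a parsimonious solution must leave idle.
* ``RANDOM`` — a seeded sparse network with a planted feasible chain, for
  property tests at configurable size.

Fixture bounds all bracket zero (no forced maintenance fluxes), so a
throttled model always retains the proportionally scaled baseline solution
and block ratios cannot fall below the throttle fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionProfile
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = ["SCENARIOS", "FixtureScenario", "make_model", "make_profiles"]

SCENARIOS = ("CHAIN3", "PARALLEL", "SELECTIVE", "CYCLE", "RANDOM")


@dataclass(frozen=True)
class FixtureScenario:
    name: str
    seed: int = 0
    size: int = 30

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")
        if self.size < 6:
            raise ValueError("RANDOM size must be >= 6")


def _rxn(rid, stoich, lb, ub, genes=()):
    return Reaction(rid, dict(stoich), lb, ub, list(genes))


def _chain3() -> MetabolicModel:
    return MetabolicModel(
        [Metabolite("A"), Metabolite("B")],
        [
            _rxn("EX_A", {"A": -1}, -10.0, DEFAULT_BOUND),
            _rxn("R1", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, ["g1"]),
            _rxn("BIOMASS", {"B": -1}, 0.0, DEFAULT_BOUND),
        ],
        "BIOMASS",
        id="CHAIN3",
    )


def _parallel() -> MetabolicModel:
    # uptake-limited so the two routes share a fixed total: alternative optima
    return MetabolicModel(
        [Metabolite("A"), Metabolite("B")],
        [
            _rxn("EX_A", {"A": -1}, -0.108, DEFAULT_BOUND),
            _rxn("R1", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, ["g1"]),
            _rxn("R2", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, ["g2"]),
            _rxn("BIOMASS", {"B": -1}, 0.0, DEFAULT_BOUND),
        ],
        "BIOMASS",
        id="PARALLEL",
    )


def _selective() -> MetabolicModel:
    # biomass needs B and C; C arrives by transport (gene gT) or by a
    # costlier internal synthesis (gene gS, consuming 2 A per C)
    return MetabolicModel(
        [Metabolite(m) for m in ("A", "B", "C", "Cext")],
        [
            _rxn("EX_A", {"A": -1}, -10.0, DEFAULT_BOUND),
            _rxn("EX_Cext", {"Cext": -1}, -10.0, DEFAULT_BOUND),
            _rxn("R1", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, ["g1"]),
            _rxn("T", {"Cext": -1, "C": 1}, 0.0, DEFAULT_BOUND, ["gT"]),
            _rxn("S", {"A": -2, "C": 1}, 0.0, DEFAULT_BOUND, ["gS"]),
            _rxn("BIOMASS", {"B": -1, "C": -1}, 0.0, DEFAULT_BOUND),
        ],
        "BIOMASS",
        id="SELECTIVE",
    )


def _cycle() -> MetabolicModel:
    m = _parallel()
    m.metabolites.append(Metabolite("D"))
    m.reactions.extend(
        [
            _rxn("C1", {"B": -1, "D": 1}, 0.0, DEFAULT_BOUND),
            _rxn("C2", {"D": -1, "B": 1}, 0.0, DEFAULT_BOUND),
        ]
    )
    m.id = "CYCLE"
    m.validate()
    return m


def _random(seed: int, size: int) -> MetabolicModel:
    rng = np.random.default_rng(seed)
    n_chain = max(2, size // 4)
    mets = [Metabolite(f"M{i}") for i in range(n_chain + 1)]
    reactions = [
        _rxn("EX_M0", {"M0": -1}, -10.0, DEFAULT_BOUND),
        *[
            _rxn(f"R{i}", {f"M{i}": -1, f"M{i + 1}": 1}, 0.0, DEFAULT_BOUND, [f"g{i}"])
            for i in range(n_chain)
        ],
        _rxn("BIOMASS", {f"M{n_chain}": -1}, 0.0, DEFAULT_BOUND),
    ]
    n_extra = size - len(reactions)
    for j in range(max(0, n_extra)):
        a, b = rng.choice(n_chain + 1, size=2, replace=False)
        coef_a, coef_b = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        reversible = bool(rng.random() < 0.3)
        genes = [f"x{j}"] if rng.random() < 0.8 else []
        reactions.append(
            _rxn(
                f"X{j}",
                {f"M{a}": -coef_a, f"M{b}": coef_b},
                -DEFAULT_BOUND if reversible else 0.0,
                DEFAULT_BOUND,
                genes,
            )
        )
    return MetabolicModel(mets, reactions, "BIOMASS", id=f"RANDOM_s{seed}_n{size}")


def make_model(scenario: FixtureScenario) -> MetabolicModel:
    """Build the scenario's model; named scenarios are seed-independent."""
    if scenario.name == "CHAIN3":
        return _chain3()
    if scenario.name == "PARALLEL":
        return _parallel()
    if scenario.name == "SELECTIVE":
        return _selective()
    if scenario.name == "CYCLE":
        return _cycle()
    return _random(scenario.seed, scenario.size)


def make_profiles(scenario: FixtureScenario) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Target and reference RPKM profiles for the scenario.

    Only ``SELECTIVE`` differentiates the pair (the target lacks the
    transporter gene); all other scenarios duplicate a single profile.
    ``RANDOM`` draws seeded uniform RPKM over the model's genes.
    """
    if scenario.name == "SELECTIVE":
        return (
            ExpressionProfile("target", {"g1": 50.0, "gS": 50.0, "gT": 0.0}),
            ExpressionProfile("reference", {"g1": 50.0, "gS": 50.0, "gT": 50.0}),
        )
    if scenario.name == "RANDOM":
        model = make_model(scenario)
        genes = sorted({g for r in model.reactions for g in r.genes})
        rng = np.random.default_rng(scenario.seed + 1)
        values = {g: float(rng.uniform(1.0, 200.0)) for g in genes}
        return ExpressionProfile("target", dict(values)), ExpressionProfile(
            "reference", dict(values)
        )
    base = {"CHAIN3": {"g1": 37.0}, "PARALLEL": {"g1": 37.0, "g2": 37.0}}
    values = base.get(scenario.name, {"g1": 37.0, "g2": 37.0})
    return ExpressionProfile("target", dict(values)), ExpressionProfile(
        "reference", dict(values)
    )
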