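"""In-memory representation of a genome-scale metabolic model.

A :class:`MetabolicModel` is the stoichiometric network used throughout the
package: metabolites, bounded reactions with flattened gene associations, and
one designated objective (biomass) reaction. The dense stoichiometric matrix
view ``S`` has one row per metabolite and one column per reaction, so the
steady-state constraint of flux balance analysis reads ``S @ v == 0``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

#: Conventional "unconstrained" flux sentinel, mmol gDW^-1 h^-1.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """The model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A bounded, gene-associated reaction.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed). ``genes`` is the flat list of genes appearing anywhere in the
    reaction's gene association; AND/OR structure is deliberately not kept
    because downstream constraining only uses the highest-expressed gene.
    Exchange reactions touch exactly one metabolite; negative flux is uptake.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A stoichiometric network with one biomass objective reaction."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        if self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective {self.objective_id!r} is not a reaction of the model"
            )

    # -- index helpers -----------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def objective(self) -> Reaction:
        return self.reaction(self.objective_id)

    # -- numerical views ---------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with shape (n_metabolites, n_reactions)."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[met_index[met], j] = coef
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)
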