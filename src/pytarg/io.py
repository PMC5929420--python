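"""Readers and writers: SBML, a tabular model dialect, and flux tables.

SBML Level 3 models are read through python-libsbml with the FBC package
(flux bounds and gene-product associations); Level 2 models are supported via
the legacy COBRA conventions (``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law
parameters and ``GENE_ASSOCIATION`` notes). Gene associations are flattened
to the set of genes appearing anywhere in the expression, because bound
setting only ever consults the highest-expressed associated gene.

The tabular dialect is a TSV with columns ``reaction_id, equation,
lower_bound, upper_bound, genes, objective``: equations like
``1 A + 2 B -> 1 C`` (``->`` irreversible, ``<=>`` reversible), genes
semicolon-separated, and the objective flag set on exactly one row. It stands
in for full SBML in tests and small studies.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

from .config import PyTargConfig
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_sbml",
    "read_tabular_model",
    "write_tabular_model",
    "write_flux_table",
    "read_flux_table",
    "read_model",
    "FormatError",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _flatten_gpr(assoc) -> list[str]:
    """Collect every fbc:GeneProductRef label below an association node."""
    import libsbml

    genes: list[str] = []

    def walk(node):
        if node is None:
            return
        if isinstance(node, libsbml.GeneProductRef):
            genes.append(node.getGeneProduct())
        elif hasattr(node, "getNumAssociations"):  # FbcAnd / FbcOr
            for i in range(node.getNumAssociations()):
                walk(node.getAssociation(i))

    walk(assoc)
    return genes


def _legacy_genes(notes: str) -> list[str]:
    m = re.search(r"GENE_ASSOCIATION:\s*([^<]*)", notes or "")
    if not m:
        return []
    raw = m.group(1)
    return sorted({g for g in re.split(r"[()\s]+|and|or", raw) if g})


def read_sbml(path: str | Path, objective: str | None = None) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Parameters
    ----------
    path : path to an SBML L3+FBC (or legacy L2) file.
    objective : optional reaction id overriding the model's declared
        objective; required when the file declares none.
    """
    import libsbml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise FormatError(
                f"SBML parse failure in {path.name}: {err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path.name}: no <model> element")

    fbc = sbml_model.getPlugin("fbc")
    gene_names = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getIdAttribute()] = gp.getLabel() or gp.getIdAttribute()

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        metabolites.append(
            Metabolite(sp.getIdAttribute(), sp.getName() or "", sp.getCompartment() or "")
        )
    met_ids = {m.id for m in metabolites}

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            raise FormatError(
                f"{path.name}: reaction {rxn.getIdAttribute()!r} has empty stoichiometry"
            )

        lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        ub = DEFAULT_BOUND
        genes: list[str] = []
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = sbml_model.getParameter(rfbc.getLowerFluxBound()).getValue()
        if rfbc is not None and rfbc.isSetUpperFluxBound():
            ub = sbml_model.getParameter(rfbc.getUpperFluxBound()).getValue()
        if rfbc is not None and rfbc.getGeneProductAssociation() is not None:
            refs = _flatten_gpr(rfbc.getGeneProductAssociation().getAssociation())
            genes = sorted({gene_names.get(g, g) for g in refs})
        if rfbc is None or (not rfbc.isSetLowerFluxBound() and not rfbc.isSetUpperFluxBound()):
            kl = rxn.getKineticLaw()
            if kl is not None:
                for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                    par = kl.getParameter(pname)
                    if par is not None:
                        if setter == "lb":
                            lb = par.getValue()
                        else:
                            ub = par.getValue()
            if not genes and rxn.isSetNotes():
                genes = _legacy_genes(rxn.getNotesString())

        reactions.append(Reaction(rxn.getIdAttribute(), stoich, lb, ub, genes))

    objective_id = objective
    if objective_id is None and fbc is not None:
        obj = fbc.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if objective_id is None:
        raise FormatError(
            f"{path.name}: no objective declared; supply one with --objective"
        )
    return MetabolicModel(metabolites, reactions, objective_id, id=sbml_model.getIdAttribute() or path.stem)


# ---------------------------------------------------------------------------
# Tabular model dialect
# ---------------------------------------------------------------------------

_TABULAR_COLUMNS = ["reaction_id", "equation", "lower_bound", "upper_bound", "genes", "objective"]
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, sign: float, stoich: dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        m = _TERM_RE.match(term.strip())
        if m is None:
            raise FormatError(f"malformed term {term.strip()!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``1 A + 2 B -> C`` into (stoichiometry, reversible)."""
    if "<=>" in equation:
        lhs, rhs = equation.split("<=>", 1)
        reversible = True
    elif "->" in equation:
        lhs, rhs = equation.split("->", 1)
        reversible = False
    else:
        raise FormatError(f"equation {equation!r} has neither '->' nor '<=>'")
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich)
    _parse_side(rhs, +1.0, stoich)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise FormatError(f"equation {equation!r} has empty net stoichiometry")
    return stoich, reversible


def format_equation(reaction: Reaction) -> str:
    def side(items):
        return " + ".join(
            f"{abs(c):g} {m}" for m, c in sorted(items))
    lhs = side((m, c) for m, c in reaction.stoichiometry.items() if c < 0)
    rhs = side((m, c) for m, c in reaction.stoichiometry.items() if c > 0)
    arrow = "<=>" if reaction.reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


def read_tabular_model(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Read the TSV model dialect (see module docstring)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path.name}: empty file")
    header = [c.strip() for c in lines[0].split("\t")]
    if header != _TABULAR_COLUMNS:
        raise FormatError(
            f"{path.name}: expected columns {_TABULAR_COLUMNS}, got {header}"
        )
    reactions: list[Reaction] = []
    objective_ids: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        cells += [""] * (len(_TABULAR_COLUMNS) - len(cells))
        rid, equation, lb_s, ub_s, genes_s, obj_s = (c.strip() for c in cells[:6])
        try:
            stoich, reversible = parse_equation(equation)
        except FormatError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
        lb = float(lb_s) if lb_s else (-DEFAULT_BOUND if reversible else 0.0)
        ub = float(ub_s) if ub_s else DEFAULT_BOUND
        genes = [g for g in (t.strip() for t in genes_s.split(";")) if g]
        reactions.append(Reaction(rid, stoich, lb, ub, genes))
        if obj_s and obj_s != "0":
            objective_ids.append(rid)
    if len(objective_ids) != 1:
        raise FormatError(
            f"{path.name}: exactly one objective row required, found {len(objective_ids)}"
        )
    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    return MetabolicModel(
        [Metabolite(m) for m in met_ids],
        reactions,
        objective_ids[0],
        id=model_id or path.stem,
    )


def write_tabular_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    rows = ["\t".join(_TABULAR_COLUMNS)]
    for r in model.reactions:
        rows.append(
            "\t".join(
                [
                    r.id,
                    format_equation(r),
                    repr(r.lower_bound),
                    repr(r.upper_bound),
                    ";".join(r.genes),
                    "1" if r.id == model.objective_id else "0",
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")


def read_model(path: str | Path, objective: str | None = None) -> MetabolicModel:
    """Dispatch on extension: ``.xml``/``.sbml`` -> SBML, else tabular."""
    suffix = Path(path).suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return read_sbml(path, objective=objective)
    return read_tabular_model(path)


# ---------------------------------------------------------------------------
# Flux tables
# ---------------------------------------------------------------------------

def write_flux_table(fluxes, path: str | Path, config: PyTargConfig | None = None) -> None:
    """Write a flux distribution as TSV, full precision.

    A leading comment line records the achieved objective value and, when a
    config is given, a hash of it, so outputs are traceable to their run.
    """
    path = Path(path)
    cfg_hash = (
        hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
        if config is not None
        else "none"
    )
    lines = [
        f"# objective_value={fluxes.objective_value!r}\tconfig_hash={cfg_hash}",
        "reaction_id\tflux",
    ]
    for rid, v in fluxes.fluxes.items():
        lines.append(f"{rid}\t{v:.17e}")
    path.write_text("\n".join(lines) + "\n")


def read_flux_table(path: str | Path) -> tuple[dict[str, float], float]:
    """Read a flux TSV back; returns (fluxes, objective_value)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    m = re.search(r"objective_value=([^\t]+)", lines[0])
    if m is None:
        raise FormatError(f"{path.name}: missing objective_value header")
    objective_value = float(m.group(1))
    fluxes: dict[str, float] = {}
    for line in lines[2:]:
        if not line.strip():
            continue
        rid, val = line.split("\t")
        fluxes[rid] = float(val)
    return fluxes, objective_value
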