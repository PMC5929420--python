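"""Expression profiles and the per-reaction expression rule.

A profile maps gene ids to RPKM (reads per kilobase per million mapped
reads). A reaction associated with several genes takes the expression of its
highest-expressed gene; genes absent from the profile count as zero
expression — absence is read conservatively as non-expression, so such
reactions end up closed after constraining. Before scaling into a flux bound
the expression level is rounded up to the next multiple of the granularity
(10 RPKM by default), which keeps the LP bounds on a coarse grid; zero stays
zero so silent reactions stay shut.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "read_expression_table",
    "reaction_expression",
    "round_up_to_granularity",
]


@dataclass
class ExpressionProfile:
    """RPKM values for one sample."""

    sample_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        negative = [g for g, v in self.values.items() if v < 0]
        if negative:
            raise ValueError(f"negative RPKM for genes {negative[:5]}")

    def __getitem__(self, gene: str) -> float:
        return self.values.get(gene, 0.0)

    def __len__(self) -> int:
        return len(self.values)


def read_expression_table(
    path: str | Path,
    sample: str,
    gene_col: str = "gene",
) -> ExpressionProfile:
    """Extract one sample column from a gene x sample RPKM table.

    Delimiter follows the extension (``.csv`` comma, otherwise tab). Empty
    cells become 0; duplicated gene rows and negative values are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if gene_col not in df.columns:
        raise ValueError(
            f"{path.name}: no {gene_col!r} column; available: {list(df.columns)}"
        )
    if sample not in df.columns:
        available = [c for c in df.columns if c != gene_col]
        raise ValueError(f"unknown sample {sample!r}; available samples: {available}")
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].tolist()
        raise ValueError(f"{path.name}: duplicated gene ids {dup[:5]}")
    values = pd.to_numeric(df[sample], errors="raise").fillna(0.0)
    if (values < 0).any():
        bad = genes[values < 0].tolist()
        raise ValueError(f"{path.name}: negative RPKM for {bad[:5]}")
    return ExpressionProfile(sample, dict(zip(genes, values.astype(float))))


def reaction_expression(reaction: Reaction, profile: ExpressionProfile) -> float:
    """Expression of a reaction = RPKM of its highest-expressed gene.

    Genes missing from the profile contribute 0. Calling this on a gene-less
    reaction is a contract violation: such reactions are left unconstrained
    and callers must skip them.
    """
    if not reaction.genes:
        raise ValueError(
            f"reaction {reaction.id!r} has no gene association; "
            "gene-less reactions are left unconstrained"
        )
    missing = [g for g in reaction.genes if g not in profile.values]
    if missing:
        logger.warning(
            "reaction %s: %d gene(s) absent from profile %s, treated as 0 RPKM",
            reaction.id, len(missing), profile.sample_id,
        )
    return max(profile[g] for g in reaction.genes)


def round_up_to_granularity(x: float, g: float) -> float:
    """Smallest multiple of ``g`` that is >= ``x``; 0 maps to 0."""
    if x < 0:
        raise ValueError(f"expression must be non-negative, got {x}")
    if g <= 0:
        raise ValueError(f"granularity must be positive, got {g}")
    if x == 0:
        return 0.0
    n = math.ceil(x / g)
    # guard the division against float under- and overshoot
    if n * g < x:
        n += 1
    elif (n - 1) * g >= x:
        n -= 1
    return n * g
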