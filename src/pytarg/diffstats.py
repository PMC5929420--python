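"""Differential-use / differential-expression statistics.

Groups of per-sample flux distributions (or RPKM profiles) are compared
feature-by-feature with a Welch (unequal-variance) two-sided t-test, and
p-values are adjusted by Benjamini-Hochberg. A reaction is a metabolic
hallmark when both it (by flux) and at least one of its associated genes
(by expression) are significant at the same FDR level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "GroupMatrix",
    "DifferentialRecord",
    "welch_t",
    "bh_fdr",
    "differential_use",
    "hallmarks",
]


@dataclass
class GroupMatrix:
    """Two features x samples matrices sharing one feature index."""

    feature_ids: list[str]
    group_a: np.ndarray
    group_b: np.ndarray

    def __post_init__(self) -> None:
        self.group_a = np.atleast_2d(np.asarray(self.group_a, dtype=float))
        self.group_b = np.atleast_2d(np.asarray(self.group_b, dtype=float))
        if self.group_a.shape[0] != len(self.feature_ids) or self.group_b.shape[0] != len(
            self.feature_ids
        ):
            raise ValueError("row count must equal the number of feature ids")
        if self.group_a.shape[1] < 2 or self.group_b.shape[1] < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class DifferentialRecord:
    feature_id: str
    t: float
    p: float
    q: float
    mean_a: float
    mean_b: float
    significant: bool = False


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value.

    Uses the Welch-Satterthwaite degrees of freedom. Two constant groups
    with equal values give (0, 1); constant but different values give a
    degenerate (inf, 0) result, logged as such.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, 1.0
        logger.warning("degenerate Welch test: both groups constant, unequal means")
        return float(np.sign(mx - my)) * float("inf"), 0.0
    se2 = vx / nx + vy / ny
    t = (mx - my) / np.sqrt(se2)
    df_denom = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    # se2 > 0 guarantees df_denom > 0 mathematically; guard float underflow
    df = se2**2 / df_denom if df_denom > 0 else nx + ny - 2

    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_use(fluxes: GroupMatrix, fdr_level: float = 0.01) -> list[DifferentialRecord]:
    """Per-feature Welch tests with BH correction across all features.

    Features with zero variance in both groups and equal means get p = 1.
    Records are returned in input feature order, flagged significant when
    q < ``fdr_level``.
    """
    if len(fluxes.feature_ids) < 2:
        logger.warning(
            "only %d feature(s): the FDR adjustment is nearly the raw p-value",
            len(fluxes.feature_ids),
        )
    ts, ps = [], []
    for i in range(len(fluxes.feature_ids)):
        t, p = welch_t(fluxes.group_a[i], fluxes.group_b[i])
        ts.append(t)
        ps.append(p)
    qs = bh_fdr(ps)
    return [
        DifferentialRecord(
            feature_id=fid,
            t=ts[i],
            p=ps[i],
            q=float(qs[i]),
            mean_a=float(fluxes.group_a[i].mean()),
            mean_b=float(fluxes.group_b[i].mean()),
            significant=bool(qs[i] < fdr_level),
        )
        for i, fid in enumerate(fluxes.feature_ids)
    ]


def hallmarks(
    diff_reactions: list[DifferentialRecord],
    diff_genes: list[DifferentialRecord],
    model: MetabolicModel,
    fdr_level: float = 0.01,
) -> list[tuple[str, list[str]]]:
    """Significant reactions paired with their significant associated genes.

    A reaction qualifies when its flux q-value and at least one associated
    gene's expression q-value are both below ``fdr_level``.
    """
    sig_genes = {r.feature_id for r in diff_genes if r.q < fdr_level}
    rxn_genes = {r.id: r.genes for r in model.reactions}
    out: list[tuple[str, list[str]]] = []
    for rec in diff_reactions:
        if rec.q >= fdr_level:
            continue
        genes = [g for g in rxn_genes.get(rec.feature_id, []) if g in sig_genes]
        if genes:
            out.append((rec.feature_id, genes))
    return out
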