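"""Method configuration.

All tunable constants of the pipeline live in a single frozen dataclass so a
run can be reproduced from its manifest. Defaults are the published operating
point of the method: flux ceilings proportional to RPKM with constant
``k = 0.0027`` mmol gDW^-1 h^-1 per RPKM unit, expression rounded up to
multiples of 10, targeted reactions throttled to 10% of baseline flux, and the
greedy target search governed by the 0.9 / 0.05 / 0.5 thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PyTargConfig:
    """Constants of the expression-constraining and targeting pipeline.

    Parameters
    ----------
    k : float
        Proportionality constant between rounded RPKM and the flux bound,
        in mmol gDW^-1 h^-1 per RPKM.
    granularity : float
        Expression levels are rounded up to the next multiple of this value
        before scaling by ``k`` (avoids many distinct near-degenerate bounds).
    block_fraction : float
        Targeted reactions are throttled to this fraction of their baseline
        flux (0.1 emulates strong but incomplete pharmacological inhibition).
    single_threshold : float
        A candidate is kept only if the target cell's relative growth falls
        below this value.
    selectivity_margin : float
        Minimum excess of reference over target relative growth for a
        candidate to be kept.
    stop_ratio : float
        The greedy search stops once target relative growth drops to this.
    fdr_level : float
        Benjamini-Hochberg significance level for differential analyses.
    solver_tolerance : float
        LP feasibility / optimality slack.
    seed : int
        Seed for stochastic steps (alternative-optima sampling).
    signed_ranking : bool
        Rank candidate reactions by signed flux difference instead of the
        default absolute-magnitude difference.
    """

    k: float = 0.0027
    granularity: float = 10.0
    block_fraction: float = 0.1
    single_threshold: float = 0.9
    selectivity_margin: float = 0.05
    stop_ratio: float = 0.5
    fdr_level: float = 0.01
    solver_tolerance: float = 1e-7
    seed: int = 0
    signed_ranking: bool = False

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not self.granularity > 0:
            raise ValueError("granularity must be positive")
        if not (0 < self.block_fraction < self.stop_ratio < self.single_threshold < 1):
            raise ValueError(
                "thresholds must satisfy 0 < block_fraction < stop_ratio "
                "< single_threshold < 1"
            )
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PyTargConfig":
        """Load a config from a JSON file whose keys are the field names."""
        data = json.loads(Path(path).read_text())
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "PyTargConfig":
        return dataclasses.replace(self, **kwargs)
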