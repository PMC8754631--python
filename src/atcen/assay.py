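"""Statistics of the centromere-replacement assay and zero-event rate bounds.

The replacement assay deletes the native centromeric DNA next to a
pre-placed candidate and scores how efficiently deletion clones are
recovered relative to an empty-vector control.  Recovery is reconstructed
from plated viable-cell counts and the fractions of recovered cells that
are uracil auxotrophic and PCR-confirmed swapped; efficiencies above 1 are
meaningful (cells carrying the enlarged pre-deletion centromere grow more
slowly than deletion clones).

When no events of a kind are seen in n trials, the tightest per-trial
probability p* still consistent with the data at confidence c solves
(1 - p*)^n = 1 - c, i.e. p* = 1 - (1 - c)^(1/n) — the exact zero-event
binomial upper bound (the "rule of three" is its Poisson limit).  Two uses:

* segregation accuracy — zero missegregations in 233 imaged mitoses bound
  the per-division error rate at 0.0196 (99% confidence);
* centromere repositioning — in a mutation-accumulation design (serial
  single-colony streaks that minimise selection), each lineage contributes
  log2(colony size) informative divisions per round (the divisions on the
  picked colony's founding lineage), giving an effective, generally
  non-integer, trial count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "AssayCounts",
    "RateBound",
    "LineageModel",
    "recovery_efficiency",
    "zero_event_upper_bound",
    "lineage_divisions",
    "movement_rate_bound",
    "read_assay_counts_tsv",
]


@dataclass(frozen=True)
class AssayCounts:
    """Counts from one arm of the replacement assay.

    ``viable_cells`` is the viable count from plating the pooled colonies
    on rich medium; ``frac_ura_minus`` the fraction of recovered cells that
    are uracil auxotrophic; ``frac_swapped`` the fraction of those that are
    PCR-confirmed centromere swaps.
    """

    arm: str  # "integrase" or "empty_vector"
    colonies_pooled: int
    viable_cells: float
    frac_ura_minus: float = 1.0
    frac_swapped: float = 1.0

    def __post_init__(self) -> None:
        if self.colonies_pooled < 0 or self.viable_cells < 0:
            raise ValueError("counts must be non-negative")
        for f in (self.frac_ura_minus, self.frac_swapped):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")


@dataclass(frozen=True)
class RateBound:
    """Upper confidence bound on a per-trial probability from zero events."""

    trials: float
    events: int
    confidence: float
    bound: float

    @property
    def bound_percent(self) -> float:
        return 100.0 * self.bound

    def to_json(self, path: str | Path, **extra) -> None:
        payload = dict(self.__dict__, bound_percent=self.bound_percent, **extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class LineageModel:
    """Division accounting for a mutation-accumulation streak experiment."""

    colony_size: float
    rounds: int
    lines: int

    def __post_init__(self) -> None:
        if self.colony_size < 2:
            raise ValueError("colony_size must be >= 2")
        if self.rounds < 1 or self.lines < 1:
            raise ValueError("rounds and lines must be >= 1")


def recovery_efficiency(test: AssayCounts, control: AssayCounts) -> float:
    """Recovery of confirmed centromere-swap cells relative to control.

    (viable x frac_ura_minus x frac_swapped) of the integrase arm divided
    by the viable count of the empty-vector arm.  May exceed 1.
    """
    if control.viable_cells <= 0:
        raise ValueError("control viable_cells must be positive")
    recovered = test.viable_cells * test.frac_ura_minus * test.frac_swapped
    return recovered / control.viable_cells


def zero_event_upper_bound(trials: float, confidence: float) -> RateBound:
    """Exact binomial upper bound on p after zero events in ``trials``.

    Solves (1 - p*)^trials = 1 - confidence.  ``trials`` may be
    non-integer (continuous extension, used for effective lineage-division
    counts).
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    bound = 1.0 - math.exp(math.log1p(-confidence) / trials)
    return RateBound(trials=trials, events=0, confidence=confidence, bound=bound)


def lineage_divisions(model: LineageModel) -> float:
    """Effective informative division count of a streak experiment.

    Each of ``lines`` lineages contributes log2(colony_size) divisions per
    round — the divisions along the founding lineage of the colony picked
    at each round, the only divisions whose outcome is ascertained.
    """
    return model.lines * model.rounds * math.log2(model.colony_size)


def movement_rate_bound(model: LineageModel, confidence: float = 0.99) -> RateBound:
    """Upper bound on the per-division centromere repositioning rate.

    Zero observed repositionings over the effective division count of the
    streak design; report via ``.bound_percent`` (e.g. ~0.1% per division
    for 20 lines x 10 rounds at colony size 5e6, 99% confidence).
    """
    return zero_event_upper_bound(lineage_divisions(model), confidence)


def read_assay_counts_tsv(path: str | Path) -> list[AssayCounts]:
    """Read assay arms from TSV with columns arm, colonies_pooled,
    viable_cells, frac_ura_minus, frac_swapped."""
    df = pd.read_csv(path, sep="\t")
    required = {"arm", "colonies_pooled", "viable_cells",
                "frac_ura_minus", "frac_swapped"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay TSV missing columns {sorted(missing)}")
    return [
        AssayCounts(arm=row.arm, colonies_pooled=int(row.colonies_pooled),
                    viable_cells=float(row.viable_cells),
                    frac_ura_minus=float(row.frac_ura_minus),
                    frac_swapped=float(row.frac_swapped))
        for row in df.itertuples()
    ]
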