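"""Single-variant carrier case-control association.

Odds ratio from a 2x2 carrier table with the Woolf (log-normal) confidence
interval: exp( ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ).  Zero cells are
a hard error unless the Haldane-Anscombe +0.5 correction is explicitly
enabled; silent corrections hide data problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from scipy.stats import norm


class ZeroCellError(ValueError):
    """A zero cell makes the odds ratio / Woolf interval undefined."""


@dataclass(frozen=True)
class Contingency2x2:
    """Carrier counts: a/c = case carriers/non-carriers, b/d = controls."""

    case_carriers: int
    control_carriers: int
    case_noncarriers: int
    control_noncarriers: int

    def __post_init__(self) -> None:
        for v in self.cells:
            if v < 0:
                raise ValueError("negative cell count")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.case_carriers,
            self.control_carriers,
            self.case_noncarriers,
            self.control_noncarriers,
        )

    @property
    def n_cases(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_controls(self) -> int:
        return self.control_carriers + self.control_noncarriers


def build_table(
    case_genotypes: Mapping[str, Optional[int]],
    control_genotypes: Mapping[str, Optional[int]],
) -> Contingency2x2:
    """Count carriers (>=1 alt allele) in disjoint case/control sample sets.

    Genotype values are alt-allele counts; ``None`` (missing) samples are
    dropped from the table.
    """
    overlap = set(case_genotypes) & set(control_genotypes)
    if overlap:
        raise ValueError(f"samples in both arms: {sorted(overlap)}")

    def count(genotypes: Mapping[str, Optional[int]]) -> tuple[int, int]:
        carriers = noncarriers = 0
        for ac in genotypes.values():
            if ac is None:
                continue
            if ac >= 1:
                carriers += 1
            else:
                noncarriers += 1
        return carriers, noncarriers

    a, c = count(case_genotypes)
    b, d = count(control_genotypes)
    return Contingency2x2(a, b, c, d)


def _effective_cells(table: Contingency2x2, correction: bool) -> tuple[float, ...]:
    cells = table.cells
    if all(v > 0 for v in cells):
        return tuple(float(v) for v in cells)
    if not correction:
        raise ZeroCellError(
            f"zero cell in {cells}; enable the Haldane-Anscombe correction "
            "to add 0.5 to every cell"
        )
    return tuple(v + 0.5 for v in cells)


def odds_ratio(table: Contingency2x2, correction: bool = False) -> float:
    """(a*d)/(b*c) on carrier counts."""
    a, b, c, d = _effective_cells(table, correction)
    return (a * d) / (b * c)


def woolf_ci(
    table: Contingency2x2, level: float = 0.95, correction: bool = False
) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    a, b, c, d = _effective_cells(table, correction)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf((1 + level) / 2))
    return math.exp(log_or - z * se), math.exp(log_or + z * se)
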