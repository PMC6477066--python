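"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

For a monogenic recessive trait an F2 population segregates 3:1
(WT:mutant); the Pearson statistic sum((obs - exp)^2 / exp) with 1 degree of
freedom tests the observed phenotype counts against that expectation. No
continuity correction is applied: the plain Pearson statistic is the one
conventionally reported for segregation tables (76/33 vs 3:1 gives 1.62;
143/43 gives 0.35).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from scipy import stats

__all__ = ["SegregationCounts", "ChiSquareResult", "chi_square_segregation"]


@dataclass(frozen=True)
class SegregationCounts:
    """Observed phenotype counts in a segregating population."""

    n_wt: int
    n_mutant: int
    ratio: Tuple[float, float] = (3.0, 1.0)  # expected wt:mutant

    def __post_init__(self) -> None:
        if self.n_wt < 0 or self.n_mutant < 0:
            raise ValueError("phenotype counts must be non-negative")
        if self.ratio[0] <= 0 or self.ratio[1] <= 0:
            raise ValueError("ratio components must be positive")

    @property
    def n_total(self) -> int:
        return self.n_wt + self.n_mutant


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.05

    def summary(self) -> str:
        verdict = "significant" if self.significant else "ns"
        return (
            f"chi-square = {self.statistic:.2f} (df = {self.df}, "
            f"p = {self.p_value:.3f}) -> {verdict} at alpha = {self.alpha}"
        )


def chi_square_segregation(
    counts: SegregationCounts,
    ratio: Tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Pearson chi-square test of phenotype counts against an expected ratio.

    The statistic is zero iff the observed counts match the expectation
    exactly, and is invariant under swapping the two classes together with
    the ratio. Raises ``ValueError`` on an empty population.
    """
    ratio = ratio if ratio is not None else counts.ratio
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("ratio components must be positive")
    n = counts.n_total
    if n == 0:
        raise ValueError("cannot test an empty population")
    total_ratio = ratio[0] + ratio[1]
    expected = [n * ratio[0] / total_ratio, n * ratio[1] / total_ratio]
    statistic, p_value = stats.chisquare([counts.n_wt, counts.n_mutant], f_exp=expected)
    return ChiSquareResult(
        statistic=float(statistic),
        df=1,
        p_value=float(p_value),
        significant=bool(p_value < alpha),
        alpha=alpha,
    )
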