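"""2x2 marker co-positivity statistics: odds ratio, Woolf CI, tests.

Implements the association analysis relating TGF-beta1 positivity to
B7-H3 / B7-H4 positivity in colorectal cancer tissue: the sample odds
ratio, the Woolf log-normal 95% confidence interval, and a choice of
significance test (Fisher exact by default).  The observed counts for
both marker pairs ship as a packaged fixture (see :func:`load_marker_tables`).
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "odds_ratio",
    "woolf_ci",
    "association_test",
    "percent_positive",
    "associate",
    "load_marker_tables",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint positivity counts.

    Layout follows the marker-association table of the study:
    ``a`` = exposure+/marker+, ``b`` = exposure-/marker+,
    ``c`` = exposure+/marker-, ``d`` = exposure-/marker-
    (rows = marker status, columns = exposure status).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("all-zero 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def has_zero_cell(self) -> bool:
        return min(self.cells) == 0


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "woolf" or "haldane_woolf"
    test: str    # "fisher", "chi2" or "chi2_yates"


def _working_cells(table: ContingencyTable2x2) -> tuple[tuple[float, float, float, float], str]:
    # Haldane-Anscombe +0.5 only when a zero cell makes the OR degenerate;
    # complete tables are never silently corrected.
    if table.has_zero_cell():
        return tuple(x + 0.5 for x in table.cells), "haldane_woolf"
    return tuple(float(x) for x in table.cells), "woolf"


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample odds ratio (a*d)/(b*c), Haldane-corrected if any cell is 0."""
    (a, b, c, d), _ = _working_cells(table)
    return (a * d) / (b * c)


def woolf_ci(table: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio.

    ``exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` on the
    (possibly Haldane-corrected) cells.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    (a, b, c, d), _ = _working_cells(table)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def association_test(table: ContingencyTable2x2, test: str = "fisher") -> float:
    """Two-sided p-value for exposure/marker independence.

    ``fisher`` sums the probabilities of all margin-fixed tables no more
    probable than the observed one; ``chi2`` / ``chi2_yates`` use the
    Pearson statistic without / with continuity correction (an
    expected-count < 5 warning is logged where the approximation is
    doubtful).
    """
    obs = [[table.a, table.b], [table.c, table.d]]
    if test == "fisher":
        return float(stats.fisher_exact(obs, alternative="two-sided")[1])
    if test in ("chi2", "chi2_yates"):
        res = stats.chi2_contingency(obs, correction=(test == "chi2_yates"))
        if res.expected_freq.min() < 5:
            log.warning(
                "chi-square expected cell count %.2f < 5; consider Fisher exact",
                res.expected_freq.min(),
            )
        return float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def percent_positive(count: int, total: int) -> float:
    """Cell percentage of the study total, reported to 2 decimal places."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, 2)


def associate(table: ContingencyTable2x2, test: str = "fisher",
              level: float = 0.95) -> AssociationResult:
    """Full association record: OR, Woolf CI, and a significance test."""
    _, method = _working_cells(table)
    low, high = woolf_ci(table, level=level)
    return AssociationResult(
        odds_ratio=odds_ratio(table),
        ci_low=low,
        ci_high=high,
        p_value=association_test(table, test=test),
        method=method,
        test=test,
    )


def load_marker_tables() -> dict[str, ContingencyTable2x2]:
    """The packaged TGF-beta1 x B7-H3 / B7-H4 positivity counts (78 tissues)."""
    text = resources.files("mirsynergy.data").joinpath("marker_positivity.tsv").read_text()
    df = pd.read_csv(_io.StringIO(text), sep="\t")
    return {
        row["marker"]: ContingencyTable2x2(
            a=int(row["a"]), b=int(row["b"]), c=int(row["c"]), d=int(row["d"])
        )
        for _, row in df.iterrows()
    }
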