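"""Cohort-level exact inference on 2x2 tables.

The male/female mosaicism comparison conditions on all margins of the
2x2 table, giving the (noncentral) hypergeometric family with odds ratio
psi as the only free parameter:

    P(X = x | psi) ∝ C(r1, x) C(r2, c1 - x) psi^x

* Two-sided Fisher p-value by the point-probability (minimum-likelihood)
  rule: sum the central (psi = 1) probabilities of all margin-consistent
  tables no more probable than the observed one.  Computed with exact
  integer weights, so ties are unambiguous.
* Conditional-MLE odds ratio: the psi solving E[X | psi] = x_obs
  (score equation of the conditional likelihood), bracketed root to
  relative tolerance 1e-8.
* Exact confidence bounds by test inversion: the lower bound is the psi
  whose upper-tail probability P(X >= x_obs | psi) equals the tail level.

Rate summaries carry exact Clopper–Pearson intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .ddpcr import clopper_pearson

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "RateSummary",
    "fisher_two_sided",
    "or_cmle",
    "or_exact_bound",
    "rate_summary",
    "CohortAssociation",
    "CohortResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; row 1 = (a, b), row 2 = (c, d).

    For the cohort comparison: row 1 males (mosaic a, non-mosaic b),
    row 2 females (mosaic c, non-mosaic d).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _support_weights(t: ContingencyTable) -> tuple[np.ndarray, list[int]]:
    """Support of the first cell given margins, with exact integer weights
    C(r1, x) * C(r2, c1 - x)."""
    r1, r2, c1, _ = t.margins
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    weights = [math.comb(r1, int(x)) * math.comb(r2, int(c1 - x)) for x in xs]
    return xs, weights


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value, point-probability rule.

    Enumerates every table with the observed margins; sums the central
    hypergeometric probabilities of those whose point probability does
    not exceed the observed table's.  Integer weights make the "no more
    probable" comparison exact (no floating-point tie tolerance).
    Degenerate margins give p = 1 with a warning.
    """
    r1, r2, c1, c2 = t.margins
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        logger.warning("degenerate margin in %s; p = 1", t)
        return 1.0
    xs, weights = _support_weights(t)
    w_obs = weights[int(t.a - xs[0])]
    num = sum(w for w in weights if w <= w_obs)
    den = sum(weights)
    return num / den


def _conditional_mean(logpsi: float, xs: np.ndarray, logw: np.ndarray) -> float:
    lw = logw + xs * logpsi
    lw -= lw.max()
    w = np.exp(lw)
    return float((w * xs).sum() / w.sum())


def _tail_prob(logpsi: float, xs: np.ndarray, logw: np.ndarray,
               x0: int, upper: bool) -> float:
    lw = logw + xs * logpsi
    lw -= lw.max()
    w = np.exp(lw)
    sel = xs >= x0 if upper else xs <= x0
    return float(w[sel].sum() / w.sum())


_BRACKET = 60.0  # log-psi search range; e^60 is effectively unbounded


@dataclass(frozen=True)
class OddsRatioResult:
    """Conditional-MLE odds ratio with exact confidence bounds."""

    or_cmle: float
    ci_low: float
    ci_high: float  # may be math.inf
    p_two_sided: float
    level: float = 0.95
    one_sided_ci: bool = False
    flag: str = ""


def or_cmle(t: ContingencyTable, rtol: float = 1e-8) -> tuple[float, str]:
    """Conditional maximum-likelihood odds ratio.

    Solves the score equation E[X | psi] = a over the noncentral
    hypergeometric support by bracketed root-finding in log psi.
    Boundary tables (observed cell at an end of the support) return 0 or
    inf with a flag.
    """
    xs, weights = _support_weights(t)
    if xs.size == 1:
        return 1.0, "degenerate"
    if t.a == xs[0]:
        return 0.0, "boundary_low"
    if t.a == xs[-1]:
        return math.inf, "boundary_high"
    logw = np.array([math.log(w) for w in weights])
    root = brentq(
        lambda lp: _conditional_mean(lp, xs, logw) - t.a,
        -_BRACKET, _BRACKET, xtol=1e-12, rtol=8.9e-16,
    )
    psi = math.exp(root)
    # polish to the requested relative tolerance (brentq already exceeds it)
    assert abs(_conditional_mean(math.log(psi), xs, logw) - t.a) < rtol * max(1, t.a)
    return psi, ""


def or_exact_bound(t: ContingencyTable, level: float = 0.95,
                   side: str = "lower") -> float:
    """Exact confidence bound on the odds ratio by test inversion.

    ``side="lower"`` returns the psi at which P(X >= a | psi) equals
    1 - level; ``side="upper"`` the psi at which P(X <= a | psi) equals
    1 - level.  A one-sided 95% lower bound pairs with an interval open
    above.  Boundary tables return 0 / inf.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    alpha = 1.0 - level
    xs, weights = _support_weights(t)
    if xs.size == 1:
        return 0.0 if side == "lower" else math.inf
    logw = np.array([math.log(w) for w in weights])
    if side == "lower":
        if t.a == xs[0]:
            return 0.0
        f = lambda lp: _tail_prob(lp, xs, logw, t.a, upper=True) - alpha
    else:
        if t.a == xs[-1]:
            return math.inf
        f = lambda lp: _tail_prob(lp, xs, logw, t.a, upper=False) - alpha
    return math.exp(brentq(f, -_BRACKET, _BRACKET, xtol=1e-12, rtol=8.9e-16))


@dataclass(frozen=True)
class RateSummary:
    """A proportion with exact binomial 95% interval and display rounding."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion

    @property
    def display(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent:.1f}%)"


def rate_summary(x: int, n: int, level: float = 0.95) -> RateSummary:
    """Exact rate summary for x events out of n subjects."""
    if n < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("numerator outside [0, n]")
    lo, hi = clopper_pearson(x, n, level)
    return RateSummary(numerator=x, denominator=n, proportion=x / n,
                       ci_low=lo, ci_high=hi)


class CohortAssociation:
    """Exact association model for a 2x2 cohort table.

    ``CohortAssociation(table).fit()`` returns :class:`CohortResults`
    carrying the two-sided Fisher p-value, the conditional-MLE odds
    ratio, and both the two-sided exact interval and the one-sided 95%
    lower bound (interval open above), as published exact-test software
    reports them.
    """

    def __init__(self, table: ContingencyTable):
        self.table = table

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int) -> "CohortAssociation":
        return cls(ContingencyTable(a, b, c, d))

    @classmethod
    def from_cohort(cls, df, group_col: str = "sex", event_col: str = "is_mosaic",
                    group_order: tuple = ("M", "F")) -> "CohortAssociation":
        """Build the 2x2 table from a per-subject cohort DataFrame."""
        g1, g2 = group_order
        ev = df[event_col].astype(bool)
        a = int(((df[group_col] == g1) & ev).sum())
        b = int(((df[group_col] == g1) & ~ev).sum())
        c = int(((df[group_col] == g2) & ev).sum())
        d = int(((df[group_col] == g2) & ~ev).sum())
        return cls(ContingencyTable(a, b, c, d))

    def fit(self, level: float = 0.95) -> "CohortResults":
        t = self.table
        p = fisher_two_sided(t)
        psi, flag = or_cmle(t)
        two_sided_level = 1 - (1 - level) / 2  # alpha/2 in each tail
        lo2 = or_exact_bound(t, level=two_sided_level, side="lower")
        hi2 = or_exact_bound(t, level=two_sided_level, side="upper")
        lo1 = or_exact_bound(t, level=level, side="lower")
        return CohortResults(
            model=self, p_two_sided=p, or_cmle=psi, flag=flag, level=level,
            ci_two_sided=(lo2, hi2), lower_bound_one_sided=lo1,
        )


@dataclass
class CohortResults:
    model: CohortAssociation
    p_two_sided: float
    or_cmle: float
    ci_two_sided: tuple[float, float]
    lower_bound_one_sided: float
    level: float
    flag: str = ""

    def to_dict(self) -> dict:
        t = self.model.table
        return {
            "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
            "p_two_sided": self.p_two_sided,
            "p_method": "fisher_exact_point_probability",
            "odds_ratio_cmle": self.or_cmle,
            "ci_two_sided": list(self.ci_two_sided),
            "ci_one_sided_lower": self.lower_bound_one_sided,
            "level": self.level,
            "flag": self.flag,
        }

    def summary(self) -> str:
        t = self.model.table
        row1 = rate_summary(t.a, t.a + t.b) if t.a + t.b else None
        row2 = rate_summary(t.c, t.c + t.d) if t.c + t.d else None
        or_str = "inf" if math.isinf(self.or_cmle) else f"{self.or_cmle:.2f}"
        lines = [
            "Cohort association (Fisher exact / conditional MLE)",
            "=" * 55,
            f"row 1: {row1.display if row1 else '0/0'}    "
            f"row 2: {row2.display if row2 else '0/0'}",
            f"two-sided p (point-probability) = {self.p_two_sided:.4g}",
            f"odds ratio (CMLE)               = {or_str}",
            f"{self.level:.0%} two-sided exact CI       = "
            f"[{self.ci_two_sided[0]:.2f}, "
            + ("inf" if math.isinf(self.ci_two_sided[1]) else f"{self.ci_two_sided[1]:.2f}")
            + "]",
            f"{self.level:.0%} one-sided lower bound    = "
            f"{self.lower_bound_one_sided:.2f} (interval open above)",
        ]
        return "\n".join(lines)
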