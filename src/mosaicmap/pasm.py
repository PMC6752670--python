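"""Amplicon-validation stage: hierarchical Bayesian MAF estimation.

Ultra-deep amplicon resequencing (~12,000x) validates candidate mosaic
sites.  At that depth the dominant nuisance is the platform error rate,
which varies from site to site; it is therefore treated hierarchically: a
Beta distribution over per-site error rates is moment-matched from
negative-control sites, and the site likelihood marginalises the error
rate over that distribution (numerical quadrature over equal-probability
Beta nodes).  The MAF posterior on a uniform grid then yields a MAP
estimate and an equal-tailed 95% credible interval, and the validation
decision applies the stage's thresholds: CI lower bound at least 0.5% and
MAP outside the 40–60% heterozygous band confirms a mosaic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .ddpcr import MafEstimate
from .screen import (
    DEFAULT_GRID_RESOLUTION,
    PileupSite,
    _equal_tailed_interval,
)

__all__ = [
    "ErrorModel",
    "PasmThresholds",
    "ValidationCall",
    "fit_error_model",
    "pasm_maf",
    "validate_candidate",
    "AmpliconMafModel",
]

logger = logging.getLogger(__name__)

ERROR_FLOOR = 1e-6
_POINT_CONCENTRATION = 1e8  # Beta concentration treated as a point mass


@dataclass(frozen=True)
class ErrorModel:
    """Beta distribution of per-site error rates across control sites."""

    alpha: float
    beta: float
    point_estimate: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if not 0.0 < self.point_estimate < 0.5:
            raise ValueError("point error estimate must lie in (0, 0.5)")

    @classmethod
    def point(cls, e: float) -> "ErrorModel":
        """Degenerate model: all mass at a single error rate."""
        e = max(e, ERROR_FLOOR)
        return cls(alpha=e * _POINT_CONCENTRATION,
                   beta=(1 - e) * _POINT_CONCENTRATION, point_estimate=e)

    def quadrature_nodes(self, n_nodes: int = 32) -> tuple[np.ndarray, np.ndarray]:
        """Equal-probability quantile-midpoint nodes and uniform weights.

        Collapses exactly to the point estimate when the Beta is (near)
        degenerate, so the marginalised posterior reduces to the
        fixed-error posterior in that limit.
        """
        if self.alpha + self.beta >= _POINT_CONCENTRATION:
            return np.full(n_nodes, self.point_estimate), np.full(n_nodes, 1.0 / n_nodes)
        q = (np.arange(n_nodes) + 0.5) / n_nodes
        nodes = beta_dist.ppf(q, self.alpha, self.beta)
        nodes = np.clip(nodes, ERROR_FLOOR, 0.5 - 1e-9)
        return nodes, np.full(n_nodes, 1.0 / n_nodes)


def fit_error_model(control_sites: list[PileupSite]) -> ErrorModel:
    """Moment-match a Beta error-rate distribution from control sites.

    Controls must be free of the variant, so their alternative-allele
    fractions measure platform error alone.  The hierarchy is
    beta-binomial: per-site error rates e_i ~ Beta(alpha, beta), observed
    alt counts Binomial(n_i, e_i).  Method-of-moments fit: the
    between-site variance of e is the observed variance of the fractions
    minus its expected within-site binomial component; when that excess
    is non-positive the sites are consistent with a single shared error
    rate and the model collapses to a point mass at the mean.  The point
    estimate is the mean fraction, floored at 1e-6.  All-zero controls
    give a degenerate floor model with a logged warning.  Deterministic
    for fixed input.
    """
    if len(control_sites) < 3:
        raise ValueError("need at least 3 control sites to fit an error model")
    kept = [s for s in control_sites if s.depth > 0]
    if len(kept) < 3:
        raise ValueError("need at least 3 control sites with nonzero depth")
    fracs = np.array([s.alt_count / s.depth for s in kept], dtype=float)
    depths = np.array([s.depth for s in kept], dtype=float)
    m = float(fracs.mean())
    if m <= 0.0:
        logger.warning(
            "all control sites error-free; degenerate error model at %.0e floor",
            ERROR_FLOOR,
        )
        return ErrorModel.point(ERROR_FLOOR)
    m = max(m, ERROR_FLOOR)
    v_obs = float(fracs.var(ddof=1))
    v_within = float(np.mean(m * (1.0 - m) / depths))
    v_between = v_obs - v_within
    if v_between <= 0.0 or v_between >= m * (1.0 - m):
        # consistent with one shared error rate across sites
        return ErrorModel.point(m)
    kappa = m * (1.0 - m) / v_between - 1.0
    kappa = max(kappa, 2.0)
    return ErrorModel(alpha=m * kappa, beta=(1.0 - m) * kappa, point_estimate=m)


@dataclass(frozen=True)
class PasmThresholds:
    """Validation-stage decision thresholds.

    The heterozygous band (40–60%) is deliberately wider than the
    screening band (45–55%): the two stages use distinct threshold
    objects.
    """

    homref_lower_bound: float = 0.005
    het_band: tuple[float, float] = (0.40, 0.60)

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not (self.homref_lower_bound < lo <= hi <= 1.0):
            raise ValueError("threshold bands must be ordered")


@dataclass(frozen=True)
class ValidationCall:
    site_id: str
    decision: str  # mosaic_confirmed | het | not_confirmed
    estimate: MafEstimate


def pasm_maf(
    k: int,
    n: int,
    error_model: ErrorModel,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
    n_nodes: int = 32,
    level: float = 0.95,
) -> MafEstimate:
    """MAF posterior from amplicon counts, error rate marginalised.

    The likelihood of ``k`` alternative reads out of ``n`` given MAF ``f``
    averages the binomial likelihood over the error-rate distribution:

        L(f) = sum_j w_j Bin(k | n, f (1 - e_j) + (1 - f) e_j)

    with quadrature nodes e_j of the fitted Beta.  Flat prior on ``f``;
    MAP and equal-tailed 95% interval from the grid posterior.
    """
    if n < 1:
        raise ValueError("posterior undefined for depth 0")
    if not 0 <= k <= n:
        raise ValueError(f"alt count {k} outside [0, {n}]")
    nodes, weights = error_model.quadrature_nodes(n_nodes)
    n_points = int(round(1.0 / grid_resolution)) + 1
    grid = np.linspace(0.0, 1.0, n_points)
    # success probability per (grid point, node)
    p = nodes[None, :] + grid[:, None] * (1.0 - 2.0 * nodes[None, :])
    with np.errstate(divide="ignore"):
        ll = k * np.log(p) + (n - k) * np.log1p(-p)
    ll_max = ll.max()
    lik = np.exp(ll - ll_max) @ weights
    density = lik / lik.sum()
    map_maf = float(grid[int(np.argmax(density))])
    ci_low, ci_high = _equal_tailed_interval(grid, density, level)
    return MafEstimate(
        map_maf=map_maf, ci_low=ci_low, ci_high=ci_high, method="pasm", n=n
    )


def validate_candidate(
    est: MafEstimate, thresholds: PasmThresholds | None = None,
    site_id: str = ".",
) -> ValidationCall:
    """Validation decision for one amplicon estimate.

    mosaic_confirmed when the CI lower bound clears the 0.5% floor and
    the MAP lies outside the heterozygous band; het when the MAP falls
    in the band; otherwise not_confirmed.
    """
    if est.method != "pasm":
        raise ValueError("validation applies to amplicon (pasm) estimates")
    t = thresholds or PasmThresholds()
    lo, hi = t.het_band
    if lo <= est.map_maf <= hi:
        decision = "het"
    elif est.ci_low >= t.homref_lower_bound:
        decision = "mosaic_confirmed"
    else:
        decision = "not_confirmed"
    return ValidationCall(site_id=site_id, decision=decision, estimate=est)


class AmpliconMafModel:
    """Validation-stage model for one amplicon site.

    ``AmpliconMafModel(k, n, error_model).fit()`` returns the marginalised
    MAF estimate; ``fit_validate()`` additionally applies the validation
    thresholds.
    """

    def __init__(
        self,
        k: int,
        n: int,
        error_model: ErrorModel | None = None,
        thresholds: PasmThresholds | None = None,
        site_id: str = ".",
    ):
        self.k = k
        self.n = n
        self.error_model = error_model or ErrorModel.point(1e-3)
        self.thresholds = thresholds or PasmThresholds()
        self.site_id = site_id

    @classmethod
    def from_site(cls, site: PileupSite, error_model=None, **kwargs):
        return cls(site.alt_count, site.depth, error_model,
                   site_id=site.site_id, **kwargs)

    def fit(self, **kwargs) -> MafEstimate:
        return pasm_maf(self.k, self.n, self.error_model, **kwargs)

    def fit_validate(self, **kwargs) -> ValidationCall:
        return validate_candidate(self.fit(**kwargs), self.thresholds,
                                  site_id=self.site_id)

    def summary(self) -> str:
        call = self.fit_validate()
        e = call.estimate
        return "\n".join(
            [
                "Amplicon validation (hierarchical Bayesian MAF)",
                "=" * 50,
                f"site {self.site_id}: {self.k} alt / {self.n} reads",
                f"error model: Beta({self.error_model.alpha:.3g}, "
                f"{self.error_model.beta:.3g}), mean {self.error_model.point_estimate:.2e}",
                f"MAP MAF = {e.map_maf:.4%} [95% CI {e.ci_low:.4%} – {e.ci_high:.4%}]",
                f"decision: {call.decision}",
            ]
        )
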