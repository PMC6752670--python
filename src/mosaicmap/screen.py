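"""Bayesian screening genotyper for mosaic variants in deep pileup counts.

Each site is summarised by its reference/alternative read counts and a
per-base miscall probability ``e``.  The mutant allelic fraction (MAF) ``f``
enters the read-level likelihood through the error-folded success
probability

    p(f) = f (1 - e) + (1 - f) e ,

i.e. a read supports the alternative allele either because it genuinely
carries it (and was read correctly) or because a reference read was
miscalled.  The posterior over ``f`` is computed on a uniform grid under a
flat prior, and each site is classified as reference-homozygous,
heterozygous, alternative-homozygous or *mosaic candidate* from the MAP
estimate and the equal-tailed 95% credible interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PileupSite",
    "MafPosterior",
    "ScreenThresholds",
    "GenotypeCall",
    "posterior_maf",
    "classify_site",
    "screen_sites",
    "ScreenModel",
    "ScreenResults",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID_RESOLUTION = 1e-4


@dataclass(frozen=True)
class PileupSite:
    """Per-site allele counts: the unit of mosaic screening.

    Parameters
    ----------
    site_id : str
        Free-form identifier (typically ``chrom:pos:ref>alt``).
    ref_count, alt_count : int
        Reads supporting the reference / alternative allele.
    error_rate : float
        Per-base miscall probability (Phred-derived), in ``[0, 0.5)``.
    true_maf : float, optional
        Generator truth, carried through simulations for calibration tests.
    """

    site_id: str
    ref_count: int
    alt_count: int
    error_rate: float = 1e-3
    chrom: str = "."
    pos: int = 0
    ref: str = "N"
    alt: str = "N"
    true_maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(f"{self.site_id}: negative read count")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(
                f"{self.site_id}: error_rate must be in [0, 0.5), got {self.error_rate}"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class MafPosterior:
    """Grid posterior over the mutant allelic fraction."""

    grid: np.ndarray
    density: np.ndarray
    map_maf: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        total = float(self.density.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior mass {total} does not normalise to 1")


@dataclass(frozen=True)
class ScreenThresholds:
    """Decision bands of the screening stage.

    hom-ref requires the 95% CI lower bound below 0.5%; the heterozygous
    band is a MAP window of 45–55%; everything outside the exclusion bands
    is a mosaic candidate.
    """

    homref_lower_bound: float = 0.005
    het_band: tuple[float, float] = (0.45, 0.55)
    homalt_band: tuple[float, float] = (0.995, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not (self.homref_lower_bound < lo <= hi < self.homalt_band[0]):
            raise ValueError("threshold bands must be ordered and disjoint")


@dataclass(frozen=True)
class GenotypeCall:
    site_id: str
    label: str  # hom_ref | het | hom_alt | mosaic_candidate
    map_maf: float
    ci_low: float
    ci_high: float


def _log_likelihood(k: int, n: int, e: float, grid: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood of k alt reads in n over a MAF grid.

    The binomial coefficient is constant in f and dropped.
    """
    p = e + grid * (1.0 - 2.0 * e)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(k > 0, k * np.log(p), 0.0) + np.where(
            n - k > 0, (n - k) * np.log1p(-p), 0.0
        )
    # p == 0 (or 1) with reads on the other allele: impossible under model
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return ll


def _equal_tailed_interval(
    grid: np.ndarray, density: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    cdf = np.cumsum(density)
    lo = float(grid[np.searchsorted(cdf, alpha)])
    hi = float(grid[min(np.searchsorted(cdf, 1.0 - alpha), grid.size - 1)])
    return lo, hi


def posterior_maf(
    k: int,
    n: int,
    e: float,
    prior: str = "uniform",
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
    level: float = 0.95,
) -> MafPosterior:
    """Posterior over the MAF from ``k`` alternative reads out of ``n``.

    Parameters
    ----------
    k, n : int
        Alternative-supporting reads and total depth, ``k <= n``, ``n >= 1``.
    e : float
        Per-base miscall probability in ``[0, 0.5)``.
    prior : {"uniform"}
        Prior over the MAF; only the flat prior is defined.
    grid_resolution : float
        Spacing of the uniform MAF grid (default 1e-4, >10x below the 0.5%
        decision boundary).
    level : float
        Credible level of the equal-tailed interval.

    Returns
    -------
    MafPosterior
        Normalised grid posterior with MAP and equal-tailed interval.
    """
    if n < 1:
        raise ValueError("posterior undefined for depth 0")
    if not 0 <= k <= n:
        raise ValueError(f"alt count {k} outside [0, {n}]")
    if not 0.0 <= e < 0.5:
        raise ValueError(f"error rate {e} outside [0, 0.5)")
    if prior != "uniform":
        raise ValueError(f"unknown prior {prior!r}")

    n_points = int(round(1.0 / grid_resolution)) + 1
    grid = np.linspace(0.0, 1.0, n_points)
    ll = _log_likelihood(k, n, e, grid)
    ll -= ll.max()
    density = np.exp(ll)
    density /= density.sum()
    map_maf = float(grid[int(np.argmax(density))])
    ci_low, ci_high = _equal_tailed_interval(grid, density, level)
    return MafPosterior(grid=grid, density=density, map_maf=map_maf,
                        ci_low=ci_low, ci_high=ci_high)


def classify_site(
    post: MafPosterior, thresholds: ScreenThresholds | None = None,
    site_id: str = "."
) -> GenotypeCall:
    """Classify one site from its MAF posterior.

    Order of precedence: hom-ref (CI lower bound below the 0.5% floor),
    then het (MAP inside the het band), then hom-alt (the mirror of the
    hom-ref rule: CI upper bound above 99.5% with MAP in the hom-alt band);
    any site surviving all exclusion bands is a mosaic candidate.
    """
    t = thresholds or ScreenThresholds()
    if post.ci_low < t.homref_lower_bound:
        label = "hom_ref"
    elif t.het_band[0] <= post.map_maf <= t.het_band[1]:
        label = "het"
    elif post.ci_high > t.homalt_band[0] and post.map_maf >= t.homalt_band[0]:
        label = "hom_alt"
    else:
        label = "mosaic_candidate"
    return GenotypeCall(site_id=site_id, label=label, map_maf=post.map_maf,
                        ci_low=post.ci_low, ci_high=post.ci_high)


def screen_sites(
    sites: list[PileupSite],
    thresholds: ScreenThresholds | None = None,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
) -> list[GenotypeCall]:
    """Screen a list of pileup sites; order-preserving, one call per site.

    Malformed sites (zero depth) are reported by ``site_id`` and skipped;
    the run continues.
    """
    if not sites:
        raise ValueError("no sites to screen")
    calls: list[GenotypeCall] = []
    for s in sites:
        try:
            post = posterior_maf(s.alt_count, s.depth, s.error_rate,
                                 grid_resolution=grid_resolution)
        except ValueError as exc:
            logger.warning("site %s skipped: %s", s.site_id, exc)
            continue
        calls.append(classify_site(post, thresholds, site_id=s.site_id))
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.label] = counts.get(c.label, 0) + 1
    logger.info("screened %d sites: %s", len(calls), counts)
    return calls


class ScreenModel:
    """Screening-stage model over a collection of pileup sites.

    ``ScreenModel(sites).fit()`` returns :class:`ScreenResults` holding one
    genotype call per site with MAP MAF and credible interval.
    """

    def __init__(
        self,
        sites: list[PileupSite],
        thresholds: ScreenThresholds | None = None,
        grid_resolution: float = DEFAULT_GRID_RESOLUTION,
    ):
        self.sites = list(sites)
        self.thresholds = thresholds or ScreenThresholds()
        self.grid_resolution = grid_resolution

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "ScreenModel":
        """Build from a site table with ref_count/alt_count/error_rate columns."""
        sites = [
            PileupSite(
                site_id=str(r.get("site_id", i)),
                ref_count=int(r["ref_count"]),
                alt_count=int(r["alt_count"]),
                error_rate=float(r.get("error_rate", 1e-3)),
                chrom=str(r.get("chrom", ".")),
                pos=int(r.get("pos", 0)),
                ref=str(r.get("ref", "N")),
                alt=str(r.get("alt", "N")),
            )
            for i, r in df.iterrows()
        ]
        return cls(sites, **kwargs)

    def fit(self) -> "ScreenResults":
        calls = screen_sites(self.sites, self.thresholds, self.grid_resolution)
        return ScreenResults(model=self, calls=calls)


@dataclass
class ScreenResults:
    model: ScreenModel
    calls: list[GenotypeCall]

    @property
    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.calls:
            out[c.label] = out.get(c.label, 0) + 1
        return out

    def candidates(self) -> list[GenotypeCall]:
        return [c for c in self.calls if c.label == "mosaic_candidate"]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site_id": [c.site_id for c in self.calls],
                "call": [c.label for c in self.calls],
                "map_maf": [c.map_maf for c in self.calls],
                "ci95_lo": [c.ci_low for c in self.calls],
                "ci95_hi": [c.ci_high for c in self.calls],
            }
        )

    def summary(self) -> str:
        t = self.model.thresholds
        lines = [
            "Mosaic screening results",
            "=" * 60,
            f"sites screened: {len(self.calls)}",
            f"hom-ref CI floor: {t.homref_lower_bound:.3%}   "
            f"het band: {t.het_band[0]:.1%}-{t.het_band[1]:.1%}",
        ]
        for label in ("hom_ref", "het", "hom_alt", "mosaic_candidate"):
            lines.append(f"  {label:<17s} {self.label_counts.get(label, 0):>6d}")
        return "\n".join(lines)
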