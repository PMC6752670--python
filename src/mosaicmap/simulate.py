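"""Synthetic-data generators for every pipeline input.

The generators reproduce the statistical structure the downstream analyses
assume, so the whole pipeline is testable without sequencing data:

* **Finite input copies.**  Deep targeted sequencing starts from a limited
  number of genome copies (about 3000 for 10 ng panel libraries, about
  6000 for 20 ng amplicon libraries).  The mutant template count is drawn
  once per site, Binomial(input_copies, true_maf), and reads then resample
  those templates — so replicate variance exceeds the pure binomial read
  variance whenever depth outruns the template pool (the PCR-bottleneck
  overdispersion an amplicon run at 12,000x over 6000 copies shows).
* **Sequencing error.**  Each read is miscalled symmetrically (ref->alt,
  alt->ref) with a single per-site probability, the Phred-derived scalar
  the screening likelihood uses.
* **Poisson droplet loading.**  Digital-PCR template molecules load
  droplets independently; a droplet reads MU if it holds any mutant
  molecule (dominant FAM signal), WT if only wild-type, NA if empty.
* **Sex-stratified cohorts** and **multi-tissue panels** including the
  four semen fractions (Sp/L1/L2/Ot), for germline-mosaicism scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ddpcr import DropletData
from .screen import PileupSite

__all__ = [
    "SimConfig",
    "DropletSimConfig",
    "CohortSimConfig",
    "simulate_pileup",
    "simulate_amplicon",
    "simulate_droplets",
    "simulate_cohort",
    "simulate_tissue_panel",
    "TISSUES",
    "SEMEN_FRACTIONS",
]

PANEL_INPUT_COPIES = 3000      # ~10 ng genomic DNA
AMPLICON_INPUT_COPIES = 6000   # ~20 ng genomic DNA
TISSUES = (
    "blood", "saliva", "hair", "buccal", "urine",
    "semen_Sp", "semen_L1", "semen_L2", "semen_Ot",
)
SEMEN_FRACTIONS = ("semen_Sp", "semen_L1", "semen_L2", "semen_Ot")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a read-count simulation.

    true_maf : mutant allelic fraction in the input DNA, in [0, 1].
    depth : mean read depth per site (panel ~1000x, amplicon ~12,000x).
    input_copies : genome copies entering amplification (panel 3000,
        amplicon 6000); the template bottleneck.
    error_rate : per-base symmetric miscall probability (default 1e-3,
        i.e. Phred 30).
    """

    true_maf: float = 0.0
    depth: int = 1000
    input_copies: int = PANEL_INPUT_COPIES
    error_rate: float = 1e-3
    seed: int = 0
    n_sites: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_maf <= 1.0:
            raise ValueError(f"true_maf {self.true_maf} outside [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_copies < 1:
            raise ValueError("input_copies must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(
                f"error_rate {self.error_rate} is in the noninformative regime"
            )
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")


@dataclass(frozen=True)
class DropletSimConfig:
    """Configuration of a digital-PCR droplet simulation.

    total_copies : template molecules loaded into the emulsion.
    n_droplets : droplets generated; mean occupancy is
        total_copies / n_droplets.
    false_mu_rate : probability that a droplet without mutant template
        misreads as MU (default 0; a nonzero value stresses the 1e-4
        detection-limit analysis).
    """

    true_maf: float = 0.0
    total_copies: int = 50_000
    n_droplets: int = 5_000_000
    false_mu_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_maf <= 1.0:
            raise ValueError("true_maf outside [0, 1]")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if not 0.0 <= self.false_mu_rate <= 1.0:
            raise ValueError("false_mu_rate outside [0, 1]")


@dataclass(frozen=True)
class CohortSimConfig:
    """Sex-stratified cohort simulation.

    Defaults reflect a Rett-spectrum screening cohort: 18 males and 453
    females, with mosaicism probabilities 3/18 and 2/453 and mosaic MAFs
    drawn uniformly over the observed somatic range 6.5%–38.1%.
    """

    n_male: int = 18
    n_female: int = 453
    rate_male: float = 3 / 18
    rate_female: float = 2 / 453
    maf_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 0.065, "high": 0.381}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("subject counts must be >= 0")
        for r in (self.rate_male, self.rate_female):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def _draw_mafs(dist: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    name = dist.get("name", "uniform")
    if name == "uniform":
        return rng.uniform(dist.get("low", 0.05), dist.get("high", 0.4), size)
    if name == "loguniform":
        lo, hi = np.log(dist["low"]), np.log(dist["high"])
        return np.exp(rng.uniform(lo, hi, size))
    if name == "fixed":
        return np.full(size, float(dist["value"]))
    raise ValueError(f"unknown MAF distribution {name!r}")


def _sample_site(
    true_maf: float, depth: int, input_copies: int, error_rate: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Two-stage draw: template bottleneck, then reads, then miscalls."""
    m = rng.binomial(input_copies, true_maf)
    template_alt_frac = m / input_copies
    # reads resample templates uniformly: alt reads ~ Bin(depth, m/copies)
    alt_true = rng.binomial(depth, template_alt_frac)
    ref_true = depth - alt_true
    # symmetric miscalls
    alt_to_ref = rng.binomial(alt_true, error_rate)
    ref_to_alt = rng.binomial(ref_true, error_rate)
    alt_count = alt_true - alt_to_ref + ref_to_alt
    return depth - alt_count, alt_count


def simulate_pileup(config: SimConfig) -> list[PileupSite]:
    """Simulate panel-sequencing pileup sites.

    Each site draws its mutant template count Binomial(input_copies,
    true_maf), resamples reads from the templates, and applies symmetric
    per-read miscalls; ref_count + alt_count equals the realised depth.
    """
    rng = np.random.default_rng(config.seed)
    sites = []
    for i in range(config.n_sites):
        ref, alt = _sample_site(
            config.true_maf, config.depth, config.input_copies,
            config.error_rate, rng,
        )
        sites.append(
            PileupSite(
                site_id=f"sim{i:05d}",
                ref_count=ref,
                alt_count=alt,
                error_rate=config.error_rate,
                chrom="chrX",
                pos=153_296_000 + i,
                ref="C",
                alt="T",
                true_maf=config.true_maf,
            )
        )
    return sites


def simulate_amplicon(config: SimConfig) -> PileupSite:
    """Simulate one ultra-deep amplicon site (validation-stage input).

    Identical two-stage model to :func:`simulate_pileup`; with the
    amplicon defaults (6000 copies, ~12,000x) the depth outruns the
    template pool and replicate variance exceeds the binomial read
    variance.
    """
    cfg = SimConfig(
        true_maf=config.true_maf,
        depth=config.depth,
        input_copies=config.input_copies,
        error_rate=config.error_rate,
        seed=config.seed,
        n_sites=1,
    )
    return simulate_pileup(cfg)[0]


def simulate_droplets(config: DropletSimConfig) -> DropletData:
    """Simulate a digital-PCR run under Poisson droplet loading.

    Mutant and wild-type molecules load droplets independently with
    channel means lam_mu = true_maf * total_copies / n_droplets and
    lam_wt = (1 - true_maf) * total_copies / n_droplets.  The MU/WT/NA
    triple is drawn from the exact aggregate law of that model:
    MU ~ Bin(n, 1 - exp(-lam_mu)), then WT ~ Bin(n - MU, 1 - exp(-lam_wt))
    (channel independence), NA the remainder; false-MU misreads are then
    applied to non-MU droplets.  Categories always partition n_droplets.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    lam_mu = config.true_maf * config.total_copies / n
    lam_wt = (1.0 - config.true_maf) * config.total_copies / n
    mu = int(rng.binomial(n, -np.expm1(-lam_mu)))
    wt = int(rng.binomial(n - mu, -np.expm1(-lam_wt)))
    na = n - mu - wt
    if config.false_mu_rate > 0:
        flip_wt = int(rng.binomial(wt, config.false_mu_rate))
        flip_na = int(rng.binomial(na, config.false_mu_rate))
        mu += flip_wt + flip_na
        wt -= flip_wt
        na -= flip_na
    return DropletData(mu=mu, wt=wt, na=na)


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Simulate a sex-stratified cohort of subjects.

    Each subject is independently mosaic with the sex-specific rate;
    mosaic subjects receive a true MAF from ``maf_distribution``.

    Returns a DataFrame with columns subject_id, sex, is_mosaic, true_maf
    (NaN for non-mosaic subjects).
    """
    rng = np.random.default_rng(config.seed)
    sexes = ["M"] * config.n_male + ["F"] * config.n_female
    rates = np.array(
        [config.rate_male] * config.n_male + [config.rate_female] * config.n_female
    )
    n = len(sexes)
    is_mosaic = (
        rng.random(n) < rates if n else np.zeros(0, dtype=bool)
    )
    mafs = np.full(n, np.nan)
    k = int(is_mosaic.sum())
    if k:
        mafs[is_mosaic] = _draw_mafs(config.maf_distribution, k, rng)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex": sexes,
            "is_mosaic": is_mosaic.astype(bool),
            "true_maf": mafs,
        }
    )


# Tissue-panel scenarios.  MAF set-points follow the published father
# panels: a germline-restricted pattern detectable only in one semen
# fraction, and an early-embryonic pattern with semen 7.55%, saliva 0.43%
# and blood 0.28% alongside it.
_SCENARIOS: dict[str, dict[str, float]] = {
    "negative_control": {},
    "germline_only": {"semen_L2": 0.014},
    "germline_only_sp_ot": {"semen_Sp": 0.0067, "semen_Ot": 0.0067},
    "early_embryonic": {
        "semen_Sp": 0.0755, "semen_L1": 0.0755, "semen_L2": 0.0755,
        "semen_Ot": 0.0755, "saliva": 0.0043, "blood": 0.0028,
    },
}


def simulate_tissue_panel(
    scenario_name: str,
    seed: int = 0,
    total_copies: int = 50_000,
    n_droplets: int = 5_000_000,
) -> dict[str, DropletData]:
    """Simulate a per-tissue droplet panel for one subject.

    Scenarios
    ---------
    ``negative_control`` : all tissues mutation-free.
    ``germline_only`` : mosaicism confined to the motile-sperm layer (L2).
    ``germline_only_sp_ot`` : mosaicism in Sperm and Others fractions.
    ``early_embryonic`` : mosaicism across all semen fractions plus low
        fractions in saliva and blood (pre-gastrulation origin).

    Returns a mapping tissue -> DropletData over the fixed tissue
    vocabulary.
    """
    if scenario_name not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario_name!r}; choose from {sorted(_SCENARIOS)}"
        )
    mafs = _SCENARIOS[scenario_name]
    panel: dict[str, DropletData] = {}
    for i, tissue in enumerate(TISSUES):
        panel[tissue] = simulate_droplets(
            DropletSimConfig(
                true_maf=mafs.get(tissue, 0.0),
                total_copies=total_copies,
                n_droplets=n_droplets,
                seed=seed * 1000 + i,
            )
        )
    return panel


def scenario_truth(scenario_name: str) -> dict[str, float]:
    """True per-tissue MAFs of a named tissue-panel scenario."""
    if scenario_name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_name!r}")
    return {t: _SCENARIOS[scenario_name].get(t, 0.0) for t in TISSUES}
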