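"""Simulation studies of estimator calibration, recovery and detection power.

These diagnostics run the package's own estimators on generated data whose
truth is known, and report the frequentist operating characteristics: the
credible-interval coverage of the screening posterior, the parameter
recovery of the amplicon (validation-stage) estimator, and the
limit-of-detection power curve of the droplet assay.  Reads are generated
bottleneck-free here: the posteriors model read sampling, so calibration
is checked against the read-sampling law; the template-bottleneck variance
of real libraries is a property of the material, not of the estimator, and
is exercised separately by the generator tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ddpcr import lod_power
from .pasm import fit_error_model, pasm_maf
from .screen import PileupSite, posterior_maf

__all__ = ["screen_calibration", "pasm_recovery", "lod_curve"]

DEFAULT_RECOVERY_FRACTIONS = (0.005, 0.01, 0.065, 0.20, 0.38)


def screen_calibration(
    n_sites: int = 2000,
    depth: int = 1000,
    error_rate: float = 1e-3,
    seed: int = 0,
) -> dict:
    """Coverage of the 95% credible interval and false-candidate rate.

    Simulates ``n_sites`` sites with true MAF uniform on [0, 1] and reads
    binomial at the error-folded success probability, plus ``n_sites``
    variant-free sites; reports the fraction of intervals containing the
    true MAF and the fraction of variant-free sites whose interval lower
    bound clears the 0.5% candidate floor.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 1.0, n_sites)
    k = rng.binomial(depth, error_rate + f * (1 - 2 * error_rate))
    covered = 0
    for fi, ki in zip(f, k):
        post = posterior_maf(int(ki), depth, error_rate)
        covered += post.ci_low <= fi <= post.ci_high
    k0 = rng.binomial(depth, error_rate, n_sites)
    false_candidates = sum(
        posterior_maf(int(ki), depth, error_rate).ci_low >= 0.005 for ki in k0
    )
    return {
        "coverage": covered / n_sites,
        "false_candidate_rate": false_candidates / n_sites,
        "n_sites": n_sites,
    }


def pasm_recovery(
    fractions: tuple = DEFAULT_RECOVERY_FRACTIONS,
    depth: int = 12_000,
    reps: int = 200,
    error_rate: float = 1e-3,
    n_controls: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter recovery of the amplicon estimator at set-point MAFs.

    For each true MAF: simulate ``reps`` amplicon runs, estimate with the
    error model fitted from simulated variant-free controls, and report
    the median absolute MAP error and the 95%-interval coverage.
    """
    rng = np.random.default_rng(seed)
    controls = [
        PileupSite(site_id=f"ctrl{i}", ref_count=depth - int(ki),
                   alt_count=int(ki), error_rate=error_rate)
        for i, ki in enumerate(rng.binomial(depth, error_rate, n_controls))
    ]
    error_model = fit_error_model(controls)
    rows = []
    for f in fractions:
        p = error_rate + f * (1 - 2 * error_rate)
        ks = rng.binomial(depth, p, reps)
        errs, covered = [], 0
        for ki in ks:
            est = pasm_maf(int(ki), depth, error_model)
            errs.append(abs(est.map_maf - f))
            covered += est.ci_low <= f <= est.ci_high
        rows.append({
            "true_maf": f,
            "median_abs_error": float(np.median(errs)),
            "coverage": covered / reps,
            "tolerance": max(0.002, 0.1 * f),
            "reps": reps,
        })
    return pd.DataFrame(rows)


def lod_curve(
    fractions=(1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 1e-2),
    total_copies: int = 100_000,
    n_droplets: int = 5_000_000,
    reps: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection power (>= 3 MU droplets) as a function of the true MAF."""
    rows = [
        {"true_maf": f,
         "power": lod_power(f, total_copies, n_droplets=n_droplets,
                            reps=reps, seed=seed + i)}
        for i, f in enumerate(fractions)
    ]
    return pd.DataFrame(rows)
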