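"""Generator distributional checks against analytic and molecule-level oracles."""

import numpy as np
import pytest

from mosaicmap import (
    CohortSimConfig,
    DropletSimConfig,
    SimConfig,
    simulate_amplicon,
    simulate_cohort,
    simulate_droplets,
    simulate_pileup,
    simulate_tissue_panel,
)
from mosaicmap.simulate import SEMEN_FRACTIONS, TISSUES, scenario_truth


class TestPileup:
    def test_error_free_homozygous(self):
        sites = simulate_pileup(
            SimConfig(true_maf=1.0, error_rate=0.0, depth=100, seed=1, n_sites=5))
        assert all(s.alt_count == 100 and s.ref_count == 0 for s in sites)

    def test_counts_sum_to_depth(self):
        sites = simulate_pileup(
            SimConfig(true_maf=0.3, depth=777, error_rate=1e-3, seed=2, n_sites=50))
        assert all(s.depth == 777 for s in sites)

    def test_error_only_sites_match_binomial_expectation(self):
        """At f=0 the mean alt count equals depth * error_rate (binomial oracle)."""
        cfg = SimConfig(true_maf=0.0, error_rate=1e-3, depth=10_000, seed=3,
                        n_sites=1000)
        sites = simulate_pileup(cfg)
        alt = np.array([s.alt_count for s in sites])
        expect = 10_000 * 1e-3
        se = np.sqrt(10_000 * 1e-3 * (1 - 1e-3) / 1000)
        assert abs(alt.mean() - expect) < 3 * se

    def test_het_symmetry(self):
        cfg = SimConfig(true_maf=0.5, error_rate=0.0, depth=10_000, seed=4,
                        n_sites=1000)
        frac = np.array([s.alt_count / s.depth for s in simulate_pileup(cfg)])
        se = np.sqrt(0.25 * (1 / 3000 + 1 / 10_000) / 1000)
        assert abs(frac.mean() - 0.5) < 3 * se

    def test_reproducibility(self):
        cfg = SimConfig(true_maf=0.1, depth=500, seed=99, n_sites=20)
        a = [(s.ref_count, s.alt_count) for s in simulate_pileup(cfg)]
        b = [(s.ref_count, s.alt_count) for s in simulate_pileup(cfg)]
        assert a == b

    @pytest.mark.parametrize("bad", [
        dict(true_maf=1.5), dict(error_rate=0.5), dict(depth=0),
        dict(input_copies=0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestAmplicon:
    def test_single_template_jackpot(self):
        fracs = {
            simulate_amplicon(
                SimConfig(true_maf=0.5, input_copies=1, error_rate=0.0,
                          depth=1000, seed=s)
            ).alt_count / 1000
            for s in range(20)
        }
        assert fracs <= {0.0, 1.0}
        assert len(fracs) == 2  # both jackpot outcomes appear

    def test_bottleneck_overdispersion(self):
        """Replicate variance at 12,000x over 6000 copies exceeds binomial
        read-sampling variance (two-stage sampling oracle)."""
        f, depth, copies = 0.05, 12_000, 6000
        fracs = np.array([
            simulate_amplicon(SimConfig(true_maf=f, depth=depth,
                                        input_copies=copies, error_rate=0.0,
                                        seed=s)).alt_count / depth
            for s in range(500)
        ])
        var_binom = f * (1 - f) / depth
        var_two_stage = f * (1 - f) * (1 / copies + 1 / depth)
        assert fracs.var() > 1.5 * var_binom
        assert abs(fracs.var() / var_two_stage - 1) < 0.35

    def test_bottleneck_free_limit(self):
        f, depth = 0.05, 1000
        fracs = np.array([
            simulate_amplicon(SimConfig(true_maf=f, depth=depth,
                                        input_copies=10**9, error_rate=0.0,
                                        seed=s)).alt_count / depth
            for s in range(2000)
        ])
        assert abs(fracs.var() / (f * (1 - f) / depth) - 1) < 0.1


class TestDroplets:
    def test_no_mutant_source(self):
        d = simulate_droplets(DropletSimConfig(true_maf=0.0, false_mu_rate=0.0,
                                               total_copies=10_000,
                                               n_droplets=100_000, seed=1))
        assert d.mu == 0

    def test_empty_run(self):
        d = simulate_droplets(DropletSimConfig(true_maf=0.3, total_copies=0,
                                               n_droplets=5000, seed=2))
        assert (d.mu, d.wt, d.na) == (0, 0, 5000)

    def test_partition_conservation(self):
        d = simulate_droplets(DropletSimConfig(true_maf=0.1, total_copies=50_000,
                                               n_droplets=200_000, seed=3,
                                               false_mu_rate=1e-5))
        assert d.mu + d.wt + d.na == 200_000

    def test_against_molecule_level_oracle(self, rng):
        """Aggregate draw matches a direct molecule-level assignment
        simulation: each molecule lands in a uniformly chosen droplet and
        droplet labels follow from their contents."""
        f, total, n = 0.1, 100_000, 1_000_000

        def oracle_run(seed):
            r = np.random.default_rng(seed)
            n_mut = r.binomial(total, f)
            mut_droplets = np.unique(r.integers(0, n, n_mut))
            wt_droplets = np.unique(r.integers(0, n, total - n_mut))
            mu = mut_droplets.size
            wt = np.setdiff1d(wt_droplets, mut_droplets, assume_unique=True).size
            return mu / (mu + wt)

        oracle = np.array([oracle_run(s) for s in range(20)])
        sim = np.array([
            (lambda d: d.mu / (d.mu + d.wt))(simulate_droplets(
                DropletSimConfig(true_maf=f, total_copies=total, n_droplets=n,
                                 seed=1000 + s)))
            for s in range(20)
        ])
        # both estimate the same occupancy-biased raw ratio
        se = np.sqrt(oracle.var() / 20 + sim.var() / 20) + 1e-4
        assert abs(oracle.mean() - sim.mean()) < 3 * se
        # and within 3 binomial SE of the analytic raw-ratio expectation
        lam = total / n
        expect = (1 - np.exp(-lam * f)) / (
            (1 - np.exp(-lam * f)) + (1 - np.exp(-lam * (1 - f))))
        assert abs(sim.mean() - expect) < 3 * np.sqrt(expect * (1 - expect) / (96_000 * 20))

    def test_false_mu_rate_creates_background(self):
        d = simulate_droplets(DropletSimConfig(true_maf=0.0, total_copies=10_000,
                                               n_droplets=1_000_000,
                                               false_mu_rate=1e-5, seed=5))
        assert d.mu > 0


class TestCohort:
    def test_deterministic_rates(self):
        df = simulate_cohort(CohortSimConfig(rate_male=1.0, rate_female=0.0, seed=1))
        assert df.is_mosaic.sum() == 18
        assert set(df.loc[df.is_mosaic, "sex"]) == {"M"}
        assert df.loc[df.is_mosaic, "true_maf"].notna().all()

    def test_empty_cohort(self):
        df = simulate_cohort(CohortSimConfig(n_male=0, n_female=0))
        assert len(df) == 0

    def test_mosaic_count_expectation(self):
        """Mean mosaic male count over replicate cohorts matches the binomial
        expectation 18 * (3/18) = 3."""
        counts = [
            simulate_cohort(CohortSimConfig(seed=s)).query(
                "sex == 'M' and is_mosaic").shape[0]
            for s in range(500)
        ]
        se = np.sqrt(18 * (3 / 18) * (15 / 18) / 500)
        assert abs(np.mean(counts) - 3.0) < 3 * se


class TestTissuePanel:
    def test_negative_control_all_zero(self):
        panel = simulate_tissue_panel("negative_control", seed=1)
        assert set(panel) == set(TISSUES)
        assert all(d.mu == 0 for d in panel.values())

    def test_germline_only_somatic_tissues_clean(self):
        panel = simulate_tissue_panel("germline_only", seed=2)
        for tissue in ("blood", "saliva", "hair", "urine", "buccal"):
            assert panel[tissue].mu == 0
        assert panel["semen_L2"].mu > 0

    def test_early_embryonic_truth_setpoints(self):
        truth = scenario_truth("early_embryonic")
        assert truth["semen_L2"] == pytest.approx(0.0755)
        assert truth["saliva"] == pytest.approx(0.0043)
        assert truth["blood"] == pytest.approx(0.0028)
        panel = simulate_tissue_panel("early_embryonic", seed=3)
        assert all(panel[t].mu > 0 for t in SEMEN_FRACTIONS)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_tissue_panel("no_such_thing", seed=0)
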