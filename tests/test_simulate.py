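"""Synthetic-chip generator: conservation, determinism, Poisson structure."""

import numpy as np
import pytest
from scipy import stats

from digiwell import simulate
from digiwell.chip import POSITIVE
from digiwell.digital import quantify_run
from digiwell.simulate import (
    EmtScenario,
    InhibitionSimParams,
    SimulationConfig,
    partition_molecules,
    simulate_bulk_qpcr,
    simulate_cell_loading,
    simulate_chip,
    simulate_dilution_series,
    simulate_emt_experiment,
    simulate_inhibited_chip,
    simulate_ntc,
)


class TestPartitioning:
    def test_zero_copies_all_empty(self, rng):
        counts = partition_molecules(0, 2500, rng)
        assert counts.sum() == 0

    @pytest.mark.parametrize("total", [1, 137, 2500, 10000])
    def test_molecule_conservation(self, total, rng):
        assert partition_molecules(total, 2500, rng).sum() == total

    def test_poisson_limit_empty_fraction(self):
        rng = np.random.default_rng(9)
        fractions = [
            np.mean(partition_molecules(2500, 2500, rng) == 0) for _ in range(20)
        ]
        assert np.mean(fractions) == pytest.approx(np.exp(-1), abs=0.01)

    def test_marginal_occupancy_is_poisson(self):
        rng = np.random.default_rng(41)
        pooled = np.concatenate(
            [partition_molecules(2500, 2500, rng) for _ in range(10)]
        )
        values, observed = np.unique(pooled, return_counts=True)
        kmax = 6
        obs = np.array(
            [observed[values == k].sum() if k in values else 0 for k in range(kmax)]
            + [observed[values >= kmax].sum()],
            dtype=float,
        )
        lam = pooled.mean()
        exp_p = np.append(stats.poisson.pmf(np.arange(kmax), lam),
                          stats.poisson.sf(kmax - 1, lam))
        chi2 = stats.chisquare(obs, exp_p * pooled.size, ddof=1)
        assert chi2.pvalue > 0.01


class TestSimulateChip:
    def test_low_template_singletons_near_anchor(self, config):
        cfg = SimulationConfig(cq_noise_sd=0.0)
        run = simulate_chip(35, cfg, np.random.default_rng(2))
        assert run.k_positive == pytest.approx(35, abs=2)  # rare collisions only
        cqs = run.positive_cqs()
        # singletons sit at the anchor; the odd doublet is one ln2/ln(1+E)
        # step (~1.08 cycles) earlier
        assert np.all(np.abs(cqs - cfg.cq1_true) < 1.2)
        assert np.median(np.abs(cqs - cfg.cq1_true)) < 0.05

    def test_saturated_chip_all_positive_low_cq(self, config, rng):
        run = simulate_chip(3_400_000, config, rng)
        assert run.k_positive == 2500
        assert run.positive_cqs().mean() < config.cq1_true - 5

    def test_end_to_end_recovery_within_poisson_interval(self, config, rng):
        run = simulate_chip(500, config, rng)
        res = quantify_run(run)
        lo, hi = stats.poisson.interval(0.95, 500)
        assert lo <= res.total_copies <= hi

    def test_fixed_seed_reproducible(self, config):
        a = simulate_chip(300, config, np.random.default_rng(6))
        b = simulate_chip(300, config, np.random.default_rng(6))
        assert a == b

    def test_different_seeds_differ(self, config):
        a = simulate_chip(300, config, np.random.default_rng(6))
        b = simulate_chip(300, config, np.random.default_rng(7))
        assert a != b


class TestNtcAndDimers:
    def test_ntc_positive_count_matches_dimer_rate(self, config):
        rng = np.random.default_rng(14)
        counts = [simulate_ntc(config, rng).k_positive for _ in range(200)]
        assert np.mean(counts) == pytest.approx(config.dimer_rate_mean, abs=0.3)

    def test_ntc_dimer_cq_signature(self, config):
        rng = np.random.default_rng(15)
        cqs = np.concatenate(
            [simulate_ntc(config, rng).positive_cqs() for _ in range(200)]
        )
        assert cqs.mean() == pytest.approx(config.dimer_cq_mean, abs=1.0)
        assert cqs.std(ddof=1) == pytest.approx(config.dimer_cq_sd, abs=1.2)

    def test_template_chips_show_no_dimers_by_default(self, config):
        rng = np.random.default_rng(16)
        run = simulate_chip(100, config, rng)
        assert run.truth["dimer_wells"].size == 0


class TestDilutionSeries:
    def test_plateau_emerges_at_low_concentration(self, config):
        rng = np.random.default_rng(19)
        concs = [3.4 * 10**i for i in range(9)]
        dig, _ = simulate_dilution_series(concs, config, rng)
        cq = dig.mean_cqs
        assert abs(cq[1] - cq[0]) < 0.5  # digital plateau
        assert cq[4] - cq[5] > 3.0  # linear regime steps ~3.6 cycles/decade

    def test_fitted_efficiency_close_to_truth(self, config):
        cfg = SimulationConfig(cq_noise_sd=0.2)
        rng = np.random.default_rng(20)
        concs = [3.4 * 10**i for i in range(9)]
        dig, bulk = simulate_dilution_series(concs, cfg, rng)
        from digiwell.standard_curve import fit_standard_curve

        fit = fit_standard_curve(dig, levels=[4, 5, 6, 7, 8])
        assert abs(fit.efficiency_percent - 100 * cfg.efficiency_true) < 2.0
        bfit = fit_standard_curve(bulk, levels=[4, 5, 6, 7, 8])
        assert abs(bfit.efficiency_percent - 100 * cfg.efficiency_true) < 2.0


class TestInhibitedChip:
    def test_zero_concentration_matches_plain_chip(self, config):
        params = InhibitionSimParams()
        a = simulate_inhibited_chip(0.0, params, config, np.random.default_rng(3), 400)
        b = simulate_chip(400, config, np.random.default_rng(3))
        assert a == b

    def test_half_of_wells_lost_at_midpoint(self, config):
        params = InhibitionSimParams()
        rng = np.random.default_rng(26)
        ratios = []
        for _ in range(30):
            nic = simulate_inhibited_chip(0.0, params, config, rng, 500)
            inh = simulate_inhibited_chip(
                params.ic50_complete, params, config, rng, 500
            )
            ratios.append(inh.k_positive / nic.k_positive)
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.03)

    def test_survivors_run_at_reduced_efficiency(self, config):
        cfg = SimulationConfig(cq_noise_sd=0.0)
        params = InhibitionSimParams()
        rng = np.random.default_rng(27)
        inh = simulate_inhibited_chip(0.25, params, cfg, rng, 200)
        assert inh.positive_cqs().mean() > cfg.cq1_true + 1.0


class TestCellLoadingAndEmt:
    def test_cell_conservation(self, rng):
        obs, counts = simulate_cell_loading(500, 2500, rng)
        assert counts.sum() == 500
        assert sum(k * v for k, v in obs.counts_per_occupancy.items()) == 500

    def test_zero_cells_all_empty(self, rng):
        obs, counts = simulate_cell_loading(0, 2500, rng)
        assert obs.counts_per_occupancy == {0: 2500}

    def test_single_cell_share_near_90_percent_at_500(self):
        rng = np.random.default_rng(33)
        shares = []
        for _ in range(50):
            obs, _ = simulate_cell_loading(500, 2500, rng)
            p0, p1, _ = obs.proportions
            shares.append(100 * p1 / (1 - p0))
        assert np.mean(shares) == pytest.approx(90.33, abs=0.5)

    def test_emt_records_have_expected_structure(self, config, rng):
        records, truth = simulate_emt_experiment(EmtScenario(), config, rng)
        assert set(records["gene"]) == {"E-cadherin", "N-cadherin", "vimentin", "GAPDH"}
        assert set(records["condition"]) == {"control", "d1", "d2", "d4"}
        # ~453 occupied wells per gene x condition at 500 cells loaded
        sizes = records.groupby(["gene", "condition"]).size()
        assert sizes.between(380, 520).all()


class TestBulkQpcr:
    def test_requested_replicates_returned(self, config):
        cfg = SimulationConfig(cq_noise_sd=0.1)
        reps = simulate_bulk_qpcr(3000, 3, cfg, np.random.default_rng(1))
        assert len(reps.cq_values) == 3

    def test_high_copy_zero_noise_identical_cq(self):
        cfg = SimulationConfig(cq_noise_sd=0.0)
        reps = simulate_bulk_qpcr(3e6, 3, cfg, np.random.default_rng(1),
                                  aliquot_sampling=False)
        assert np.ptp(reps.cq_values) == pytest.approx(0.0, abs=1e-12)

    def test_low_copy_bulk_cv_exceeds_digital(self, config):
        rng = np.random.default_rng(44)
        from digiwell.chip import summarize_replicates

        bulk_cv, dig_cv = [], []
        for _ in range(60):
            reps = simulate_bulk_qpcr(21, 3, config, rng)
            if len(reps.cq_values) >= 2:
                bulk_cv.append(summarize_replicates(reps).cv_percent)
            means = []
            for _ in range(3):
                run = simulate_chip(int(rng.poisson(21)), config, rng)
                means.append(run.positive_cqs().mean())
            means = np.asarray(means)
            dig_cv.append(100 * means.std(ddof=1) / means.mean())
        assert np.mean(dig_cv) < np.mean(bulk_cv)
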