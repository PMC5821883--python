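"""Single-cell expression: copy conversion, geometric means, KS testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from digiwell import simulate
from digiwell.errors import FormatError, InsufficientDataError
from digiwell.expression import (
    ExpressionProfile,
    copies_per_cell,
    geometric_mean_copies,
    ks_one_sample,
    ks_two_sample,
    log_histogram,
    profile_timecourse,
)


class TestCopiesPerCell:
    @pytest.mark.parametrize(
        "cq,cq1,expected", [(26.2, 26.2, 1.0), (16.2, 26.2, 1024.0), (28.2, 26.2, 0.25)]
    )
    def test_doubling_arithmetic(self, cq, cq1, expected):
        assert copies_per_cell(cq, cq1) == pytest.approx(expected)

    @given(cq=st.floats(5.0, 39.0), d=st.floats(0.01, 5.0))
    def test_strictly_decreasing_in_cq(self, cq, d):
        assert copies_per_cell(cq + d, 26.2) < copies_per_cell(cq, 26.2)


class TestGeometricMean:
    def test_two_and_eight(self):
        assert geometric_mean_copies([2.0, 8.0]) == pytest.approx(4.0)

    def test_constant(self):
        assert geometric_mean_copies([7.0] * 5) == pytest.approx(7.0)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            geometric_mean_copies([])

    @given(cqs=st.lists(st.floats(10.0, 35.0), min_size=1, max_size=30))
    def test_equals_copies_at_arithmetic_mean_cq(self, cqs):
        copies = copies_per_cell(np.array(cqs), 26.2)
        gm = geometric_mean_copies(copies)
        assert gm == pytest.approx(float(copies_per_cell(np.mean(cqs), 26.2)), rel=1e-9)


class TestKsOneSample:
    def test_null_behaviour_on_normal_draws(self, rng):
        x = rng.normal(5.0, 1.0, size=1000)
        res = ks_one_sample(x, family="normal")
        assert res.statistic_d < 0.05
        assert res.p_value > 0.001

    def test_lognormal_family_tests_log_values(self, rng):
        x = np.exp(rng.normal(2.0, 0.5, size=500))
        res = ks_one_sample(x, family="lognormal")
        assert res.p_value > 0.001

    def test_bimodal_mixture_rejected_with_power(self):
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(40):
            x = np.concatenate(
                [rng.normal(-3, 1, size=150), rng.normal(3, 1, size=150)]
            )
            if ks_one_sample(x, family="normal").p_value < 0.05:
                rejections += 1
        assert rejections / 40 >= 0.95

    def test_constant_values_degenerate(self):
        with pytest.raises(InsufficientDataError):
            ks_one_sample([3.0] * 20, family="normal")

    def test_nonpositive_values_rejected_for_lognormal(self):
        with pytest.raises(FormatError):
            ks_one_sample([1.0, 2.0, -1.0, 4.0, 5.0], family="lognormal")

    def test_bootstrap_p_value_close_to_asymptotic_under_null(self, rng):
        x = rng.normal(0, 1, size=300)
        res = ks_one_sample(x, family="normal", n_bootstrap=200, rng=1)
        assert 0.0 < res.p_value <= 1.0


class TestKsTwoSample:
    def test_identical_samples_d_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = ks_two_sample(x, x)
        assert res.statistic_d == pytest.approx(0.0)

    def test_disjoint_supports_d_one(self):
        res = ks_two_sample([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert res.statistic_d == pytest.approx(1.0)

    @given(
        a=st.lists(st.floats(0.1, 100.0), min_size=5, max_size=40),
        b=st.lists(st.floats(0.1, 100.0), min_size=5, max_size=40),
    )
    def test_symmetric_and_log_invariant(self, a, b):
        d_ab = ks_two_sample(a, b).statistic_d
        d_ba = ks_two_sample(b, a).statistic_d
        assert d_ab == pytest.approx(d_ba)
        d_log = ks_two_sample(np.log(a), np.log(b)).statistic_d
        assert d_ab == pytest.approx(d_log)

    def test_twofold_shift_detected_with_power(self):
        rng = np.random.default_rng(23)
        rejections = 0
        for _ in range(30):
            a = np.exp(rng.normal(1.0, 1.0, size=400))
            b = 2.0 * np.exp(rng.normal(1.0, 1.0, size=400))
            if ks_two_sample(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / 30 >= 0.9


class TestProfileTimecourse:
    def test_emt_scenario_flags_shifting_genes(self, config):
        records, truth = simulate.simulate_emt_experiment(
            simulate.EmtScenario(), config, np.random.default_rng(11)
        )
        report = profile_timecourse(
            records, cq1_ref=26.20, condition_order=["control", "d1", "d2", "d4"]
        )
        ncad = report.genes["N-cadherin"]
        assert len(ncad.significant_pairs()) == 6  # all pairwise shifts detected
        gms = [ncad.geometric_means[c] for c in ("control", "d1", "d2", "d4")]
        assert gms == sorted(gms)  # monotone increase through the time course
        vim = report.genes["vimentin"]
        assert len(vim.significant_pairs()) == 6
        v = [vim.geometric_means[c] for c in ("control", "d1", "d2", "d4")]
        assert v[1] > v[0] and v[2] > v[1] and v[3] < v[2]  # up then down

    def test_null_scenario_rarely_flagged(self, config):
        """With no true effects, Holm across the whole report keeps runs with
        any significant pair to <= 10%."""
        flagged = 0
        n_seeds = 20
        for seed in range(n_seeds):
            records, _ = simulate.simulate_emt_experiment(
                simulate.EmtScenario.null(), config, np.random.default_rng(100 + seed)
            )
            report = profile_timecourse(records, cq1_ref=26.20)
            if any(len(rep.significant_pairs()) > 0 for rep in report.genes.values()):
                flagged += 1
        assert flagged <= 0.1 * n_seeds

    def test_single_condition_reports_means_only(self):
        records = pd.DataFrame(
            {
                "well_id": [f"w{i}" for i in range(20)],
                "gene": ["g"] * 20,
                "condition": ["control"] * 20,
                "cq": np.linspace(20, 25, 20),
            }
        )
        report = profile_timecourse(records, cq1_ref=26.2)
        assert report.genes["g"].pairwise is None
        assert "control" in report.genes["g"].geometric_means

    def test_geometric_means_recover_truth(self, config):
        records, truth = simulate.simulate_emt_experiment(
            simulate.EmtScenario(), config, np.random.default_rng(4)
        )
        # single-cell wells only: the simulator's truth excludes multiplets
        singles = records[records["n_cells"] == 1]
        profile = ExpressionProfile(singles, cq1_ref=26.20)
        gms = profile.geometric_means()
        rel_errors = [
            abs(gms.loc[gene, cond] / true_gm - 1)
            for (gene, cond), true_gm in truth["geometric_means"].items()
        ]
        assert np.mean(rel_errors) < 0.10
        assert max(rel_errors) < 0.20


def test_one_sample_ks_null_p_values_uniform(config):
    """Under lognormal truth, the moment-estimated one-sample KS p-values are
    close to uniform (the Lilliefors inflation is mild at these sizes)."""
    rng = np.random.default_rng(55)
    pvals = []
    for _ in range(300):
        x = np.exp(rng.normal(1.5, 0.6, size=200))
        pvals.append(ks_one_sample(x, family="lognormal").p_value)
    # KS-of-KS against uniform: moment estimation shifts p high, never spuriously low
    from scipy import stats

    d, p = stats.kstest(pvals, "uniform")
    assert np.mean(np.array(pvals) < 0.05) <= 0.05  # conservative type-I behaviour


def test_log_histogram_fd_bins():
    rng = np.random.default_rng(2)
    copies = np.exp(rng.normal(3, 1, size=500))
    edges, counts = log_histogram(copies)
    assert counts.sum() == 500
    assert len(edges) == len(counts) + 1
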