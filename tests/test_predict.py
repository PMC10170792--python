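import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqblup.errors import ConfigurationError, DataError
from seqblup.grm import GRM, compute_grm
from seqblup.predict import (
    accuracy,
    bias_slope,
    cross_validate,
    gblup_predict,
    multiblup_predict,
    percent_increase,
)

from conftest import random_gm
from test_varcomp import simulate_y


class TestAccuracy:
    def test_identity(self, rng):
        y = rng.normal(size=10)
        assert accuracy(y, y) == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        y = rng.normal(size=10)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # pairs (1,2),(2,1),(3,3),(4,4): r = 1.0/1.25 = 0.8
        assert accuracy([1, 2, 3, 4], [2, 1, 3, 4]) == pytest.approx(0.8)

    def test_zero_variance_flagged(self):
        with pytest.raises(DataError):
            accuracy([1, 2, 3], [5, 5, 5])

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            accuracy([1, 2], [1, 2])


class TestBiasSlope:
    def test_identity(self, rng):
        y = rng.normal(size=10)
        assert bias_slope(y, y) == pytest.approx(1.0)

    def test_halved_gebv_doubles_slope(self, rng):
        y = rng.normal(size=20)
        assert bias_slope(y, 0.5 * y) == pytest.approx(2.0)

    @given(c=st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_location_invariance(self, c):
        rng = np.random.default_rng(0)
        y = rng.normal(size=15)
        g = rng.normal(size=15)
        assert bias_slope(y, g + c) == pytest.approx(bias_slope(y, g), abs=1e-8)

    def test_zero_gebv_variance_flagged(self):
        with pytest.raises(DataError):
            bias_slope([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestGblup:
    def _setup(self, n=120, m=400, h2=0.5, seed=1):
        gm, y, _ = simulate_y(n=n, m=m, h2=h2, seed=seed)
        g = compute_grm(gm)
        n_train = int(0.8 * n)
        return y, g, g.sample_ids[:n_train], g.sample_ids[n_train:], n_train

    def test_floored_variance_gives_zero_gebv(self):
        y, g, train, _, n_t = self._setup()
        res = gblup_predict(y[:n_t], g, train, variances=(1e-15, 1.0))
        np.testing.assert_allclose(res.gebv, 0.0)
        assert res.mu_hat == pytest.approx(y[:n_t].mean())

    def test_independent_individual_zero_gebv(self):
        n = 20
        values = np.eye(n)
        values[:5, :5] += 0.5  # correlated block, sample 19 isolated
        np.fill_diagonal(values, 1.0)
        ids = [f"s{i}" for i in range(n)]
        g = GRM(ids, values, n_markers=10, algorithm="vanraden1")
        rng = np.random.default_rng(2)
        y = rng.normal(size=n - 1)
        res = gblup_predict(y, g, ids[:-1], variances=(0.5, 0.5))
        # last sample has zero genomic covariance with all training samples
        assert abs(res.gebv[-1]) < 1e-10

    def test_mme_equals_closed_form(self):
        for seed in range(3):
            gm, y, _ = simulate_y(n=30, m=200, h2=0.5, seed=40 + seed)
            g = compute_grm(gm)
            train = g.sample_ids[:24]
            a = gblup_predict(y[:24], g, train, variances=(0.6, 0.4), method="mme")
            b = gblup_predict(
                y[:24], g, train, variances=(0.6, 0.4), method="closed_form"
            )
            np.testing.assert_allclose(a.gebv, b.gebv, atol=1e-8)
            assert a.mu_hat == pytest.approx(b.mu_hat, abs=1e-8)

    def test_shift_equivariance(self):
        y, g, train, _, n_t = self._setup(seed=5)
        a = gblup_predict(y[:n_t], g, train, variances=(0.5, 0.5))
        b = gblup_predict(y[:n_t] + 7.0, g, train, variances=(0.5, 0.5))
        assert b.mu_hat == pytest.approx(a.mu_hat + 7.0, abs=1e-8)
        np.testing.assert_allclose(a.gebv, b.gebv, atol=1e-8)


class TestMultiblup:
    def _setup(self, seed=2):
        gm, y, _ = simulate_y(n=100, m=400, h2=0.5, seed=seed)
        half = 200
        gf = compute_grm(gm.subset_variants(np.arange(half)))
        gr = compute_grm(gm.subset_variants(np.arange(half, 400)))
        train = gf.sample_ids[:80]
        return y[:80], gf, gr, train

    def test_floored_component_reduces_to_gblup(self):
        y, gf, gr, train = self._setup()
        m = multiblup_predict(y, gf, gr, train, variances=(1e-14, 0.6, 0.5))
        g = gblup_predict(y, gr, train, variances=(0.6, 0.5), method="closed_form")
        np.testing.assert_allclose(m.gebv, g.gebv, atol=1e-6)

    def test_duplicated_grm_additivity(self):
        y, gf, gr, train = self._setup()
        m = multiblup_predict(y, gr, gr, train, variances=(0.2, 0.3, 0.5))
        g = gblup_predict(y, gr, train, variances=(0.5, 0.5), method="closed_form")
        np.testing.assert_allclose(m.gebv, g.gebv, atol=1e-6)

    def test_label_swap_symmetry(self):
        y, gf, gr, train = self._setup()
        a = multiblup_predict(y, gf, gr, train, variances=(0.3, 0.5, 0.4))
        b = multiblup_predict(y, gr, gf, train, variances=(0.5, 0.3, 0.4))
        np.testing.assert_allclose(a.components["g_f"], b.components["g_r"], atol=1e-10)
        np.testing.assert_allclose(a.components["g_r"], b.components["g_f"], atol=1e-10)

    def test_components_sum_to_total(self):
        y, gf, gr, train = self._setup()
        res = multiblup_predict(y, gf, gr, train, variances=(0.3, 0.4, 0.5))
        np.testing.assert_allclose(
            res.components["g_f"] + res.components["g_r"], res.gebv, atol=1e-8
        )


class TestCrossValidate:
    def test_exact_round_count(self):
        gm, y, _ = simulate_y(n=100, m=300, h2=0.4, seed=3)
        g = compute_grm(gm)
        res = cross_validate(y, [g], k=5, reps=5, seed=1,
                             refit_variances=False, variances=(0.5, 0.5))
        assert res.n_rounds == 25

    def test_null_h2_accuracy_near_zero(self, rng):
        gm = random_gm(200, 400, rng)
        y = rng.normal(size=200)
        g = compute_grm(gm)
        res = cross_validate(y, [g], k=5, reps=2, seed=2)
        se = res.summary["sd_accuracy"] / np.sqrt(res.n_rounds)
        assert abs(res.summary["mean_accuracy"]) < 2.5 * se + 0.05

    def test_deterministic(self):
        gm, y, _ = simulate_y(n=80, m=200, h2=0.4, seed=6)
        g = compute_grm(gm)
        a = cross_validate(y, [g], k=4, reps=2, seed=5)
        b = cross_validate(y, [g], k=4, reps=2, seed=5)
        assert a.records.equals(b.records)

    def test_folds_partition(self):
        gm, y, _ = simulate_y(n=53, m=150, h2=0.4, seed=8)
        g = compute_grm(gm)
        res = cross_validate(y, [g], k=5, reps=2, seed=4,
                             refit_variances=False, variances=(0.4, 0.6))
        sizes = res.records.groupby("repetition")["n_validation"].sum()
        assert (sizes == 53).all()
        per_fold = res.records["n_validation"]
        assert per_fold.max() - per_fold.min() <= 1

    def test_signal_recovered(self):
        gm, y, _ = simulate_y(n=300, m=1000, h2=0.6, seed=10)
        g = compute_grm(gm)
        res = cross_validate(y, [g], k=5, reps=1, seed=3)
        assert res.summary["mean_accuracy"] > 0.25

    def test_k_too_small(self):
        gm, y, _ = simulate_y(n=30, m=100, h2=0.4, seed=12)
        with pytest.raises(ConfigurationError):
            cross_validate(y, [compute_grm(gm)], k=1)


class TestPercentIncrease:
    def test_printed_table_examples(self):
        assert percent_increase(0.23, 0.27) == 17.39
        assert percent_increase(0.08, 0.14) == 75.00

    def test_no_change(self):
        assert percent_increase(0.4, 0.4) == 0.0

    def test_nonpositive_baseline(self):
        with pytest.raises(ConfigurationError):
            percent_increase(0.0, 0.5)

    @given(
        base=st.floats(0.01, 10, allow_nan=False),
        new=st.floats(0, 10, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_definition(self, base, new):
        assert percent_increase(base, new) == pytest.approx(
            100 * (new - base) / base, abs=0.005
        )
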