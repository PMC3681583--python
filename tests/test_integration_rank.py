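import numpy as np
import pytest

from pcov import cpc, simulate
from pcov.datamodel import CANONICAL_TRAITS, CovarianceEstimate, ValidationError
from pcov.integration import (
    build_integration_report,
    estimate_rank,
    rel_sd_lambda,
    rel_sd_lambda_adjusted,
    simulate_repeats,
    simulate_repeats_gaussian,
)
from helpers import random_table


def _corr_est(matrix, n=60):
    p = matrix.shape[0]
    return CovarianceEstimate(matrix, n, CANONICAL_TRAITS[:p],
                              scale="correlation")


class TestRelSdLambda:
    def test_identity_is_zero(self):
        assert rel_sd_lambda(_corr_est(np.eye(5))) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p", [2, 4, 9])
    def test_all_ones_is_one(self, p):
        assert rel_sd_lambda(_corr_est(np.ones((p, p)))) == pytest.approx(1.0)

    def test_two_by_two_equals_abs_r(self):
        for r in (-0.6, 0.3, 0.6, 0.95):
            mat = np.array([[1.0, r], [r, 1.0]])
            assert rel_sd_lambda(_corr_est(mat)) == pytest.approx(abs(r))

    def test_invariant_to_reordering_and_scaling(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 5))
        cov = a @ a.T + 5 * np.eye(5)
        est = CovarianceEstimate(cov, 60, CANONICAL_TRAITS[:5])
        base = rel_sd_lambda(est)
        perm = rng.permutation(5)
        est_perm = CovarianceEstimate(cov[np.ix_(perm, perm)], 60,
                                      tuple(CANONICAL_TRAITS[i] for i in perm))
        assert rel_sd_lambda(est_perm) == pytest.approx(base)
        est_scaled = CovarianceEstimate(7.3 * cov, 60, CANONICAL_TRAITS[:5])
        assert rel_sd_lambda(est_scaled) == pytest.approx(base)

    def test_monotone_in_common_correlation(self):
        values = []
        for r in np.arange(0.0, 0.95, 0.1):
            mat = np.full((6, 6), r) + (1 - r) * np.eye(6)
            values.append(rel_sd_lambda(_corr_est(mat)))
        assert np.all(np.diff(values) > 0)

    def test_adjusted_variant_shrinks_toward_zero(self):
        mat = np.full((4, 4), 0.3) + 0.7 * np.eye(4)
        raw = rel_sd_lambda(_corr_est(mat, n=50))
        adj = rel_sd_lambda_adjusted(_corr_est(mat, n=50))
        assert 0.0 < adj < raw

    def test_single_trait_rejected(self):
        with pytest.raises(ValidationError):
            rel_sd_lambda(CovarianceEstimate(np.eye(1), 30, ("CPD",)))


class TestSimulateRepeats:
    def test_plus_minus_one_percent(self):
        table = random_table(2, 10, seed=1)
        table.values[0, 0] = 10.0
        reps = simulate_repeats(table, 1.0)
        assert reps.replicate1[0, 0] == pytest.approx(10.1)
        assert reps.replicate2[0, 0] == pytest.approx(9.9)

    def test_zero_error_degenerate(self):
        table = random_table(3, 12, seed=2)
        reps = simulate_repeats(table, 0.0)
        np.testing.assert_array_equal(reps.replicate1, table.values)
        np.testing.assert_array_equal(reps.replicate2, table.values)

    def test_replicate_mean_reproduces_table(self):
        table = random_table(4, 15, seed=3)
        reps = simulate_repeats(table, np.array([0.5, 1.0, 0.2, 0.9]))
        np.testing.assert_allclose(
            (reps.replicate1 + reps.replicate2) / 2, table.values)

    def test_negative_error_rejected(self):
        with pytest.raises(ValidationError):
            simulate_repeats(random_table(2, 8, seed=4), -1.0)

    def test_gaussian_variant_mean_preserved_and_seeded(self):
        table = random_table(3, 20, seed=5)
        a = simulate_repeats_gaussian(table, 1.0, seed=11)
        b = simulate_repeats_gaussian(table, 1.0, seed=11)
        np.testing.assert_array_equal(a.replicate1, b.replicate1)
        np.testing.assert_allclose(
            (a.replicate1 + a.replicate2) / 2, table.values)


def _simulated_table(p, m, spectrum, seed):
    spec = simulate.SimSpec(p=p, level=cpc.EQUAL, n_per_group=(m, m),
                            basis_seed=seed, noise_seed=seed + 10_000,
                            spectra=(spectrum,))
    return simulate.simulate_population(spec, 0)


class TestEstimateRank:
    def test_noiseless_limit_recovers_exact_rank(self):
        lam = simulate.default_spectrum(6, decay=0.5)
        lam[-2:] = 0.0  # exact rank 4 truth
        table = _simulated_table(6, 40, lam, seed=0)
        reps = simulate_repeats(table, 0.0)
        assert estimate_rank(reps) == 4

    def test_full_rank_with_small_error(self):
        lam = simulate.default_spectrum(6, decay=0.5)
        hits = sum(
            estimate_rank(simulate_repeats(_simulated_table(6, 66, lam, s), 1.0)) == 6
            for s in range(20)
        )
        assert hits >= 18

    def test_rank_deficient_truth_detected(self):
        lam = simulate.default_spectrum(6, decay=0.5)
        lam[-2:] = 0.0
        hits = sum(
            estimate_rank(simulate_repeats(_simulated_table(6, 70, lam, s), 1.0)) == 4
            for s in range(20)
        )
        assert hits >= 18

    def test_monotone_non_increasing_in_error(self):
        lam = simulate.default_spectrum(5, decay=0.5)
        for s in range(3):
            table = _simulated_table(5, 60, lam, seed=100 + s)
            ranks = [
                estimate_rank(simulate_repeats(table, e))
                for e in (0.5, 2.0, 8.0, 25.0)
            ]
            assert all(a >= b for a, b in zip(ranks, ranks[1:]))

    def test_rank_never_exceeds_traits(self):
        table = random_table(4, 30, seed=6)
        assert estimate_rank(simulate_repeats(table, 1.0)) <= 4


class TestIntegrationReport:
    def test_nm_ratios_match_two_decimal_convention(self):
        t1 = random_table(9, 53, seed=7)   # 9/53 -> 0.17
        t2 = random_table(6, 47, seed=8)   # 6/47 -> 0.13
        df = build_integration_report([t1, t2])
        assert df.loc[0, "nm_ratio"] == 0.17
        assert df.loc[1, "nm_ratio"] == 0.13

    def test_uncorrelated_population_scores_near_zero(self):
        rng = np.random.default_rng(9)
        from pcov.datamodel import TraitTable

        values = 50.0 + rng.normal(size=(800, 5))
        table = TraitTable("A a", "LZI", "C", CANONICAL_TRAITS[:5], values)
        df = build_integration_report([table])
        assert df.loc[0, "rel_sd_lambda"] <= 0.05

    def test_one_row_per_population_with_adjusted_column(self):
        tables = [random_table(4, 40, seed=s) for s in (10, 11, 12)]
        df = build_integration_report(tables, include_adjusted=True)
        assert len(df) == 3
        assert "rel_sd_lambda_adj" in df.columns
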