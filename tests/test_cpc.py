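import numpy as np
import pytest

from pcov import cpc, simulate
from pcov.cpc import (
    CPC,
    EQUAL,
    PROPORTIONAL,
    UNRELATED,
    aic_select,
    count_params,
    fg_common_basis,
    fit_hierarchy,
    fit_level,
    hierarchy,
    pcpc,
    step_up_select,
)
from pcov.datamodel import CANONICAL_TRAITS, CovarianceEstimate, sample_covariance


def _est(matrix, n=60, p=None):
    p = p or matrix.shape[0]
    return CovarianceEstimate(np.asarray(matrix, float), n, CANONICAL_TRAITS[:p])


def _rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _grid_search_angle(S1, S2, w1, w2, n_grid=100_000):
    """Brute-force oracle: deviance-minimising common basis angle at p=2."""
    thetas = np.linspace(0.0, np.pi / 2, n_grid, endpoint=False)
    c, s = np.cos(thetas), np.sin(thetas)
    total = np.zeros_like(thetas)
    for S, w in ((S1, w1), (S2, w2)):
        d1 = c * c * S[0, 0] + 2 * c * s * S[0, 1] + s * s * S[1, 1]
        d2 = s * s * S[0, 0] - 2 * c * s * S[0, 1] + c * c * S[1, 1]
        total += w * (np.log(d1) + np.log(d2))
    return thetas[int(np.argmin(total))]


class TestHierarchyStructure:
    @pytest.mark.parametrize("p", [2, 4, 6, 7, 9, 12])
    def test_ladder_has_p_plus_two_levels(self, p):
        ladder = hierarchy(p)
        assert len(ladder) == p + 2
        assert ladder[0] == UNRELATED and ladder[-1] == EQUAL
        assert ladder == sorted(ladder)  # ordered by increasing constraint

    @pytest.mark.parametrize("p", range(2, 13))
    @pytest.mark.parametrize("g", range(2, 6))
    def test_parameter_count_identities(self, p, g):
        # PCPC(0) coincides with unrelated, PCPC(p-1) with CPC
        assert count_params(pcpc(0), p, g) == count_params(UNRELATED, p, g)
        assert count_params(pcpc(p - 1), p, g) == count_params(CPC, p, g)

    def test_unrelated_param_count(self):
        assert count_params(UNRELATED, 9, 2) == 2 * 9 * 10 // 2


class TestFGCommonBasis:
    def test_diagonal_matrices_give_axes(self):
        B = fg_common_basis([_est(np.diag([3.0, 1.0])), _est(np.diag([5.0, 2.0]))])
        np.testing.assert_allclose(np.abs(B), np.eye(2), atol=1e-9)

    def test_single_group_is_pca(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 4))
        S = a @ a.T + 4 * np.eye(4)
        B = fg_common_basis([_est(S, p=4)])
        evals, evecs = np.linalg.eigh(S)
        recon = B @ np.diag(np.diag(B.T @ S @ B)) @ B.T
        np.testing.assert_allclose(recon, S, atol=1e-8)
        np.testing.assert_allclose(
            np.diag(B.T @ S @ B), evals[::-1], atol=1e-8)

    def test_orthogonality(self):
        rng = np.random.default_rng(3)
        ests = []
        for _ in range(2):
            a = rng.normal(size=(5, 5))
            ests.append(_est(a @ a.T + 5 * np.eye(5), p=5))
        B = fg_common_basis(ests)
        assert np.max(np.abs(B.T @ B - np.eye(5))) < 1e-8

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_search_oracle_p2(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, np.pi / 2)
        R = _rotation(theta)
        S1 = R @ np.diag(rng.uniform(2, 6, 2) * [2, 0.5]) @ R.T
        S2 = R @ np.diag(rng.uniform(2, 6, 2) * [2, 0.5]) @ R.T
        # perturb so the optimum is not exactly the construction angle
        S2 += 0.05 * np.outer([1, -1], [1, -1])
        n1, n2 = 50, 70
        B = fg_common_basis([_est(S1, n1), _est(S2, n2)])
        got = np.arctan2(B[1, 0], B[0, 0]) % (np.pi / 2)
        want = _grid_search_angle(S1, S2, n1 - 1, n2 - 1) % (np.pi / 2)
        delta = min(abs(got - want), np.pi / 2 - abs(got - want))
        assert delta < 1e-3

    def test_singular_input_rejected(self):
        S = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            fg_common_basis([_est(S, p=3), _est(np.eye(3), p=3)])


class TestFitLevel:
    def test_equal_on_identical_inputs(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 4))
        S = a @ a.T + 4 * np.eye(4)
        fit = fit_level([_est(S, p=4), _est(S, p=4)], EQUAL)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.constrained[0], S, atol=1e-10)

    def test_proportional_exact_doubling(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, 3))
        S = a @ a.T + 3 * np.eye(3)
        fit = fit_level([_est(S, p=3), _est(2.0 * S, p=3)], PROPORTIONAL)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        ratio = fit.constrained[1] / fit.constrained[0]
        np.testing.assert_allclose(ratio, 2.0, atol=1e-8)

    def test_cpc_reconstructs_shared_eigenvectors(self):
        spec = simulate.SimSpec(p=4, level=CPC, basis_seed=9, noise_seed=0)
        covs = simulate.group_covariances(spec)
        fit = fit_level([_est(c, p=4) for c in covs], CPC)
        # exact CPC truth: constrained estimates equal the inputs
        for C, S in zip(fit.constrained, covs):
            np.testing.assert_allclose(C, S, atol=1e-7)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-7)

    def test_infeasible_pcpc_order_rejected(self):
        S = np.eye(3)
        with pytest.raises(ValueError, match="infeasible"):
            fit_level([_est(S + 0.1 * np.eye(3), p=3), _est(S, p=3)], pcpc(2))

    def test_params_and_aic_consistent(self):
        spec = simulate.SimSpec(p=5, level=CPC, basis_seed=4, noise_seed=5)
        ests = [
            sample_covariance(simulate.simulate_population(spec, g))
            for g in (0, 1)
        ]
        fit = fit_level(ests, pcpc(2))
        assert fit.params == count_params(pcpc(2), 5, 2)
        assert fit.aic == pytest.approx(fit.chi2 + 2 * fit.params)


@pytest.fixture(scope="module")
def identical_fit():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(5, 5))
    S = a @ a.T + 5 * np.eye(5)
    return fit_hierarchy([_est(S, 60, p=5), _est(S, 60, p=5)])


class TestSelection:

    def test_identical_inputs_select_equal_both_ways(self, identical_fit):
        assert identical_fit.stepup_selected == EQUAL
        assert identical_fit.aic_selected == EQUAL
        assert all(pv > 0.999 for pv in identical_fit.stepup_pvalues)

    def test_weights_sum_to_one(self, identical_fit):
        assert sum(identical_fit.weights) == pytest.approx(1.0, abs=1e-12)

    def test_confidence_set_smallest_prefix(self, identical_fit):
        w = dict(zip(identical_fit.levels, identical_fit.weights))
        inside = sum(w[l] for l in identical_fit.confidence_set)
        assert inside >= 0.95
        # dropping the last member must fall below the target mass
        without_last = inside - w[identical_fit.confidence_set[-1]]
        assert without_last < 0.95

    def test_chi2_monotone_and_deltas_nonnegative(self):
        spec = simulate.SimSpec(p=6, level=pcpc(2), basis_seed=21, noise_seed=22)
        ests = [
            sample_covariance(simulate.simulate_population(spec, g))
            for g in (0, 1)
        ]
        result = fit_hierarchy(ests)
        chis = [f.chi2 for f in result.fits]
        assert np.all(np.diff(chis) >= -1e-9)
        assert chis[0] == 0.0  # unrelated fits perfectly by definition

    def test_unrelated_truth_selected_with_strong_signal(self):
        hits = 0
        for rep in range(5):
            spec = simulate.SimSpec(
                p=5, level=UNRELATED, n_per_group=(200, 200),
                basis_seed=30 + rep, noise_seed=40 + rep,
            )
            ests = [
                sample_covariance(simulate.simulate_population(spec, g))
                for g in (0, 1)
            ]
            r = fit_hierarchy(ests)
            hits += r.stepup_selected == UNRELATED and r.aic_selected == UNRELATED
        assert hits >= 4

    def test_stepup_respects_alpha(self):
        spec = simulate.SimSpec(p=5, level=CPC, basis_seed=50, noise_seed=51)
        ests = [
            sample_covariance(simulate.simulate_population(spec, g))
            for g in (0, 1)
        ]
        fits = list(fit_hierarchy(ests).fits)
        # alpha = 1 rejects at the first test; alpha = 0 never rejects
        lo, _ = step_up_select(fits, alpha=1.0 - 1e-12)
        hi, _ = step_up_select(fits, alpha=0.0)
        assert lo == UNRELATED
        assert hi == EQUAL

    def test_aic_weights_invariant_to_constant_shift(self):
        spec = simulate.SimSpec(p=4, level=CPC, basis_seed=60, noise_seed=61)
        ests = [
            sample_covariance(simulate.simulate_population(spec, g))
            for g in (0, 1)
        ]
        fits = list(fit_hierarchy(ests).fits)
        _, w1, _ = aic_select(fits)
        deltas = np.array([f.aic for f in fits])
        shifted = np.exp(-(deltas + 123.4 - (deltas + 123.4).min()) / 2)
        np.testing.assert_allclose(w1, shifted / shifted.sum(), atol=1e-12)
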