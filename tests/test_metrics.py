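"""Unit and property tests for the fragility/responsiveness metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragnet import (ControllabilityError, LinearNetwork, StabilityError,
                     TimeMode, all_drivers, average_singular_value,
                     controllability_gramian, eigvec_condition,
                     evaluate_bounds, fragility_report, min_control_energy,
                     non_normality, skew_normal_family,
                     spectral_stability_margin, stability_radius,
                     stability_radius_grid)
from conftest import random_stable_matrix


class TestStabilityMargin:
    @pytest.mark.parametrize("A, mode, expected", [
        (np.diag([-1.0, -3.0]), TimeMode.CONTINUOUS, 1.0),
        (np.array([[0.0, 3.0], [-3.0, 0.0]]) - 2 * np.eye(2),
         TimeMode.CONTINUOUS, 2.0),
        (np.array([[1.0]]), TimeMode.CONTINUOUS, -1.0),
        (np.array([[0.3]]), TimeMode.DISCRETE, 0.7),
        (np.zeros((3, 3)), TimeMode.DISCRETE, 1.0),
    ])
    def test_known_margins(self, A, mode, expected):
        assert spectral_stability_margin(A, mode) == pytest.approx(expected)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            spectral_stability_margin(np.zeros((2, 3)))


class TestStabilityRadius:
    def test_normal_matrix_radius_equals_margin(self):
        # for normal matrices the radius coincides with the margin
        assert stability_radius(np.diag([-2.0, -5.0])) == pytest.approx(
            2.0, abs=1e-6)

    def test_discrete_scalar(self):
        r = stability_radius(np.array([[0.3]]), TimeMode.DISCRETE)
        assert r == pytest.approx(0.7, abs=1e-6)

    def test_nonnormal_shear(self):
        # frozen from the dense-grid oracle: min_w sigma_min(A - iwI)
        A = np.array([[-1.0, 10.0], [0.0, -1.0]])
        assert stability_radius(A) == pytest.approx(0.09901951, abs=1e-5)

    def test_unstable_returns_zero(self):
        assert stability_radius(np.array([[1.0]])) == 0.0
        assert stability_radius(np.array([[1.2]]), TimeMode.DISCRETE) == 0.0

    def test_parameter_and_input_errors(self):
        with pytest.raises(ValueError):
            stability_radius(np.eye(2), tol=0.0)
        with pytest.raises(ValueError):
            stability_radius(np.array([[np.nan]]))

    @pytest.mark.parametrize("mode", [TimeMode.CONTINUOUS, TimeMode.DISCRETE])
    def test_matches_grid_oracle(self, rng, mode):
        for n in (3, 5, 8):
            for _ in range(4):
                A = random_stable_matrix(n, rng, mode)
                assert stability_radius(A, mode) == pytest.approx(
                    stability_radius_grid(A, mode), abs=1e-4)


class TestEigvecCondition:
    def test_normal_and_symmetric_are_perfectly_conditioned(self, rng):
        assert eigvec_condition(skew_normal_family(6, 1.0, seed=1).A) \
            == pytest.approx(1.0, abs=1e-6)
        M = rng.standard_normal((5, 5))
        assert eigvec_condition(M + M.T) == pytest.approx(1.0, abs=1e-8)

    def test_conjugated_2x2_matches_hand_computed_svd(self):
        # D^{-1} [[-2,1],[1,-2]] D with D = diag(1, 2): eigenvalues -1, -3,
        # unit eigenvectors (2,1)/sqrt5 and (2,-1)/sqrt5, whose Gram matrix
        # has eigenvalues 8/5 and 2/5 => kappa = sqrt(8/2) = 2
        D = np.diag([1.0, 2.0])
        A = np.linalg.inv(D) @ np.array([[-2.0, 1.0], [1.0, -2.0]]) @ D
        kappa = eigvec_condition(A)
        assert kappa == pytest.approx(2.0, abs=1e-10)
        assert kappa > 1.0

    def test_defective_matrix_flagged_undefined(self):
        assert math.isnan(eigvec_condition(np.array([[0.0, 1.0],
                                                     [0.0, 0.0]])))


class TestNonNormality:
    def test_symmetric_is_zero(self, rng):
        M = rng.standard_normal((4, 4))
        assert non_normality(M + M.T) == 0.0

    def test_rotation(self):
        assert non_normality(np.array([[0.0, 1.0], [-1.0, 0.0]])) \
            == pytest.approx(2.0)

    def test_one_norm_chain_bound(self, rng):
        # ||A - A^T|| <= 2 sqrt(||A||_1 ||A^T||_1)
        for _ in range(10):
            A = rng.standard_normal((6, 6))
            bound = 2 * math.sqrt(np.linalg.norm(A, 1)
                                  * np.linalg.norm(A.T, 1))
            assert non_normality(A) <= bound + 1e-12


class TestAverageSingularValue:
    @pytest.mark.parametrize("M, expected", [
        (np.eye(3), 1.0),
        (np.diag([2.0, 0.0]), 1.0),
    ])
    def test_examples(self, M, expected):
        assert average_singular_value(M) == pytest.approx(expected)

    def test_psd_equals_trace_over_n(self, rng):
        M = rng.standard_normal((5, 5))
        G = M @ M.T
        assert average_singular_value(G) == pytest.approx(np.trace(G) / 5,
                                                          rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_singular_value(np.empty((0, 0)))


class TestGramian:
    def test_decoupled_continuous(self):
        net = all_drivers(-np.eye(2))
        rep = controllability_gramian(net)
        assert np.allclose(rep.G, 0.5 * np.eye(2))
        assert rep.sigma_bar == pytest.approx(0.5)

    def test_scalar_discrete(self):
        net = LinearNetwork(np.array([[0.5]]), (0,), TimeMode.DISCRETE)
        rep = controllability_gramian(net)
        assert rep.G[0, 0] == pytest.approx(4.0 / 3.0)

    def test_skew_family_trace_identity(self):
        # tr(G) = n_c / (2 alpha) for A = A_skew - alpha I, any drivers
        for seed in range(3):
            net = skew_normal_family(4, 1.0, seed=seed).with_drivers((0, 2))
            rep = controllability_gramian(net)
            assert rep.sigma_bar == pytest.approx(2 / (2 * 1.0 * 4),
                                                  abs=1e-10)

    def test_report_invariants(self, rng):
        for mode in (TimeMode.CONTINUOUS, TimeMode.DISCRETE):
            A = random_stable_matrix(6, rng, mode)
            net = LinearNetwork(A, (0, 3, 5), mode)
            rep = controllability_gramian(net)
            assert rep.min_eig >= -1e-8 * max(1.0, rep.trace)
            assert rep.sigma_bar == pytest.approx(rep.trace / 6, rel=1e-10)
            assert rep.residual <= 1e-6 * (1 + np.linalg.norm(net.B @ net.B.T))

    def test_unstable_and_empty_drivers_rejected(self):
        with pytest.raises(StabilityError):
            controllability_gramian(all_drivers(np.array([[1.0]])))
        with pytest.raises(ValueError):
            controllability_gramian(LinearNetwork(-np.eye(2), ()))


class TestMinControlEnergy:
    def test_known_values(self):
        rep = controllability_gramian(all_drivers(-np.eye(2)))  # G = I/2
        assert min_control_energy(rep, np.array([1.0, 0.0])) \
            == pytest.approx(2.0)
        assert min_control_energy(rep, np.zeros(2)) == 0.0

    def test_rayleigh_lower_bound(self, rng):
        A = random_stable_matrix(5, rng)
        rep = controllability_gramian(all_drivers(A))
        x = rng.standard_normal(5)
        max_eig = np.linalg.eigvalsh(rep.G)[-1]
        assert min_control_energy(rep, x) >= np.dot(x, x) / max_eig - 1e-8

    def test_singular_gramian_rejected(self):
        # a single driver on a decoupled pair leaves one mode unreachable
        net = LinearNetwork(-np.eye(2), (0,))
        rep = controllability_gramian(net)
        with pytest.raises(ControllabilityError):
            min_control_energy(rep, np.array([0.0, 1.0]))


class TestBounds:
    def _reports(self, A, drivers=None):
        net = all_drivers(A) if drivers is None else LinearNetwork(A, drivers)
        frag = fragility_report(A)
        gram = controllability_gramian(net)
        return net, frag, gram

    def test_symmetric_collapses_general_to_symmetric_rhs(self, rng):
        M = rng.standard_normal((5, 5))
        A = random_stable_matrix(5, rng)
        A = 0.5 * (A + A.T)
        A = A - (np.max(np.linalg.eigvalsh(A)) + 0.5) * np.eye(5)
        rep = evaluate_bounds(*self._reports(A))
        assert rep.is_symmetric and rep.is_normal
        assert rep.rhs_general == pytest.approx(rep.rhs_symmetric, rel=1e-9)
        # normal rhs improves on (halves) the symmetric rhs
        assert rep.rhs_normal == pytest.approx(rep.rhs_symmetric / 2)

    def test_normal_family_attains_normal_bound(self):
        # for A_skew - alpha I with all nodes driven the normal-case bound
        # holds with equality via the Gramian trace identity
        net = skew_normal_family(6, 1.3, seed=7)
        rep = evaluate_bounds(net, fragility_report(net.A),
                              controllability_gramian(net))
        assert rep.is_normal
        assert rep.ratio_normal == pytest.approx(1.0, abs=1e-6)

    def test_all_applicable_ratios_at_most_one(self, rng):
        for _ in range(10):
            A = random_stable_matrix(7, rng)
            rep = evaluate_bounds(*self._reports(A, drivers=(0, 2, 4)))
            for name, ratio in rep.applicable_ratios().items():
                assert ratio <= 1 + 1e-8, name
            assert rep.sandwich_ok

    def test_unstable_rejected(self):
        A = np.array([[1.0]])
        frag = fragility_report(A)
        with pytest.raises(StabilityError):
            evaluate_bounds(all_drivers(A), frag, None)

    def test_discrete_mode_rejected(self):
        net = LinearNetwork(0.5 * np.eye(2), (0, 1), TimeMode.DISCRETE)
        frag = fragility_report(net.A, TimeMode.DISCRETE)
        gram = controllability_gramian(net)
        with pytest.raises(ValueError):
            evaluate_bounds(net, frag, gram)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.sampled_from([3, 5, 8]))
def test_sandwich_inequality_property(seed, n):
    """s/kappa(V) - tol <= r <= s + tol on random stable matrices."""
    rng = np.random.default_rng(seed)
    A = random_stable_matrix(n, rng)
    frag = fragility_report(A)
    assert frag.r <= frag.s + 2e-6
    if math.isfinite(frag.kappa_V):
        assert frag.r >= frag.s / frag.kappa_V - 2e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_driver_additivity_and_trace_inequality(seed):
    """sigma_bar is additive over disjoint driver sets, and bounded below
    by n / trace(G^{-1}) whenever the Gramian is invertible."""
    rng = np.random.default_rng(seed)
    A = random_stable_matrix(6, rng)
    S, T = (0, 2), (1, 5)
    g_s = controllability_gramian(LinearNetwork(A, S)).sigma_bar
    g_t = controllability_gramian(LinearNetwork(A, T)).sigma_bar
    g_union = controllability_gramian(LinearNetwork(A, S + T)).sigma_bar
    assert g_union == pytest.approx(g_s + g_t, abs=1e-8)

    full = controllability_gramian(all_drivers(A))
    tr_inv = np.trace(np.linalg.inv(full.G))
    assert full.sigma_bar >= 6 / tr_inv - 1e-10


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_normal_matrix_collapse_property(seed):
    """Normal matrices have r = s and kappa(V) = 1."""
    net = skew_normal_family(5, 1.0 + (seed % 7) * 0.2, seed=seed)
    frag = fragility_report(net.A, tol=1e-8)
    assert abs(frag.r - frag.s) <= 1e-6
    assert abs(frag.kappa_V - 1.0) <= 1e-6
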