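"""Estimator algebra and maximum-likelihood fitting of the four frameworks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moraldm.dilemma import CATEGORIES, CategoryProfile
from moraldm.estimators import (
    can_params,
    can_params_arrays,
    cni_fit,
    cni_gsq,
    cni_invert,
    cni_loglik,
    cni_predict,
    pd_forward,
    pd_params,
    traditional_score,
)

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _tree_probs_by_enumeration(C, N, I):
    """Independent oracle: sum the three-branch tree outcomes per category."""
    out = {}
    for cat in CATEGORIES:
        benefits = cat in ("PB", "AB")
        norm_allows = cat in ("AB", "AC")
        p_action = 0.0
        p_action += C * (1.0 if benefits else 0.0)          # consequence branch
        p_action += (1 - C) * N * (1.0 if norm_allows else 0.0)  # norm branch
        p_action += (1 - C) * (1 - N) * (1 - I)              # general action branch
        out[cat] = p_action
    return np.array([out[c] for c in CATEGORIES])


class TestProcessDissociation:
    def test_printed_parameter_pair(self):
        est = pd_params(0.57, 0.38)
        assert est.U == pytest.approx(0.19)
        assert est.D == pytest.approx(0.469, abs=5e-4)

    def test_degenerate_full_dissociation(self):
        est = pd_params(1.0, 0.0)
        assert est.U == 1.0 and not est.defined and math.isnan(est.D)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pd_params(1.2, 0.5)

    @settings(max_examples=300, derandomize=True)
    @given(probs, probs)
    def test_forward_inverse_exact(self, a, b):
        est = pd_params(a, b)
        if not est.defined:
            return
        fa, fb = pd_forward(est.U, est.D)
        assert fa == pytest.approx(a, abs=1e-12)
        assert fb == pytest.approx(b, abs=1e-12)


class TestCniPredict:
    def test_pure_consequence_driven(self):
        assert np.allclose(cni_predict(1, 0.3, 0.7), [1, 0, 1, 0])

    def test_pure_norm_driven(self):
        assert np.allclose(cni_predict(0, 1, 0.2), [0, 0, 1, 1])

    def test_hand_evaluated_cell(self):
        assert np.allclose(cni_predict(0.2, 0.25, 0.4), [0.56, 0.36, 0.76, 0.56])

    def test_parameter_range_enforced(self):
        with pytest.raises(ValueError):
            cni_predict(1.2, 0.5, 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(probs, probs, probs)
    def test_matches_branch_enumeration_oracle(self, C, N, I):
        assert np.allclose(cni_predict(C, N, I), _tree_probs_by_enumeration(C, N, I), atol=1e-12)


class TestCniInvert:
    def test_inverse_of_forward_example(self):
        C, N, I = cni_invert([0.56, 0.36, 0.76, 0.56])
        assert (C, N, I) == pytest.approx((0.2, 0.25, 0.4))

    def test_flat_cells(self):
        assert cni_invert([0.5, 0.5, 0.5, 0.5]) == pytest.approx((0.0, 0.0, 0.5))

    def test_contradictory_contrasts_infeasible(self):
        assert cni_invert([1, 0, 0, 1]) is None

    def test_never_raises_on_degenerate_cells(self):
        for p in ([0, 0, 0, 0], [1, 1, 1, 1], [1, 0, 1, 0], [0, 1, 0, 1]):
            cni_invert(p)  # must return a tuple or None, not raise

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(0.01, 0.95), st.floats(0.01, 0.95), st.floats(0.01, 0.95)
    )
    def test_round_trip_interior(self, C, N, I):
        rec = cni_invert(cni_predict(C, N, I))
        assert rec is not None
        assert rec == pytest.approx((C, N, I), abs=1e-7)


class TestCniFit:
    def test_saturating_consequence_branch(self):
        fit = cni_fit([6, 0, 6, 0], [6, 6, 6, 6])
        assert fit.C == pytest.approx(1.0, abs=1e-4)
        assert fit.gsq < 1e-6
        assert set(fit.unidentified) == {"N", "I"}

    def test_recovers_generator_from_expected_counts(self):
        n = np.full(4, 2500.0)
        k = cni_predict(0.2, 0.25, 0.4) * n
        fit = cni_fit(k, n)
        assert (fit.C, fit.N, fit.I) == pytest.approx((0.2, 0.25, 0.4), abs=1e-4)
        assert fit.gsq < 1e-6
        assert not fit.excluded

    def test_equal_cells_force_zero_contrasts(self):
        fit = cni_fit([3, 3, 3, 3], [6, 6, 6, 6])
        assert (fit.C, fit.N, fit.I) == pytest.approx((0.0, 0.0, 0.5), abs=1e-8)

    def test_misfitting_counts_flagged_excluded(self):
        # strong anti-tree pattern: accepts only where the tree cannot put them
        fit = cni_fit([0, 20, 0, 20], [20, 20, 20, 20])
        assert fit.fit_p < 0.05 and fit.excluded

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cni_fit([1, 2, 3], [6, 6, 6])
        with pytest.raises(ValueError):
            cni_fit([7, 0, 0, 0], [6, 6, 6, 6])

    def test_fit_likelihood_never_below_coarse_grid(self, rng):
        # cheap sanity sweep; the fine-grid oracle lives in the acceptance suite
        grid = np.linspace(0, 1, 21)
        G = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
        for _ in range(10):
            n = np.full(4, 6.0)
            k = rng.integers(0, 7, size=4).astype(float)
            fit = cni_fit(k, n)
            best_grid = max(cni_loglik(k, n, g) for g in G)
            assert fit.loglik >= best_grid - 1e-6


class TestCanParams:
    def test_binary_cells_from_tree_example(self):
        est = can_params([0.56, 0.36, 0.76, 0.56], mode="binary")
        assert (est.C, est.N, est.A) == pytest.approx((0.20, 0.20, 0.56))
        assert est.scale == "binary"

    def test_flat_binary_cells(self):
        est = can_params([0.5] * 4, mode="binary")
        assert (est.C, est.N, est.A) == (0.0, 0.0, 0.5)

    def test_continuous_midpoint(self):
        est = can_params([3.5] * 4, mode="continuous")
        assert (est.C, est.N, est.A) == (0.0, 0.0, 3.5)
        assert est.scale == "continuous"

    def test_range_validation_per_scale(self):
        with pytest.raises(ValueError):
            can_params([2.0, 0.5, 0.5, 0.5], mode="binary")
        with pytest.raises(ValueError):
            can_params([0.5] * 4, mode="continuous")

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(probs, min_size=4, max_size=4))
    def test_binary_ranges_preserved(self, cells):
        est = can_params(cells, mode="binary")
        assert -1 <= est.C <= 1 and -1 <= est.N <= 1 and 0 <= est.A <= 1

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(1.0, 6.0), min_size=4, max_size=4))
    def test_continuous_ranges_preserved(self, cells):
        est = can_params(cells, mode="continuous")
        assert -5 <= est.C <= 5 and -5 <= est.N <= 5 and 1 <= est.A <= 6

    def test_monotonicity_in_cells(self, rng):
        v = rng.uniform(0.1, 0.8, size=4)
        base = can_params(v, mode="binary")
        # raising both benefits>costs cells raises consequence sensitivity
        bumped = can_params(v + np.array([0.1, 0, 0.1, 0]), mode="binary")
        assert bumped.C > base.C
        # raising every cell raises the action bias
        assert can_params(v + 0.1, mode="binary").A > base.A

    def test_vectorized_contrasts_match_scalar(self, rng):
        V = rng.uniform(size=(20, 4))
        C, A, N = can_params_arrays(V)
        for i in range(20):
            est = can_params(V[i], mode="binary")
            assert (C[i], A[i], N[i]) == pytest.approx((est.C, est.A, est.N))


class TestTraditional:
    def test_passthrough_of_pb_cell(self):
        assert traditional_score([4 / 6, 0.2, 0.5, 0.5]) == pytest.approx(0.667, abs=5e-4)

    def test_all_accept(self):
        assert traditional_score([1.0, 1.0, 1.0, 1.0]) == 1.0

    def test_rejects_continuous_profile(self):
        prof = CategoryProfile("P1", "continuous", {c: 3.5 for c in CATEGORIES}, {c: 6 for c in CATEGORIES})
        with pytest.raises(ValueError):
            traditional_score(prof)

    def test_cohort_mean_is_mean_of_cells(self, rng):
        pb = rng.uniform(size=100)
        scores = [traditional_score([p, 0.3, 0.7, 0.4]) for p in pb]
        assert np.mean(scores) == pytest.approx(pb.mean())
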