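"""Trajectory-space tests: PCA fitting and projection, condition
alignment, distance series, TSI, and the distance ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppcdrift import generate_session
from ppcdrift.detection import classify_session
from ppcdrift.trajectory import (
    align_to_preferred,
    analyze_trajectories,
    distance_roc,
    fit_trajectory_space,
    project,
    trajectory_distances,
    tsi,
)
from tests.conftest import brute_force_auroc


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


class TestFitAndProject:
    def test_planar_data_two_components(self, rng):
        basis = rng.normal(size=(2, 8))
        coeff = rng.normal(size=(100, 2))
        X = coeff @ basis
        model = fit_trajectory_space(X, n_components=5)
        assert model.explained_variance_fraction[:2].sum() == pytest.approx(
            1.0, abs=1e-9
        )
        assert model.explained_variance_fraction[2:].sum() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(80, 10))
        V = fit_trajectory_space(X).loadings
        assert np.allclose(V.T @ V, np.eye(5), atol=1e-10)

    def test_neuron_permutation_equivariance(self, rng):
        X = rng.normal(size=(60, 7))
        perm = rng.permutation(7)
        a = fit_trajectory_space(X, 3)
        b = fit_trajectory_space(X[:, perm], 3)
        assert np.allclose(np.abs(b.loadings), np.abs(a.loadings[perm]), atol=1e-8)

    def test_eigen_optimality_vs_subspace_oracle(self, rng):
        """Top-k eigenvalue mass beats any coordinate subset and any random
        orthonormal k-frame (brute-force check on 10 neurons)."""
        from itertools import combinations

        X = rng.normal(size=(50, 10)) @ rng.normal(size=(10, 10))
        mu, sd = X.mean(0), X.std(0, ddof=1)
        Z = (X - mu) / sd
        C = Z.T @ Z / (len(Z) - 1)
        model = fit_trajectory_space(X, 5)
        top = np.linalg.eigvalsh(C)[::-1][:5].sum()
        for subset in combinations(range(10), 5):
            assert top >= np.trace(C[np.ix_(subset, subset)]) - 1e-9
        for _ in range(200):
            Q, _ = np.linalg.qr(rng.normal(size=(10, 5)))
            assert top >= np.trace(Q.T @ C @ Q) - 1e-9
        total = np.trace(C)
        assert model.explained_variance_fraction.sum() == pytest.approx(
            top / total
        )

    def test_projection_reproduces_scores(self, rng):
        X = rng.normal(size=(40, 6))
        model = fit_trajectory_space(X, 3)
        Z = (X - model.mean) / model.sd
        assert np.allclose(project(model, X), Z @ model.loadings)

    def test_projection_affine_relation(self, rng):
        X = rng.normal(size=(40, 6))
        model = fit_trajectory_space(X, 3)
        a, b = 2.5, 0.7
        lhs = project(model, a * X + b)
        rhs = a * project(model, X) + ((b + (a - 1) * model.mean) / model.sd) \
            @ model.loadings
        assert np.allclose(lhs, rhs)

    def test_zero_variance_neuron_flagged(self, rng):
        X = rng.normal(size=(40, 6))
        X[:, 2] = 3.0
        model = fit_trajectory_space(X, 3)
        assert 2 in model.zero_variance_neurons

    def test_neuron_mismatch_rejected(self, rng):
        model = fit_trajectory_space(rng.normal(size=(40, 6)), 3)
        with pytest.raises(ValueError, match="6 neurons"):
            project(model, rng.normal(size=(40, 5)))


class TestAlignment:
    def test_all_right_preferring_is_identity(self, clean_session):
        labels = classify_session(clean_session)
        right = labels[labels.direction == "right"].set_index("neuron").direction
        pop = align_to_preferred(clean_session, right)
        pp = pop.condition_average("PP")
        manual = clean_session.condition_tensor(stim="right", resp="right") \
            .mean(axis=0)[:, pop.neurons]
        assert np.allclose(pp, manual)

    def test_left_preferring_pp_is_left_trials(self, clean_session):
        labels = classify_session(clean_session)
        left = labels[labels.direction == "left"].set_index("neuron").direction
        pop = align_to_preferred(clean_session, left)
        pp = pop.condition_average("PP")
        manual = clean_session.condition_tensor(stim="left", resp="left") \
            .mean(axis=0)[:, pop.neurons]
        assert np.allclose(pp, manual)

    def test_mixed_population_shape(self, clean_session):
        labels = classify_session(clean_session)
        dirs = labels[labels.direction.isin(["left", "right"])] \
            .set_index("neuron").direction
        pop = align_to_preferred(clean_session, dirs)
        assert pop.condition_average("OO").shape == (
            clean_session.timing.trial_frames, len(dirs)
        )

    def test_unlabeled_only_rejected(self, clean_session):
        with pytest.raises(ValueError, match="no direction-labeled"):
            align_to_preferred(
                clean_session, pd.Series(["none"] * 3, index=[0, 1, 2])
            )


class TestTsi:
    def test_equal_distances_zero(self):
        assert tsi(2.0, 2.0) == 0.0

    def test_pp_zero_gives_plus_one(self):
        assert tsi(0.0, 1.3) == 1.0

    def test_worked_arithmetic(self):
        assert tsi(3.0, 1.0) == pytest.approx(-0.5)

    def test_undefined_at_origin(self):
        assert np.isnan(tsi(0.0, 0.0))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            tsi(-1.0, 1.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        dpp=st.floats(0, 1e6, allow_nan=False),
        doo=st.floats(0, 1e6, allow_nan=False),
    )
    def test_bound_property(self, dpp, doo):
        if dpp + doo > 0:
            v = tsi(dpp, doo)
            assert -1.0 <= v <= 1.0
            if v == 1.0:
                # attained only when dPP vanishes (up to float resolution)
                assert dpp <= 1e-15 * doo


class TestDistances:
    def _trajs(self, rng, n_trials=8, offset=0.0):
        base = rng.normal(size=(n_trials, 30, 5)) * 0.01
        base[..., 0] += offset
        return base

    def test_identical_trajectories_zero_distance(self, rng):
        pp = self._trajs(rng)
        d = trajectory_distances(
            {"PP": pp, "OO": pp.copy(), "PO": pp.copy()}, n_iter=5, seed=0
        )
        assert np.all(d.d1 < 0.05)

    def test_unit_offset_along_component(self, rng):
        pp = np.zeros((8, 30, 5))
        oo = np.zeros((8, 30, 5))
        oo[..., 0] = 1.0
        d = trajectory_distances({"PP": pp, "OO": oo}, n_iter=3, seed=0)
        assert np.allclose(d.d1, 1.0)
        assert np.allclose(d.d0, 0.0)

    def test_symmetry_and_triangle_inequality(self, rng):
        a = rng.normal(size=(30, 5))
        b = rng.normal(size=(30, 5))
        c = rng.normal(size=(30, 5))
        from ppcdrift.trajectory import _frame_distance

        assert np.allclose(_frame_distance(a, b), _frame_distance(b, a))
        assert np.all(
            _frame_distance(a, c) <= _frame_distance(a, b) + _frame_distance(b, c) + 1e-12
        )

    def test_needs_four_pp_trials(self, rng):
        with pytest.raises(ValueError, match=">=4 PP"):
            trajectory_distances({"PP": self._trajs(rng)[:3]}, n_iter=2, seed=0)


class TestDistanceRoc:
    def test_identical_distributions_half(self, rng):
        a = rng.normal(size=(50, 10))
        roc = distance_roc(a, a.copy())
        assert np.allclose(roc, 0.5, atol=0.01)

    def test_fully_separated_one(self, rng):
        a = rng.uniform(0, 1, size=(20, 5))
        b = a + 2.0
        assert np.allclose(distance_roc(b, a), 1.0)

    def test_small_n_matches_pairwise_oracle(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(7, 4))
        roc = distance_roc(a, b)
        for t in range(4):
            assert roc[t] == pytest.approx(brute_force_auroc(a[:, t], b[:, t]))


class TestSplitPcaAnalysis:
    def test_error_trials_never_enter_the_fit(self, drift_session):
        """Non-circularity: removing error trials entirely from the traces
        (zeroing them) leaves the fitted spaces identical."""
        labels = classify_session(drift_session)
        dirs = labels[labels.direction.isin(["left", "right"])] \
            .set_index("neuron").direction
        s2 = generate_session(seed=11, drift_rate=0.5)
        err_idx = np.asarray(s2.trials.errors.index)
        tf = s2.timing.trial_frames
        for i in err_idx:
            s2.traces[i * tf : (i + 1) * tf] = 0.0
        _, _, m1 = analyze_trajectories(drift_session, dirs, n_iter=3, seed=9)
        _, _, m2 = analyze_trajectories(s2, dirs, n_iter=3, seed=9)
        assert np.allclose(m1.loadings, m2.loadings)

    def test_drift_shrinks_same_response_distance(self, drift_session):
        labels = classify_session(drift_session)
        dirs = labels[labels.direction.isin(["left", "right"])] \
            .set_index("neuron").direction
        dist, _, _ = analyze_trajectories(drift_session, dirs, n_iter=20, seed=1)
        resp = dist.mean("d_same_resp")
        early_delay = resp[120:130].mean()
        late_delay = resp[160:170].mean()
        assert late_delay < early_delay
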