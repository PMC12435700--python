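"""Event-related detection tests: amplitude fitting, the one-sample
t gate, pixelwise ROI clustering, and GLM neuron classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppcdrift import generate_movie, generate_session
from ppcdrift.detection import (
    BetaFit,
    build_event_template,
    classify_neuron,
    classify_session,
    detect_rois,
    exclude_drifting_neurons,
    fit_betas,
)
from ppcdrift.detection import test_event_relevance as relevance_gate
from ppcdrift.session import KernelParams, PixelMovie, TimingConfig, TrialTable
from tests.conftest import ALL_SELECTIVE_MIX


def _fit(betas):
    betas = np.asarray(betas, float)
    from ppcdrift.detection import _betas_to_fit

    return _betas_to_fit(betas)


@pytest.fixture(scope="module")
def small_session():
    return generate_session(
        n_neurons=8, n_trials=16, noise_sd=0.0, drift_rate=0.0,
        error_rate=0.25, seed=3,
    )


class TestTemplates:
    def test_column_count_matches_trials(self, small_session, kernel):
        s = small_session
        n_right = len(s.trials.select(stim="right", outcome="correct"))
        t = build_event_template(
            s.trials, "sample_R", s.timing, kernel, s.n_frames
        )
        assert t.k == n_right

    def test_columns_peak_normalized(self, small_session, kernel):
        t = build_event_template(
            small_session.trials, "sample_R", small_session.timing, kernel,
            small_session.n_frames,
        )
        assert t.matrix.max() == pytest.approx(1.0)
        assert (t.matrix >= 0).all()

    def test_delay_template_anchored_at_delay_onset(self, small_session, kernel):
        s = small_session
        t = build_event_template(s.trials, "delay_L", s.timing, kernel, s.n_frames)
        expected = s.trials.select(stim="left", outcome="correct")["delay_onset"]
        assert np.array_equal(t.event_frames, expected.to_numpy())
        for j, ev in enumerate(t.event_frames):
            assert t.matrix[ev - 1, j] == 0.0
            assert t.matrix[ev + 1, j] > 0.0

    def test_no_matching_trials_raises(self, small_session, kernel):
        only_right = TrialTable(
            small_session.trials.select(stim="right").reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="no matching trials"):
            build_event_template(
                only_right, "sample_L", small_session.timing, kernel,
                small_session.n_frames,
            )


class TestFitBetas:
    def test_exact_recovery(self, small_session, kernel):
        s = small_session
        t = build_event_template(s.trials, "delay_R", s.timing, kernel, s.n_frames)
        trace = t.matrix @ np.full(t.k, 2.0)
        fit = fit_betas(trace, t)
        assert np.allclose(fit.betas, 2.0)
        assert fit.beta_mean == pytest.approx(2.0)

    def test_orthogonal_trace_zero_betas(self, small_session, kernel):
        s = small_session
        t = build_event_template(s.trials, "delay_R", s.timing, kernel, s.n_frames)
        # activity only on left trials is orthogonal to right-trial columns
        trace = np.zeros(s.n_frames)
        for row in s.trials.select(stim="left").itertuples(index=False):
            trace[row.stim_onset : row.stim_onset + 50] = 1.0
        fit = fit_betas(trace, t)
        assert np.allclose(fit.betas, 0.0, atol=1e-10)

    def test_statistic_arithmetic(self):
        fit = _fit([1.0, 2.0, 3.0])
        assert fit.beta_mean == pytest.approx(2.0)
        assert fit.beta_sd == pytest.approx(1.0)
        assert fit.t_statistic == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-9)

    def test_rank_deficient_names_collision(self, small_session, kernel):
        s = small_session
        t = build_event_template(s.trials, "sample_R", s.timing, kernel, s.n_frames)
        t.matrix = np.hstack([t.matrix, t.matrix[:, :1]])
        t.event_frames = np.append(t.event_frames, t.event_frames[0])
        with pytest.raises(ValueError, match="coinciding"):
            fit_betas(np.zeros(s.n_frames), t)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, scale):
        """Scaling the trace scales beta-hat and leaves t unchanged."""
        s = generate_session(
            n_neurons=4, n_trials=12, noise_sd=0.1, error_rate=0.25, seed=6
        )
        kp = KernelParams.cytosolic()
        t = build_event_template(s.trials, "sample_R", s.timing, kp, s.n_frames)
        base = fit_betas(s.traces[:, 0], t)
        scaled = fit_betas(scale * s.traces[:, 0], t)
        assert np.allclose(scaled.betas, scale * base.betas, rtol=1e-8)
        assert scaled.t_statistic == pytest.approx(base.t_statistic, rel=1e-6)


class TestRelevanceGate:
    def test_degenerate_identical_positive(self):
        fit = _fit([1.0, 1.0, 1.0])
        sig, p = relevance_gate(fit)
        assert sig and p == 0.0

    def test_symmetric_betas_not_significant(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, 200)
        fit = _fit(b - b.mean())  # exactly zero mean
        sig, p = relevance_gate(fit)
        assert not sig

    def test_negative_mean_one_tailed_not_significant(self):
        fit = _fit([-3.0, -2.9, -3.1])
        sig, _ = relevance_gate(fit)
        assert not sig
        sig2, _ = relevance_gate(fit, two_tailed=True)
        assert sig2

    def test_null_rejection_rate_near_alpha(self, small_session, kernel):
        """Monte-Carlo null: white-noise pixels reject at ~alpha."""
        s = small_session
        t = build_event_template(s.trials, "sample_R", s.timing, kernel, s.n_frames)
        from ppcdrift.detection import _batch_pvalues

        rng = np.random.default_rng(42)
        traces = rng.normal(0, 1, (s.n_frames, 4000))
        p = _batch_pvalues(traces, t)
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.012)

    def test_shuffled_events_kill_detection(self, kernel):
        """Shuffling event frames drops planted-neuron detection to chance."""
        s = generate_session(
            n_neurons=1, n_trials=20, noise_sd=0.3,
            mix={("sample", "right"): 1.0}, error_rate=0.0, seed=8,
        )
        t = build_event_template(s.trials, "sample_R", s.timing, kernel, s.n_frames)
        assert relevance_gate(fit_betas(s.traces[:, 0], t))[0]
        rng = np.random.default_rng(1)
        hits = 0
        n_shuffles = 60
        for _ in range(n_shuffles):
            tt = build_event_template(
                s.trials, "sample_R", s.timing, kernel, s.n_frames
            )
            # displace each event to a random frame of a random trial
            k = tt.matrix.shape[1]
            shape = tt.matrix[tt.event_frames[0]:, 0]
            cols = np.zeros_like(tt.matrix)
            evs = rng.choice(s.n_frames - len(shape), size=k, replace=False)
            for j, ev in enumerate(evs):
                cols[ev : ev + len(shape), j] = shape
            tt.matrix = cols
            if relevance_gate(fit_betas(s.traces[:, 0], tt))[0]:
                hits += 1
        assert hits / n_shuffles < 0.25


class TestDetectRois:
    def test_recovers_planted_footprints(self):
        quarters = {
            ("sample", "right"): 0.25, ("sample", "left"): 0.25,
            ("delay", "right"): 0.25, ("delay", "left"): 0.25,
        }
        s = generate_session(
            n_neurons=6, n_trials=16, noise_sd=0.1, amplitude_beta=1.0,
            mix=quarters, error_rate=0.25, seed=3,
        )
        assert (s.ground_truth.phase != "none").all()
        mv = generate_movie(s, image_size=(20, 20), background_sd=0.0, seed=4)
        res = detect_rois(mv, s.trials)
        assert len(res.rois) == 6
        planted = {frozenset(map(tuple, fp)) for fp in mv.footprints}
        found = {frozenset(map(tuple, roi)) for roi in res.rois}
        assert found == planted

    def test_diagonal_pixels_one_roi(self, small_session, kernel):
        """Two responsive pixels touching only diagonally cluster together
        under the Moore neighborhood."""
        s = small_session
        sel = s.ground_truth.query("phase == 'sample'").iloc[0]
        stack = np.zeros((s.n_frames, 6, 6))
        stack[:, 2, 2] = s.traces[:, sel.neuron]
        stack[:, 3, 3] = s.traces[:, sel.neuron]
        mv = PixelMovie(stack=stack, footprints=[np.array([[2, 2], [3, 3]])])
        res = detect_rois(mv, s.trials)
        assert len(res.rois) == 1
        assert len(res.rois[0]) == 2

    def test_all_zero_movie_no_rois(self, small_session):
        stack = np.zeros((small_session.n_frames, 5, 5))
        mv = PixelMovie(stack=stack, footprints=[])
        res = detect_rois(mv, small_session.trials)
        assert res.rois == []
        assert not res.significance_mask.any()


class TestClassifyNeuron:
    def test_recovers_planted_labels_noiseless(self, clean_session):
        labels = classify_session(clean_session)
        gt = clean_session.ground_truth
        assert (labels.phase == gt.phase).all()
        assert (labels.direction == gt.preferred_direction).all()

    def test_noise_neuron_unlabeled(self, clean_session):
        noise = clean_session.ground_truth.query("phase == 'none'").iloc[0]
        lab = classify_neuron(
            clean_session.traces[:, noise.neuron], clean_session.trials,
            clean_session.timing,
        )
        assert lab.direction == "none"
        assert lab.phases == set()

    def test_bidirectional_delay_neuron_nondirectional(self, timing, kernel):
        s = generate_session(
            n_neurons=2, n_trials=16, noise_sd=0.0, error_rate=0.25,
            mix={("delay", "right"): 0.5, ("delay", "left"): 0.5}, seed=9,
        )
        both = s.traces[:, 0] + s.traces[:, 1]
        lab = classify_neuron(both, s.trials, timing, kernel)
        assert lab.primary_phase == "delay"
        assert lab.direction == "nondirectional"


class TestExcludeDrifting:
    @pytest.mark.parametrize(
        "pref_level,opp_level,kept",
        [(1.0, 0.2, True), (0.2, 1.0, False), (0.5, 0.5, True)],
        ids=["preferred_dominates", "opposite_dominates", "equality_retained"],
    )
    def test_exclusion_rule(self, pref_level, opp_level, kept, timing):
        n_trials = 8
        tf = timing.trial_frames
        df = pd.DataFrame({
            "trial": range(n_trials),
            "stim_dir": ["right", "left"] * 4,
            "resp_dir": ["right", "left"] * 4,
            "outcome": ["correct"] * n_trials,
            "stim_onset": np.arange(n_trials) * tf,
            "delay_onset": np.arange(n_trials) * tf + 120,
            "port_contact": np.arange(n_trials) * tf + 170,
            "delay_s": 1.5,
        })
        trials = TrialTable(df)
        traces = np.zeros((n_trials * tf, 1))
        for t in range(n_trials):
            level = pref_level if df.stim_dir[t] == "right" else opp_level
            traces[t * tf + 120 : t * tf + 170, 0] = level
        labels = pd.DataFrame(
            [{"neuron": 0, "phase": "delay", "direction": "right"}]
        )
        out = exclude_drifting_neurons(labels, traces, trials, timing)
        assert (len(out) == 1) == kept
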