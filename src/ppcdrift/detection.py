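"""Automated event-related neuron detection and GLM neuron classification.

The detection model treats an event-related calcium trace as a train of
impulses at the task-event times, convolved with the double-exponential
indicator kernel.  For each pixel (or neuron trace) the per-event
amplitudes β are estimated jointly by least squares against the
event-locked template, and event relevance is decided by a one-sample
t-test on the fitted amplitudes: t = β̄ / (s/√k) with k−1 degrees of
freedom.  Significant pixels are clustered into ROIs under the Moore
(8-connected) neighborhood.

Neuron-level classification regresses a trace on the six task-event
templates (right/left × sample/delay/reward, anchored on correct trials)
in one joint design and labels the neuron by the phases and directions
whose amplitude distributions test significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as _cc_label

from .session import (
    DELAY, LEFT, PHASES, REWARD, RIGHT, SAMPLE,
    KernelParams, PixelMovie, Session, TimingConfig, TrialTable, opposite,
)
from .synthetic import kernel_frames

EVENT_KINDS = (
    "sample_R", "sample_L", "delay_R", "delay_L", "reward_R", "reward_L",
)

_KIND_PHASE = {"sample": SAMPLE, "delay": DELAY, "reward": REWARD}
_KIND_DIR = {"R": RIGHT, "L": LEFT}


def _parse_kind(event_kind: str) -> tuple[str, str]:
    try:
        phase_key, dir_key = event_kind.split("_")
        return _KIND_PHASE[phase_key], _KIND_DIR[dir_key]
    except (ValueError, KeyError):
        raise ValueError(f"unknown event kind {event_kind!r}") from None


@dataclass
class EventTemplate:
    """Event-locked design: one unit-amplitude kernel copy per event."""

    event_frames: np.ndarray
    kernel: KernelParams
    matrix: np.ndarray  # n_frames x k, columns are non-negative
    kind: str | None = None

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BetaFit:
    """Least-squares per-event amplitudes and the relevance statistic."""

    betas: np.ndarray
    beta_mean: float
    beta_sd: float
    t_statistic: float
    p_value: float
    k: int


@dataclass
class RoiDetectionResult:
    significance_mask: np.ndarray
    roi_labels: np.ndarray
    rois: list[np.ndarray]
    p_values: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class GlmNeuronLabel:
    """Per-neuron GLM classification outcome.

    ``phases`` is the set of phases with at least one significant
    regressor; ``primary_phase`` is the phase of the significant
    regressor with the largest mean amplitude (ties broken by smaller
    p), used for ground-truth label comparison.  ``direction`` is
    left/right if only that direction's regressors pass, "nondirectional"
    if both do, "none" if no regressor passes.  Neurons whose significant
    phases disagree in direction across phases are flagged ambiguous and
    carry a per-phase direction map.
    """

    p_values: dict[str, float]
    fits: dict[str, BetaFit]
    phases: set[str]
    primary_phase: str | None
    direction: str
    per_phase_direction: dict[str, str] = field(default_factory=dict)
    ambiguous: bool = False


def build_event_template(
    trials: TrialTable,
    event_kind: str,
    timing: TimingConfig,
    kernel: KernelParams,
    n_frames: int,
    correct_only: bool = True,
    impulse: bool = False,
) -> EventTemplate:
    """Template for one task-event kind, anchored at each matching event.

    Sample events anchor at stimulus onset, delay events at delay onset
    and reward events at port contact, on (by default) correct trials of
    the given direction.  Each column is the binary presence indicator of
    the event over its phase window convolved with the indicator kernel
    and normalized to peak 1, so responses anywhere within the phase are
    captured; with ``impulse=True`` the column is instead a single
    peak-normalized kernel copy at the anchor frame (a point event).
    """
    phase, direction = _parse_kind(event_kind)
    sel = trials.select(
        stim=direction if phase != REWARD else None,
        resp=direction if phase == REWARD else None,
        outcome="correct" if correct_only else None,
    )
    if len(sel) == 0:
        raise ValueError(f"no matching trials for event kind {event_kind!r}")
    anchor_col = {SAMPLE: "stim_onset", DELAY: "delay_onset", REWARD: "port_contact"}
    onsets = sel[anchor_col[phase]].to_numpy(dtype=int)
    lo, hi = timing.phase_interval(phase)
    duration = 1 if impulse else hi - lo
    ker = kernel_frames(n_frames, kernel, timing.frame_rate_hz)
    # kernel-smoothed phase indicator, one copy per event
    shape = np.convolve(np.ones(duration), ker)[:n_frames]
    shape = shape / shape.max()
    # trials are modeled as independent: columns stop at their trial's end
    trial_starts = sel["stim_onset"].to_numpy(dtype=int) - timing.pre_frames \
        - timing.sample_frames[0]
    trial_ends = np.minimum(trial_starts + timing.trial_frames, n_frames)
    cols = np.zeros((n_frames, len(onsets)))
    for j, (ev, end) in enumerate(zip(onsets, trial_ends)):
        if not 0 <= ev < n_frames:
            raise ValueError(f"event frame {ev} outside the session")
        cols[ev:end, j] = shape[: end - ev]
    return EventTemplate(
        event_frames=onsets, kernel=kernel, matrix=cols, kind=event_kind
    )


def _snap_tiny(betas: np.ndarray) -> np.ndarray:
    """Zero out amplitudes at floating-point-noise scale (relative 1e-9)."""
    scale = np.abs(betas).max(initial=0.0)
    if scale > 0:
        betas = np.where(np.abs(betas) < 1e-9 * scale, 0.0, betas)
    return betas


def _betas_to_fit(betas: np.ndarray) -> BetaFit:
    k = betas.size
    if k < 2:
        raise ValueError("need at least 2 events for the t statistic")
    bmean = float(betas.mean())
    bsd = float(betas.std(ddof=1))
    if bsd == 0.0:
        # degenerate contract: identical amplitudes
        if bmean > 0:
            t, p = np.inf, 0.0
        elif bmean < 0:
            t, p = -np.inf, 1.0
        else:
            t, p = 0.0, 1.0
    else:
        t = bmean / (bsd / np.sqrt(k))
        p = float(stats.t.sf(t, df=k - 1))
    return BetaFit(
        betas=betas, beta_mean=bmean, beta_sd=bsd,
        t_statistic=float(t), p_value=p, k=k,
    )


def fit_betas(trace: np.ndarray, template: EventTemplate) -> BetaFit:
    """Joint least-squares per-event amplitudes for one trace.

    The reported p-value is one-tailed (positive activation); see
    :func:`test_event_relevance` for the gating rules.
    """
    trace = np.asarray(trace, dtype=np.float64)
    T = template.matrix
    if trace.shape[0] != T.shape[0]:
        raise ValueError("trace and template lengths differ")
    if np.linalg.matrix_rank(T) < T.shape[1]:
        ev = template.event_frames
        dup = sorted(set(int(e) for e in ev if (ev == e).sum() > 1))
        raise ValueError(
            f"rank-deficient template; coinciding events at frames {dup}"
        )
    betas = _snap_tiny(np.linalg.lstsq(T, trace, rcond=None)[0])
    return _betas_to_fit(betas)


def test_event_relevance(
    fit: BetaFit, alpha: float = 0.05, two_tailed: bool = False
) -> tuple[bool, float]:
    """Gate a fit by the one-sample t-test on its amplitudes.

    Default is one-tailed toward positive activation (calcium events are
    positive-going): significant iff p < alpha and β̄ > 0.  The two-tailed
    variant is available behind ``two_tailed``.
    """
    if fit.k < 2:
        raise ValueError("t test undefined for k < 2")
    p = fit.p_value
    if two_tailed:
        if np.isinf(fit.t_statistic):
            p = 0.0
        elif fit.beta_sd == 0.0:
            p = 1.0
        else:
            p = 2.0 * float(stats.t.sf(abs(fit.t_statistic), df=fit.k - 1))
        return (p < alpha and fit.beta_mean != 0.0), p
    return (p < alpha and fit.beta_mean > 0.0), p


def _batch_pvalues(traces: np.ndarray, template: EventTemplate) -> np.ndarray:
    """Vectorized one-tailed p-values for many traces against one template."""
    T = template.matrix
    betas = np.linalg.pinv(T) @ traces  # k x n_traces
    k = betas.shape[0]
    bmean = betas.mean(axis=0)
    bsd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = bmean / (bsd / np.sqrt(k))
    p = np.where(
        bsd == 0.0,
        np.where(bmean > 0, 0.0, 1.0),
        stats.t.sf(np.where(bsd == 0.0, 0.0, t), df=k - 1),
    )
    return p


def detect_rois(
    movie: PixelMovie,
    trials: TrialTable,
    event_kinds: tuple[str, ...] = EVENT_KINDS,
    timing: TimingConfig | None = None,
    kernel: KernelParams | None = None,
    alpha: float = 0.05,
) -> RoiDetectionResult:
    """Pixelwise event-relevance test + Moore-neighborhood ROI clustering.

    A pixel enters the significance mask if any event kind tests
    significant at ``alpha``; the mask is clustered into ROIs under
    8-connectivity.  No multiple-testing correction across pixels is
    applied.  An empty mask yields an empty ROI list.
    """
    if timing is None:
        timing = TimingConfig()
    if kernel is None:
        kernel = KernelParams.cytosolic()
    n_frames, h, w = movie.shape
    traces = movie.pixel_traces()
    mask = np.zeros(h * w, dtype=bool)
    p_values: dict[str, np.ndarray] = {}
    for kind in event_kinds:
        template = build_event_template(trials, kind, timing, kernel, n_frames)
        p = _batch_pvalues(traces, template)
        p_values[kind] = p.reshape(h, w)
        mask |= p < alpha
    mask = mask.reshape(h, w)
    labels = _cc_label(mask, connectivity=2)  # Moore neighborhood
    rois = [
        np.column_stack(np.nonzero(labels == i))
        for i in range(1, labels.max() + 1)
    ]
    return RoiDetectionResult(
        significance_mask=mask, roi_labels=labels, rois=rois, p_values=p_values
    )


def classify_neuron(
    trace: np.ndarray,
    trials: TrialTable,
    timing: TimingConfig | None = None,
    kernel: KernelParams | None = None,
    alpha_neuron: float = 0.01,
    two_tailed: bool = False,
) -> GlmNeuronLabel:
    """Label one neuron by phase(s) and direction from the six-event GLM.

    All six templates are fitted in a single joint design so that
    overlapping kernel tails are attributed once; each kind's amplitude
    subvector is then tested separately at ``alpha_neuron``.
    """
    if timing is None:
        timing = TimingConfig()
    if kernel is None:
        kernel = KernelParams.cytosolic()
    trace = np.asarray(trace, dtype=np.float64)
    n_frames = trace.shape[0]

    templates = {
        kind: build_event_template(trials, kind, timing, kernel, n_frames)
        for kind in EVENT_KINDS
    }
    design = np.hstack([templates[k].matrix for k in EVENT_KINDS])
    all_betas = _snap_tiny(np.linalg.lstsq(design, trace, rcond=None)[0])

    fits: dict[str, BetaFit] = {}
    p_values: dict[str, float] = {}
    offset = 0
    for kind in EVENT_KINDS:
        k = templates[kind].k
        fits[kind] = _betas_to_fit(all_betas[offset:offset + k])
        offset += k
    sig_kinds = []
    for kind in EVENT_KINDS:
        significant, p = test_event_relevance(
            fits[kind], alpha=alpha_neuron, two_tailed=two_tailed
        )
        p_values[kind] = p
        if significant:
            sig_kinds.append(kind)

    phases = {_parse_kind(k)[0] for k in sig_kinds}
    per_phase_dir: dict[str, str] = {}
    for phase in PHASES:
        dirs = {_parse_kind(k)[1] for k in sig_kinds if _parse_kind(k)[0] == phase}
        if dirs == {LEFT}:
            per_phase_dir[phase] = LEFT
        elif dirs == {RIGHT}:
            per_phase_dir[phase] = RIGHT
        elif dirs == {LEFT, RIGHT}:
            per_phase_dir[phase] = "nondirectional"

    all_dirs = {_parse_kind(k)[1] for k in sig_kinds}
    if not sig_kinds:
        direction = "none"
    elif all_dirs == {LEFT}:
        direction = LEFT
    elif all_dirs == {RIGHT}:
        direction = RIGHT
    else:
        direction = "nondirectional"
    distinct = {d for d in per_phase_dir.values() if d != "nondirectional"}
    ambiguous = len(distinct) > 1

    primary = None
    if sig_kinds:
        best = max(
            sig_kinds, key=lambda k: (fits[k].beta_mean, -p_values[k])
        )
        primary = _parse_kind(best)[0]
    return GlmNeuronLabel(
        p_values=p_values, fits=fits, phases=phases, primary_phase=primary,
        direction=direction, per_phase_direction=per_phase_dir,
        ambiguous=ambiguous,
    )


def classify_session(
    session: Session,
    alpha_neuron: float = 0.01,
    kernel: KernelParams | None = None,
    two_tailed: bool = False,
) -> pd.DataFrame:
    """Classify every neuron of a session; returns a tidy label table."""
    rows = []
    for i in range(session.n_neurons):
        lab = classify_neuron(
            session.traces[:, i], session.trials, session.timing,
            kernel=kernel, alpha_neuron=alpha_neuron, two_tailed=two_tailed,
        )
        row = {
            "neuron": i,
            "phase": lab.primary_phase if lab.primary_phase else "none",
            "phases": "+".join(sorted(lab.phases)) if lab.phases else "none",
            "direction": lab.direction,
            "ambiguous": lab.ambiguous,
        }
        for kind in EVENT_KINDS:
            row[f"p_{kind}"] = lab.p_values[kind]
        rows.append(row)
    return pd.DataFrame(rows)


def exclude_drifting_neurons(
    labels: pd.DataFrame,
    traces: np.ndarray,
    trials: TrialTable,
    timing: TimingConfig | None = None,
) -> pd.DataFrame:
    """Drop directional neurons that respond more to the nonpreferred signal.

    A directional neuron is excluded when its mean ΔF/F on correct trials
    of the opposite direction strictly exceeds its preferred-direction
    mean within its selective phase (guards against slow baseline drifts
    masquerading as selectivity).  Equality retains the neuron.
    """
    if timing is None:
        timing = TimingConfig()
    tf = timing.trial_frames
    n_trials = len(trials)
    tensor = np.asarray(traces).reshape(n_trials, tf, -1)
    keep = []
    for row in labels.itertuples(index=False):
        if row.direction not in (LEFT, RIGHT) or row.phase not in PHASES:
            keep.append(True)
            continue
        sl = timing.phase_slice(row.phase)
        pref_idx = trials.select(stim=row.direction, outcome="correct").index
        opp_idx = trials.select(stim=opposite(row.direction), outcome="correct").index
        pref_mean = tensor[np.asarray(pref_idx), sl, row.neuron].mean()
        opp_mean = tensor[np.asarray(opp_idx), sl, row.neuron].mean()
        keep.append(not (opp_mean > pref_mean))
    out = labels.copy()
    out["retained"] = keep
    return out[out.retained].drop(columns="retained").reset_index(drop=True)
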