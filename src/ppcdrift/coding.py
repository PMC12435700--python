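"""Coding-direction modes, projections and residual separation.

A coding direction (CD) is the unit vector in neuron-activity space
along the difference between trial-averaged correct-right and
correct-left activity within a phase window: Δr̄ normalized by its l2
norm.  The standard windows (0-based, half-open, 30 Hz) are frames
65–115 for CD_sample, 120–170 for CD_delay and 170–200 for CD_reward;
the nonselective ramping mode D_reward contrasts the first reward second
(170–200) with the last delay second (140–170), pooled over both correct
directions.  Modes are orthogonalized by Gram-Schmidt in a stated order
so each captures a unique component of the dynamics.

Error trials are never used to define a mode; they are projected onto
correct-trial modes only.  Residual separation is the ratio of the
incorrect-trial right−left projected separation to the correct-trial
separation within the mode's window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .session import LEFT, RIGHT, Session, TimingConfig

MODE_KINDS = ("CD_sample", "CD_delay", "CD_reward", "D_reward")

#: Phase windows per mode kind (0-based, half-open frame intervals).
MODE_WINDOWS = {
    "CD_sample": (65, 115),
    "CD_delay": (120, 170),
    "CD_reward": (170, 200),
    "D_reward": (170, 200),
}
_D_REWARD_BASELINE = (140, 170)  # last delay second

PROJECTION_CONDITIONS = ("R-correct", "L-correct", "R-error", "L-error")


@dataclass
class ModeVector:
    weights: np.ndarray  # unit l2 norm, one weight per neuron
    window: tuple[int, int]
    kind: str
    raw_delta: np.ndarray


@dataclass
class ProjectionSeries:
    """Per-frame projections P(t) for the four stimulus × outcome conditions."""

    series: dict[str, np.ndarray]
    window: tuple[int, int]
    normalization: float | None = None  # mean correct-right in-window value

    def window_mean(self, condition: str, window: tuple[int, int] | None = None):
        lo, hi = window if window is not None else self.window
        return float(self.series[condition][lo:hi].mean())


@dataclass
class ResidualSeparation:
    value: float
    window: tuple[int, int]

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


def _condition_average(session: Session, stim: str, outcome: str) -> np.ndarray:
    """trial_frames × neurons trial-averaged activity of one condition."""
    tensor = session.condition_tensor(stim=stim, outcome=outcome)
    if tensor.shape[0] == 0:
        raise ValueError(f"no {outcome} trials with stimulus {stim}")
    return tensor.mean(axis=0)


def compute_mode(
    session: Session, kind: str, timing: TimingConfig | None = None
) -> ModeVector:
    """Window-mean activity difference of correct trials, l2-normalized.

    CD kinds contrast correct-right vs correct-left in the kind's window;
    D_reward contrasts the reward window vs the late-delay window with
    both correct directions pooled.
    """
    if kind not in MODE_KINDS:
        raise ValueError(f"unknown mode kind {kind!r}")
    timing = timing or session.timing
    pre = timing.pre_frames
    lo, hi = (MODE_WINDOWS[kind][0] + pre, MODE_WINDOWS[kind][1] + pre)
    if kind == "D_reward":
        pooled = session.condition_tensor(outcome="correct").mean(axis=0)
        blo, bhi = (_D_REWARD_BASELINE[0] + pre, _D_REWARD_BASELINE[1] + pre)
        delta = pooled[lo:hi].mean(axis=0) - pooled[blo:bhi].mean(axis=0)
    else:
        r = _condition_average(session, RIGHT, "correct")
        l = _condition_average(session, LEFT, "correct")
        delta = r[lo:hi].mean(axis=0) - l[lo:hi].mean(axis=0)
    norm = np.linalg.norm(delta)
    if norm == 0:
        raise ValueError(f"degenerate mode {kind}: zero activity difference")
    return ModeVector(
        weights=delta / norm, window=(lo, hi), kind=kind, raw_delta=delta
    )


def orthogonalize(modes: list[ModeVector], tol: float = 1e-8) -> list[ModeVector]:
    """Gram-Schmidt in the given order; outputs are orthonormal.

    Raises if a mode collapses (lies in the span of its predecessors).
    """
    basis: list[np.ndarray] = []
    out: list[ModeVector] = []
    dim = modes[0].weights.shape[0]
    for m in modes:
        if m.weights.shape[0] != dim:
            raise ValueError("modes must share the neuron dimension")
        v = m.weights.astype(np.float64).copy()
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n < tol:
            raise ValueError(
                f"mode {m.kind} collapses under orthogonalization"
            )
        v /= n
        basis.append(v)
        out.append(
            ModeVector(weights=v, window=m.window, kind=m.kind, raw_delta=m.raw_delta)
        )
    return out


def project_trials(
    mode: ModeVector,
    session: Session,
    normalize: bool = True,
) -> ProjectionSeries:
    """Per-frame projection of each condition's trial-averaged activity.

    With ``normalize``, every series is divided by the mean correct-right
    projection within the mode's window (so that value is 1 by
    construction); a zero constant falls back to unnormalized output with
    a warning.
    """
    if mode.weights.shape[0] != session.n_neurons:
        raise ValueError("mode dimension does not match session neurons")
    series: dict[str, np.ndarray] = {}
    for cond in PROJECTION_CONDITIONS:
        stim = RIGHT if cond.startswith("R") else LEFT
        outcome = "correct" if cond.endswith("correct") else "error"
        tensor = session.condition_tensor(stim=stim, outcome=outcome)
        if tensor.shape[0] == 0:
            continue
        series[cond] = tensor.mean(axis=0) @ mode.weights
    norm_const = None
    if normalize:
        lo, hi = mode.window
        norm_const = float(series["R-correct"][lo:hi].mean())
        if norm_const == 0.0:
            warnings.warn(
                "normalization constant is zero; returning unnormalized projections",
                stacklevel=2,
            )
            norm_const = None
        else:
            series = {c: s / norm_const for c, s in series.items()}
    return ProjectionSeries(series=series, window=mode.window, normalization=norm_const)


def per_trial_projection(mode: ModeVector, session: Session) -> np.ndarray:
    """(n_trials, trial_frames) projection of every trial onto the mode."""
    return session.trial_tensor() @ mode.weights


def residual_separation(
    proj: ProjectionSeries, window: tuple[int, int] | None = None
) -> ResidualSeparation:
    """(incorrect R − incorrect L) / (correct R − correct L) window means."""
    required = set(PROJECTION_CONDITIONS)
    if not required <= set(proj.series):
        missing = sorted(required - set(proj.series))
        raise ValueError(f"missing projection conditions: {missing}")
    win = window if window is not None else proj.window
    num = proj.window_mean("R-error", win) - proj.window_mean("L-error", win)
    den = proj.window_mean("R-correct", win) - proj.window_mean("L-correct", win)
    value = num / den if den != 0 else np.nan
    return ResidualSeparation(value=float(value), window=win)


def rt_cd_correlation(
    session: Session,
    mode: ModeVector | None = None,
    timing: TimingConfig | None = None,
) -> dict[str, float]:
    """Correlate late-delay CD-projection boundary distance with relative RT.

    Each trial's projection onto the delay coding direction is averaged
    over the final second of the delay; its signed distance to the
    decision boundary (the midpoint between mean correct-right and
    correct-left projections, positive toward right) is correlated
    against the trial's reaction time relative to the session median.
    """
    timing = timing or session.timing
    if "reaction_time_s" not in session.trials.df.columns:
        raise ValueError("trial table has no reaction_time_s column")
    if session.trials.n_trials < 3:
        raise ValueError("need at least 3 trials")
    if mode is None:
        mode = compute_mode(session, "CD_delay", timing)
    proj = per_trial_projection(mode, session)
    d_lo, d_hi = timing.phase_interval("delay")
    one_s = int(round(timing.frame_rate_hz))
    win = slice(max(d_hi - one_s, d_lo), d_hi)
    late = proj[:, win].mean(axis=1)

    df = session.trials.df
    rr = late[(df.stim_dir == RIGHT) & (df.outcome == "correct")].mean()
    ll = late[(df.stim_dir == LEFT) & (df.outcome == "correct")].mean()
    boundary = 0.5 * (rr + ll)
    sign = 1.0 if rr >= ll else -1.0
    distance = sign * (late - boundary)

    rt = df.reaction_time_s.to_numpy(dtype=float)
    rel_rt = rt - np.median(rt)
    if np.allclose(rel_rt, rel_rt[0]):
        return {"pearson_r": np.nan, "p": np.nan}
    r, p = pearsonr(distance, rel_rt)
    return {"pearson_r": float(r), "p": float(p)}
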