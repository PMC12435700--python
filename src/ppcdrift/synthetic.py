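"""Synthetic session generator with known ground truth.

Emulates 30-Hz delayed match-to-sample sessions: direction- and
phase-selective neurons with sequentially tiled peak times, balanced
pseudo-random trial orders, and a configurable error-trial drift of
delay-period activity toward the opposite-direction representation.

The drift model is a convex combination: within the delay (and the
remainder of the trial), the noiseless activity of a delay-selective
neuron on an error trial is ``(1 - w(t)) * a_stim(t) + w(t) * a_opp(t)``
where ``a_d`` is the neuron's correct-trial response pattern to stimulus
``d`` and ``w(t) = clip(drift_rate * t_delay_seconds, 0, 1)`` grows
linearly in time since delay onset at ``drift_rate`` per second.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .session import (
    DELAY, LEFT, PHASES, REWARD, RIGHT, SAMPLE,
    KernelParams, PixelMovie, Session, TimingConfig, TrialTable, opposite,
)

#: Default population mixture: (phase, preferred direction) -> fraction of
#: neurons. Delay-selective neurons are the most abundant group and about
#: half the population is task-selective; the remainder is unselective noise.
DEFAULT_MIX: dict[tuple[str, str], float] = {
    (SAMPLE, RIGHT): 0.10,
    (SAMPLE, LEFT): 0.10,
    (DELAY, RIGHT): 0.15,
    (DELAY, LEFT): 0.15,
    (REWARD, RIGHT): 0.05,
    (REWARD, LEFT): 0.05,
}


def calcium_kernel(
    t: np.ndarray, params: KernelParams, normalize: bool = False
) -> np.ndarray:
    """Double-exponential indicator kernel c(t) = exp(-t/τd) − exp(-t/τr).

    ``t`` is a non-negative, increasing time grid in seconds.  With
    ``normalize=True`` the kernel is scaled so its peak equals 1
    (evaluated in closed form at the analytic time-to-peak).
    """
    t = np.asarray(t, dtype=np.float64)
    if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
        raise ValueError("t must be non-negative and strictly increasing")
    c = np.exp(-t / params.tau_decay_s) - np.exp(-t / params.tau_rise_s)
    if normalize:
        tp = params.time_to_peak_s
        peak = np.exp(-tp / params.tau_decay_s) - np.exp(-tp / params.tau_rise_s)
        c = c / peak
    return c


def kernel_frames(
    n_frames: int,
    params: KernelParams,
    frame_rate_hz: float,
    normalize: bool = True,
) -> np.ndarray:
    """Kernel sampled on the frame grid, peak-normalized by default."""
    t = np.arange(n_frames, dtype=np.float64) / frame_rate_hz
    return calcium_kernel(t, params, normalize=normalize)


def synthesize_trace(
    events: Sequence[int],
    betas: Sequence[float],
    params: KernelParams,
    timing: TimingConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Single-neuron ΔF/F trace: Σ βᵢ·c(t−tᵢ) plus Gaussian noise.

    Events are frame indices; each contributes a peak-normalized kernel
    copy scaled by its amplitude.  Deterministic given ``seed``.
    """
    if n_frames is None:
        n_frames = timing.trial_frames
    events = np.asarray(events, dtype=int)
    betas = np.asarray(betas, dtype=np.float64)
    if events.shape != betas.shape:
        raise ValueError("betas must align one-to-one with events")
    if events.size and (events.min() < 0 or events.max() >= n_frames):
        raise ValueError("event frame outside the session")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ker = kernel_frames(n_frames, params, timing.frame_rate_hz)
    trace = np.zeros(n_frames)
    for ev, b in zip(events, betas):
        span = n_frames - ev
        trace[ev:] += b * ker[:span]
    if noise_sd > 0:
        trace += np.random.default_rng(seed).normal(0.0, noise_sd, n_frames)
    return trace


def _balanced_directions(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    n_right = n_trials // 2 + (n_trials % 2) * int(rng.integers(2))
    dirs = np.array([RIGHT] * n_right + [LEFT] * (n_trials - n_right))
    return rng.permutation(dirs)


def _assign_neurons(
    n_neurons: int, mix: Mapping[tuple[str, str], float], rng: np.random.Generator
) -> pd.DataFrame:
    total = float(sum(mix.values()))
    if total > 1 + 1e-9:
        raise ValueError("mix fractions must sum to <= 1")
    rows = []
    for (phase, direction), frac in mix.items():
        if phase not in PHASES or direction not in (LEFT, RIGHT):
            raise ValueError(f"bad mix key {(phase, direction)!r}")
        for _ in range(int(round(frac * n_neurons))):
            if len(rows) < n_neurons:
                rows.append({"phase": phase, "preferred_direction": direction})
    while len(rows) < n_neurons:
        rows.append({"phase": "none", "preferred_direction": "none"})
    df = pd.DataFrame(rows)
    df.insert(0, "neuron", np.arange(len(df)))
    return df


def _sequence_peaks(
    gt: pd.DataFrame, timing: TimingConfig, kernel: KernelParams
) -> pd.DataFrame:
    """Evenly tile event times of each phase group across its phase window.

    Events keep a trailing margin of one indicator decay half-life
    (clipped to half the window) before the phase end, so each
    transient's rising limb and the majority of its area stay within the
    assigned phase; without the margin, late-phase events would fluoresce
    mostly in the following window and their planted label would be
    unrecoverable by any fluorescence-based classifier.
    """
    gt = gt.copy()
    gt["peak_time_frame"] = -1
    half_life = np.log(2.0) * kernel.tau_decay_s * timing.frame_rate_hz
    for phase in PHASES:
        lo, hi = timing.phase_interval(phase)
        margin = int(min(round(half_life), (hi - lo) // 2))
        idx = gt.index[gt.phase == phase]
        if len(idx) == 0:
            continue
        peaks = np.linspace(lo, hi - margin, len(idx) + 2)[1:-1]
        gt.loc[idx, "peak_time_frame"] = np.round(peaks).astype(int)
    return gt


def generate_session(
    n_neurons: int = 60,
    n_trials: int = 60,
    mix: Mapping[tuple[str, str], float] | None = None,
    error_rate: float = 0.3,
    drift_rate: float = 0.0,
    noise_sd: float = 0.15,
    timing: TimingConfig | None = None,
    kernel: KernelParams | None = None,
    amplitude_beta: float = 1.0,
    seed: int = 0,
) -> Session:
    """Generate a full synthetic session with recorded ground truth.

    Trial directions are pseudo-random and balanced; a fraction
    ``error_rate`` of each direction's trials (rounded) is made incorrect.
    Selective neurons fire one event per matching trial at their assigned
    peak time; on error trials delay-selective activity drifts toward the
    opposite-direction pattern at ``drift_rate`` per second.  Per-trial
    reaction times (independent jitter) are emitted for the RT analyses.
    """
    if timing is None:
        timing = TimingConfig()
    if kernel is None:
        kernel = KernelParams.cytosolic()
    if mix is None:
        mix = DEFAULT_MIX
    if not (0 <= error_rate <= 1):
        raise ValueError("error_rate must be in [0, 1]")
    if drift_rate < 0:
        raise ValueError("drift_rate must be non-negative")
    rng = np.random.default_rng(seed)

    stim = _balanced_directions(n_trials, rng)
    for d in (LEFT, RIGHT):
        if (stim == d).sum() < 2:
            raise ValueError("need at least 2 trials per direction")

    outcome = np.array(["correct"] * n_trials, dtype=object)
    for d in (LEFT, RIGHT):
        idx = np.flatnonzero(stim == d)
        n_err = int(round(error_rate * len(idx)))
        n_err = min(n_err, max(len(idx) - 2, 0))  # keep >=2 correct per side
        outcome[rng.choice(idx, size=n_err, replace=False)] = "error"
    resp = np.array(
        [s if o == "correct" else opposite(s) for s, o in zip(stim, outcome)],
        dtype=object,
    )

    tf = timing.trial_frames
    starts = np.arange(n_trials) * tf
    trials = TrialTable(pd.DataFrame({
        "trial": np.arange(n_trials),
        "stim_dir": stim,
        "resp_dir": resp,
        "outcome": outcome,
        "stim_onset": starts + timing.pre_frames,
        "delay_onset": starts + timing.phase_interval(DELAY)[0],
        "port_contact": starts + timing.phase_interval(REWARD)[0],
        "delay_s": rng.choice([1.5, 2.0], size=n_trials),
        "reaction_time_s": np.clip(rng.normal(0.15, 0.03, n_trials), 0.02, None),
    }))

    gt = _assign_neurons(n_neurons, mix, rng)
    gt = _sequence_peaks(gt, timing, kernel)
    gt["amplitude_beta"] = np.where(gt.phase == "none", 0.0, amplitude_beta)
    gt["drift_rate"] = np.where(gt.phase == DELAY, drift_rate, 0.0)

    ker = kernel_frames(tf, kernel, timing.frame_rate_hz)
    delay_lo = timing.phase_interval(DELAY)[0]
    # Drift mixing weight over one trial (zero before delay onset).
    t_since_delay = (np.arange(tf) - delay_lo) / timing.frame_rate_hz
    w = np.clip(drift_rate * np.clip(t_since_delay, 0.0, None), 0.0, 1.0)

    traces = np.zeros((n_trials * tf, n_neurons))
    for row in gt.itertuples(index=False):
        if row.phase == "none":
            continue
        ev = int(row.peak_time_frame)
        resp_pattern = np.zeros(tf)
        span = tf - ev
        resp_pattern[ev:] = row.amplitude_beta * ker[:span]
        for ti in range(n_trials):
            s, r, o = stim[ti], resp[ti], outcome[ti]
            if row.phase == REWARD:
                # reward responses are locked to the response side
                active = r == row.preferred_direction
                trial_trace = resp_pattern if active else None
            elif row.phase == SAMPLE:
                trial_trace = resp_pattern if s == row.preferred_direction else None
            else:  # delay-selective: drift on error trials
                a_stim = 1.0 if s == row.preferred_direction else 0.0
                if o == "error":
                    a_opp = 1.0 if opposite(s) == row.preferred_direction else 0.0
                    mixcoef = (1.0 - w) * a_stim + w * a_opp
                else:
                    mixcoef = a_stim
                if np.isscalar(mixcoef) and mixcoef == 0.0:
                    trial_trace = None
                else:
                    trial_trace = resp_pattern * mixcoef
            if trial_trace is not None:
                sl = slice(ti * tf, (ti + 1) * tf)
                traces[sl, row.neuron] += trial_trace
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, traces.shape)

    return Session(
        traces=traces, trials=trials, timing=timing, ground_truth=gt, seed=seed
    )


def generate_movie(
    session: Session,
    footprint_shape: tuple[int, int] = (4, 4),
    image_size: tuple[int, int] = (32, 32),
    background_sd: float = 0.1,
    seed: int = 0,
    positions: Sequence[tuple[int, int]] | None = None,
) -> PixelMovie:
    """Paint each neuron's trace onto a compact pixel footprint.

    Footprints (default 4 × 4 px, matching typical two-photon neuron
    sizes) are placed on a non-overlapping grid unless explicit
    ``positions`` (top-left corners) are given; overlapping explicit
    footprints raise a warning and are recorded in ``overlap_map``.
    Background noise (sd ``background_sd``) is added to every pixel, so
    non-footprint pixels carry no event-locked signal.
    """
    fh, fw = footprint_shape
    h, wdt = image_size
    n = session.n_neurons
    rng = np.random.default_rng(seed)

    if positions is None:
        cells = [
            (r, c)
            for r in range(0, h - fh + 1, fh + 1)
            for c in range(0, wdt - fw + 1, fw + 1)
        ]
        if len(cells) < n:
            raise ValueError(
                f"image {image_size} fits only {len(cells)} footprints of "
                f"{footprint_shape}; session has {n} neurons"
            )
        positions = [cells[i] for i in rng.permutation(len(cells))[:n]]
    else:
        positions = list(positions)
        if len(positions) != n:
            raise ValueError("need one position per neuron")

    footprints = []
    count = np.zeros(image_size, dtype=int)
    for r, c in positions:
        if r < 0 or c < 0 or r + fh > h or c + fw > wdt:
            raise ValueError(f"footprint at {(r, c)} does not fit in the image")
        rr, cc = np.mgrid[r:r + fh, c:c + fw]
        fp = np.column_stack([rr.ravel(), cc.ravel()])
        footprints.append(fp)
        count[rr, cc] += 1
    overlap = count > 1
    if overlap.any():
        warnings.warn(
            f"{int(overlap.sum())} pixels shared by multiple footprints",
            stacklevel=2,
        )

    stack = np.zeros((session.n_frames, h, wdt))
    if background_sd > 0:
        stack += rng.normal(0.0, background_sd, stack.shape)
    for i, fp in enumerate(footprints):
        stack[:, fp[:, 0], fp[:, 1]] += session.traces[:, [i]]
    return PixelMovie(
        stack=stack,
        footprints=footprints,
        seed=seed,
        overlap_map=overlap if overlap.any() else None,
    )
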