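"""Core data containers for trial-structured calcium-imaging sessions.

A session is a ΔF/F trace matrix (frames × neurons) plus a trial table and
the timing constants of the delayed match-to-sample task: a 4-s sample
phase, a delay, and a reward (response) phase, all defined in frames at
30 Hz.  Frame intervals are half-open and 0-based throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"
DIRECTIONS = (LEFT, RIGHT)

SAMPLE = "sample"
DELAY = "delay"
REWARD = "reward"
PHASES = (SAMPLE, DELAY, REWARD)

TRIAL_COLUMNS = [
    "trial", "stim_dir", "resp_dir", "outcome",
    "stim_onset", "delay_onset", "port_contact", "delay_s",
]


def opposite(direction: str) -> str:
    if direction == LEFT:
        return RIGHT
    if direction == RIGHT:
        return LEFT
    raise ValueError(f"no opposite for direction {direction!r}")


@dataclass(frozen=True)
class TimingConfig:
    """Task timing in frames (0-based, half-open intervals) at a fixed rate.

    Defaults follow the standard trial layout: 120 sample frames (4 s at
    30 Hz), 50 delay frames, 30 reward frames; no pre-stimulus baseline.
    """

    frame_rate_hz: float = 30.0
    sample_frames: tuple[int, int] = (0, 120)
    delay_frames: tuple[int, int] = (120, 170)
    reward_frames: tuple[int, int] = (170, 200)
    pre_frames: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pre_frames < 0:
            raise ValueError("pre_frames must be non-negative")
        ivs = [self.sample_frames, self.delay_frames, self.reward_frames]
        for lo, hi in ivs:
            if not 0 <= lo < hi:
                raise ValueError(f"bad frame interval ({lo}, {hi})")
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if b > c:
                raise ValueError("phase intervals must be disjoint and ordered")

    @property
    def trial_frames(self) -> int:
        return self.pre_frames + self.reward_frames[1]

    def phase_interval(self, phase: str) -> tuple[int, int]:
        lo, hi = {
            SAMPLE: self.sample_frames,
            DELAY: self.delay_frames,
            REWARD: self.reward_frames,
        }[phase]
        return (self.pre_frames + lo, self.pre_frames + hi)

    def phase_slice(self, phase: str) -> slice:
        lo, hi = self.phase_interval(phase)
        return slice(lo, hi)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TimingConfig":
        d = dict(d)
        for k in ("sample_frames", "delay_frames", "reward_frames"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class KernelParams:
    """Double-exponential calcium-indicator kernel time constants (seconds).

    The decay constant is 1.0 s for cytosolic indicators and 3.0 s for
    nuclear-localized ones; the rise constant defaults to 0.1 s (typical
    fast GCaMP rise), configurable.
    """

    tau_rise_s: float = 0.1
    tau_decay_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_decay_s > self.tau_rise_s > 0):
            raise ValueError(
                "require tau_decay_s > tau_rise_s > 0, got "
                f"decay={self.tau_decay_s}, rise={self.tau_rise_s}"
            )

    @classmethod
    def cytosolic(cls) -> "KernelParams":
        return cls(tau_rise_s=0.1, tau_decay_s=1.0)

    @classmethod
    def nuclear(cls) -> "KernelParams":
        return cls(tau_rise_s=0.1, tau_decay_s=3.0)

    @property
    def time_to_peak_s(self) -> float:
        """Closed-form argmax of exp(-t/τd) − exp(-t/τr)."""
        r, d = self.tau_rise_s, self.tau_decay_s
        return r * d / (d - r) * np.log(d / r)

    def to_dict(self) -> dict:
        return asdict(self)


class TrialTable:
    """Per-trial metadata: stimulus/response direction, outcome, event frames.

    Backed by a pandas DataFrame with columns
    ``trial, stim_dir, resp_dir, outcome, stim_onset, delay_onset,
    port_contact, delay_s`` (optionally ``reaction_time_s``).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        df = df.reset_index(drop=True)
        bad = df[(df.outcome == "correct") != (df.resp_dir == df.stim_dir)]
        if len(bad):
            raise ValueError(
                f"outcome inconsistent with directions on trials {list(bad.trial)}"
            )
        mono = (df.stim_onset < df.delay_onset) & (df.delay_onset < df.port_contact)
        if not mono.all():
            raise ValueError("event frames must be strictly increasing within trials")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def select(
        self,
        stim: str | None = None,
        resp: str | None = None,
        outcome: str | None = None,
    ) -> pd.DataFrame:
        m = pd.Series(True, index=self.df.index)
        if stim is not None:
            m &= self.df.stim_dir == stim
        if resp is not None:
            m &= self.df.resp_dir == resp
        if outcome is not None:
            m &= self.df.outcome == outcome
        return self.df[m]

    @property
    def correct(self) -> pd.DataFrame:
        return self.select(outcome="correct")

    @property
    def errors(self) -> pd.DataFrame:
        return self.select(outcome="error")

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly through text
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class Session:
    """One imaging session: ΔF/F traces, trial table, timing, ground truth.

    ``ground_truth`` is a per-neuron DataFrame (columns ``neuron,
    preferred_direction, phase, peak_time_frame, amplitude_beta,
    drift_rate``) for synthetic sessions and ``None`` for real data.
    """

    traces: np.ndarray
    trials: TrialTable
    timing: TimingConfig
    ground_truth: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 2:
            raise ValueError("traces must be frames x neurons")
        if not np.isfinite(self.traces).all():
            raise ValueError("traces must be finite")
        expected = self.trials.n_trials * self.timing.trial_frames
        if self.traces.shape[0] != expected:
            raise ValueError(
                f"traces have {self.traces.shape[0]} frames; trial table implies {expected}"
            )

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[1]

    def trial_tensor(self, trial_indices: Iterable[int] | None = None) -> np.ndarray:
        """Traces reshaped to (trials, trial_frames, neurons)."""
        t = self.traces.reshape(
            self.trials.n_trials, self.timing.trial_frames, self.n_neurons
        )
        if trial_indices is None:
            return t
        return t[np.asarray(list(trial_indices), dtype=int)]

    def condition_tensor(
        self, stim: str | None = None, resp: str | None = None,
        outcome: str | None = None,
    ) -> np.ndarray:
        idx = self.trials.select(stim=stim, resp=resp, outcome=outcome).index
        return self.trial_tensor(idx)

    # -- persistence ------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with h5py.File(out / "traces.h5", "w") as f:
            f.create_dataset("dff", data=self.traces, dtype="float64")
        self.trials.to_csv(out / "trials.csv")
        meta = {"timing": self.timing.to_dict(), "seed": self.seed}
        (out / "session.json").write_text(json.dumps(meta, indent=2))
        if self.ground_truth is not None:
            self.ground_truth.to_csv(out / "ground_truth.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "Session":
        src = Path(in_dir)
        with h5py.File(src / "traces.h5", "r") as f:
            traces = f["dff"][:]
        trials = TrialTable.from_csv(src / "trials.csv")
        meta = json.loads((src / "session.json").read_text())
        gt_path = src / "ground_truth.csv"
        gt = pd.read_csv(gt_path) if gt_path.exists() else None
        return cls(
            traces=traces,
            trials=trials,
            timing=TimingConfig.from_dict(meta["timing"]),
            ground_truth=gt,
            seed=meta.get("seed"),
        )


@dataclass
class PixelMovie:
    """Synthetic pixel movie: stack (frames × height × width) plus the
    ground-truth pixel footprint of each painted neuron."""

    stack: np.ndarray
    footprints: list[np.ndarray]
    seed: int | None = None
    overlap_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 3:
            raise ValueError("stack must be frames x height x width")
        if not np.isfinite(self.stack).all():
            raise ValueError("stack must be finite")
        h, w = self.stack.shape[1:]
        for fp in self.footprints:
            fp = np.asarray(fp)
            if fp.size and (
                fp[:, 0].min() < 0 or fp[:, 0].max() >= h
                or fp[:, 1].min() < 0 or fp[:, 1].max() >= w
            ):
                raise ValueError("footprint outside image bounds")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stack.shape

    def pixel_traces(self) -> np.ndarray:
        """Flattened (frames × pixels) view for pixelwise regression."""
        f, h, w = self.stack.shape
        return self.stack.reshape(f, h * w)

    def save(self, out_dir: str | Path) -> None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "movie.tif", self.stack.astype(np.float32))
        meta = {
            "seed": self.seed,
            "footprints": [np.asarray(fp).tolist() for fp in self.footprints],
        }
        (out / "movie.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, in_dir: str | Path) -> "PixelMovie":
        import tifffile

        src = Path(in_dir)
        stack = tifffile.imread(src / "movie.tif").astype(np.float64)
        meta = json.loads((src / "movie.json").read_text())
        fps = [np.asarray(fp, dtype=int) for fp in meta["footprints"]]
        return cls(stack=stack, footprints=fps, seed=meta.get("seed"))
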