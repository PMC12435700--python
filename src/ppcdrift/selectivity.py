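"""ROC-based selectivity indices and permutation validation.

All indices share one construction: an ideal-observer auROC between two
value distributions, mapped to [−1, +1] by 2·(auROC − 0.5).  The
preference index (PI) compares trial-mean ΔF/F on right vs left trials
(right is the positive class, so PI > 0 means right preference); the
reliability index (RI) applies the same machinery to pooled single-trial
frame values; the phase-selectivity index (PSI) compares a neuron's
in-phase trial means against its pooled out-of-phase trial means.

Ties receive 0.5 credit, so the auROC equals the exhaustive pairwise
count (wins + 0.5·ties)/(n_pos·n_neg); computed via the rank-sum
identity with midranks.  Any strictly increasing transform of the inputs
leaves every index unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .session import (
    DELAY, LEFT, PHASES, RIGHT, SAMPLE, REWARD,
    Session, TimingConfig, TrialTable,
)


@dataclass(frozen=True)
class RocIndex:
    auroc: float
    index: float
    n_pos: int
    n_neg: int


@dataclass
class PermutationResult:
    observed_index: float
    null_distribution: np.ndarray
    z_score: float
    percentile_95: float
    trial_pass_fraction: float

    @property
    def significant(self) -> bool:
        return self.observed_index > self.percentile_95


def auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Area under the ROC curve of ``pos`` vs ``neg`` with 0.5 tie credit."""
    pos = np.asarray(pos, dtype=np.float64).ravel()
    neg = np.asarray(neg, dtype=np.float64).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both distributions must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _roc_index(pos, neg, min_per_side: int = 1) -> RocIndex:
    pos = np.asarray(pos, dtype=np.float64).ravel()
    neg = np.asarray(neg, dtype=np.float64).ravel()
    if pos.size < min_per_side or neg.size < min_per_side:
        raise ValueError(f"need at least {min_per_side} values per side")
    a = auroc(pos, neg)
    return RocIndex(auroc=a, index=2.0 * (a - 0.5), n_pos=pos.size, n_neg=neg.size)


def preference_index(trial_means_right, trial_means_left) -> RocIndex:
    """PI: ROC index of right- vs left-trial mean responses in a phase."""
    return _roc_index(trial_means_right, trial_means_left, min_per_side=2)


def reliability_index(
    frame_values_right, frame_values_left, max_dff: float | None = None
) -> RocIndex:
    """RI: same ROC construction on pooled single-trial frame values.

    ``max_dff`` optionally normalizes both pools to the neuron's maximum
    ΔF/F across the trial; being a positive rescaling it cannot change
    the index (kept for parity with reported per-neuron normalization).
    """
    r = np.asarray(frame_values_right, dtype=np.float64).ravel()
    l = np.asarray(frame_values_left, dtype=np.float64).ravel()
    if max_dff is not None:
        if max_dff <= 0:
            raise ValueError("max_dff must be positive")
        r, l = r / max_dff, l / max_dff
    return _roc_index(r, l, min_per_side=2)


def phase_selectivity_index(in_phase_values, out_phase_values) -> RocIndex:
    """PSI: in-phase trial means vs pooled out-of-phase trial means."""
    return _roc_index(in_phase_values, out_phase_values, min_per_side=1)


def _phase_trial_means(
    trace: np.ndarray, trials: TrialTable, timing: TimingConfig
) -> np.ndarray:
    """(n_trials, 3) per-trial mean ΔF/F in sample/delay/reward windows."""
    tf = timing.trial_frames
    per_trial = np.asarray(trace).reshape(len(trials), tf)
    return np.column_stack(
        [per_trial[:, timing.phase_slice(p)].mean(axis=1) for p in PHASES]
    )


def permutation_validation(
    trace: np.ndarray,
    trials: TrialTable,
    preferred_phase: str,
    timing: TimingConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Trial-level validation of a phase label against shuffled phase labels.

    The observed per-trial selectivity index is the trial's preferred-phase
    mean minus its mean over the other phases; the session statistic is its
    trial average.  The null shuffles which phase counts as "preferred"
    independently per trial, ``n_perm`` times.  Reports the Z-score of the
    observed statistic within the null, the 95th-percentile threshold, and
    the fraction of trials whose individual index exceeds the one-tailed
    p < 0.05 per-trial null threshold.

    The per-trial threshold is built from non-identity relabelings only
    (the "preferred" pointer moved to one of the other two phases):
    including the identity assignment would plant one third of the true
    signal inside its own null and cap the attainable pass fraction far
    below 1 even for a perfectly phase-locked neuron.
    """
    if timing is None:
        timing = TimingConfig()
    if preferred_phase not in PHASES:
        raise ValueError(f"unknown phase {preferred_phase!r}")
    rng = np.random.default_rng(seed)
    M = _phase_trial_means(trace, trials, timing)
    n_trials = M.shape[0]
    j = PHASES.index(preferred_phase)
    others = [i for i in range(3) if i != j]
    per_trial_obs = M[:, j] - M[:, others].mean(axis=1)
    observed = float(per_trial_obs.mean())

    choice = rng.integers(0, 3, size=(n_perm, n_trials))
    rest_mean = (M.sum(axis=1)[None, :] - M[np.arange(n_trials), choice]) / 2.0
    null_trial = M[np.arange(n_trials), choice] - rest_mean  # n_perm x n_trials
    null = null_trial.mean(axis=1)

    sd = float(null.std(ddof=1))
    z = (observed - float(null.mean())) / sd if sd > 0 else np.nan
    # per-trial null from non-identity relabelings only
    off_choice = np.asarray(others)[rng.integers(0, 2, size=(n_perm, n_trials))]
    off_rest = (M.sum(axis=1)[None, :] - M[np.arange(n_trials), off_choice]) / 2.0
    off_trial = M[np.arange(n_trials), off_choice] - off_rest
    trial_thr = float(np.quantile(off_trial.ravel(), 0.95))
    pass_frac = float((per_trial_obs > trial_thr).mean())
    return PermutationResult(
        observed_index=observed,
        null_distribution=null,
        z_score=z,
        percentile_95=float(np.quantile(null, 0.95)),
        trial_pass_fraction=pass_frac,
    )


def selectivity_table(
    session: Session,
    labels: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-neuron PI/RI/PSI (correct trials) plus permutation Z for labeled
    neurons; columns ``neuron, phase, direction, PI, RI, PSI, z,
    trial_pass_frac``."""
    timing = session.timing
    tensor = session.trial_tensor()
    right_idx = np.asarray(session.trials.select(stim=RIGHT, outcome="correct").index)
    left_idx = np.asarray(session.trials.select(stim=LEFT, outcome="correct").index)
    rows = []
    for row in labels.itertuples(index=False):
        i = row.neuron
        phase = row.phase if row.phase in PHASES else DELAY
        sl = timing.phase_slice(phase)
        r_mat = tensor[right_idx, sl, i]
        l_mat = tensor[left_idx, sl, i]
        pi = preference_index(r_mat.mean(axis=1), l_mat.mean(axis=1))
        max_dff = max(float(np.abs(session.traces[:, i]).max()), 1e-12)
        ri = reliability_index(r_mat.ravel(), l_mat.ravel(), max_dff=max_dff)
        corr_idx = np.asarray(session.trials.correct.index)
        pm = np.column_stack(
            [tensor[corr_idx, timing.phase_slice(p), i].mean(axis=1) for p in PHASES]
        )
        j = PHASES.index(phase)
        others = [k for k in range(3) if k != j]
        psi = phase_selectivity_index(pm[:, j], pm[:, others].ravel())
        perm = (
            permutation_validation(
                session.traces[:, i], session.trials, phase, timing,
                n_perm=n_perm, seed=seed + i,
            )
            if row.phase in PHASES
            else None
        )
        rows.append({
            "neuron": i,
            "phase": row.phase,
            "direction": row.direction,
            "PI": pi.index,
            "RI": ri.index,
            "PSI": psi.index,
            "z": perm.z_score if perm else np.nan,
            "trial_pass_frac": perm.trial_pass_fraction if perm else np.nan,
        })
    return pd.DataFrame(rows)
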