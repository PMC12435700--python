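"""Population decoding: LDA-based SNR, SVM direction decoding, and
native-space Pearson correlations.

The LDA follows the classical two-class construction: within-class
scatter S_W and between-class scatter S_B are accumulated from per-trial
population vectors, and the leading eigenvector v_max of S_W⁻¹S_B is the
discriminant.  The windowed signal-to-noise ratio divides the mean
projected separation of two conditions within a sliding window by the
root of the session-total within-class projected variance, and is
normalized to each session's maximum.

Trial conditions use two-letter codes with the first letter the stimulus
and the second the response (RR/LL correct; RL/LR errors).  The
"same-stimulation" comparison pairs LL↔LR and RR↔RL; "same-response"
pairs LL↔RL and RR↔LR.  Discriminants are always trained on the
correct-trial (RR vs LL) contrast, refit per window by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.svm import SVC

from .session import LEFT, RIGHT, Session, TimingConfig

SAME_STIMULATION = "same_stimulation"
SAME_RESPONSE = "same_response"

#: (correct, error) condition pairs per comparison, as (stim, resp) codes.
_PAIRINGS = {
    SAME_STIMULATION: [(("left", "left"), ("left", "right")),
                       (("right", "right"), ("right", "left"))],
    SAME_RESPONSE: [(("left", "left"), ("right", "left")),
                    (("right", "right"), ("left", "right"))],
}


@dataclass
class LdaModel:
    s_w: np.ndarray
    s_b: np.ndarray
    v_max: np.ndarray  # unit norm; class-a mean projects higher
    class_means: tuple[np.ndarray, np.ndarray]
    grand_mean: np.ndarray
    ridge_added: bool = False


@dataclass
class SnrSeries:
    window_starts: np.ndarray
    snr: np.ndarray
    window_w: int
    normalized: bool
    session_max: float


@dataclass
class DecodingSeries:
    window_starts: np.ndarray
    acc_correct: np.ndarray
    acc_same_stim: np.ndarray
    acc_same_resp: np.ndarray
    acc_shuffled: np.ndarray
    train_fraction: float
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.window_starts,
            "acc_correct": self.acc_correct,
            "acc_same_stim": self.acc_same_stim,
            "acc_same_resp": self.acc_same_resp,
            "acc_shuffled": self.acc_shuffled,
        })


def fit_lda(class_a: np.ndarray, class_b: np.ndarray) -> LdaModel:
    """Two-class LDA from per-sample population vectors (samples × dim).

    S_W sums within-class outer products of deviations from the class
    means; S_B is the between-class scatter of the class means around the
    grand mean.  If S_W is singular a small ridge (1e-6·trace/dim) is
    added with a warning.  The discriminant is the leading eigenvector of
    S_W⁻¹S_B, unit norm, signed so class a projects higher.
    """
    a = np.atleast_2d(np.asarray(class_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(class_b, dtype=np.float64))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per class")
    if a.shape[1] != b.shape[1]:
        raise ValueError("classes must share the feature dimension")
    dim = a.shape[1]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    m = np.vstack([a, b]).mean(axis=0)
    da, db = a - m1, b - m2
    s_w = da.T @ da + db.T @ db
    s_b = np.outer(m1 - m, m1 - m) + np.outer(m2 - m, m2 - m)

    ridge_added = False
    s_w_solve = s_w
    if np.linalg.matrix_rank(s_w) < dim:
        lam = 1e-6 * (np.trace(s_w) / dim if np.trace(s_w) > 0 else 1.0)
        s_w_solve = s_w + lam * np.eye(dim)
        ridge_added = True
        warnings.warn("singular within-class scatter; ridge added", stacklevel=2)
    w = np.linalg.solve(s_w_solve, s_b)
    evals, evecs = np.linalg.eig(w)
    v = np.real(evecs[:, np.argmax(np.real(evals))])
    v = v / np.linalg.norm(v)
    if (m1 - m2) @ v < 0:
        v = -v
    return LdaModel(
        s_w=s_w, s_b=s_b, v_max=v, class_means=(m1, m2), grand_mean=m,
        ridge_added=ridge_added,
    )


def _condition_tensors(session: Session) -> dict[tuple[str, str], np.ndarray]:
    out = {}
    for stim in (LEFT, RIGHT):
        for resp in (LEFT, RIGHT):
            out[(stim, resp)] = session.condition_tensor(stim=stim, resp=resp)
    return out


def _pair_snr(
    v: np.ndarray,
    tens_a: np.ndarray,
    tens_b: np.ndarray,
    lo: int,
    hi: int,
) -> float:
    """Windowed projected separation over root total within-class variance."""
    ya = tens_a.mean(axis=0) @ v  # per-frame projected condition mean
    yb = tens_b.mean(axis=0) @ v
    num = np.abs(ya[lo:hi] - yb[lo:hi]).mean()
    dev_a = (tens_a @ v) - ya[None, :]
    dev_b = (tens_b @ v) - yb[None, :]
    total = dev_a.size + dev_b.size
    var = (np.sum(dev_a**2) + np.sum(dev_b**2)) / total
    return float(num / np.sqrt(var)) if var > 0 else 0.0


def snr_timecourse(
    session: Session,
    pairing: str,
    window_w: int = 50,
    refit_per_window: bool = True,
    normalize: bool = True,
    timing: TimingConfig | None = None,
) -> SnrSeries:
    """Sliding-window LDA-SNR between correct and error trial conditions.

    The discriminant is trained on the correct right vs correct left
    contrast (per-frame trial population vectors within the window; refit
    per window by default, or fit once on all frames).  The SNR of each
    correct/error pair is the window-mean absolute projected separation
    over the root session-total within-class projected variance of the
    pair, averaged over the two direction pairings, optionally normalized
    to the session maximum.
    """
    if pairing not in _PAIRINGS:
        raise ValueError(f"unknown pairing {pairing!r}")
    timing = timing or session.timing
    tens = _condition_tensors(session)
    rr, ll = tens[("right", "right")], tens[("left", "left")]
    for name, t in (("RR", rr), ("LL", ll)):
        if t.shape[0] < 2:
            raise ValueError(f"need >=2 {name} trials to train the discriminant")
    for (ca, cb) in _PAIRINGS[pairing]:
        if tens[cb].shape[0] < 2:
            raise ValueError(f"need >=2 trials in error condition {cb}")
    tf = timing.trial_frames
    starts = np.arange(0, tf - window_w + 1)

    def train_v(lo: int, hi: int) -> np.ndarray:
        xa = rr[:, lo:hi, :].reshape(-1, session.n_neurons)
        xb = ll[:, lo:hi, :].reshape(-1, session.n_neurons)
        return fit_lda(xa, xb).v_max

    v_global = None if refit_per_window else train_v(0, tf)
    snr = np.empty(len(starts))
    for i, lo in enumerate(starts):
        hi = lo + window_w
        v = train_v(lo, hi) if refit_per_window else v_global
        vals = [
            _pair_snr(v, tens[ca], tens[cb], lo, hi)
            for ca, cb in _PAIRINGS[pairing]
        ]
        snr[i] = np.mean(vals)
    session_max = float(snr.max())
    if normalize and session_max > 0:
        snr = snr / session_max
    return SnrSeries(
        window_starts=starts, snr=snr, window_w=window_w,
        normalized=normalize and session_max > 0, session_max=session_max,
    )


def svm_decode(
    session: Session,
    train_fraction: float = 0.7,
    n_repeats: int = 10,
    window: int = 8,
    step: int = 1,
    seed: int = 0,
    C: float = 1.0,
    timing: TimingConfig | None = None,
) -> DecodingSeries:
    """Sliding-window linear SVM direction decoding.

    Per window and repeat, a linear-kernel maximum-margin classifier is
    trained on window-mean population vectors of a random (stratified)
    ``train_fraction`` of correct trials, labeled by stimulus direction,
    then scored on held-out correct trials, on error trials labeled by
    stimulus (same-stimulus curve), on error trials labeled by response
    (same-response curve), and on a label-shuffled control.  Deterministic
    given ``seed``.
    """
    timing = timing or session.timing
    tf = timing.trial_frames
    rng = np.random.default_rng(seed)
    tensor = session.trial_tensor()
    df = session.trials.df
    correct_idx = {
        d: np.asarray(df[(df.outcome == "correct") & (df.stim_dir == d)].index)
        for d in (LEFT, RIGHT)
    }
    for d, idx in correct_idx.items():
        if int(round(train_fraction * len(idx))) < 2 or \
                len(idx) - int(round(train_fraction * len(idx))) < 1:
            raise ValueError(f"too few correct {d} trials for a {train_fraction} split")
    err_idx = np.asarray(df[df.outcome == "error"].index)
    err_stim = df.loc[err_idx, "stim_dir"].to_numpy()
    err_resp = df.loc[err_idx, "resp_dir"].to_numpy()

    starts = np.arange(0, tf - window + 1, step)
    accs = {k: np.zeros(len(starts)) for k in
            ("correct", "same_stim", "same_resp", "shuffled")}
    splits = []
    for _ in range(n_repeats):
        train, test = [], []
        for d in (LEFT, RIGHT):
            idx = rng.permutation(correct_idx[d])
            n_tr = int(round(train_fraction * len(idx)))
            train.extend(idx[:n_tr])
            test.extend(idx[n_tr:])
        splits.append((np.array(train), np.array(test)))

    y_all = df.stim_dir.to_numpy()
    for i, lo in enumerate(starts):
        X = tensor[:, lo:lo + window, :].mean(axis=1)  # trials x neurons
        for train, test in splits:
            clf = SVC(kernel="linear", C=C)
            clf.fit(X[train], y_all[train])
            accs["correct"][i] += (clf.predict(X[test]) == y_all[test]).mean()
            if err_idx.size:
                pred_err = clf.predict(X[err_idx])
                accs["same_stim"][i] += (pred_err == err_stim).mean()
                accs["same_resp"][i] += (pred_err == err_resp).mean()
            sh = SVC(kernel="linear", C=C)
            sh.fit(X[train], rng.permutation(y_all[train]))
            accs["shuffled"][i] += (sh.predict(X[test]) == y_all[test]).mean()
    for k in accs:
        accs[k] /= n_repeats
    if not err_idx.size:
        accs["same_stim"][:] = np.nan
        accs["same_resp"][:] = np.nan
    return DecodingSeries(
        window_starts=starts,
        acc_correct=accs["correct"],
        acc_same_stim=accs["same_stim"],
        acc_same_resp=accs["same_resp"],
        acc_shuffled=accs["shuffled"],
        train_fraction=train_fraction,
        n_repeats=n_repeats,
    )


SIX_BINS = "six_25frame_bins"
SLIDING_15 = "sliding_15frame"
#: Bin start frames of the six 25-frame scheme (0-based), spanning the
#: late sample and the delay.
_SIX_BIN_STARTS = (20, 45, 70, 95, 120, 145)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(pearsonr(a, b)[0])


def population_correlation(
    session: Session,
    scheme: str = SIX_BINS,
    n_splits: int = 100,
    seed: int = 0,
    timing: TimingConfig | None = None,
) -> pd.DataFrame:
    """Native-space Pearson correlations of population activity vectors.

    Per bin, the within-correct baseline correlates the trial-averaged
    neuron × time vector of a random half of correct trials with the
    remaining half (averaged over ``n_splits`` random splits), and the
    correct-vs-error series correlates the correct-trial mean with the
    same-stimulus error-trial mean; both are computed per stimulus
    direction and averaged.  Returns columns
    ``bin_start, bin_end, r_within_correct, r_correct_error``.
    """
    timing = timing or session.timing
    tf = timing.trial_frames
    if scheme == SIX_BINS:
        bins = [(s, s + 25) for s in _SIX_BIN_STARTS]
    elif scheme == SLIDING_15:
        bins = [(s, s + 15) for s in range(0, tf - 15 + 1)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    tensor = session.trial_tensor()
    df = session.trials.df

    rows = []
    halves: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for d in (LEFT, RIGHT):
        idx = np.asarray(df[(df.outcome == "correct") & (df.stim_dir == d)].index)
        if len(idx) < 2:
            raise ValueError(f"need >=2 correct {d} trials")
        halves[d] = []
        for _ in range(n_splits):
            perm = rng.permutation(idx)
            halves[d].append((perm[: len(idx) // 2], perm[len(idx) // 2:]))
    err = {
        d: np.asarray(df[(df.outcome == "error") & (df.stim_dir == d)].index)
        for d in (LEFT, RIGHT)
    }
    for lo, hi in bins:
        within, between = [], []
        for d in (LEFT, RIGHT):
            r_splits = [
                _safe_pearson(
                    tensor[a, lo:hi, :].mean(axis=0).ravel(),
                    tensor[b, lo:hi, :].mean(axis=0).ravel(),
                )
                for a, b in halves[d]
            ]
            r_splits = [r for r in r_splits if np.isfinite(r)]
            within.append(np.mean(r_splits) if r_splits else np.nan)
            if err[d].size:
                idx = np.asarray(df[(df.outcome == "correct") & (df.stim_dir == d)].index)
                between.append(_safe_pearson(
                    tensor[idx, lo:hi, :].mean(axis=0).ravel(),
                    tensor[err[d], lo:hi, :].mean(axis=0).ravel(),
                ))
        def _mean(vals):
            vals = [v for v in vals if np.isfinite(v)]
            return float(np.mean(vals)) if vals else np.nan

        rows.append({
            "bin_start": lo,
            "bin_end": hi,
            "r_within_correct": _mean(within),
            "r_correct_error": _mean(between),
        })
    return pd.DataFrame(rows)
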