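"""Population trajectory analysis in a correct-trial PCA space.

Direction-selective neurons are first aligned to a common
"preferred-direction" frame (left-preferring neurons have their
left/right trial labels flipped), so conditions are written as two-letter
codes: first letter the stimulus, second the response, each P(referred)
or O(pposite).  PP and OO are the two correct conditions, PO/OP the two
error conditions.

The trajectory space is fitted by PCA on Z-scored trial-averaged
correct-trial activity (a random 50% of PP trials per iteration), and
held-out correct trials plus error trials are projected into the top
five components.  Per-frame Euclidean distances between condition
trajectories give d0 (within-PP split baseline), d1 (PP↔OO),
the same-stimulation distance (PP↔PO) and the same-response distance
(OO↔PO); the trajectory similarity index
TSI = (dOO − dPP)/(dOO + dPP) locates an error trajectory between the
two correct prototypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selectivity import auroc
from .session import LEFT, RIGHT, Session, opposite

logger = logging.getLogger(__name__)

CONDITIONS = ("PP", "OO", "PO", "OP")


@dataclass
class TrajectoryModel:
    """Loadings and Z-scoring constants of the correct-trial PCA space."""

    loadings: np.ndarray  # neurons x n_components, orthonormal columns
    explained_variance_fraction: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_components: int
    zero_variance_neurons: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )


@dataclass
class DistanceSeries:
    """Per-iteration, per-frame condition distances (n_iter × frames)."""

    d0: np.ndarray
    d1: np.ndarray
    d_same_stim: np.ndarray  # PP <-> PO
    d_same_resp: np.ndarray  # OO <-> PO
    n_iterations: int

    def mean(self, which: str) -> np.ndarray:
        return getattr(self, which).mean(axis=0)


@dataclass
class TsiSeries:
    tsi: np.ndarray  # n_iter x frames
    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.tsi, axis=0)


class AlignedPopulation:
    """Direction-selective neurons of one session in preferred-direction frame.

    Neurons without a left/right label are excluded (logged).  Because a
    condition's trial set differs between right- and left-preferring
    groups, condition averages are assembled per group and concatenated
    over neuron columns.
    """

    def __init__(self, session: Session, directions: pd.Series):
        self.session = session
        keep = directions[directions.isin([LEFT, RIGHT])]
        dropped = directions.index.difference(keep.index)
        if len(dropped):
            logger.info("excluding %d neurons without direction label", len(dropped))
        if keep.empty:
            raise ValueError("no direction-labeled neurons to align")
        self.neurons = np.asarray(keep.index, dtype=int)
        self.preferred = keep.to_numpy()
        self._tensor = session.trial_tensor()

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def condition_trials(self, condition: str) -> dict[str, np.ndarray]:
        """Trial indices of a PP/OO/PO/OP condition, per preferred side."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        out = {}
        for pref in (RIGHT, LEFT):
            stim = pref if condition[0] == "P" else opposite(pref)
            resp = pref if condition[1] == "P" else opposite(pref)
            idx = self.session.trials.select(stim=stim, resp=resp).index
            out[pref] = np.asarray(idx, dtype=int)
        return out

    def condition_average(
        self,
        condition: str,
        trial_subsets: dict[str, np.ndarray] | None = None,
    ) -> np.ndarray:
        """frames × aligned-neurons trial-averaged activity for a condition."""
        trials = trial_subsets if trial_subsets is not None \
            else self.condition_trials(condition)
        cols = np.empty((self.session.timing.trial_frames, self.n_neurons))
        for j, (neuron, pref) in enumerate(zip(self.neurons, self.preferred)):
            idx = trials[pref]
            if idx.size == 0:
                raise ValueError(
                    f"condition {condition} has no trials for {pref}-preferring neurons"
                )
            cols[:, j] = self._tensor[idx, :, neuron].mean(axis=0)
        return cols


def align_to_preferred(session: Session, directions: pd.Series) -> AlignedPopulation:
    """Flip left-preferring neurons' trial labels into the common frame."""
    return AlignedPopulation(session, directions)


def fit_trajectory_space(
    correct_trial_averages: np.ndarray, n_components: int = 5
) -> TrajectoryModel:
    """PCA of Z-scored trial-averaged activity (frames × neurons).

    Columns are Z-scored with a σ floor of 1e-12 (zero-variance neurons
    flagged); the covariance across frames is eigendecomposed and the top
    ``n_components`` eigenvectors returned with explained-variance
    fractions.  Loading signs are fixed so each component's largest
    absolute weight is positive.
    """
    X = np.asarray(correct_trial_averages, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected frames x neurons")
    n_frames, n_neurons = X.shape
    if n_neurons < n_components:
        raise ValueError("need at least n_components neurons")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd < 1e-12)
    sd = np.where(sd < 1e-12, 1e-12, sd)
    Z = (X - mu) / sd
    C = Z.T @ Z / (n_frames - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    V = evecs[:, :n_components]
    # deterministic sign convention
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    total = evals.sum()
    frac = evals[:n_components] / total if total > 0 else np.zeros(n_components)
    return TrajectoryModel(
        loadings=V,
        explained_variance_fraction=frac,
        mean=mu,
        sd=sd,
        n_components=n_components,
        zero_variance_neurons=zero_var,
    )


def project(model: TrajectoryModel, trial_averages: np.ndarray) -> np.ndarray:
    """Project frames × neurons activity into the fitted component space."""
    X = np.asarray(trial_averages, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"expected frames x {model.loadings.shape[0]} neurons, got {X.shape}"
        )
    Z = (X - model.mean) / model.sd
    return Z @ model.loadings


def tsi(d_pp, d_oo):
    """Trajectory similarity index (dOO − dPP)/(dOO + dPP), in [−1, +1].

    Positive values mean the trajectory is nearer the preferred-correct
    prototype.  Undefined (NaN) where both distances are zero.
    """
    d_pp = np.asarray(d_pp, dtype=np.float64)
    d_oo = np.asarray(d_oo, dtype=np.float64)
    if (d_pp < 0).any() or (d_oo < 0).any():
        raise ValueError("distances must be non-negative")
    denom = d_pp + d_oo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (d_oo - d_pp) / np.where(denom > 0, denom, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _frame_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean distance between two frames × k trajectories."""
    return np.linalg.norm(a - b, axis=1)


def _split(rng: np.random.Generator, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(idx)
    half = len(idx) // 2
    return perm[:half], perm[half:]


def analyze_trajectories(
    session: Session,
    directions: pd.Series,
    n_components: int = 5,
    n_iter: int = 100,
    seed: int = 0,
) -> tuple[DistanceSeries, TsiSeries, TrajectoryModel]:
    """Split-trial PCA distance/TSI analysis of one session.

    Each of ``n_iter`` iterations splits the PP trials 50/50, fits the
    component space on one half's trial average, and projects the held-out
    PP half, the OO average and the PO error average.  Error trials never
    enter the fit.  Returns the per-iteration distance series, the TSI
    series of the PO condition, and the model from the final iteration.
    """
    pop = align_to_preferred(session, directions)
    pp_trials = pop.condition_trials("PP")
    for pref, idx in pp_trials.items():
        if idx.size < 4:
            raise ValueError(
                f"need >=4 PP trials for the d0 split ({pref}: {idx.size})"
            )
    oo_trials = pop.condition_trials("OO")
    po_trials = pop.condition_trials("PO")

    rng = np.random.default_rng(seed)
    tf = session.timing.trial_frames
    d0 = np.empty((n_iter, tf))
    d1 = np.empty((n_iter, tf))
    ds = np.empty((n_iter, tf))
    dr = np.empty((n_iter, tf))
    model: TrajectoryModel | None = None
    for it in range(n_iter):
        fit_half, held_half = {}, {}
        for pref, idx in pp_trials.items():
            fit_half[pref], held_half[pref] = _split(rng, idx)
        model = fit_trajectory_space(
            pop.condition_average("PP", fit_half), n_components
        )
        traj_fit = project(model, pop.condition_average("PP", fit_half))
        traj_pp = project(model, pop.condition_average("PP", held_half))
        traj_oo = project(model, pop.condition_average("OO", oo_trials))
        traj_po = project(model, pop.condition_average("PO", po_trials))
        d0[it] = _frame_distance(traj_fit, traj_pp)
        d1[it] = _frame_distance(traj_pp, traj_oo)
        ds[it] = _frame_distance(traj_pp, traj_po)
        dr[it] = _frame_distance(traj_oo, traj_po)
    dist = DistanceSeries(
        d0=d0, d1=d1, d_same_stim=ds, d_same_resp=dr, n_iterations=n_iter
    )
    return dist, TsiSeries(tsi=tsi(ds, dr)), model


def trajectory_distances(
    condition_trajectories: dict[str, np.ndarray],
    n_iter: int = 100,
    seed: int = 0,
) -> DistanceSeries:
    """Distance series from pre-projected per-trial condition trajectories.

    ``condition_trajectories`` maps PP/OO/PO (OP optional) to arrays of
    shape (n_trials, frames, n_components).  Each iteration splits the PP
    trials 50/50 for the d0 baseline and takes random half-subsets of the
    other conditions before averaging; distances are between iteration
    means per frame.  Conditions with zero trials are skipped (logged).
    """
    if "PP" not in condition_trajectories:
        raise ValueError("PP trajectories are required")
    pp = np.asarray(condition_trajectories["PP"], dtype=np.float64)
    if pp.shape[0] < 4:
        raise ValueError("need >=4 PP trials for the d0 split")
    rng = np.random.default_rng(seed)
    tf = pp.shape[1]

    def half_mean(arr, rng):
        n = arr.shape[0]
        take = rng.permutation(n)[: max(n // 2, 1)]
        return arr[take].mean(axis=0)

    oo = condition_trajectories.get("OO")
    po = condition_trajectories.get("PO")
    for name, arr in (("OO", oo), ("PO", po)):
        if arr is not None and len(arr) == 0:
            logger.info("condition %s has no trials; series absent", name)
    nan = np.full((n_iter, tf), np.nan)
    d0, d1 = np.empty((n_iter, tf)), nan.copy()
    ds, dr = nan.copy(), nan.copy()
    for it in range(n_iter):
        a_idx, b_idx = _split(rng, np.arange(pp.shape[0]))
        pp_a, pp_b = pp[a_idx].mean(axis=0), pp[b_idx].mean(axis=0)
        d0[it] = _frame_distance(pp_a, pp_b)
        if oo is not None and len(oo):
            oo_m = half_mean(np.asarray(oo), rng)
            d1[it] = _frame_distance(pp_b, oo_m)
            if po is not None and len(po):
                po_m = half_mean(np.asarray(po), rng)
                ds[it] = _frame_distance(pp_b, po_m)
                dr[it] = _frame_distance(oo_m, po_m)
        elif po is not None and len(po):
            ds[it] = _frame_distance(pp_b, half_mean(np.asarray(po), rng))
    return DistanceSeries(
        d0=d0, d1=d1, d_same_stim=ds, d_same_resp=dr, n_iterations=n_iter
    )


def distance_roc(series_a: np.ndarray, series_b: np.ndarray) -> np.ndarray:
    """Per-frame auROC between two (n_iter × frames) distance distributions."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape[1] != b.shape[1]:
        raise ValueError("series must share the frame axis")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >=2 iterations per series")
    return np.array([auroc(a[:, t], b[:, t]) for t in range(a.shape[1])])
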