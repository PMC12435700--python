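"""End-to-end pipeline: simulate/load a session, detect and classify
neurons, compute selectivity metrics, trajectory distances, coding
directions and decoding, writing per-stage CSV/JSON outputs plus a run
manifest with checksums for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coding, decoding, detection, selectivity, trajectory
from .session import KernelParams, Session, TimingConfig
from .synthetic import generate_session

logger = logging.getLogger(__name__)

STAGES = (
    "synthetic", "detection", "selectivity", "trajectory", "coding", "decoding",
)


@dataclass
class PipelineConfig:
    """Single-document configuration for a pipeline run.

    Defaults mirror the standard analysis constants: 30 Hz, 200-frame
    trials (120/50/30), alphas 0.05/0.01, 1,000 permutations, 5
    components, 100 iterations, 50/25/8-frame windows, 70/30 SVM split
    with 10 repeats.
    """

    session_dir: str | None = None  # load a saved session instead of simulating
    n_neurons: int = 60
    n_trials: int = 60
    error_rate: float = 0.3
    drift_rate: float = 0.5
    noise_sd: float = 0.15
    kernel: str = "cytosolic"  # or "nuclear"
    seed: int = 0

    alpha_pixel: float = 0.05
    alpha_neuron: float = 0.01
    n_perm: int = 1000
    n_components: int = 5
    n_iter: int = 100
    snr_window: int = 50
    svm_window: int = 8
    svm_train_fraction: float = 0.7
    svm_repeats: int = 10

    seeds: dict = field(default_factory=lambda: {
        "selectivity": 1, "trajectory": 2, "decoding": 3,
    })
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    v: list[str] = []
    if config.kernel not in ("cytosolic", "nuclear"):
        v.append(f"unknown kernel {config.kernel!r}")
    for name in ("alpha_pixel", "alpha_neuron"):
        a = getattr(config, name)
        if not 0 < a < 1:
            v.append(f"{name} must be in (0, 1), got {a}")
    if not 0 <= config.error_rate <= 1:
        v.append("error_rate must be in [0, 1]")
    if config.drift_rate < 0:
        v.append("drift_rate must be non-negative")
    if not 0 < config.svm_train_fraction < 1:
        v.append("svm_train_fraction must be in (0, 1)")
    for k in ("n_perm", "n_components", "n_iter", "snr_window", "svm_window",
              "svm_repeats", "n_neurons", "n_trials"):
        if getattr(config, k) < 1:
            v.append(f"{k} must be >= 1")
    if config.seed is None:
        v.append("missing seed for the generator stage")
    for stage in ("selectivity", "trajectory", "decoding"):
        if config.stages.get(stage, False) and stage not in config.seeds:
            v.append(f"missing seed for stochastic stage {stage!r}")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        v.append(f"unknown stages: {sorted(unknown)}")
    try:
        TimingConfig()
    except ValueError as e:  # pragma: no cover - defaults are valid
        v.append(str(e))
    return v


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    stages: list[str]
    outputs: dict[str, str]  # relative path -> sha256
    log_path: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the enabled stages in order and write all stage outputs.

    Any stage error aborts the run with the stage named; outputs written
    by earlier stages are preserved.  Two runs from one config produce
    byte-identical CSV/JSON outputs.
    """
    from . import __version__

    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kernel = (
        KernelParams.cytosolic() if config.kernel == "cytosolic"
        else KernelParams.nuclear()
    )
    ran: list[str] = []
    outputs: dict[str, Path] = {}

    def stage_enabled(name: str) -> bool:
        return bool(config.stages.get(name, False))

    def run_stage(name, fn):
        if not stage_enabled(name):
            return None
        try:
            result = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        ran.append(name)
        return result

    # --- synthetic / load -------------------------------------------------
    if config.session_dir is not None:
        session = Session.load(config.session_dir)
        if stage_enabled("synthetic"):
            ran.append("synthetic")
    else:
        def _sim():
            s = generate_session(
                n_neurons=config.n_neurons, n_trials=config.n_trials,
                error_rate=config.error_rate, drift_rate=config.drift_rate,
                noise_sd=config.noise_sd, kernel=kernel, seed=config.seed,
            )
            s.save(out / "session")
            for f in ("traces.h5", "trials.csv", "session.json", "ground_truth.csv"):
                outputs[f"session/{f}"] = out / "session" / f
            return s
        session = run_stage("synthetic", _sim)
        if session is None:
            raise ValueError("no session: enable the synthetic stage or set session_dir")

    # --- detection --------------------------------------------------------
    labels = None

    def _detect():
        lab = detection.classify_session(
            session, alpha_neuron=config.alpha_neuron, kernel=kernel
        )
        lab = detection.exclude_drifting_neurons(
            lab, session.traces, session.trials, session.timing
        )
        p = out / "neuron_labels.csv"
        lab.to_csv(p, index=False)
        outputs["neuron_labels.csv"] = p
        return lab

    labels = run_stage("detection", _detect)

    def need_labels():
        if labels is None:
            raise RuntimeError("stage requires the detection stage outputs")
        return labels

    # --- selectivity ------------------------------------------------------
    def _select():
        tab = selectivity.selectivity_table(
            session, need_labels(), n_perm=config.n_perm,
            seed=config.seeds["selectivity"],
        )
        p = out / "selectivity.csv"
        tab.to_csv(p, index=False)
        outputs["selectivity.csv"] = p
        return tab

    run_stage("selectivity", _select)

    # --- trajectory -------------------------------------------------------
    def _traj():
        lab = need_labels()
        directions = lab[lab.direction.isin(["left", "right"])] \
            .set_index("neuron").direction
        dist, tsi_series, model = trajectory.analyze_trajectories(
            session, directions, n_components=config.n_components,
            n_iter=config.n_iter, seed=config.seeds["trajectory"],
        )
        df = pd.DataFrame({
            "frame": np.arange(dist.d0.shape[1]),
            "d0": dist.mean("d0"),
            "d1": dist.mean("d1"),
            "d_same_stim": dist.mean("d_same_stim"),
            "d_same_resp": dist.mean("d_same_resp"),
            "tsi": tsi_series.mean,
        })
        p = out / "trajectory_distances.csv"
        df.to_csv(p, index=False)
        outputs["trajectory_distances.csv"] = p
        _write_json(out / "trajectory_model.json", {
            "n_components": model.n_components,
            "explained_variance_fraction":
                model.explained_variance_fraction.tolist(),
        })
        outputs["trajectory_model.json"] = out / "trajectory_model.json"
        return df

    run_stage("trajectory", _traj)

    # --- coding direction -------------------------------------------------
    def _coding():
        modes = {k: coding.compute_mode(session, k) for k in coding.MODE_KINDS}
        ortho = coding.orthogonalize(
            [modes["CD_reward"], modes["D_reward"], modes["CD_delay"]]
        )
        cd_delay = ortho[-1]
        proj = coding.project_trials(cd_delay, session)
        res = {
            "delay": coding.residual_separation(proj).value,
            "sample": coding.residual_separation(
                proj, coding.MODE_WINDOWS["CD_sample"]
            ).value,
        }
        weights = pd.DataFrame(
            {k: m.weights for k, m in modes.items()}
        )
        weights.insert(0, "neuron", np.arange(session.n_neurons))
        p = out / "mode_weights.csv"
        weights.to_csv(p, index=False)
        outputs["mode_weights.csv"] = p
        proj_df = pd.DataFrame(
            {c: s for c, s in proj.series.items()}
        )
        proj_df.insert(0, "frame", np.arange(len(proj_df)))
        p2 = out / "cd_projections.csv"
        proj_df.to_csv(p2, index=False)
        outputs["cd_projections.csv"] = p2
        rt = coding.rt_cd_correlation(session, modes["CD_delay"])
        _write_json(out / "residual_separation.json",
                    {"residual_separation": res, "rt_correlation": rt})
        outputs["residual_separation.json"] = out / "residual_separation.json"

    run_stage("coding", _coding)

    # --- decoding ---------------------------------------------------------
    def _decode():
        snr_stim = decoding.snr_timecourse(
            session, decoding.SAME_STIMULATION, window_w=config.snr_window
        )
        snr_resp = decoding.snr_timecourse(
            session, decoding.SAME_RESPONSE, window_w=config.snr_window
        )
        snr_df = pd.DataFrame({
            "window_start": snr_stim.window_starts,
            "snr_same_stim": snr_stim.snr,
            "snr_same_resp": snr_resp.snr,
            "normalized": snr_stim.normalized,
        })
        p = out / "snr_timecourse.csv"
        snr_df.to_csv(p, index=False)
        outputs["snr_timecourse.csv"] = p
        dec = decoding.svm_decode(
            session, train_fraction=config.svm_train_fraction,
            n_repeats=config.svm_repeats, window=config.svm_window,
            seed=config.seeds["decoding"],
        )
        p2 = out / "decoding.csv"
        dec.to_frame().to_csv(p2, index=False)
        outputs["decoding.csv"] = p2
        corr = decoding.population_correlation(
            session, seed=config.seeds["decoding"]
        )
        p3 = out / "correlations.csv"
        corr.to_csv(p3, index=False)
        outputs["correlations.csv"] = p3

    run_stage("decoding", _decode)

    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        software_version=__version__,
        stages=ran,
        outputs={rel: _sha256(p) for rel, p in sorted(outputs.items())},
    )
    manifest.to_json(out / "manifest.json")
    return manifest
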