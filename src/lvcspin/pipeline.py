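"""End-to-end orchestration: schedule -> Hamiltonians -> dynamics -> metrics.

The pipeline runs against a synthetic quadratic ground truth (the stand-in
for explicit reference calculations at every step): it generates or loads an
anchor parametrization and trajectory, places anchors according to a
schedule, re-expands the truth at each anchor, builds the per-frame LVC and
truth Hamiltonian series in a common basis, propagates both, and reports
truncation-error and density-similarity traces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, InputError
from .geometry import Frame, PeriodicBox, write_trajectory
from .hamiltonian import HamiltonianMatrix
from .metrics import ErrorTrace, hamiltonian_error, similarity
from .propagation import PropagatorConfig, propagate
from .scheduler import (
    ParametrizationSchedule,
    adaptive_schedule,
    bisection_schedule,
    fixed_schedule,
)
from .stevens import AngularMomentumBasis, project_spin_parameters, select_term_block
from .synthetic import (
    GroundTruthModel,
    SyntheticTrajectorySpec,
    frame_from_parametrization,
    generate_parametrization,
    generate_trajectory,
    make_ground_truth,
    reparametrize,
)
from .paramio import save_parametrization

__all__ = [
    "RunConfig",
    "ScheduleStudy",
    "build_schedule",
    "anchor_models_for_schedule",
    "hamiltonian_series",
    "run_schedule_study",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Schedule-driven Hamiltonian series against a synthetic truth
# ---------------------------------------------------------------------------

def build_schedule(
    frames: Sequence[Frame],
    mode: str,
    interval: Optional[float] = None,
    depth: Optional[int] = None,
    threshold: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
) -> ParametrizationSchedule:
    """Dispatch to the fixed / bisection / rmsd-adaptive scheduling rules."""
    times = [f.time for f in frames]
    if mode == "fixed":
        if interval is None:
            raise ConfigurationError("fixed schedule requires an interval")
        return fixed_schedule(times[0], times[-1], interval, frame_times=times)
    if mode == "bisection":
        if depth is None:
            raise ConfigurationError("bisection schedule requires a depth")
        return bisection_schedule(times[0], times[-1], depth, frame_times=times)
    if mode == "adaptive":
        if threshold is None:
            raise ConfigurationError("adaptive schedule requires an RMSD threshold")
        return adaptive_schedule(frames, threshold, mask=mask)
    raise ConfigurationError(f"unknown schedule mode {mode!r}")


def anchor_models_for_schedule(
    root: GroundTruthModel,
    frames: Sequence[Frame],
    schedule: ParametrizationSchedule,
) -> dict:
    """Re-expand the truth at every anchor time; the root anchor is reused.

    Each reparametrization plays the role of a fresh reference calculation
    at the anchor frame's geometry.
    """
    by_time = {f.time: f for f in frames}
    models = {}
    for t in schedule.anchor_times:
        if t not in by_time:
            raise InputError(f"anchor time {t} fs has no trajectory frame")
        if t == root.base.anchor_time:
            models[t] = root
            continue
        disp = (by_time[t].coordinates - root.base.reference_geometry).reshape(-1)
        models[t] = reparametrize(root, disp, anchor_time=t)
    return models


def hamiltonian_series(
    root: GroundTruthModel,
    frames: Sequence[Frame],
    schedule: ParametrizationSchedule,
) -> tuple[list[HamiltonianMatrix], list[HamiltonianMatrix]]:
    """(LVC series, truth series) per frame, both in the root basis."""
    models = anchor_models_for_schedule(root, frames, schedule)
    lvc_series = []
    truth_series = []
    for i, frame in enumerate(frames):
        model = models[schedule.anchor_for_frame(i)]
        disp = (frame.coordinates - model.base.reference_geometry).reshape(-1)
        lvc_series.append(model.lvc_hamiltonian_global(disp))
        disp_root = (frame.coordinates - root.base.reference_geometry).reshape(-1)
        truth_series.append(root.hamiltonian(disp_root))
    return lvc_series, truth_series


@dataclass
class ScheduleStudy:
    """Per-schedule comparison of the LVC series against the truth."""

    schedule: ParametrizationSchedule
    error_trace: ErrorTrace
    similarity_times: np.ndarray
    similarities: np.ndarray
    max_error: float
    final_similarity: float
    trace_drift: float


def run_schedule_study(
    root: GroundTruthModel,
    frames: Sequence[Frame],
    schedule: ParametrizationSchedule,
    cfg: Optional[PropagatorConfig] = None,
) -> ScheduleStudy:
    """Errors per frame plus propagated-density similarity for one schedule."""
    cfg = cfg or PropagatorConfig()
    lvc_series, truth_series = hamiltonian_series(root, frames, schedule)
    errors = np.array(
        [hamiltonian_error(a, b) for a, b in zip(lvc_series, truth_series)]
    )
    times = np.array([f.time for f in frames])
    anchor_times = np.array([schedule.anchor_for_frame(i) for i in range(len(frames))])
    trace = ErrorTrace(times, errors, anchor_times)
    prop_truth = propagate(truth_series, cfg)
    prop_lvc = propagate(lvc_series, cfg, initial_state=prop_truth.states[0])
    sims = np.array(
        [similarity(a, b) for a, b in zip(prop_lvc.states, prop_truth.states)]
    )
    return ScheduleStudy(
        schedule=schedule,
        error_trace=trace,
        similarity_times=prop_truth.times,
        similarities=sims,
        max_error=float(errors.max()),
        final_similarity=float(sims[-1]),
        trace_drift=max(prop_lvc.max_trace_drift, prop_truth.max_trace_drift),
    )


# ---------------------------------------------------------------------------
# Config-driven run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One-file configuration of a synthetic end-to-end run."""

    seed: int = 0
    n_states: int = 8
    spin_S: float = 0.5
    n_sites: int = 6
    n_frames: int = 50
    dt_fs: float = 1.0
    temperature: float = 300.0
    schedule_mode: str = "fixed"
    interval: Optional[float] = 10.0
    depth: Optional[int] = None
    threshold: Optional[float] = None
    quad_scale: float = 0.04
    n_modes: int = 4
    taylor_cutoff: float = 1e-14
    output_dir: str = "lvcspin-out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    #: fields that do not affect the computed numbers (excluded from the hash)
    _NON_SCIENTIFIC = ("output_dir", "log_level")

    def canonical(self) -> str:
        keys = sorted(set(self.__dataclass_fields__) - set(self._NON_SCIENTIFIC))
        return json.dumps({k: getattr(self, k) for k in keys}, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


def _write_csv(path, header_cols, rows, config_hash):
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash}\n")
        fh.write(",".join(header_cols) + "\n")
        for row in rows:
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline and write its artifact bundle.

    Artifacts (all stamped with the config hash): the anchor parametrization
    container, the trajectory, the schedule, per-frame spin-parameter /
    population / trace CSV, the error trace and the similarity trace.
    Deterministic for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    param = generate_parametrization(
        n_states=config.n_states,
        spin_S=config.spin_S,
        n_sites=config.n_sites,
        seed=rng_seed,
    )
    root = make_ground_truth(
        param, n_modes=config.n_modes, quad_scale=config.quad_scale, seed=rng_seed + 1
    )
    spec = SyntheticTrajectorySpec(
        n_frames=config.n_frames, dt=config.dt_fs, seed=rng_seed + 2
    )
    frames = generate_trajectory(frame_from_parametrization(param), spec)
    schedule = build_schedule(
        frames,
        config.schedule_mode,
        interval=config.interval,
        depth=config.depth,
        threshold=config.threshold,
    )
    cfg = PropagatorConfig(
        dt_fs=config.dt_fs,
        taylor_cutoff=config.taylor_cutoff,
        temperature=config.temperature,
    )
    study = run_schedule_study(root, frames, schedule, cfg)

    chash = config.config_hash
    save_parametrization(param, out / "parametrization.json")
    write_trajectory(out / "trajectory.xyz", frames)
    schedule.to_json(out / "schedule.json")
    _write_csv(
        out / "error.csv",
        ["time_fs", "error", "anchor_time_fs"],
        zip(study.error_trace.times, study.error_trace.errors,
            study.error_trace.parametrization_times),
        chash,
    )
    _write_csv(
        out / "similarity.csv",
        ["time_fs", "similarity"],
        zip(study.similarity_times, study.similarities),
        chash,
    )
    # propagate once more to emit populations of the truth trajectory
    _, truth_series = hamiltonian_series(root, frames, schedule)
    prop = propagate(truth_series, cfg)
    pops = prop.populations()
    rows = [
        [t, *pop, abs(s.trace), s.purity]
        for t, pop, s in zip(prop.times, pops, prop.states)
    ]
    _write_csv(
        out / "populations.csv",
        ["time_fs"]
        + [f"p{i}" for i in range(pops.shape[1])]
        + ["trace", "purity"],
        rows,
        chash,
    )
    # spin-parameter table at the anchor, when term labels exist
    tables = None
    if param.ml_labels is not None:
        L = int(np.max(param.ml_labels[param.ml_labels <= 50]))
        basis = AngularMomentumBasis(L, param.spin_S)
        block = select_term_block(
            root.hamiltonian(np.zeros(param.n_dof)),
            param.ml_labels,
            L,
            param.spin_multiplicity,
        )
        params_proj, residual = project_spin_parameters(
            HamiltonianMatrix(block, "term-basis"), basis
        )
        tables = {
            "lambda": params_proj.lambda_soc,
            "residual_norm": residual,
            "cfps": {f"{k},{q}": v for (k, q), v in params_proj.cfps.items()},
        }
        with open(out / "spin_parameters.json", "w") as fh:
            json.dump({"config": chash, **tables}, fh, indent=1)
    meta = {
        "config": chash,
        "settings": json.loads(config.canonical()),
        "n_anchors": int(schedule.n_anchors),
        "anchor_times": schedule.anchor_times.tolist(),
        "max_error": study.max_error,
        "final_similarity": study.final_similarity,
        "max_trace_drift": study.trace_drift,
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return {
        "schedule": schedule,
        "study": study,
        "spin_parameters": tables,
        "meta": meta,
        "output_dir": out,
    }
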