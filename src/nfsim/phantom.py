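"""Synthetic study generator: phantom BOLD series and behavioural agents.

This module fabricates everything the analysis consumes, with the
statistical structure the method assumes:

* a digital phantom with a compact "SMA" blob whose mental-imagery
  activation is HRF-shaped and scales with the instructed target level
  and session, a disjoint "motor" blob active during finger tapping,
  Gaussian noise and a linear scanner drift;
* a behavioural agent whose trial predictions mix the running average of
  its last five same-target-level feedback values with the actually
  achieved value (weight w per session), and whose confidence may or may
  not track prediction accuracy.

``simulate_study`` runs the full closed loop per participant x session
(localizer -> GLM -> region selection -> MaxPSC -> neurofeedback runs ->
scored feedback -> agent ratings), exactly as the online system would.
``simulate_behaviour_study`` is a lightweight path that draws feedback
values directly from the planted amplitudes, for large simulation
batteries where rendering 4D volumes is unnecessary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import localizer as loc
from . import roi as roi_mod
from .engine import (
    TARGET_SCALE_POSITIONS,
    NFRecord,
    TrialSchedule,
    TrialTiming,
    build_session_schedule,
    records_to_frame,
    score_run,
)
from .hrf import block_regressor
from .volume import VolumeSeries

__all__ = [
    "PhantomSpec",
    "AgentParams",
    "StudyConfig",
    "StudyDataset",
    "default_phantom",
    "ellipsoid_coords",
    "anatomical_premask",
    "simulate_localizer_run",
    "simulate_nf_run",
    "simulate_agent_ratings",
    "simulate_study",
    "simulate_behaviour_study",
    "BEHAVIOUR_COLUMNS",
]

BEHAVIOUR_COLUMNS = [
    "participant",
    "session",
    "run",
    "trial",
    "target_level",
    "catch",
    "nf_value",
    "prediction",
    "confidence",
]


def ellipsoid_coords(center, radii, grid_dims) -> np.ndarray:
    """Integer voxel coordinates inside an axis-aligned ellipsoid."""
    cx, cy, cz = center
    rx, ry, rz = radii
    out = []
    for x in range(max(0, math.floor(cx - rx)), min(grid_dims[0], math.ceil(cx + rx) + 1)):
        for y in range(max(0, math.floor(cy - ry)), min(grid_dims[1], math.ceil(cy + ry) + 1)):
            for z in range(max(0, math.floor(cz - rz)), min(grid_dims[2], math.ceil(cz + rz) + 1)):
                if ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0:
                    out.append((x, y, z))
    return np.array(out, dtype=int)


@dataclass
class PhantomSpec:
    """Digital-phantom geometry, signal and noise parameters.

    ``max_psc_true`` is the planted drawing-block amplitude as a percent
    of baseline — the ground truth that the localizer-derived MaxPSC
    estimates. Neurofeedback-trial amplitudes are expressed as fractions
    of it, so an agent regulating at fraction 0.9 should land near scale
    position 9.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 2.0
    tr_s: float = 1.0
    roi_truth: np.ndarray | None = None  # (n, 3) voxel coords of the imagery blob
    tapping_truth: np.ndarray | None = None  # disjoint blob active during tapping
    noise_sd: float = 1.0  # Gaussian noise, signal units
    drift_slope: float = 0.002  # signal units per volume
    baseline_level: float = 100.0
    max_psc_true: float = 2.0  # planted drawing amplitude, % of baseline

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must all be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be > 0")
        if self.roi_truth is None:
            self.roi_truth = ellipsoid_coords(
                (self.grid_dims[0] * 0.25, self.grid_dims[1] * 0.5, self.grid_dims[2] * 0.5),
                (2.5, 2.5, 2.0),
                self.grid_dims,
            )
        if self.tapping_truth is None:
            self.tapping_truth = ellipsoid_coords(
                (self.grid_dims[0] * 0.8, self.grid_dims[1] * 0.5, self.grid_dims[2] * 0.5),
                (2.5, 2.5, 2.0),
                self.grid_dims,
            )
        for name, coords in (("roi_truth", self.roi_truth), ("tapping_truth", self.tapping_truth)):
            coords = np.asarray(coords, dtype=int)
            if coords.ndim != 2 or coords.shape[1] != 3:
                raise ValueError(f"{name} must be an (n, 3) coordinate array")
            if (coords < 0).any() or (coords >= np.array(self.grid_dims)).any():
                raise ValueError(f"{name} has voxels outside the grid")
        overlap = {tuple(v) for v in self.roi_truth} & {tuple(v) for v in self.tapping_truth}
        if overlap:
            raise ValueError(
                f"roi_truth and tapping_truth overlap in {len(overlap)} voxels; "
                "the drawing-vs-tapping contrast needs disjoint blobs"
            )

    def mask(self, coords: np.ndarray) -> np.ndarray:
        m = np.zeros(self.grid_dims, dtype=bool)
        m[tuple(np.asarray(coords, dtype=int).T)] = True
        return m

    @property
    def roi_truth_mask(self) -> np.ndarray:
        return self.mask(self.roi_truth)

    @property
    def tapping_truth_mask(self) -> np.ndarray:
        return self.mask(self.tapping_truth)


def default_phantom(**overrides) -> PhantomSpec:
    return PhantomSpec(**overrides)


def anatomical_premask(spec: PhantomSpec, margin: int = 2) -> np.ndarray:
    """Box around the true imagery blob, mimicking an expert SMA pre-selection."""
    lo = np.maximum(spec.roi_truth.min(axis=0) - margin, 0)
    hi = np.minimum(spec.roi_truth.max(axis=0) + margin, np.array(spec.grid_dims) - 1)
    m = np.zeros(spec.grid_dims, dtype=bool)
    m[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return m


def _base_series(spec: PhantomSpec, n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_volumes)
    data = np.empty(spec.grid_dims + (n_volumes,), dtype=np.float64)
    data[...] = spec.baseline_level + spec.drift_slope * t
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return data


def _add_activation(
    data: np.ndarray,
    mask: np.ndarray,
    regressor: np.ndarray,
    amplitude_psc: float,
    baseline: float,
) -> None:
    data[mask] += (amplitude_psc / 100.0) * baseline * regressor


def simulate_localizer_run(
    spec: PhantomSpec,
    design: loc.BlockDesign,
    seed: int | np.random.SeedSequence = 0,
    *,
    tapping_amp_psc: float | None = None,
) -> VolumeSeries:
    """Render the localizer run: drawing blocks activate the imagery blob,
    tapping blocks the disjoint motor blob, plus noise and drift.

    The drawing amplitude is ``spec.max_psc_true`` percent of baseline;
    tapping defaults to the same so the drawing-vs-tapping contrast is
    driven by location, not amplitude.
    """
    n_vol = design.n_volumes(spec.tr_s)
    rng = np.random.default_rng(seed)
    data = _base_series(spec, n_vol, rng)
    for condition, mask, amp in (
        ("drawing", spec.roi_truth_mask, spec.max_psc_true),
        ("tapping", spec.tapping_truth_mask, tapping_amp_psc or spec.max_psc_true),
    ):
        onsets = design.onsets(condition)
        if not onsets:
            continue
        dur = next(b.duration_s for b in design.blocks if b.condition == condition)
        reg = block_regressor(onsets, dur, n_vol, spec.tr_s)
        _add_activation(data, mask, reg, amp, spec.baseline_level)
    return VolumeSeries(data, spec.voxel_size_mm, spec.tr_s)


@dataclass
class AgentParams:
    """Behavioural agent: regulation skill, prediction heuristic, confidence.

    * ``amp60``/``amp90`` — intended regulation amplitudes per target
      level, as fractions of the true MaxPSC (faithful regulation is
      0.6 / 0.9).
    * ``bias_by_session`` — additive regulation bias per session and
      target level (fraction of MaxPSC); positive = overshoot. Defaults
      encode the overshoot-at-60 / undershoot-at-90 pattern that shrinks
      with training.
    * ``prior_weight_by_session`` — weight w of the running-average prior
      in predictions; 1 means predictions ignore the trial entirely.
    * ``conf_base``/``conf_acc_slope`` — mean confidence (%) and its slope
      on the prediction error; 0 slope means confidence carries no
      metacognitive signal.
    """

    amp60: float = 0.6
    amp90: float = 0.9
    bias_by_session: dict = field(
        default_factory=lambda: {
            1: {60: 0.186, 90: -0.053},
            2: {60: 0.120, 90: -0.032},
            3: {60: 0.054, 90: -0.011},
        }
    )
    prior_weight_by_session: dict = field(
        default_factory=lambda: {1: 0.85, 2: 0.75, 3: 0.65}
    )
    pred_noise_sd: float = 1.0
    conf_base: float = 70.0
    conf_acc_slope: float = 0.0
    conf_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        for s, w in self.prior_weight_by_session.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"prior weight for session {s} must be in [0, 1]")
        if not 50.0 <= self.conf_base <= 100.0:
            raise ValueError("conf_base must be in [50, 100]")
        for name in ("pred_noise_sd", "conf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def amplitude_fraction(self, target_level: int, session: int) -> float:
        amp = {60: self.amp60, 90: self.amp90}[target_level]
        return amp + self.bias_by_session.get(session, {}).get(target_level, 0.0)


def null_agent(**overrides) -> AgentParams:
    """Agent with no target-level, session, prior-side or confidence effects.

    With w = 0.5 the prediction sits midway between prior and achieved
    value, so the distances to either reference are exchangeable.
    """
    params = dict(
        amp60=0.75,
        amp90=0.75,
        bias_by_session={s: {60: 0.0, 90: 0.0} for s in (1, 2, 3)},
        prior_weight_by_session={s: 0.5 for s in (1, 2, 3)},
        conf_acc_slope=0.0,
    )
    params.update(overrides)
    return AgentParams(**params)


def simulate_nf_run(
    spec: PhantomSpec,
    schedule: TrialSchedule,
    agent: AgentParams,
    session: int,
    seed: int | np.random.SeedSequence = 0,
) -> VolumeSeries:
    """Render one neurofeedback run.

    Each imagery period adds HRF-convolved activation in the true blob
    with amplitude (amp_TL + bias) x MaxPSC_true percent of baseline.
    """
    n_vol = schedule.n_volumes(spec.tr_s)
    rng = np.random.default_rng(seed)
    data = _base_series(spec, n_vol, rng)
    imagery_s = schedule.timing.imagery_s
    mask = spec.roi_truth_mask
    for trial in schedule.trials:
        frac = agent.amplitude_fraction(trial.target_level, session)
        reg = block_regressor([trial.onset_s], imagery_s, n_vol, spec.tr_s)
        _add_activation(data, mask, reg, frac * spec.max_psc_true, spec.baseline_level)
    return VolumeSeries(data, spec.voxel_size_mm, spec.tr_s)


def _round_to_grid(x: float, lo: float, hi: float, step: float) -> float:
    """Round half-up to the nearest scale tick, then clip."""
    k = math.floor((x - lo) / step + 0.5)
    return float(min(max(lo + k * step, lo), hi))


def simulate_agent_ratings(
    nf_values,
    schedule: TrialSchedule,
    agent: AgentParams,
    session: int,
    seed: int | np.random.SeedSequence = 0,
    *,
    history: dict[int, list[float]] | None = None,
    prior_window: int = 5,
) -> pd.DataFrame:
    """Prediction and confidence ratings for one run's feedback values.

    prediction = round(w * prior + (1 - w) * nf + noise) on the 0-12 grid,
    where the prior is the running mean of the last five same-target-level
    feedback values (the target's own scale position anchors the very
    first trial). Confidence = conf_base + slope * |prediction - nf| +
    noise, rounded to the 50-100 step-5 grid. Catch trials take their
    instructed values instead. ``history`` (per-target-level feedback
    lists) is updated in place so it can be threaded across runs.
    """
    nf_values = list(nf_values)
    if len(nf_values) != len(schedule.trials):
        raise ValueError("nf_values must align with the schedule")
    rng = np.random.default_rng(seed)
    if history is None:
        history = {60: [], 90: []}
    w = agent.prior_weight_by_session.get(session, 0.5)
    rows = []
    for k, (trial, nf) in enumerate(zip(schedule.trials, nf_values)):
        tl = trial.target_level
        past = history[tl]
        if past:
            prior = float(np.mean(past[-prior_window:]))
        else:
            prior = TARGET_SCALE_POSITIONS[tl]
        if trial.catch:
            pred = float(trial.instructed_prediction)
            conf = float(trial.instructed_confidence)
            # keep the noise stream aligned across catch/non-catch variants
            rng.normal(size=2)
        else:
            raw = w * prior + (1.0 - w) * nf + rng.normal(0.0, agent.pred_noise_sd)
            pred = _round_to_grid(raw, 0.0, 12.0, 1.0)
            conf_raw = (
                agent.conf_base
                + agent.conf_acc_slope * abs(pred - nf)
                + rng.normal(0.0, agent.conf_noise_sd)
            )
            conf = _round_to_grid(conf_raw, 50.0, 100.0, 5.0)
        rows.append(
            {
                "trial": k,
                "target_level": tl,
                "catch": trial.catch,
                "nf_value": nf,
                "prediction": pred,
                "confidence": conf,
                "prior": prior if past else math.nan,
            }
        )
        past.append(float(nf))
    return pd.DataFrame(rows)


@dataclass
class StudyConfig:
    """Scale and content of one synthetic study."""

    n_participants: int = 8
    sessions: tuple[int, ...] = (1, 2, 3)
    n_runs: int = 6
    trials_per_run: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    agent: AgentParams = field(default_factory=AgentParams)
    timing: TrialTiming = field(default_factory=TrialTiming)
    smoothing_fwhm_mm: float = 4.0
    roi_n_target: int = 30
    roi_max_slices: int = 6

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class SessionData:
    """Per participant x session artefacts of the closed simulation loop."""

    participant: int
    session: int
    localizer_design: loc.BlockDesign
    schedules: list[TrialSchedule]
    roi: roi_mod.ROIMask
    max_psc: loc.MaxPSC
    records: list[NFRecord]
    localizer: VolumeSeries | None = None
    nf_runs: list[VolumeSeries] | None = None


@dataclass
class StudyDataset:
    config: StudyConfig
    seed: int
    sessions: list[SessionData]
    behaviour: pd.DataFrame

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.behaviour.to_csv(out / "behaviour.csv", index=False)
        for sd in self.sessions:
            tag = f"sub-{sd.participant:02d}_ses-{sd.session}"
            sd.localizer_design.to_json(out / f"{tag}_localizer_design.json")
            sd.roi.save_report(out / f"{tag}_roi.json")
            sd.max_psc.to_json(out / f"{tag}_maxpsc.json")
            for r, sched in enumerate(sd.schedules, start=1):
                sched.to_json(out / f"{tag}_run-{r}_schedule.json")
            if sd.localizer is not None:
                sd.localizer.save(out / f"{tag}_localizer.nii.gz")
            if sd.nf_runs is not None:
                for r, vol in enumerate(sd.nf_runs, start=1):
                    vol.save(out / f"{tag}_run-{r}_nf.nii.gz")


def _session_seeds(master_seed: int, n_participants: int, n_sessions: int):
    root = np.random.SeedSequence(master_seed)
    per_part = root.spawn(n_participants)
    return [p.spawn(n_sessions) for p in per_part]


def simulate_session(
    cfg: StudyConfig,
    participant: int,
    session: int,
    seed: np.random.SeedSequence,
    *,
    history: dict[int, list[float]] | None = None,
    keep_volumes: bool = False,
    out_dir: Path | None = None,
) -> tuple[SessionData, pd.DataFrame]:
    """Run the closed loop for one participant-session.

    Localizer simulation, smoothing, GLM, target-region selection and
    MaxPSC estimation feed the online scoring of six freshly simulated
    neurofeedback runs, whose feedback values drive the agent's ratings.
    """
    spec = cfg.phantom
    s_loc, s_sched, s_runs, s_agent = seed.spawn(4)
    design = loc.default_localizer_design()
    localizer = simulate_localizer_run(spec, design, s_loc)
    smoothed = loc.smooth_gaussian(localizer, cfg.smoothing_fwhm_mm)
    X = loc.build_design_matrix(design, smoothed.n_volumes, spec.tr_s)
    fit = loc.fit_glm(smoothed, X)
    tmap = loc.contrast_tmap(fit)
    premask = anatomical_premask(spec)
    roi = roi_mod.select_target_region(
        tmap.data,
        premask,
        n_target=cfg.roi_n_target,
        max_slices=cfg.roi_max_slices,
        contrast=tmap.contrast,
    )
    roi_arr = roi.to_array()
    max_psc = loc.compute_max_psc(
        smoothed, design, roi_arr, participant=participant, session=session
    )
    schedules = build_session_schedule(
        cfg.n_runs, cfg.trials_per_run, s_sched, timing=cfg.timing
    )
    run_seeds = s_runs.spawn(cfg.n_runs)
    agent_seeds = s_agent.spawn(cfg.n_runs)
    if history is None:
        history = {60: [], 90: []}
    all_records: list[NFRecord] = []
    behaviour_rows = []
    nf_runs: list[VolumeSeries] | None = [] if keep_volumes else None
    for r in range(cfg.n_runs):
        vol = simulate_nf_run(spec, schedules[r], cfg.agent, session, run_seeds[r])
        smoothed_run = loc.smooth_gaussian(vol, cfg.smoothing_fwhm_mm)
        records = score_run(
            smoothed_run,
            roi_arr,
            schedules[r],
            max_psc.value,
            participant=participant,
            session=session,
            run=r + 1,
        )
        ratings = simulate_agent_ratings(
            [rec.nf_value for rec in records],
            schedules[r],
            cfg.agent,
            session,
            agent_seeds[r],
            history=history,
        )
        for rec, (_, rating) in zip(records, ratings.iterrows()):
            rec.prediction = rating["prediction"]
            rec.confidence = rating["confidence"]
        all_records.extend(records)
        behaviour_rows.append(records_to_frame(records))
        if keep_volumes:
            nf_runs.append(vol)
        if out_dir is not None:
            tag = f"sub-{participant:02d}_ses-{session}_run-{r + 1}"
            vol.save(out_dir / f"{tag}_nf.nii.gz")
    if out_dir is not None:
        localizer.save(out_dir / f"sub-{participant:02d}_ses-{session}_localizer.nii.gz")
    sd = SessionData(
        participant=participant,
        session=session,
        localizer_design=design,
        schedules=schedules,
        roi=roi,
        max_psc=max_psc,
        records=all_records,
        localizer=localizer if keep_volumes else None,
        nf_runs=nf_runs,
    )
    return sd, pd.concat(behaviour_rows, ignore_index=True)


def simulate_study(
    cfg: StudyConfig | None = None,
    seed: int = 0,
    *,
    keep_volumes: bool = False,
    out_dir: str | Path | None = None,
) -> StudyDataset:
    """Simulate a full study: every participant, session and run.

    Deterministic under (config, seed): each participant-session draws
    from its own spawned seed stream, so any subset reproduces
    independently of the others.
    """
    cfg = cfg or StudyConfig()
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    seeds = _session_seeds(seed, cfg.n_participants, len(cfg.sessions))
    sessions = []
    tables = []
    for p in range(cfg.n_participants):
        history: dict[int, list[float]] = {60: [], 90: []}
        for si, s in enumerate(cfg.sessions):
            sd, table = simulate_session(
                cfg,
                participant=p,
                session=s,
                seed=seeds[p][si],
                history=history,
                keep_volumes=keep_volumes,
                out_dir=out,
            )
            sessions.append(sd)
            tables.append(table)
    behaviour = pd.concat(tables, ignore_index=True)
    ds = StudyDataset(config=cfg, seed=seed, sessions=sessions, behaviour=behaviour)
    if out is not None:
        ds.save(out)
    return ds


def simulate_behaviour_study(
    agent: AgentParams | None = None,
    n_participants: int = 8,
    seed: int = 0,
    *,
    sessions: tuple[int, ...] = (1, 2, 3),
    n_runs: int = 6,
    trials_per_run: int = 10,
    nf_noise_sd: float = 1.5,
    timing: TrialTiming | None = None,
) -> pd.DataFrame:
    """Behaviour-only study: draw feedback values from planted amplitudes.

    The achieved feedback of a trial is 10 x (amp_TL + bias) plus
    Gaussian noise on the 0-12 scale (clipped), standing in for the whole
    imaging chain; ratings follow the same agent model as the full
    simulator. Used for large model-recovery batteries.
    """
    agent = agent or AgentParams()
    seeds = _session_seeds(seed, n_participants, len(sessions))
    tables = []
    for p in range(n_participants):
        history: dict[int, list[float]] = {60: [], 90: []}
        for si, s in enumerate(sessions):
            s_sched, s_nf, s_agent = seeds[p][si].spawn(3)
            schedules = build_session_schedule(n_runs, trials_per_run, s_sched, timing=timing)
            nf_rng = np.random.default_rng(s_nf)
            agent_seeds = s_agent.spawn(n_runs)
            for r, sched in enumerate(schedules, start=1):
                nf_values = [
                    float(
                        np.clip(
                            10.0 * agent.amplitude_fraction(t.target_level, s)
                            + nf_rng.normal(0.0, nf_noise_sd),
                            0.0,
                            12.0,
                        )
                    )
                    for t in sched.trials
                ]
                ratings = simulate_agent_ratings(
                    nf_values, sched, agent, s, agent_seeds[r - 1], history=history
                )
                ratings.insert(0, "participant", p)
                ratings.insert(1, "session", s)
                ratings.insert(2, "run", r)
                tables.append(ratings.drop(columns=["prior"]))
    return pd.concat(tables, ignore_index=True)[BEHAVIOUR_COLUMNS]
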