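"""End-to-end pipeline: simulate -> localize -> select -> feedback -> metrics -> models.

The ``simulate`` stage runs the closed online loop (the agent's ratings
depend on the feedback the scoring engine computes in session), writing
raw NIfTI runs, schedules and the behavioural table. The offline stages
then re-derive everything from those files — t-maps, target regions,
MaxPSC, trial records, analysis tables and the fitted hypothesis
battery — exactly as an offline analysis of archived data would.

Every stage logs its inputs and outputs into a manifest with SHA-256
hashes, so re-running a deterministic configuration reproduces identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import bayes, localizer as loc, metrics, phantom, roi as roi_mod
from .engine import TrialSchedule, records_to_frame, score_run
from .volume import VolumeSeries

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "localize", "select-roi", "feedback", "metrics", "fit")


class AgentConfig(BaseModel):
    amp60: float = 0.6
    amp90: float = 0.9
    bias_by_session: dict[int, dict[int, float]] = Field(
        default_factory=lambda: {
            1: {60: 0.186, 90: -0.053},
            2: {60: 0.120, 90: -0.032},
            3: {60: 0.054, 90: -0.011},
        }
    )
    prior_weight_by_session: dict[int, float] = Field(
        default_factory=lambda: {1: 0.85, 2: 0.75, 3: 0.65}
    )
    pred_noise_sd: float = 1.0
    conf_base: float = 70.0
    conf_acc_slope: float = 0.0
    conf_noise_sd: float = 6.0


class MCMCSection(BaseModel):
    chains: int = 2
    iterations: int = 1500
    warmup: int = 500


class RunConfig(BaseModel):
    """Complete, serialisable description of one pipeline run.

    The default scale is a desk-size study: a 24 x 24 x 12 voxel grid,
    8 participants, the full 3-session / 6-run / 10-trial schedule, and
    a trimmed MCMC schedule (restore the full 2 x 5000 / 2000 schedule
    via ``paper_mcmc=True``).
    """

    n_participants: int = 8
    sessions: tuple[int, ...] = (1, 2, 3)
    n_runs: int = 6
    trials_per_run: int = 10
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: float = 2.0
    tr_s: float = 1.0
    noise_sd: float = 1.0
    drift_slope: float = 0.002
    baseline_level: float = 100.0
    max_psc_true: float = 2.0
    smoothing_fwhm_mm: float = 4.0
    roi_n_target: int = 30
    roi_max_slices: int = 6
    agent: AgentConfig = Field(default_factory=AgentConfig)
    mcmc: MCMCSection = Field(default_factory=MCMCSection)
    paper_mcmc: bool = False
    master_seed: int = 0

    def phantom_spec(self) -> phantom.PhantomSpec:
        return phantom.PhantomSpec(
            grid_dims=tuple(self.grid_dims),
            voxel_size_mm=self.voxel_size_mm,
            tr_s=self.tr_s,
            noise_sd=self.noise_sd,
            drift_slope=self.drift_slope,
            baseline_level=self.baseline_level,
            max_psc_true=self.max_psc_true,
        )

    def agent_params(self) -> phantom.AgentParams:
        return phantom.AgentParams(**self.agent.model_dump())

    def study_config(self) -> phantom.StudyConfig:
        return phantom.StudyConfig(
            n_participants=self.n_participants,
            sessions=tuple(self.sessions),
            n_runs=self.n_runs,
            trials_per_run=self.trials_per_run,
            phantom=self.phantom_spec(),
            agent=self.agent_params(),
            smoothing_fwhm_mm=self.smoothing_fwhm_mm,
            roi_n_target=self.roi_n_target,
            roi_max_slices=self.roi_max_slices,
        )

    def mcmc_config(self, seed: int = 0) -> bayes.MCMCConfig:
        if self.paper_mcmc:
            return bayes.MCMCConfig(seed=seed)
        return bayes.MCMCConfig(
            chains=self.mcmc.chains,
            iterations=self.mcmc.iterations,
            warmup=self.mcmc.warmup,
            seed=seed,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


class RunManifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.stages: dict[str, dict] = {}

    @staticmethod
    def _sha256(path: Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as f:
            for chunk in iter(lambda: f.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    def record(self, stage: str, outputs: list[Path], seconds: float, seed=None) -> None:
        self.stages[stage] = {
            "seed": seed,
            "seconds": round(seconds, 3),
            "outputs": {
                str(p.relative_to(self.out_dir)): self._sha256(p) for p in sorted(outputs)
            },
        }

    def save(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.stages, indent=1))
        return path


def _session_tags(cfg: RunConfig):
    for p in range(cfg.n_participants):
        for s in cfg.sessions:
            yield p, s, f"sub-{p:02d}_ses-{s}"


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> RunManifest:
    """Execute the requested stages, in canonical order, under ``out_dir``."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out)
    raw = out / "raw"
    deriv = out / "derivatives"
    spec = config.phantom_spec()

    if "simulate" in stages:
        t0 = time.time()
        raw.mkdir(exist_ok=True)
        phantom.simulate_study(config.study_config(), config.master_seed, out_dir=raw)
        premask = phantom.anatomical_premask(spec)
        _save_mask(premask, raw / "premask.nii.gz", spec.voxel_size_mm)
        manifest.record(
            "simulate", list(raw.iterdir()), time.time() - t0, seed=config.master_seed
        )

    if "localize" in stages:
        t0 = time.time()
        deriv.mkdir(exist_ok=True)
        outputs = []
        for _, _, tag in _session_tags(config):
            series = VolumeSeries.load(raw / f"{tag}_localizer.nii.gz")
            design = loc.BlockDesign.from_json(raw / f"{tag}_localizer_design.json")
            smoothed = loc.smooth_gaussian(series, config.smoothing_fwhm_mm)
            X = loc.build_design_matrix(design, smoothed.n_volumes, series.tr_s)
            tmap = loc.contrast_tmap(loc.fit_glm(smoothed, X))
            path = deriv / f"{tag}_tmap.nii.gz"
            tmap.save(path, series.voxel_size_mm)
            outputs.append(path)
        manifest.record("localize", outputs, time.time() - t0)

    if "select-roi" in stages:
        t0 = time.time()
        outputs = []
        premask = phantom.anatomical_premask(spec)
        for _, _, tag in _session_tags(config):
            import nibabel as nib

            tmap = np.asarray(nib.load(deriv / f"{tag}_tmap.nii.gz").dataobj, dtype=float)
            mask = roi_mod.select_target_region(
                tmap, premask, n_target=config.roi_n_target,
                max_slices=config.roi_max_slices, contrast="drawing-tapping",
            )
            nii = deriv / f"{tag}_roi.nii.gz"
            rep = deriv / f"{tag}_roi.json"
            mask.save(nii, spec.voxel_size_mm)
            mask.save_report(rep)
            outputs += [nii, rep]
        manifest.record("select-roi", outputs, time.time() - t0)

    if "feedback" in stages:
        t0 = time.time()
        outputs = []
        frames = []
        for p, s, tag in _session_tags(config):
            import nibabel as nib

            roi_arr = np.asarray(nib.load(deriv / f"{tag}_roi.nii.gz").dataobj) > 0
            series = VolumeSeries.load(raw / f"{tag}_localizer.nii.gz")
            design = loc.BlockDesign.from_json(raw / f"{tag}_localizer_design.json")
            smoothed = loc.smooth_gaussian(series, config.smoothing_fwhm_mm)
            max_psc = loc.compute_max_psc(
                smoothed, design, roi_arr, participant=p, session=s
            )
            mp_path = deriv / f"{tag}_maxpsc.json"
            max_psc.to_json(mp_path)
            outputs.append(mp_path)
            for r in range(1, config.n_runs + 1):
                run_vol = VolumeSeries.load(raw / f"{tag}_run-{r}_nf.nii.gz")
                run_vol = loc.smooth_gaussian(run_vol, config.smoothing_fwhm_mm)
                sched = TrialSchedule.from_json(raw / f"{tag}_run-{r}_schedule.json")
                frames.append(
                    records_to_frame(
                        score_run(
                            run_vol, roi_arr, sched, max_psc.value,
                            participant=p, session=s, run=r,
                        )
                    )
                )
        records = pd.concat(frames, ignore_index=True)
        behaviour = pd.read_csv(raw / "behaviour.csv")
        keys = ["participant", "session", "run", "trial"]
        records = records.drop(columns=["prediction", "confidence"]).merge(
            behaviour[keys + ["prediction", "confidence"]], on=keys, how="left"
        )
        rec_path = deriv / "records.csv"
        records.to_csv(rec_path, index=False)
        outputs.append(rec_path)
        manifest.record("feedback", outputs, time.time() - t0)

    if "metrics" in stages:
        t0 = time.time()
        records = pd.read_csv(deriv / "records.csv")
        wide = metrics.build_analysis_table(records)
        long = metrics.long_format_distances(wide)
        summary = metrics.session_summary(wide)
        paths = []
        for name, df in (
            ("analysis_wide", wide),
            ("analysis_long", long),
            ("session_summary", summary),
        ):
            p = deriv / f"{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        manifest.record("metrics", paths, time.time() - t0)

    if "fit" in stages:
        t0 = time.time()
        wide = pd.read_csv(deriv / "analysis_wide.csv")
        long = pd.read_csv(deriv / "analysis_long.csv")
        mcmc_cfg = config.mcmc_config(config.master_seed)
        fits = bayes.fit_all_models(wide, long, mcmc_cfg)
        battery = bayes.hypothesis_battery(
            fits["selfreg"], fits["prediction"], fits["confidence"]
        )
        bat_path = deriv / "battery.csv"
        battery.to_csv(bat_path, index=False)
        card = {
            name: {
                "max_rhat": res.max_rhat,
                "min_ess": min(res.ess.values()),
                "n_draws": res.n_draws,
                "chains": res.config.chains,
                "iterations": res.config.iterations,
                "warmup": res.config.warmup,
            }
            for name, res in fits.items()
        }
        card_path = deriv / "model_card.json"
        card_path.write_text(json.dumps(card, indent=1))
        manifest.record(
            "fit", [bat_path, card_path], time.time() - t0, seed=mcmc_cfg.seed
        )

    manifest.save()
    return manifest


def _save_mask(mask: np.ndarray, path: Path, voxel_size_mm: float) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
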