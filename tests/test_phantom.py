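"""Synthetic data generator: signal structure, agents, study shape."""

import numpy as np
import pandas as pd
import pytest

from nfsim.engine import IMAGERY_WINDOW_S, BASELINE_WINDOW_S, build_session_schedule, score_run, window_indices
from nfsim.hrf import block_regressor
from nfsim.localizer import default_localizer_design
from nfsim.phantom import (
    AgentParams,
    PhantomSpec,
    StudyConfig,
    anatomical_premask,
    null_agent,
    simulate_agent_ratings,
    simulate_behaviour_study,
    simulate_localizer_run,
    simulate_nf_run,
    simulate_study,
)


class TestPhantomSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_dims=(0, 4, 4))
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(baseline_level=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(grid_dims=(4, 4, 4), roi_truth=np.array([[5, 0, 0]]))

    def test_blobs_are_disjoint_and_premask_covers_roi(self):
        spec = PhantomSpec()
        roi = {tuple(v) for v in spec.roi_truth}
        tap = {tuple(v) for v in spec.tapping_truth}
        assert not roi & tap
        premask = anatomical_premask(spec)
        assert all(premask[v] for v in roi)


class TestLocalizerSimulation:
    def test_default_design_gives_528_volumes(self, noisy_spec):
        vol = simulate_localizer_run(noisy_spec, default_localizer_design(), seed=0)
        assert vol.n_volumes == 528

    def test_non_integer_volume_count_rejected(self, small_spec):
        from nfsim.localizer import Block, BlockDesign

        design = BlockDesign([Block("rest", 0, 10.5)])
        with pytest.raises(ValueError, match="integer"):
            simulate_localizer_run(small_spec, design, seed=0)

    def test_zero_everything_gives_baseline_plus_drift(self):
        spec = PhantomSpec(
            grid_dims=(12, 12, 6), noise_sd=0.0, drift_slope=0.01, max_psc_true=0.0
        )
        vol = simulate_localizer_run(spec, default_localizer_design(), seed=0)
        t = np.arange(vol.n_volumes)
        expected = np.broadcast_to(
            spec.baseline_level + spec.drift_slope * t, vol.data.shape
        )
        np.testing.assert_allclose(vol.data, expected, rtol=0, atol=1e-12)

    def test_block_psc_matches_convolution_oracle(self):
        """1% planted amplitude yields ~1% block-averaged PSC (plateau factor)."""
        spec = PhantomSpec(grid_dims=(10, 10, 6), noise_sd=0.0, drift_slope=0.0, max_psc_true=1.0)
        design = default_localizer_design()
        vol = simulate_localizer_run(spec, design, seed=0)
        tc = vol.roi_timecourse(spec.roi_truth_mask)
        onset = design.onsets("drawing")[3]
        reg = block_regressor(design.onsets("drawing"), 16.0, vol.n_volumes, 1.0)
        imagery = tc[window_indices(onset, IMAGERY_WINDOW_S, 1.0)].mean()
        base = tc[window_indices(onset, BASELINE_WINDOW_S, 1.0)].mean()
        psc = 100 * (imagery - base) / base
        # closed-form oracle: reconstruct the time-course from the regressor
        amp_units = spec.max_psc_true / 100 * spec.baseline_level
        recon = spec.baseline_level + amp_units * reg
        b_o = recon[window_indices(onset, BASELINE_WINDOW_S, 1.0)].mean()
        i_o = recon[window_indices(onset, IMAGERY_WINDOW_S, 1.0)].mean()
        assert psc == pytest.approx(100 * (i_o - b_o) / b_o, rel=1e-9)
        # and the windowed plateau keeps the PSC close to the planted 1%
        plateau = (
            reg[window_indices(onset, IMAGERY_WINDOW_S, 1.0)].mean()
            - reg[window_indices(onset, BASELINE_WINDOW_S, 1.0)].mean()
        )
        assert 0.8 < plateau <= 1.05
        assert psc == pytest.approx(spec.max_psc_true * plateau, rel=1e-4)


class TestNFRunSimulation:
    def test_equal_amplitudes_give_identical_level_responses(self, small_spec):
        agent = AgentParams(
            amp60=0.7, amp90=0.7,
            bias_by_session={s: {60: 0.0, 90: 0.0} for s in (1, 2, 3)},
        )
        sched = build_session_schedule(n_runs=1, seed=1)[0]
        vol = simulate_nf_run(small_spec, sched, agent, session=1, seed=0)
        records = score_run(vol, small_spec.roi_truth_mask, sched, 2.0)
        by_level = pd.DataFrame([(r.target_level, r.psc_raw) for r in records],
                                columns=["tl", "psc"]).groupby("tl").psc.mean()
        # tolerance covers HRF-undershoot carryover from the preceding trial
        assert by_level[60] == pytest.approx(by_level[90], abs=2e-3)

    def test_higher_target_level_scores_strictly_higher(self, small_spec):
        agent = AgentParams(
            bias_by_session={s: {60: 0.0, 90: 0.0} for s in (1, 2, 3)}
        )
        sched = build_session_schedule(n_runs=1, seed=2)[0]
        vol = simulate_nf_run(small_spec, sched, agent, session=1, seed=0)
        records = score_run(vol, small_spec.roi_truth_mask, sched, 2.0)
        p60 = [r.psc_raw for r in records if r.target_level == 60]
        p90 = [r.psc_raw for r in records if r.target_level == 90]
        assert max(p60) < min(p90)

    def test_planted_amplitude_recovered_through_scoring(self, small_spec):
        """Noise-free closed loop: trial PSC = amplitude x plateau, to 1e-6."""
        agent = AgentParams(
            amp60=0.6, amp90=0.9,
            bias_by_session={s: {60: 0.0, 90: 0.0} for s in (1, 2, 3)},
        )
        sched = build_session_schedule(n_runs=1, seed=3)[0]
        vol = simulate_nf_run(small_spec, sched, agent, session=1, seed=0)
        records = score_run(vol, small_spec.roi_truth_mask, sched, 2.0)
        n = vol.n_volumes
        for rec, trial in zip(records, sched.trials):
            reg = np.zeros(n)
            for tr2 in sched.trials:  # all trials contribute to the time-course
                frac = agent.amplitude_fraction(tr2.target_level, 1)
                reg += frac * block_regressor([tr2.onset_s], 16.0, n, 1.0)
            reg *= small_spec.max_psc_true / 100 * small_spec.baseline_level
            tc = small_spec.baseline_level + reg
            b = tc[window_indices(trial.onset_s, BASELINE_WINDOW_S, 1.0)].mean()
            i = tc[window_indices(trial.onset_s, IMAGERY_WINDOW_S, 1.0)].mean()
            assert rec.psc_raw == pytest.approx(100 * (i - b) / b, abs=1e-6)


class TestAgentRatings:
    def _schedule(self, seed=0):
        return build_session_schedule(n_runs=1, seed=seed)[0]

    def test_pure_prior_agent_predicts_rounded_prior(self):
        sched = self._schedule()
        agent = AgentParams(
            prior_weight_by_session={1: 1.0, 2: 1.0, 3: 1.0}, pred_noise_sd=0.0
        )
        nf = [5.0, 7.0, 6.0, 8.0, 4.0, 9.0, 5.5, 6.5, 7.5, 8.5]
        history = {60: [], 90: []}
        df = simulate_agent_ratings(nf, sched, agent, 1, seed=0, history=history)
        running = {60: [], 90: []}
        for _, row in df.iterrows():
            tl = row["target_level"]
            expected_prior = np.mean(running[tl][-5:]) if running[tl] else {60: 6, 90: 9}[tl]
            if not row["catch"]:
                assert row["prediction"] == np.floor(expected_prior + 0.5)
            running[tl].append(row["nf_value"])

    def test_pure_feedback_agent_predicts_rounded_feedback(self):
        sched = self._schedule(seed=1)
        agent = AgentParams(
            prior_weight_by_session={1: 0.0, 2: 0.0, 3: 0.0}, pred_noise_sd=0.0
        )
        nf = [5.2, 7.9, 6.1, 8.6, 4.4, 9.0, 5.5, 6.5, 7.5, 8.4]
        df = simulate_agent_ratings(nf, sched, agent, 1, seed=0)
        real = df[~df["catch"]]
        assert (abs(real["prediction"] - real["nf_value"]) <= 0.5).all()

    def test_catch_trials_take_instructed_values(self):
        sched = self._schedule(seed=2)
        df = simulate_agent_ratings([6.0] * 10, sched, AgentParams(), 1, seed=0)
        catch_trial = next(t for t in sched.trials if t.catch)
        row = df[df["catch"]].iloc[0]
        assert row["prediction"] == catch_trial.instructed_prediction
        assert row["confidence"] == catch_trial.instructed_confidence

    def test_flat_confidence_uncorrelated_with_accuracy(self):
        """Monte-Carlo oracle over ~1000 trials, tolerance 3/sqrt(n)."""
        agent = AgentParams(conf_acc_slope=0.0, conf_noise_sd=8.0)
        rng = np.random.default_rng(42)
        rows = []
        history = {60: [], 90: []}
        for k in range(100):
            sched = build_session_schedule(n_runs=1, seed=1000 + k)[0]
            nf = list(np.clip(rng.normal(7.5, 1.5, 10), 0, 12))
            rows.append(
                simulate_agent_ratings(nf, sched, agent, 1, seed=2000 + k, history=history)
            )
        df = pd.concat(rows)
        df = df[~df["catch"]]
        acc = (df["prediction"] - df["nf_value"]).abs()
        r = np.corrcoef(df["confidence"], acc)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(df))

    def test_scale_bounds_respected(self):
        sched = self._schedule(seed=3)
        agent = AgentParams(pred_noise_sd=10.0, conf_noise_sd=50.0)
        df = simulate_agent_ratings([12.0] * 10, sched, agent, 1, seed=5)
        assert df["prediction"].between(0, 12).all()
        assert df["confidence"].between(50, 100).all()
        assert (df["confidence"] % 5 == 0).all()


class TestStudySimulation:
    def test_behaviour_study_counts(self):
        beh = simulate_behaviour_study(n_participants=2, seed=0)
        per_part = beh.groupby("participant").size()
        assert (per_part == 180).all()
        per_level = beh.groupby(["participant", "target_level"]).size()
        assert (per_level == 90).all()

    def test_single_session_has_60_trials(self):
        beh = simulate_behaviour_study(n_participants=1, seed=0, sessions=(1,))
        assert len(beh) == 60

    def test_behaviour_study_deterministic(self):
        a = simulate_behaviour_study(n_participants=2, seed=9)
        b = simulate_behaviour_study(n_participants=2, seed=9)
        assert a.to_csv() == b.to_csv()  # byte-identical after serialisation

    def test_full_study_closed_loop_small(self, tmp_path):
        """1 participant, full sessions on a small grid: shape + determinism
        of the written artefacts."""
        cfg = StudyConfig(
            n_participants=1,
            n_runs=2,
            phantom=PhantomSpec(grid_dims=(12, 12, 6)),
        )
        ds = simulate_study(cfg, seed=4)
        assert len(ds.behaviour) == 3 * 2 * 10
        assert ds.behaviour["nf_value"].between(0, 12).all()
        assert {sd.roi.n_voxels for sd in ds.sessions} == {30}
        ds2 = simulate_study(cfg, seed=4)
        pd.testing.assert_frame_equal(ds.behaviour, ds2.behaviour)

    def test_null_agent_has_no_structured_effects(self):
        agent = null_agent()
        assert agent.amplitude_fraction(60, 1) == agent.amplitude_fraction(90, 3)
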