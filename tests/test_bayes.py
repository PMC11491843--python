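"""Hierarchical model fitting, diagnostics and the hypothesis battery."""

import numpy as np
import pandas as pd
import pytest

from nfsim.bayes import (
    HYPOTHESES,
    BayesMixedLM,
    ConvergenceError,
    MCMCConfig,
    MixedLMResults,
    PredictionModel,
    SelfRegulationModel,
    fit_all_models,
    hypothesis_battery,
)
from nfsim.metrics import build_analysis_table, long_format_distances
from nfsim.phantom import AgentParams, null_agent, simulate_behaviour_study


def _simulate_lmm(beta, n_groups=8, n_per_cell=30, re_sd=0.5, noise_sd=1.0, seed=0):
    """Direct draw from the mixed model: cell-means design, one random
    deviation vector per group."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, re_sd, p)
        for c in range(p):
            y = beta[c] + b[c] + rng.normal(0, noise_sd, n_per_cell)
            for v in y:
                rows.append((g, c, v))
    df = pd.DataFrame(rows, columns=["g", "cell", "y"])
    X = pd.get_dummies(df["cell"]).to_numpy(dtype=float)
    names = [f"c{c}" for c in range(p)]
    return BayesMixedLM(df["y"], X, df["g"], names)


class TestSampler:
    def test_parameter_recovery_within_two_posterior_sd(self):
        beta = np.array([1.0, -0.5, 0.0, 2.0, 0.7, -1.2])
        model = _simulate_lmm(beta, seed=1)
        res = model.fit(MCMCConfig.trimmed(seed=2))
        s = res.summary()
        for c, true in enumerate(beta):
            mean, sd = s.loc[f"c{c}", "mean"], s.loc[f"c{c}", "sd"]
            assert abs(mean - true) < 2 * sd + 0.05

    def test_null_outcome_intervals_cover_zero(self):
        model = _simulate_lmm(np.zeros(4), re_sd=0.05, noise_sd=0.1, seed=3)
        res = model.fit(MCMCConfig.trimmed(seed=4))
        s = res.summary()
        for c in range(4):
            assert s.loc[f"c{c}", "ci_2.5%"] < 0 < s.loc[f"c{c}", "ci_97.5%"]

    def test_same_seed_gives_identical_draws(self):
        model = _simulate_lmm(np.array([1.0, 2.0]), seed=5)
        a = model.fit(MCMCConfig.trimmed(seed=6))
        b = model.fit(MCMCConfig.trimmed(seed=6))
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_draw_count_matches_config(self):
        model = _simulate_lmm(np.array([0.0, 1.0]), seed=7)
        cfg = MCMCConfig(chains=2, iterations=300, warmup=100, seed=0)
        res = model.fit(cfg)
        assert res.n_draws == 400
        assert res.draws["c0"].shape == (2, 200)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            BayesMixedLM(np.zeros(20), X, np.repeat([0, 1], 10), ["a", "b"])

    def test_single_group_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="two participants"):
            BayesMixedLM(np.zeros(10), X, np.zeros(10), ["a"])

    def test_invalid_mcmc_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(warmup=10, iterations=10)


@pytest.fixture(scope="module")
def fitted():
    model = _simulate_lmm(np.array([1.0, -1.0, 0.0]), seed=11)
    return model.fit(MCMCConfig.trimmed(seed=12))


@pytest.fixture(scope="module")
def fits():
    beh = simulate_behaviour_study(n_participants=8, seed=3)
    wide = build_analysis_table(beh)
    long = long_format_distances(wide)
    return fit_all_models(wide, long, MCMCConfig.trimmed(seed=11))


class TestHypothesisTests:
    def test_all_positive_draws_give_probability_one(self, fitted):
        r = fitted.test_hypothesis({"c0": 1.0}, const=100.0)
        assert r.posterior_probability == 1.0

    def test_probability_and_complement_sum_to_one(self, fitted):
        p = fitted.test_hypothesis({"c0": 1.0, "c1": -1.0}).posterior_probability
        q = fitted.test_hypothesis({"c0": -1.0, "c1": 1.0}).posterior_probability
        # continuous draws: ties have measure zero
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_draws_give_half(self, fitted):
        """Fabricated draws symmetric about zero score 0.5 +- 2/sqrt(n)."""
        rng = np.random.default_rng(0)
        n = fitted.draws["c0"].shape[1]
        sym = rng.normal(0.0, 1.0, size=(2, n))
        res = MixedLMResults(
            model=fitted.model,
            config=fitted.config,
            draws={**fitted.draws, "c0": sym},
            random_draws=fitted.random_draws,
        )
        p = res.test_hypothesis({"c0": 1.0}, force=True).posterior_probability
        assert abs(p - 0.5) < 2 / np.sqrt(sym.size)

    def test_unknown_effect_rejected(self, fitted):
        with pytest.raises(KeyError):
            fitted.test_hypothesis({"nope": 1.0})

    def test_unknown_participant_rejected(self, fitted):
        with pytest.raises(KeyError):
            fitted.test_hypothesis({"c0": 1.0}, level="ghost")

    def test_participant_level_uses_random_effects(self, fitted):
        group = fitted.test_hypothesis({"c0": 1.0}).posterior_probability
        per_part = [
            fitted.test_hypothesis({"c0": 1.0}, level=g).posterior_probability
            for g in fitted.model.group_labels
        ]
        assert len(set(per_part)) > 1  # participants genuinely differ
        assert min(per_part) <= group <= 1.0

    def test_nonconverged_fit_refuses_unless_forced(self, fitted):
        bad = MixedLMResults(
            model=fitted.model,
            config=fitted.config,
            draws={**fitted.draws, "c0": np.array([[0.0] * 50, [100.0] * 50])},
            random_draws=fitted.random_draws,
        )
        assert not bad.converged
        with pytest.raises(ConvergenceError):
            bad.test_hypothesis({"c1": 1.0})
        bad.test_hypothesis({"c1": 1.0}, force=True)  # explicit override works


class TestBattery:
    def test_battery_shape_and_bounds(self, fits):
        bat = hypothesis_battery(fits["selfreg"], fits["prediction"], fits["confidence"])
        assert len(bat) == 17 * (1 + 8)
        assert set(bat["hypothesis"]) == set(HYPOTHESES)
        assert bat["probability"].between(0, 1).all()

    def test_planted_target_level_difference_detected(self, fits):
        """Agent regulating 0.61 scale points higher at TL 90 in session 1."""
        r = fits["selfreg"].test_hypothesis(
            {"tl90:s1": 1.0, "tl60:s1": -1.0}, const=3.0
        )
        assert r.posterior_probability > 0.95

    def test_strong_prior_weight_detected_each_session(self, fits):
        for h in ("G", "H", "I"):
            _, expr, const, _ = HYPOTHESES[h]
            r = fits["prediction"].test_hypothesis(expr, const=const)
            assert r.posterior_probability > 0.95

    def test_flat_confidence_slopes_stay_undecided(self, fits):
        for h in ("L", "M", "N"):
            _, expr, const, _ = HYPOTHESES[h]
            r = fits["confidence"].test_hypothesis(expr, const=const)
            assert 0.05 < r.posterior_probability < 0.95

    def test_null_agent_session_effects_near_half(self):
        """No session change and symmetric prior weight: D, E, F, K average
        near 0.5 over seeds (each study carries its own sampling noise)."""
        probs = {h: [] for h in ("D", "E", "F", "K")}
        for seed in (29, 30, 31, 32):
            beh = simulate_behaviour_study(null_agent(), n_participants=8, seed=seed)
            wide = build_analysis_table(beh)
            long = long_format_distances(wide)
            fits = fit_all_models(wide, long, MCMCConfig.trimmed(seed=seed))
            for h in probs:
                model_key, expr, const, _ = HYPOTHESES[h]
                probs[h].append(
                    fits[model_key].test_hypothesis(expr, const=const).posterior_probability
                )
        for h, values in probs.items():
            assert abs(np.mean(values) - 0.5) < 0.25, (h, values)


class TestModelBuilders:
    def test_selfreg_cells(self):
        beh = simulate_behaviour_study(n_participants=2, seed=0)
        wide = build_analysis_table(beh)
        model = SelfRegulationModel.from_dataframe(wide)
        assert model.fixed_names == [
            "tl60:s1", "tl60:s2", "tl60:s3", "tl90:s1", "tl90:s2", "tl90:s3",
        ]
        assert model.X.sum(axis=1).max() == 1.0  # one-hot cells

    def test_prediction_long_cells(self):
        beh = simulate_behaviour_study(n_participants=2, seed=0)
        long = long_format_distances(build_analysis_table(beh))
        model = PredictionModel.from_dataframe(long)
        assert "real:s1" in model.fixed_names and "prior:s3" in model.fixed_names
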