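"""Hierarchical Bayesian linear models and the directional hypothesis battery.

Three multi-level Gaussian linear models summarise the behavioural data,
each with random intercepts and slopes per participant:

* **self-regulation** — target-centred feedback ~ target level x session
  (cell means);
* **prediction** — prediction distance ~ reference (real vs prior) x
  session, on the long-format distance table;
* **confidence** — confidence ~ session + per-session slopes on
  prediction accuracy and on the achieved self-regulation value.

Models follow the statsmodels idiom: build a model object from a
DataFrame, call :meth:`fit` to obtain a results object carrying posterior
draws, diagnostics and ``summary()``, then query directional hypotheses.
A directional hypothesis is a linear combination of effects; its
posterior probability is the fraction of retained MCMC draws in which
the combination is positive, with 0.95 as the conventional decision
threshold. At the participant level, the participant's random effects
are added to the fixed part before thresholding.

Sampling uses a blocked Gibbs sampler with conjugate updates (flat prior
on fixed effects, inverse-gamma on the residual variance,
inverse-Wishart on the random-effect covariance) — see docs/methods.md
for the prior constants. Convergence is checked with split-R-hat and
effective sample size; hypothesis evaluation refuses on R-hat >= 1.01
unless forced. Any sampler producing named draws can stand in for the
built-in one via :class:`MixedLMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = [
    "MCMCConfig",
    "BayesMixedLM",
    "MixedLMResults",
    "HypothesisResult",
    "SelfRegulationModel",
    "PredictionModel",
    "ConfidenceModel",
    "HYPOTHESES",
    "hypothesis_battery",
    "ConvergenceError",
]

RHAT_LIMIT = 1.01
DECISION_THRESHOLD = 0.95


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule: 2 chains x 5000 iterations, 2000 warm-up."""

    chains: int = 2
    iterations: int = 5000
    warmup: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("need 0 <= warmup < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained(self) -> int:
        return self.chains * (self.iterations - self.warmup)

    @classmethod
    def trimmed(cls, seed: int = 0) -> "MCMCConfig":
        """Shorter schedule (2 x 1500, 500 warm-up) for simulation batteries."""
        return cls(chains=2, iterations=1500, warmup=500, seed=seed)


@dataclass
class HypothesisResult:
    name: str
    level: str  # "group" or a participant label
    posterior_probability: float
    n_draws: int
    description: str = ""

    @property
    def decision(self) -> bool:
        return self.posterior_probability > DECISION_THRESHOLD


class BayesMixedLM:
    """Gaussian linear mixed model estimated by blocked Gibbs sampling.

    Every fixed effect carries a participant-level random deviation
    (random intercepts and slopes): row i of group j contributes
    ``y_i ~ N(x_i' (beta + b_j), sigma^2)`` with ``b_j ~ N(0, Sigma_b)``.
    The sampler works in the hierarchically centred parameterisation
    ``eta_j = beta + b_j`` (``eta_j ~ N(beta, Sigma_b)``), whose
    conditionals are conjugate and mix well even when group effects are
    large relative to the residual noise.

    Parameters
    ----------
    endog
        Outcome vector (n,).
    exog
        Design matrix (n, p), shared by the fixed and random parts.
    groups
        Group (participant) label per row.
    fixed_names
        Design column names.
    """

    def __init__(self, endog, exog, groups, fixed_names):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        self.groups = np.asarray(groups)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.groups) != n:
            raise ValueError("endog, exog and groups must align")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.fixed_names = list(fixed_names)
        if len(self.fixed_names) != self.X.shape[1]:
            raise ValueError("fixed_names must match the design width")
        self.group_labels = list(pd.unique(self.groups))
        if len(self.group_labels) < 2:
            raise ValueError("need at least two participants for a multi-level model")

    # -- Gibbs internals ---------------------------------------------------

    def _grams(self):
        out = []
        for g in self.group_labels:
            idx = self.groups == g
            Xg, yg = self.X[idx], self.y[idx]
            out.append(
                dict(XtX=Xg.T @ Xg, Xty=Xg.T @ yg, yty=float(yg @ yg), n=int(idx.sum()))
            )
        return out

    def _run_chain(self, grams, n_iter, rng):
        q, J = self.X.shape[1], len(grams)
        n = len(self.y)
        sd_y = float(np.std(self.y)) or 1.0
        # weakly-informative conjugate priors (see docs/methods.md)
        a0 = b0 = 1e-3
        nu0 = q + 2
        S0 = np.eye(q) * (0.5 * sd_y) ** 2

        XtX_inv = np.linalg.inv(sum(g["XtX"] for g in grams))
        beta = XtX_inv @ sum(g["Xty"] for g in grams)
        eta = np.tile(beta, (J, 1))
        sigma2 = max(sd_y**2, 1e-12)
        Sigma_b = np.eye(q) * (0.5 * sd_y) ** 2

        betas = np.empty((n_iter, q))
        bs = np.empty((n_iter, J, q))
        sigmas = np.empty(n_iter)
        for it in range(n_iter):
            # per-group coefficients | rest
            Omega = np.linalg.inv(Sigma_b)
            Omega_beta = Omega @ beta
            for j, g in enumerate(grams):
                A = g["XtX"] / sigma2 + Omega
                L = np.linalg.cholesky(A)
                mu = np.linalg.solve(A, g["Xty"] / sigma2 + Omega_beta)
                eta[j] = mu + np.linalg.solve(L.T, rng.standard_normal(q))
            # population mean | eta (flat prior): N(mean(eta), Sigma_b / J)
            L_b = np.linalg.cholesky(Sigma_b / J)
            beta = eta.mean(axis=0) + L_b @ rng.standard_normal(q)
            # residual variance | eta
            rss = sum(
                g["yty"] - 2.0 * eta[j] @ g["Xty"] + eta[j] @ g["XtX"] @ eta[j]
                for j, g in enumerate(grams)
            )
            sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * max(rss, 1e-12)))
            # random-effect covariance | eta, beta
            dev = eta - beta
            S = S0 + dev.T @ dev
            Sigma_b = np.atleast_2d(invwishart.rvs(df=nu0 + J, scale=S, random_state=rng))

            betas[it] = beta
            bs[it] = dev
            sigmas[it] = np.sqrt(sigma2)
        return betas, bs, sigmas

    def fit(self, cfg: MCMCConfig | None = None) -> "MixedLMResults":
        cfg = cfg or MCMCConfig()
        grams = self._grams()
        kept = cfg.iterations - cfg.warmup
        q, J = self.X.shape[1], len(grams)
        betas = np.empty((cfg.chains, kept, q))
        randoms = np.empty((cfg.chains, kept, J, q))
        sigmas = np.empty((cfg.chains, kept))
        for c, ss in enumerate(np.random.SeedSequence(cfg.seed).spawn(cfg.chains)):
            rng = np.random.default_rng(ss)
            bet, bs, sig = self._run_chain(grams, cfg.iterations, rng)
            betas[c] = bet[cfg.warmup :]
            randoms[c] = bs[cfg.warmup :]
            sigmas[c] = sig[cfg.warmup :]
        draws = {name: betas[:, :, i] for i, name in enumerate(self.fixed_names)}
        draws["sigma"] = sigmas
        return MixedLMResults(
            model=self,
            config=cfg,
            draws=draws,
            random_draws=randoms,
        )


class MixedLMResults:
    """Posterior draws, diagnostics and hypothesis tests for a fitted model."""

    def __init__(self, model: BayesMixedLM, config: MCMCConfig, draws, random_draws):
        self.model = model
        self.config = config
        self.draws = draws  # name -> (chains, kept)
        self.random_draws = random_draws  # (chains, kept, J, q)
        self._idata = az.from_dict(posterior=draws)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(self._idata)
            ess = az.ess(self._idata)
        self.rhat = {k: float(rhat[k].values) for k in draws}
        self.ess = {k: float(ess[k].values) for k in draws}

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_LIMIT

    @property
    def n_draws(self) -> int:
        return self.config.retained

    def summary(self) -> pd.DataFrame:
        """Posterior means, sds, 95% credible intervals and diagnostics."""
        rows = []
        for name, d in self.draws.items():
            flat = d.reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append(
                {
                    "effect": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "ci_2.5%": lo,
                    "ci_97.5%": hi,
                    "rhat": self.rhat[name],
                    "ess": self.ess[name],
                }
            )
        return pd.DataFrame(rows).set_index("effect")

    def _expression_draws(self, expression, const, level):
        val = np.full(self.random_draws.shape[:2], float(const))
        for name, w in expression.items():
            if name not in self.draws:
                raise KeyError(f"unknown effect name {name!r}")
            val = val + w * self.draws[name]
        if level != "group":
            labels = self.model.group_labels
            if level not in labels:
                raise KeyError(f"unknown participant {level!r}")
            j = labels.index(level)
            for name, w in expression.items():
                qi = self.model.fixed_names.index(name)
                val = val + w * self.random_draws[:, :, j, qi]
        return val

    def test_hypothesis(
        self,
        expression: dict[str, float],
        *,
        const: float = 0.0,
        level: str = "group",
        name: str = "",
        description: str = "",
        force: bool = False,
    ) -> HypothesisResult:
        """Posterior probability that a linear combination of effects is > 0.

        ``expression`` maps effect names to weights; ``const`` adds a fixed
        offset (used when the combination is stated on a shifted scale).
        ``level='group'`` uses fixed effects only; a participant label adds
        that participant's random effects.
        """
        if not self.converged and not force:
            raise ConvergenceError(
                f"max split-R-hat {self.max_rhat:.3f} >= {RHAT_LIMIT}; "
                "pass force=True to evaluate anyway"
            )
        val = self._expression_draws(expression, const, level)
        prob = float((val > 0).mean())
        return HypothesisResult(
            name=name,
            level=str(level),
            posterior_probability=prob,
            n_draws=val.size,
            description=description,
        )


def _cells(df: pd.DataFrame, factor_a: str, values_a, factor_b: str, values_b, fmt):
    names, cols = [], []
    for va in values_a:
        for vb in values_b:
            names.append(fmt(va, vb))
            cols.append(
                ((df[factor_a] == va) & (df[factor_b] == vb)).to_numpy(dtype=float)
            )
    return names, np.column_stack(cols)


class SelfRegulationModel(BayesMixedLM):
    """Target-centred self-regulation ~ target level x session (cell means)."""

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "SelfRegulationModel":
        sessions = sorted(table["session"].unique())
        names, X = _cells(
            table, "target_level", (60, 90), "session", sessions,
            lambda tl, s: f"tl{tl}:s{s}",
        )
        return cls(
            endog=table["centred_selfreg"],
            exog=X,
            groups=table["participant"],
            fixed_names=names,
        )


class PredictionModel(BayesMixedLM):
    """Prediction distance ~ reference (real | prior) x session (cell means)."""

    @classmethod
    def from_dataframe(cls, long_table: pd.DataFrame) -> "PredictionModel":
        sessions = sorted(long_table["session"].unique())
        names, X = _cells(
            long_table, "reference", ("real", "prior"), "session", sessions,
            lambda ref, s: f"{ref}:s{s}",
        )
        return cls(
            endog=long_table["distance"],
            exog=X,
            groups=long_table["participant"],
            fixed_names=names,
        )


class ConfidenceModel(BayesMixedLM):
    """Confidence ~ session + per-session accuracy and self-regulation slopes.

    Accuracy (|prediction - feedback|) and the achieved feedback value are
    grand-mean centred, so the per-session intercepts read as session mean
    confidence at average accuracy and regulation. Fitting the slopes via
    session interactions keeps every hypothesis readable as a single
    coefficient (or a difference of two).
    """

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "ConfidenceModel":
        sessions = sorted(table["session"].unique())
        acc = (table["pred_accuracy"] - table["pred_accuracy"].mean()).to_numpy()
        nf = (table["nf_value"] - table["nf_value"].mean()).to_numpy()
        names, cols = [], []
        for prefix, values in (("", None), ("acc:", acc), ("nf:", nf)):
            for s in sessions:
                ind = (table["session"] == s).to_numpy(dtype=float)
                names.append(f"{prefix}s{s}" if prefix else f"s{s}")
                cols.append(ind if values is None else ind * values)
        return cls(
            endog=table["confidence"],
            exog=np.column_stack(cols),
            groups=table["participant"],
            fixed_names=names,
        )


#: The directional hypothesis battery, reconstructed from the study's
#: results narrative: (model key, effect weights, constant offset,
#: description). Probabilities are the posterior mass of the expression
#: being positive.
HYPOTHESES: dict[str, tuple[str, dict[str, float], float, str]] = {
    "A": ("selfreg", {"tl90:s1": 1, "tl60:s1": -1}, 3.0,
          "higher regulation for TL 90 than TL 60 in session 1 (feedback scale)"),
    "B": ("selfreg", {"tl60:s1": 1}, 0.0, "overshoot of the TL 60 target in session 1"),
    "C": ("selfreg", {"tl90:s1": -1}, 0.0, "undershoot of the TL 90 target in session 1"),
    "D": ("selfreg", {"tl60:s1": 1, "tl60:s3": -1}, 0.0,
          "TL 60 regulation moves toward the target from session 1 to 3"),
    "E": ("selfreg", {"tl90:s3": 1, "tl90:s1": -1}, 0.0,
          "TL 90 regulation moves toward the target from session 1 to 3"),
    "F": ("prediction", {"real:s1": 1, "real:s3": -1}, 0.0,
          "prediction error (distance to real value) decreases from session 1 to 3"),
    "G": ("prediction", {"real:s1": 1, "prior:s1": -1}, 0.0,
          "predictions closer to the running-average prior than to the real value, session 1"),
    "H": ("prediction", {"real:s2": 1, "prior:s2": -1}, 0.0,
          "predictions closer to the prior than to the real value, session 2"),
    "I": ("prediction", {"real:s3": 1, "prior:s3": -1}, 0.0,
          "predictions closer to the prior than to the real value, session 3"),
    "J": ("prediction", {"real:s1": 1, "real:s3": -1, "prior:s1": -1, "prior:s3": 1}, 0.0,
          "distance to the real value decreases more than distance to the prior"),
    "K": ("confidence", {"s3": 1, "s1": -1}, 0.0, "confidence increases from session 1 to 3"),
    "L": ("confidence", {"acc:s1": -1}, 0.0,
          "confidence tracks prediction accuracy in session 1 (negative error slope)"),
    "M": ("confidence", {"acc:s2": -1}, 0.0, "confidence tracks prediction accuracy, session 2"),
    "N": ("confidence", {"acc:s3": -1}, 0.0, "confidence tracks prediction accuracy, session 3"),
    "O": ("confidence", {"nf:s1": 1}, 0.0,
          "confidence increases with the achieved self-regulation value, session 1"),
    "P": ("confidence", {"nf:s2": 1}, 0.0, "confidence tracks self-regulation, session 2"),
    "Q": ("confidence", {"nf:s3": 1}, 0.0, "confidence tracks self-regulation, session 3"),
}


def hypothesis_battery(
    selfreg: MixedLMResults,
    prediction: MixedLMResults,
    confidence: MixedLMResults,
    *,
    force: bool = False,
) -> pd.DataFrame:
    """Evaluate hypotheses A-Q at group level and per participant.

    Returns one row per hypothesis x (group + each participant) with the
    posterior probability and the 0.95 decision flag.
    """
    fits = {"selfreg": selfreg, "prediction": prediction, "confidence": confidence}
    participants = fits["selfreg"].model.group_labels
    rows = []
    for hid, (model_key, expr, const, desc) in HYPOTHESES.items():
        res = fits[model_key]
        for level in ["group"] + list(participants):
            r = res.test_hypothesis(
                expr, const=const, level=level, name=hid, description=desc, force=force
            )
            rows.append(
                {
                    "hypothesis": hid,
                    "model": model_key,
                    "level": r.level,
                    "probability": r.posterior_probability,
                    "pass_95": r.decision,
                    "description": desc,
                }
            )
    return pd.DataFrame(rows)


def fit_all_models(
    analysis_table: pd.DataFrame,
    long_table: pd.DataFrame,
    cfg: MCMCConfig | None = None,
) -> dict[str, MixedLMResults]:
    """Fit the three models with per-model seeds derived from the config seed."""
    cfg = cfg or MCMCConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3) % (2**31)
    out = {}
    specs = [
        ("selfreg", SelfRegulationModel, analysis_table),
        ("prediction", PredictionModel, long_table),
        ("confidence", ConfidenceModel, analysis_table),
    ]
    for i, (key, model_cls, table) in enumerate(specs):
        model = model_cls.from_dataframe(table)
        out[key] = model.fit(
            MCMCConfig(cfg.chains, cfg.iterations, cfg.warmup, int(seeds[i]))
        )
    return out
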