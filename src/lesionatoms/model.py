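"""Bayesian hierarchical outcome model with hemisphere-grouped dispersions.

One model per cognitive outcome. The generative structure is

    tau        ~ HalfNormal(hyperprior_scale)          joint hyperprior
    sigma_h    ~ HalfNormal(tau),  h in {L, R}         hemisphere dispersions
    beta_{h,a} ~ Normal(0, sigma_h^2)                  atom coefficients
    gamma_j    ~ Normal(0, covariate_prior_sd^2)       covariate coefficients
    alpha      ~ Normal(0, 1)                          intercept
    sigma_eps  ~ HalfNormal(noise_prior_scale)         residual scale
    y_i        ~ Normal(alpha + H_i beta + x_i gamma, sigma_eps^2)

The joint dispersion prior per hemisphere lets the posterior of sigma_L and
sigma_R quantify each hemisphere's predictive relevance across all of its
atoms. Internally beta is non-centred (beta = sigma_h * b, b ~ N(0,1)) to
avoid funnel pathologies, and positive scales are sampled on the log scale
with the Jacobian correction. Posterior draws come from the package's own
No-U-Turn sampler (:mod:`lesionatoms.nuts`); convergence problems set flags
in the diagnostics rather than raising, so sensitivity reruns can proceed
and be inspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp, log

import arviz as az
import numpy as np
import pandas as pd

from .atoms import AtomLoadings
from .errors import AlignmentError, DomainError, InvalidConfigError, UndefinedStatisticError
from .nuts import ChainResult, _adaptation_windows, sample_chain
from .parcellation import zscore
from .relevance import hpdi
from .simulate import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Sampler and prior settings for one outcome model.

    ``include_lesion_volume=False`` reproduces the reduced covariate set
    used when the volume covariate destabilizes a model (the visuospatial
    outcome in the motivating analysis). ``clamp``, when given, fixes the
    scale parameters (keys ``tau``, ``sigma_left``, ``sigma_right``,
    ``sigma_eps``) and samples only the Gaussian location block — the
    configuration whose posterior has a ridge-regression closed form.
    """

    outcome_name: str = "outcome"
    include_lesion_volume: bool = True
    hyperprior_scale: float = 0.5
    covariate_prior_sd: float = 1.0
    noise_prior_scale: float = 1.0
    draws: int = 3500
    tune: int = 1000
    chains: int = 4
    target_accept: float = 0.9
    max_treedepth: int = 10
    seed: int = 0
    clamp: dict | None = None

    def __post_init__(self) -> None:
        if self.draws < 1 or self.tune < 0 or self.chains < 1:
            raise InvalidConfigError("draws >= 1, tune >= 0 and chains >= 1 required")
        for name in ("hyperprior_scale", "covariate_prior_sd", "noise_prior_scale"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise InvalidConfigError("target_accept must lie in (0, 1)")


@dataclass
class ModelData:
    """Aligned, complete-case model inputs (outcome z-scored)."""

    H: np.ndarray  # n x 2k standardized slotted loadings
    X: np.ndarray  # n x p covariates in fixed column order
    y: np.ndarray  # n, z-scored
    covariate_names: list[str]
    atom_names: list[str]
    patient_ids: list[str]
    complete_case_mask: np.ndarray
    outcome_name: str = "outcome"

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.H.shape[1] // 2


def build_model_data(
    loadings: AtomLoadings | pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: pd.Series,
    include_lesion_volume: bool = True,
    outcome_name: str = "outcome",
) -> ModelData:
    """Assemble row-aligned complete-case model inputs for one outcome.

    Rows with a missing outcome are dropped (per-outcome complete cases; no
    imputation) and the retained outcome values are z-scored.
    """
    H_df = loadings.standardized() if isinstance(loadings, AtomLoadings) else loadings
    if not (H_df.index.equals(covariates.index) and H_df.index.equals(outcome.index)):
        raise AlignmentError("loadings, covariates and outcome must share an index")
    cols = [
        c for c in COVARIATE_COLUMNS if include_lesion_volume or c != "lesion_volume"
    ]
    missing_cols = [c for c in cols if c not in covariates.columns]
    if missing_cols:
        raise AlignmentError(f"covariate table missing columns {missing_cols}")
    mask = outcome.notna().to_numpy() & covariates[cols].notna().all(axis=1).to_numpy()
    y_raw = outcome.to_numpy(dtype=float)[mask]
    if len(y_raw) < 2 or np.ptp(y_raw) == 0:
        raise DomainError("outcome is constant or has fewer than 2 observed values")
    return ModelData(
        H=H_df.to_numpy(dtype=float)[mask],
        X=covariates[cols].to_numpy(dtype=float)[mask],
        y=zscore(y_raw),
        covariate_names=cols,
        atom_names=list(H_df.columns),
        patient_ids=[str(i) for i in H_df.index[mask]],
        complete_case_mask=mask,
        outcome_name=outcome_name,
    )


class LesionOutcomeModel:
    """Log-posterior (and gradient) of the hierarchical model.

    The unconstrained parameter vector is
    ``[alpha, b (2k), gamma (p), log tau, log sigma_L, log sigma_R,
    log sigma_eps]``; with clamped scales only the first ``1 + 2k + p``
    entries are sampled.
    """

    def __init__(self, data: ModelData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.k = data.k
        self.p = data.X.shape[1]
        self.n = data.n
        if np.ptp(data.y) == 0:
            raise DomainError("constant outcome: model is unidentifiable")
        Z = np.column_stack([np.ones(self.n), data.H, data.X])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            logger.warning(
                "design matrix for %s is rank-deficient (%d cols)",
                data.outcome_name, Z.shape[1],
            )
        self.H_L = np.ascontiguousarray(data.H[:, : self.k])
        self.H_R = np.ascontiguousarray(data.H[:, self.k :])
        self.X = np.ascontiguousarray(data.X)
        self.y = data.y
        self.clamp = dict(spec.clamp) if spec.clamp else None
        self.dim = 1 + 2 * self.k + self.p + (0 if self.clamp else 4)
        # fused design for fast log-density evaluation: two matvecs per call
        self._Z = np.ascontiguousarray(
            np.column_stack([np.ones(self.n), data.H, data.X])
        )
        self._Zt = np.ascontiguousarray(self._Z.T)
        self._sl_b_left = slice(1, 1 + self.k)
        self._sl_b_right = slice(1 + self.k, 1 + 2 * self.k)
        self._sl_gamma = slice(1 + 2 * self.k, 1 + 2 * self.k + self.p)
        self._inv_cov_sd2 = 1.0 / spec.covariate_prior_sd**2
        self._inv_hyper2 = 1.0 / spec.hyperprior_scale**2
        self._inv_noise2 = 1.0 / spec.noise_prior_scale**2

    def logp_and_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        k, p, n = self.k, self.p, self.n
        alpha = q[0]
        b_l = q[self._sl_b_left]
        b_r = q[self._sl_b_right]
        gamma = q[self._sl_gamma]
        if self.clamp:
            s_l = self.clamp["sigma_left"]
            s_r = self.clamp["sigma_right"]
            s_e = self.clamp["sigma_eps"]
        else:
            # scales are non-centred too: sigma_h = tau * e_h, e_h ~ HalfNormal(1),
            # which removes the tau-sigma funnel from the sampled geometry
            lt, ll, lr, le = q[-4], q[-3], q[-2], q[-1]
            tau = exp(lt)
            e_l, e_r = exp(ll), exp(lr)
            s_l, s_r, s_e = tau * e_l, tau * e_r, exp(le)

        theta = np.empty(1 + 2 * k + p)
        theta[0] = alpha
        np.multiply(b_l, s_l, out=theta[self._sl_b_left])
        np.multiply(b_r, s_r, out=theta[self._sl_b_right])
        theta[self._sl_gamma] = gamma
        r = self.y - self._Z @ theta
        zr = self._Zt @ r  # [sum(r), H_L'r, H_R'r, X'r] in one pass
        rss = float(r @ r)
        inv_se2 = 1.0 / (s_e * s_e)

        logp = (
            -0.5 * alpha * alpha
            - 0.5 * float(b_l @ b_l + b_r @ b_r)
            - 0.5 * float(gamma @ gamma) * self._inv_cov_sd2
            - n * log(s_e)
            - 0.5 * rss * inv_se2
        )
        grad = np.empty_like(q)
        grad[0] = -alpha + zr[0] * inv_se2
        zr_l = zr[self._sl_b_left]
        zr_r = zr[self._sl_b_right]
        grad[self._sl_b_left] = -b_l + (s_l * inv_se2) * zr_l
        grad[self._sl_b_right] = -b_r + (s_r * inv_se2) * zr_r
        grad[self._sl_gamma] = -gamma * self._inv_cov_sd2 + zr[self._sl_gamma] * inv_se2
        if not self.clamp:
            logp += (
                -0.5 * tau * tau * self._inv_hyper2
                + lt
                - 0.5 * (e_l * e_l + e_r * e_r)
                + ll
                + lr
                - 0.5 * s_e * s_e * self._inv_noise2
                + le
            )
            # dL/dsigma_h = sigma_h^-1 * likelihood pull; A_h @ r == b_h @ (H_h' r)
            pull_l = (s_l * inv_se2) * float(b_l @ zr_l)
            pull_r = (s_r * inv_se2) * float(b_r @ zr_r)
            grad[-4] = -tau * tau * self._inv_hyper2 + 1.0 + pull_l + pull_r
            grad[-3] = -e_l * e_l + 1.0 + pull_l
            grad[-2] = -e_r * e_r + 1.0 + pull_r
            grad[-1] = -s_e * s_e * self._inv_noise2 + 1.0 - n + rss * inv_se2
        return logp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        q = 0.1 * rng.standard_normal(self.dim)
        if not self.clamp:
            # start scales near their prior medians, jittered
            q[-4] = np.log(self.spec.hyperprior_scale * 0.6) + 0.1 * rng.standard_normal()
            q[-3:-1] = np.log(0.6) + 0.1 * rng.standard_normal(2)
            q[-1] = np.log(max(self.y.std(), 0.1)) + 0.05 * rng.standard_normal()
        return q


def build_model(data: ModelData, spec: ModelSpec) -> LesionOutcomeModel:
    """Validate inputs and assemble the log-posterior handle."""
    model = LesionOutcomeModel(data, spec)
    if spec.clamp is not None:
        missing = {"tau", "sigma_left", "sigma_right", "sigma_eps"} - set(spec.clamp)
        if missing:
            raise InvalidConfigError(f"clamp missing keys {sorted(missing)}")
    return model


@dataclass
class PosteriorSamples:
    """Posterior draws (chains x draws [x dim]) on the natural scale."""

    alpha: np.ndarray
    beta: np.ndarray  # chains x draws x 2k (sigma_h * b, original scale)
    gamma: np.ndarray  # chains x draws x p
    tau: np.ndarray
    sigma_left: np.ndarray
    sigma_right: np.ndarray
    sigma_eps: np.ndarray
    atom_names: list[str]
    covariate_names: list[str]
    diagnostics: dict = field(default_factory=dict)
    spec: ModelSpec | None = None

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    @property
    def k(self) -> int:
        return self.beta.shape[2] // 2

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains (draws first axis)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def beta_hemisphere(self, hemisphere: str) -> np.ndarray:
        """Pooled atom-coefficient draws of one hemisphere, (draws, k)."""
        pooled = self.pooled("beta")
        return pooled[:, : self.k] if hemisphere == "left" else pooled[:, self.k :]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat export: one row per draw, one column per parameter."""
        cols = {
            "chain": np.repeat(np.arange(self.n_chains), self.n_draws),
            "draw": np.tile(np.arange(self.n_draws), self.n_chains),
            "alpha": self.pooled("alpha"),
            "tau": self.pooled("tau"),
            "sigma_left": self.pooled("sigma_left"),
            "sigma_right": self.pooled("sigma_right"),
            "sigma_eps": self.pooled("sigma_eps"),
        }
        beta = self.pooled("beta")
        for j, name in enumerate(self.atom_names):
            cols[f"beta_{name}"] = beta[:, j]
        gamma = self.pooled("gamma")
        for j, name in enumerate(self.covariate_names):
            cols[f"gamma_{name}"] = gamma[:, j]
        return pd.DataFrame(cols)

    def to_inferencedata(self) -> az.InferenceData:
        return az.from_dict(
            posterior={
                "alpha": self.alpha,
                "beta": self.beta,
                "gamma": self.gamma,
                "tau": self.tau,
                "sigma_left": self.sigma_left,
                "sigma_right": self.sigma_right,
                "sigma_eps": self.sigma_eps,
            }
        )


def _finite_values(dataset) -> np.ndarray:
    values = np.concatenate(
        [np.atleast_1d(dataset[v].values).ravel() for v in dataset.data_vars]
    )
    return values[np.isfinite(values)]  # constant (clamped) parameters give NaN


def _diagnostics(samples: PosteriorSamples, n_divergent: int) -> dict:
    idata = samples.to_inferencedata()
    with np.errstate(invalid="ignore", divide="ignore"):
        ess_vals = _finite_values(az.ess(idata))
    min_ess = float(ess_vals.min()) if ess_vals.size else float("nan")
    if samples.n_chains >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat_vals = _finite_values(az.rhat(idata))
        max_rhat = float(rhat_vals.max()) if rhat_vals.size else float("nan")
        rhat_ok = not np.isfinite(max_rhat) or max_rhat <= 1.01
    else:  # split-R-hat needs >= 2 chains
        max_rhat, rhat_ok = float("nan"), True
    total = samples.n_chains * samples.n_draws
    divergence_rate = n_divergent / total
    return {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "n_divergent": int(n_divergent),
        "divergence_rate": divergence_rate,
        "converged": bool(rhat_ok and divergence_rate <= 0.001),
    }


def sample_posterior(
    model: LesionOutcomeModel, spec: ModelSpec, engine: str = "numba"
) -> PosteriorSamples:
    """Draw from the posterior with NUTS; never raises on poor convergence —
    the diagnostics carry a ``converged`` flag instead.

    ``engine="numba"`` (default) runs the compiled kernel; ``"python"``
    runs the readable reference engine in :mod:`lesionatoms.nuts` (same
    algorithm, used for cross-validation in the test suite). Scale-clamped
    models have an exactly Gaussian posterior with strong linear
    correlations, so they are routed through the reference engine with a
    dense mass matrix, which samples them nearly independently.
    """
    k, p = model.k, model.p
    chains = []
    n_divergent = 0
    dense_mass = bool(model.clamp)
    if model.clamp and engine == "numba":
        engine = "python"  # the compiled kernel is diagonal-metric only
    if engine == "numba":
        from . import _kernel

        mdl = _kernel.make_model_tuple(model)
        window_ends = np.asarray(_adaptation_windows(spec.tune), dtype=np.int64)
    elif engine != "python":
        raise InvalidConfigError(f"unknown sampling engine {engine!r}")
    for chain in range(spec.chains):
        rng = np.random.default_rng([int(spec.seed) % 2**31, 17, chain])
        q0 = model.initial_point(rng)
        logp0, _ = model.logp_and_grad(q0)
        if not np.isfinite(logp0):
            raise RuntimeError(
                f"sampler initialization failed for chain {chain} "
                f"({model.data.outcome_name}): non-finite log density"
            )
        if engine == "numba":
            draws, ndiv, mean_accept, eps, mean_depth = _kernel.run_chain(
                mdl, q0, spec.draws, spec.tune, window_ends,
                spec.target_accept, spec.max_treedepth, rng,
            )
            result = ChainResult(
                draws=draws,
                n_divergent=int(ndiv),
                mean_accept=float(mean_accept),
                step_size=float(eps),
                mean_tree_depth=float(mean_depth),
            )
        else:
            result = sample_chain(
                model.logp_and_grad,
                q0,
                n_draws=spec.draws,
                n_warmup=spec.tune,
                rng=rng,
                target_accept=spec.target_accept,
                max_treedepth=spec.max_treedepth,
                dense_mass=dense_mass,
            )
        chains.append(result)
        n_divergent += result.n_divergent
    Q = np.stack([c.draws for c in chains])  # chains x draws x dim

    alpha = Q[:, :, 0]
    b = Q[:, :, 1 : 1 + 2 * k]
    gamma = Q[:, :, 1 + 2 * k : 1 + 2 * k + p]
    if model.clamp:
        shape = alpha.shape
        tau = np.full(shape, model.clamp["tau"])
        sigma_left = np.full(shape, model.clamp["sigma_left"])
        sigma_right = np.full(shape, model.clamp["sigma_right"])
        sigma_eps = np.full(shape, model.clamp["sigma_eps"])
    else:
        tau = np.exp(Q[:, :, -4])
        sigma_left = tau * np.exp(Q[:, :, -3])
        sigma_right = tau * np.exp(Q[:, :, -2])
        sigma_eps = np.exp(Q[:, :, -1])
    beta = np.concatenate(
        [sigma_left[:, :, None] * b[:, :, :k], sigma_right[:, :, None] * b[:, :, k:]],
        axis=2,
    )
    samples = PosteriorSamples(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        tau=tau,
        sigma_left=sigma_left,
        sigma_right=sigma_right,
        sigma_eps=sigma_eps,
        atom_names=model.data.atom_names,
        covariate_names=model.data.covariate_names,
        spec=spec,
    )
    samples.diagnostics = _diagnostics(samples, n_divergent)
    samples.diagnostics.update(
        {
            "step_sizes": [c.step_size for c in chains],
            "mean_accept": float(np.mean([c.mean_accept for c in chains])),
            "mean_tree_depth": float(np.mean([c.mean_tree_depth for c in chains])),
            "draws": spec.draws,
            "tune": spec.tune,
            "chains": spec.chains,
            "seed": spec.seed,
        }
    )
    if not samples.diagnostics["converged"]:
        logger.warning(
            "model %s flagged non-converged: max R-hat %.3f, %d divergences",
            model.data.outcome_name,
            samples.diagnostics["max_rhat"],
            n_divergent,
        )
    return samples


def ridge_posterior_mean(model: LesionOutcomeModel) -> np.ndarray:
    """Gaussian closed-form posterior mean of (alpha, beta, gamma) for the
    scale-clamped model: (Z'Z / s_e^2 + D^-1)^-1 Z'y / s_e^2."""
    if not model.clamp:
        raise InvalidConfigError("closed form requires clamped scale parameters")
    k = model.k
    Z = np.column_stack([np.ones(model.n), model.H_L, model.H_R, model.X])
    prior_sd = np.concatenate(
        [
            [1.0],
            np.full(k, model.clamp["sigma_left"]),
            np.full(k, model.clamp["sigma_right"]),
            np.full(model.p, model.spec.covariate_prior_sd),
        ]
    )
    s_e2 = model.clamp["sigma_eps"] ** 2
    A = Z.T @ Z / s_e2 + np.diag(1.0 / prior_sd**2)
    return np.linalg.solve(A, Z.T @ model.y / s_e2)


def posterior_predictive_r2(
    samples: PosteriorSamples, data: ModelData, prob: float = 0.94
) -> dict:
    """Per-draw Bayesian R^2 on the fitting data, summarized over draws.

    For each draw, R^2 = Var(fitted) / (Var(fitted) + sigma_eps^2): the
    explained-variance ratio implied by that draw's linear predictor and
    residual scale.
    """
    alpha = samples.pooled("alpha")
    beta = samples.pooled("beta")
    gamma = samples.pooled("gamma")
    sigma_eps = samples.pooled("sigma_eps")
    fitted = alpha[:, None] + beta @ data.H.T + gamma @ data.X.T
    var_fit = fitted.var(axis=1)
    if np.all(var_fit == 0):
        raise UndefinedStatisticError("fitted values have zero variance in all draws")
    r2 = var_fit / (var_fit + sigma_eps**2)
    interval = hpdi(r2, prob)
    return {
        "mean": float(r2.mean()),
        "hpdi_lower": interval.lower,
        "hpdi_upper": interval.upper,
        "prob": prob,
        "draws": r2,
    }


def prior_predictive_scales(spec: ModelSpec, n_draws: int = 4000, seed: int = 0) -> dict:
    """Forward draws of (tau, sigma_L, sigma_R) from the hierarchy's prior."""
    rng = np.random.default_rng(seed)
    tau = np.abs(rng.normal(0.0, spec.hyperprior_scale, n_draws))
    sigma_left = np.abs(rng.normal(0.0, tau))
    sigma_right = np.abs(rng.normal(0.0, tau))
    return {"tau": tau, "sigma_left": sigma_left, "sigma_right": sigma_right}
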