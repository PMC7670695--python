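"""Bayesian animal models with herd and Matérn spatial effects.

The observation model is

    y = X beta + Z a + W h + M s + e,

with a ~ N(0, sigma_a^2 K) for K the pedigree (A) or genomic (G)
relationship matrix over phenotyped plus prediction animals, h ~ N(0,
sigma_h^2 I) independent herd effects, s a Matérn (nu=1) Gaussian field
over the unique herd locations, e ~ N(0, sigma_e^2 I), and beta (intercept
and any fixed covariates) given a diffuse N(0, 1000) prior.  Variance
parameters carry penalised-complexity (exponential-on-sigma) priors and
the spatial range its PC prior; see :data:`TABLE1_PRIORS` for the
per-model settings.

Inference integrates all location effects out of the Gaussian likelihood
and runs adaptive random-walk Metropolis on the log hyper-parameters
against that marginal; location effects are then drawn jointly and exactly
for each retained hyper-parameter sample by Matheron-style conditioning
(one multivariate Gaussian solve per draw).  A deterministic Henderson
mixed-model-equations solver is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .relatedness import RelationshipMatrix
from .spatial import MaternParams, matern_cov

# ---------------------------------------------------------------------------
# penalised complexity priors


@dataclass(frozen=True)
class PCPrior:
    """PC prior defined by a tail statement: P(sigma > u) = alpha for a
    standard deviation, P(rho < u) = alpha for the spatial range."""

    u: float
    alpha: float
    target: str = "sd"      # "sd" | "range"

    def __post_init__(self):
        if self.u <= 0:
            raise ValueError("u must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be strictly inside (0, 1)")
        if self.target not in ("sd", "range"):
            raise ValueError("target must be 'sd' or 'range'")

    @property
    def lam(self) -> float:
        if self.target == "sd":
            return -np.log(self.alpha) / self.u          # sigma ~ Exp(lam)
        return -np.log(self.alpha) * self.u              # p(rho) = lam/rho^2 e^{-lam/rho}

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        lam = self.lam
        if self.target == "sd":
            return np.where(x > 0, np.log(lam) - lam * x, -np.inf)
        return np.where(x > 0, np.log(lam) - 2 * np.log(x) - lam / x, -np.inf)

    def cdf(self, x) -> float:
        lam = self.lam
        if self.target == "sd":
            return 1.0 - np.exp(-lam * np.asarray(x, dtype=float))
        return np.exp(-lam / np.asarray(x, dtype=float))

    def ppf(self, p):
        lam = self.lam
        p = np.asarray(p, dtype=float)
        if self.target == "sd":
            return -np.log1p(-p) / lam
        return -lam / np.log(p)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size))

    @property
    def median(self) -> float:
        return float(self.ppf(0.5))


def pc_prior_sd(u: float, alpha: float) -> PCPrior:
    """PC prior for a standard deviation: sigma ~ Exp(-ln(alpha)/u)."""
    return PCPrior(u=u, alpha=alpha, target="sd")


def pc_prior_range(u: float, alpha: float) -> PCPrior:
    """PC prior for the Matérn range: p(rho) = (lam/rho^2) exp(-lam/rho)."""
    return PCPrior(u=u, alpha=alpha, target="range")


#: Per-model (u, alpha) prior settings for the simulated-data analyses.
TABLE1_PRIORS: dict[str, dict[str, tuple[float, float]]] = {
    "G": {"e": (0.30, 0.50), "a": (0.10, 0.50)},
    "GH": {"e": (0.15, 0.50), "a": (0.10, 0.50), "h": (0.25, 0.50)},
    "GS": {"e": (0.15, 0.50), "a": (0.10, 0.50), "s": (0.25, 0.50),
           "rho": (0.60, 0.95)},
    "GHS": {"e": (0.15, 0.50), "a": (0.10, 0.50), "h": (0.15, 0.50),
            "s": (0.10, 0.50), "rho": (0.60, 0.95)},
    # the covariate model reuses the GHS hyper-priors; covariate effects get
    # the diffuse N(0, 1000) fixed-effect prior
    "GHSC": {"e": (0.15, 0.50), "a": (0.10, 0.50), "h": (0.15, 0.50),
             "s": (0.10, 0.50), "rho": (0.60, 0.95)},
}


@dataclass
class ModelSpec:
    """Which terms the evaluation model carries, and their priors."""

    name: str
    genetic_source: str = "pedigree"        # "pedigree" | "genomic"
    use_herd: bool = False
    use_spatial: bool = False
    use_covariates: bool = False
    priors: dict = field(default_factory=dict)   # effect -> PCPrior
    prior_beta_variance: float = 1000.0

    @classmethod
    def named(cls, name: str, genetic_source: str = "pedigree",
              prior_table: dict | None = None) -> "ModelSpec":
        """The five study models: G, GH, GS, GHS, GHSC."""
        if name not in TABLE1_PRIORS:
            raise ValueError(f"unknown model {name!r}")
        table = (prior_table or TABLE1_PRIORS)[name]
        priors = {k: (pc_prior_range(*v) if k == "rho" else pc_prior_sd(*v))
                  for k, v in table.items()}
        return cls(name=name, genetic_source=genetic_source,
                   use_herd="h" in table, use_spatial="s" in table,
                   use_covariates=name.endswith("C"), priors=priors)

    @property
    def hyper_names(self) -> list[str]:
        names = ["sigma2_a"]
        if self.use_herd:
            names.append("sigma2_h")
        if self.use_spatial:
            names += ["sigma2_s", "rho"]
        names.append("sigma2_e")
        return names


@dataclass
class McmcConfig:
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 4
    target_accept: float = 0.30
    init_step: float = 0.4
    adapt_start: int = 50

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelData:
    """Inputs to one model fit, in canonical (id-sorted) order.

    ``K`` is the relationship matrix over phenotyped (first) plus
    prediction animals; ``herd_index`` maps each record to a row of
    ``herd_coords``; ``covariates`` is an optional herd-level design block.
    """

    y: np.ndarray
    herd_index: np.ndarray
    herd_coords: np.ndarray
    K: RelationshipMatrix
    obs_ids: np.ndarray
    pred_ids: np.ndarray
    covariates: np.ndarray | None = None     # (n_herds, q), already coded


def build_model_data(records: pd.DataFrame, herd_coords: np.ndarray,
                     K: RelationshipMatrix, pred_ids,
                     covariate_table: pd.DataFrame | None = None) -> ModelData:
    """Assemble :class:`ModelData` from phenotype records and a herd map.

    ``records`` needs id, herd (1-based) and y; ``herd_coords`` is indexed
    by herd-1.  Continuous covariates are standardised, the two- and
    three-level factors dummy-coded with the first level as reference.
    """
    records = records.sort_values("id")
    obs_ids = records["id"].to_numpy()
    pred_ids = np.sort(np.asarray(pred_ids, dtype=obs_ids.dtype))
    order = np.concatenate([obs_ids, pred_ids])
    cov = None
    if covariate_table is not None:
        cov = _code_covariates(covariate_table)
    return ModelData(y=records["y"].to_numpy(dtype=float),
                     herd_index=records["herd"].to_numpy() - 1,
                     herd_coords=np.asarray(herd_coords, dtype=float),
                     K=K.submatrix(order), obs_ids=obs_ids, pred_ids=pred_ids,
                     covariates=cov)


def _code_covariates(table: pd.DataFrame) -> np.ndarray:
    table = table.sort_values("herd")
    cols = []
    for c in table.columns:
        if c == "herd":
            continue
        x = table[c].to_numpy(dtype=float)
        if c in ("v7", "v8"):
            for level in np.unique(x)[1:]:       # first level = reference
                cols.append((x == level).astype(float))
        else:
            sd = x.std()
            cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
    return np.column_stack(cols)


@dataclass
class PosteriorSummary:
    """Posterior of breeding values, hyper-parameters and model fit."""

    ids: np.ndarray                 # phenotyped then prediction animals
    n_obs: int
    bv_mean: np.ndarray
    bv_sd: np.ndarray
    bv_samples: np.ndarray          # (S, n_animals)
    hyper_samples: pd.DataFrame
    fixed_mean: np.ndarray
    fixed_sd: np.ndarray
    dic: float
    diagnostics: dict

    @property
    def ebv(self) -> np.ndarray:
        return self.bv_mean[:self.n_obs]

    @property
    def pbv(self) -> np.ndarray:
        return self.bv_mean[self.n_obs:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "bv_mean": self.bv_mean,
                             "bv_sd": self.bv_sd})


# ---------------------------------------------------------------------------
# internals


def _chol_psd(mat: np.ndarray, jitter0: float = 1e-10, jitter_max: float = 1e-4):
    scale = float(np.mean(np.diag(mat))) or 1.0
    jitter = jitter0
    while True:
        try:
            return np.linalg.cholesky(mat + (jitter * scale) * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10
            if jitter > jitter_max:
                raise np.linalg.LinAlgError(
                    f"matrix not positive definite (jitter escalated to {jitter:.1e})")


# lookup table for the nu=1 Matérn correlation x*K_1(x); the argument
# x = kappa*d is shared by every range value, so one table serves the chain
_MATERN1_X = np.concatenate([[0.0], np.geomspace(1e-6, 40.0, 4096)])
_MATERN1_Y = matern_cov(_MATERN1_X, MaternParams(sigma2=1.0, rho=np.sqrt(8.0)))


def _matern1_corr(kd: np.ndarray) -> np.ndarray:
    """Interpolated nu=1 Matérn correlation (max abs error ~1e-6)."""
    return np.interp(kd, _MATERN1_X, _MATERN1_Y, right=0.0)


class _Marginal:
    """Marginal Gaussian likelihood of y with location effects integrated out."""

    def __init__(self, data: ModelData, spec: ModelSpec):
        n = data.y.size
        self.data, self.spec = data, spec
        self.n = n
        self.hidx = data.herd_index
        self.n_herds = data.herd_coords.shape[0]
        self.K_oo = data.K.matrix[:n, :n]
        self.same_herd = (self.hidx[:, None] == self.hidx[None, :]).astype(float)
        X = [np.ones((n, 1))]
        if spec.use_covariates:
            if data.covariates is None:
                raise ValueError("model includes covariates but none supplied")
            X.append(data.covariates[self.hidx])
        self.X = np.hstack(X)
        self.XXt = spec.prior_beta_variance * (self.X @ self.X.T)
        self.herd_dist = cdist(data.herd_coords, data.herd_coords)
        self._gather = (self.hidx[:, None] * self.n_herds + self.hidx[None, :]).ravel()
        self._eye = np.eye(n)
        self._corr_cache = (None, None)

    def spatial_corr(self, rho: float) -> np.ndarray:
        if self._corr_cache[0] != rho:
            C = _matern1_corr(np.sqrt(8.0) / rho * self.herd_dist)
            self._corr_cache = (rho, C)
        return self._corr_cache[1]

    def build_V(self, hp: dict) -> np.ndarray:
        V = hp["sigma2_a"] * self.K_oo
        V += self.XXt
        V += hp["sigma2_e"] * self._eye
        if self.spec.use_herd:
            V += hp["sigma2_h"] * self.same_herd
        if self.spec.use_spatial:
            C = self.spatial_corr(hp["rho"])
            V += hp["sigma2_s"] * C.take(self._gather).reshape(self.n, self.n)
        return V

    def loglik(self, hp: dict) -> tuple[float, tuple]:
        V = self.build_V(hp)
        try:
            cf = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        alpha = cho_solve(cf, self.data.y, check_finite=False)
        ll = -0.5 * (self.n * np.log(2 * np.pi) + logdet + self.data.y @ alpha)
        return float(ll), cf


def _log_prior(spec: ModelSpec, hp: dict) -> float:
    """Prior density on the log-parameterisation (with Jacobian)."""
    lp = 0.0
    for name in spec.hyper_names:
        key = name.split("_")[-1] if name.startswith("sigma2") else "rho"
        prior = spec.priors[key]
        x = hp[name]
        if name == "rho":
            lp += float(prior.logpdf(x)) + np.log(x)          # theta = log rho
        else:
            sd = np.sqrt(x)
            lp += float(prior.logpdf(sd)) + np.log(sd / 2.0)  # theta = log sigma^2
    return lp


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    tau = 1.0
    for k in range(1, min(n // 2, 500)):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


# ---------------------------------------------------------------------------
# fitting


def fit(data: ModelData, spec: ModelSpec, mcmc: McmcConfig | None = None,
        seed=None, fixed_hypers: dict | None = None) -> PosteriorSummary:
    """Sample the posterior of one evaluation model.

    With ``fixed_hypers`` (a full map of the model's hyper-parameters) the
    Metropolis stage is skipped and only exact conditional draws of the
    location effects are made — the posterior mean then coincides with the
    Henderson mixed-model solution.
    """
    mcmc = mcmc or McmcConfig()
    rng = np.random.default_rng(seed)
    marg = _Marginal(data, spec)
    names = spec.hyper_names
    d = len(names)

    def unpack(theta):
        return {k: float(np.exp(t)) for k, t in zip(names, theta)}

    if fixed_hypers is not None:
        missing = set(names) - set(fixed_hypers)
        if missing:
            raise ValueError(f"fixed_hypers missing {sorted(missing)}")
        kept = np.tile([np.log(fixed_hypers[k]) for k in names], (mcmc.n_samples, 1))
        accept_rate = 1.0
    else:
        theta = np.log(_moment_init(marg, spec, names))
        lp, _ = marg.loglik(unpack(theta))
        lp += _log_prior(spec, unpack(theta))
        kept = np.empty((mcmc.n_samples, d))
        n_kept = 0
        # adaptive random-walk Metropolis (Haario-style with scale tuning)
        log_step = np.log(mcmc.init_step / np.sqrt(d))
        mean = theta.copy()
        cov = np.eye(d)
        accepted = 0
        for it in range(mcmc.n_iter):
            if it < mcmc.adapt_start:
                prop_cov = np.exp(2 * log_step) * np.eye(d)
            else:
                prop_cov = np.exp(2 * log_step) * (cov + 1e-8 * np.eye(d))
            prop = rng.multivariate_normal(theta, prop_cov)
            ll, _ = marg.loglik(unpack(prop))
            lp_prop = ll + _log_prior(spec, unpack(prop))
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                theta, lp = prop, lp_prop
                accepted += 1
            if it < mcmc.burn_in:
                # Robbins-Monro on the global scale, recursive moment updates
                g = (it + 2) ** -0.6
                log_step += g * ((1.0 if accept else 0.0) - mcmc.target_accept)
                delta = theta - mean
                mean += g * delta
                cov = (1 - g) * cov + g * np.outer(delta, delta)
            elif (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1 \
                    and n_kept < mcmc.n_samples:
                kept[n_kept] = theta
                n_kept += 1
        kept = kept[:n_kept]
        accept_rate = accepted / mcmc.n_iter
        if accept_rate < 0.05:
            raise RuntimeError(
                f"Metropolis chain diverged: acceptance rate {accept_rate:.3f} "
                f"after adaptation (model {spec.name})")

    summary = _draw_effects(marg, spec, kept, names, rng)
    summary.diagnostics.update(
        acceptance_rate=float(accept_rate),
        ess={k: _ess(np.exp(kept[:, i])) for i, k in enumerate(names)})
    return summary


def _moment_init(marg: "_Marginal", spec: ModelSpec, names: list) -> np.ndarray:
    """Chain start from a crude within/between-herd variance decomposition.

    The initial point only has to land in the bulk of the posterior; the
    within-herd variance seeds the genetic and residual components, the
    between-herd variance the herd/spatial components.
    """
    y = marg.data.y
    hidx = marg.hidx
    counts = np.bincount(hidx, minlength=marg.n_herds).astype(float)
    sums = np.bincount(hidx, weights=y, minlength=marg.n_herds)
    herd_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    within = float(np.mean((y - herd_mean[hidx]) ** 2)) or y.var()
    between = max(float(y.var() - within), 0.05 * float(y.var()))
    n_env = int(spec.use_herd) + int(spec.use_spatial)
    init = {"sigma2_a": within / 2 if n_env else y.var() / 2,
            "sigma2_e": within / 2 if n_env else y.var() / 2,
            "sigma2_h": between / max(n_env, 1),
            "sigma2_s": between / max(n_env, 1),
            "rho": 0.25}
    return np.array([max(init[k], 1e-3) for k in names])


def _draw_effects(marg: _Marginal, spec: ModelSpec, kept: np.ndarray,
                  names: list, rng: np.random.Generator) -> PosteriorSummary:
    """Joint conditional draws of all location effects per hyper sample.

    Draw a prior realisation of every effect and the data, then correct it
    with Cov(effect, y) V^{-1} (y - y_prior): an exact sample from the
    joint conditional given the hyper-parameters (Matheron's rule).
    """
    data = marg.data
    n, H = marg.n, marg.n_herds
    m = data.K.matrix.shape[0]
    L_K = _chol_psd(data.K.matrix, jitter0=1e-8)
    X, hidx = marg.X, marg.hidx
    p = X.shape[1]
    S = kept.shape[0]
    bv = np.empty((S, m))
    fixed = np.empty((S, p))
    deviances = np.empty(S)
    herd_eff = np.zeros((S, H))
    spat_eff = np.zeros((S, H))
    resid_var = np.empty(S)
    K_cross = data.K.matrix[:, :n]            # Cov(a_all, y)/sigma2_a

    # MH rejections leave duplicate hyper samples; factorisations are reused
    cf_cache: dict = {}
    ls_cache: dict = {}
    for s_i in range(S):
        hp = {k: float(np.exp(t)) for k, t in zip(names, kept[s_i])}
        key = kept[s_i].tobytes()
        if key not in cf_cache:
            if len(cf_cache) > 64:
                cf_cache.clear()
            cf_cache[key] = cho_factor(marg.build_V(hp), lower=True,
                                       check_finite=False)
        cf = cf_cache[key]

        beta0 = rng.standard_normal(p) * np.sqrt(spec.prior_beta_variance)
        a0 = np.sqrt(hp["sigma2_a"]) * (L_K @ rng.standard_normal(m))
        y0 = X @ beta0 + a0[:n]
        h0 = s0 = None
        if spec.use_herd:
            h0 = np.sqrt(hp["sigma2_h"]) * rng.standard_normal(H)
            y0 = y0 + h0[hidx]
        if spec.use_spatial:
            C = marg.spatial_corr(hp["rho"])
            if hp["rho"] not in ls_cache:
                if len(ls_cache) > 64:
                    ls_cache.clear()
                ls_cache[hp["rho"]] = _chol_psd(C)
            L_S = ls_cache[hp["rho"]]
            s0 = np.sqrt(hp["sigma2_s"]) * (L_S @ rng.standard_normal(H))
            y0 = y0 + s0[hidx]
        y0 = y0 + np.sqrt(hp["sigma2_e"]) * rng.standard_normal(n)

        r = cho_solve(cf, data.y - y0, check_finite=False)
        r_herd = np.bincount(hidx, weights=r, minlength=H)
        a = a0 + hp["sigma2_a"] * (K_cross @ r)
        beta = beta0 + spec.prior_beta_variance * (X.T @ r)
        mean_i = X @ beta + a[:n]
        if spec.use_herd:
            h = h0 + hp["sigma2_h"] * r_herd
            herd_eff[s_i] = h
            mean_i = mean_i + h[hidx]
        if spec.use_spatial:
            s_eff = s0 + hp["sigma2_s"] * (C @ r_herd)
            spat_eff[s_i] = s_eff
            mean_i = mean_i + s_eff[hidx]
        bv[s_i] = a
        fixed[s_i] = beta
        resid_var[s_i] = hp["sigma2_e"]
        dev_resid = data.y - mean_i
        deviances[s_i] = n * np.log(2 * np.pi * hp["sigma2_e"]) \
            + dev_resid @ dev_resid / hp["sigma2_e"]

    hyper_df = pd.DataFrame(np.exp(kept), columns=names)
    mean_dev = float(deviances.mean())
    # plug-in deviance at posterior means (effects and residual variance)
    bv_mean = bv.mean(axis=0)
    mean_fit = X @ fixed.mean(axis=0) + bv_mean[:n]
    if spec.use_herd:
        mean_fit = mean_fit + herd_eff.mean(axis=0)[hidx]
    if spec.use_spatial:
        mean_fit = mean_fit + spat_eff.mean(axis=0)[hidx]
    sig2e_hat = float(resid_var.mean())
    resid_hat = data.y - mean_fit
    dev_at_mean = n * np.log(2 * np.pi * sig2e_hat) + resid_hat @ resid_hat / sig2e_hat
    model_dic = dic(deviances, float(dev_at_mean))

    return PosteriorSummary(
        ids=np.concatenate([data.obs_ids, data.pred_ids]), n_obs=n,
        bv_mean=bv_mean, bv_sd=bv.std(axis=0), bv_samples=bv,
        hyper_samples=hyper_df, fixed_mean=fixed.mean(axis=0),
        fixed_sd=fixed.std(axis=0), dic=model_dic,
        diagnostics={"n_samples": S, "mean_deviance": mean_dev,
                     "deviances": deviances,
                     "herd_effect_mean": herd_eff.mean(axis=0),
                     "spatial_effect_mean": spat_eff.mean(axis=0)})


def dic(deviances: np.ndarray, deviance_at_posterior_mean: float) -> float:
    """Deviance information criterion: mean deviance plus p_D."""
    mean_dev = float(np.mean(deviances))
    p_d = mean_dev - float(deviance_at_posterior_mean)
    return mean_dev + p_d


# ---------------------------------------------------------------------------
# Henderson mixed-model-equations oracle


def blup_given_variances(data: ModelData, spec: ModelSpec,
                         hypers: dict) -> dict:
    """Exact BLUP/BLUE at fixed variances via the mixed model equations.

    Returns estimates for beta, the breeding values a (phenotyped plus
    prediction animals), and herd/spatial effects where the model has
    them.  A random effect with variance zero is dropped (its estimate is
    identically zero, the infinite-shrinkage limit).
    """
    n = data.y.size
    m = data.K.matrix.shape[0]
    H = data.herd_coords.shape[0]
    hidx = data.herd_index
    marg = _Marginal(data, spec)
    X = marg.X
    p = X.shape[1]

    use_a = hypers["sigma2_a"] > 0
    use_h = spec.use_herd and hypers.get("sigma2_h", 0) > 0
    use_s = spec.use_spatial and hypers.get("sigma2_s", 0) > 0

    blocks = [X]
    if use_a:
        Z = np.zeros((n, m))
        Z[np.arange(n), np.arange(n)] = 1.0
        blocks.append(Z)
    onehot = np.zeros((n, H))
    onehot[np.arange(n), hidx] = 1.0
    if use_h:
        blocks.append(onehot)
    if use_s:
        blocks.append(onehot)
    T = np.hstack(blocks)
    sig2e = hypers["sigma2_e"]
    C = T.T @ T / sig2e
    rhs = T.T @ data.y / sig2e

    i = p
    C[:p, :p] += np.eye(p) / spec.prior_beta_variance
    if use_a:
        Kinv = np.linalg.inv(data.K.matrix +
                             1e-8 * np.eye(m) * np.mean(np.diag(data.K.matrix)))
        C[i:i + m, i:i + m] += Kinv / hypers["sigma2_a"]
        i += m
    if use_h:
        C[i:i + H, i:i + H] += np.eye(H) / hypers["sigma2_h"]
        i += H
    if use_s:
        Corr = marg.spatial_corr(hypers["rho"])
        Cinv = np.linalg.inv(Corr + 1e-10 * np.eye(H))
        C[i:i + H, i:i + H] += Cinv / hypers["sigma2_s"]

    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular mixed-model coefficient matrix") from err

    out = {"beta": sol[:p]}
    i = p
    out["a"] = sol[i:i + m] if use_a else np.zeros(m)
    i += m if use_a else 0
    out["h"] = sol[i:i + H] if use_h else np.zeros(H)
    i += H if use_h else 0
    out["s"] = sol[i:i + H] if use_s else np.zeros(H)
    out["ids"] = np.concatenate([data.obs_ids, data.pred_ids])
    return out
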