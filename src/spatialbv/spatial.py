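"""Matérn Gaussian random fields for herd-level environmental effects.

The large-scale environment is the weighted sum of eight independent
Matérn (ν=1) Gaussian random fields evaluated at the herd coordinates,
rescaled to a fixed marginal variance.  Some of the underlying processes
are additionally exposed as observed environmental covariates — exactly,
with noise, or as categorical surrogates — plus two null processes that do
not enter the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import k1, kv


@dataclass(frozen=True)
class MaternParams:
    """Matérn covariance parameters.

    ``rho`` is the range: the distance at which the correlation has fallen
    to ~0.1 (0.14 exactly at ν=1).  ``kappa = sqrt(8 nu) / rho``.
    """

    sigma2: float
    rho: float
    nu: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0 or self.rho <= 0 or self.nu <= 0:
            raise ValueError("sigma2, rho and nu must be positive")

    @property
    def kappa(self) -> float:
        return np.sqrt(8.0 * self.nu) / self.rho


def matern_cov(d, p: MaternParams):
    """Matérn covariance at distance(s) ``d`` (σ² at d=0, continuous there)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    kd = p.kappa * d
    with np.errstate(invalid="ignore"):
        if p.nu == 1.0:          # fast path: K_1 avoids the generic kv machinery
            cov = p.sigma2 * kd * k1(kd)
        else:
            cov = p.sigma2 * (2.0 ** (1.0 - p.nu) / gamma_fn(p.nu)) \
                * kd ** p.nu * kv(p.nu, kd)
    cov = np.where(d == 0, p.sigma2, cov)
    return cov if cov.ndim else float(cov)


def matern_cov_matrix(coords: np.ndarray, p: MaternParams) -> np.ndarray:
    """Dense Matérn covariance matrix over ``(n, 2)`` coordinates."""
    d = cdist(coords, coords)
    return matern_cov(d, p)


_JITTER0, _JITTER_MAX = 1e-10, 1e-6


def _chol_with_jitter(cov: np.ndarray, sigma2: float) -> np.ndarray:
    """Lower Cholesky factor, escalating diagonal jitter 1e-10σ²..1e-6σ²."""
    jitter = _JITTER0 * sigma2
    while True:
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
            if jitter > _JITTER_MAX * sigma2:
                raise np.linalg.LinAlgError(
                    "covariance not positive definite after jitter escalation")


def sample_grf(coords: np.ndarray, p: MaternParams, seed) -> np.ndarray:
    """One mean-zero draw of the field at ``coords`` via dense Cholesky."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    rng = np.random.default_rng(seed)
    L = _chol_with_jitter(matern_cov_matrix(coords, p), p.sigma2)
    return L @ rng.standard_normal(coords.shape[0])


@dataclass
class SpatialEnvironment:
    """Eight Matérn process realisations and their weighted, rescaled sum."""

    process_values: np.ndarray          # (8, n_herds)
    process_params: list[MaternParams]
    alpha_weights: np.ndarray           # (8,), zero where unused
    beta_weights: np.ndarray
    total_effect: np.ndarray            # (n_herds,), mean 0, var sigma_s2
    sigma_s2: float
    coords: np.ndarray = field(repr=False, default=None)


def compose_total_effect(processes: np.ndarray, alphas: np.ndarray,
                         betas: np.ndarray, sigma_s2: float) -> np.ndarray:
    """Weighted sum of the eight processes, rescaled to mean 0, var ``sigma_s2``.

    Processes 1–3 enter with weight 1, 4–6 with (1+α), 7–8 with (1+α+β).
    """
    processes = np.asarray(processes, dtype=float)
    if processes.shape[0] != 8:
        raise ValueError("expected 8 spatial processes")
    w = np.ones(8)
    w[3:6] += alphas[3:6]
    w[6:8] += alphas[6:8] + betas[6:8]
    total = w @ processes
    sd = total.std()
    if sd == 0:
        raise ValueError("degenerate (zero-variance) spatial sum")
    if sigma_s2 == 0:
        return np.zeros_like(total)
    return (total - total.mean()) / sd * np.sqrt(sigma_s2)


def simulate_environment(coords: np.ndarray, seed, sigma_s2: float = 0.4,
                         rho_range=(0.1, 0.5), sigma2_choices=(0.2, 0.3)) -> SpatialEnvironment:
    """Simulate the eight-process spatial environment at herd coordinates.

    Per process: range ρ ~ U(0.1, 0.5) of the unit square, marginal variance
    0.2 or 0.3 equiprobably, ν fixed at 1; emphasis weights α (processes
    4–8) and β (7–8) ~ U(−0.5, 0.5).
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    params, values = [], np.empty((8, n))
    for k in range(8):
        p = MaternParams(sigma2=float(rng.choice(sigma2_choices)),
                         rho=float(rng.uniform(*rho_range)))
        params.append(p)
        values[k] = sample_grf(coords, p, rng)
    alphas = np.zeros(8)
    betas = np.zeros(8)
    alphas[3:8] = rng.uniform(-0.5, 0.5, size=5)
    betas[6:8] = rng.uniform(-0.5, 0.5, size=2)
    total = compose_total_effect(values, alphas, betas, sigma_s2)
    return SpatialEnvironment(process_values=values, process_params=params,
                              alpha_weights=alphas, beta_weights=betas,
                              total_effect=total, sigma_s2=sigma_s2, coords=coords)


def observe_covariates(env: SpatialEnvironment, seed,
                       null_rho_range=(0.1, 0.5),
                       null_sigma2_choices=(0.2, 0.3)) -> pd.DataFrame:
    """Observed environmental covariates at herd locations.

    v1–v3 are observed exactly; v4–v6 get N(0, 0.1 σ_k²) measurement noise;
    v7 is dichotomised at a threshold ~ U(mean ± 1 sd); v8 trichotomised at
    thresholds ~ U(mean − 2 sd, mean) and U(mean, mean + 2 sd).  Two further
    Matérn null processes (n1, n2), unrelated to the phenotype, are observed
    exactly.  A threshold can leave a factor level empty; that is permitted
    and recorded as a DataFrame attribute.
    """
    rng = np.random.default_rng(seed)
    v = env.process_values
    out = {"herd": np.arange(1, v.shape[1] + 1)}
    for k in range(3):
        out[f"v{k + 1}"] = v[k].copy()
    for k in range(3, 6):
        noise_sd = np.sqrt(0.1 * env.process_params[k].sigma2)
        out[f"v{k + 1}"] = v[k] + rng.standard_normal(v.shape[1]) * noise_sd

    m7, s7 = v[6].mean(), v[6].std()
    thr7 = rng.uniform(m7 - s7, m7 + s7)
    out["v7"] = (v[6] > thr7).astype(int)

    m8, s8 = v[7].mean(), v[7].std()
    lo = rng.uniform(m8 - 2 * s8, m8)
    hi = rng.uniform(m8, m8 + 2 * s8)
    out["v8"] = np.digitize(v[7], [lo, hi])

    for j in range(2):
        p = MaternParams(sigma2=float(rng.choice(null_sigma2_choices)),
                         rho=float(rng.uniform(*null_rho_range)))
        out[f"n{j + 1}"] = sample_grf(env.coords, p, rng)

    df = pd.DataFrame(out)
    df.attrs["empty_levels"] = {
        "v7": sorted(set(range(2)) - set(np.unique(df["v7"]))),
        "v8": sorted(set(range(3)) - set(np.unique(df["v8"]))),
    }
    return df


def variance_partition(prop_spatial: float, total: float = 0.65) -> tuple[float, float]:
    """Split the between-herd environmental variance into (σ_s², σ_h²).

    The study holds σ_s² + σ_h² = 0.65 fixed while varying the spatial
    proportion over {0, 0.2, 0.4, 0.6, 0.8, 1}.
    """
    if not 0 <= prop_spatial <= 1:
        raise ValueError("prop_spatial must be in [0, 1]")
    return total * prop_spatial, total * (1.0 - prop_spatial)


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_spatial_truth(herd_ids: np.ndarray, total_effect: np.ndarray, path) -> None:
    pd.DataFrame({"herd": herd_ids, "s_true": total_effect}).to_csv(path, index=False)
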