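"""Evaluation statistics: accuracy, top-k ranking, CRPS, confounding.

Accuracy is the Pearson correlation between true and posterior-mean
breeding values; EBV refers to phenotyped animals and PBV to the
prediction cohort.  The CRPS compares the whole posterior sample to the
truth (lower is better).  The confounding correlation — between estimated
breeding values and the true spatial effect of the animal's herd — is
near zero when a model separates genetic and spatial effects cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def accuracy(true_bv: np.ndarray, inferred_mean: np.ndarray) -> float:
    """Pearson correlation between true and inferred breeding values."""
    true_bv = np.asarray(true_bv, dtype=float)
    inferred_mean = np.asarray(inferred_mean, dtype=float)
    if true_bv.size < 3:
        raise ValueError("need at least 3 animals")
    if true_bv.std() == 0 or inferred_mean.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(true_bv, inferred_mean)[0, 1])


def top_k_rank_corr(true_bv: np.ndarray, inferred_mean: np.ndarray,
                    k: int = 100, select: str = "true") -> float:
    """Spearman rank correlation over the top-k animals.

    The selection set defaults to the k animals with the highest *true*
    breeding values; ``select="inferred"`` switches to the inferred side.
    Ties get average ranks (scipy convention).
    """
    true_bv = np.asarray(true_bv, dtype=float)
    inferred_mean = np.asarray(inferred_mean, dtype=float)
    if true_bv.size < k:
        raise ValueError(f"need at least k={k} animals")
    key = true_bv if select == "true" else inferred_mean
    top = np.argsort(-key, kind="stable")[:k]
    return float(stats.spearmanr(true_bv[top], inferred_mean[top]).statistic)


def crps(samples: np.ndarray, truth: float) -> float:
    """Sample-based CRPS for one animal.

    Empirical (V-statistic) estimator mean|X - y| - 0.5 mean|X - X'| over
    all ordered sample pairs; nonnegative and invariant to sample order.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 posterior samples")
    term1 = np.mean(np.abs(x - truth))
    # mean over all ordered pairs |x_i - x_j| via the sorted representation
    i = np.arange(1, m + 1)
    term2 = 2.0 * np.sum((2 * i - m - 1) * x) / (m * m)
    return float(term1 - 0.5 * term2)


def mean_crps(samples: np.ndarray, truths: np.ndarray) -> float:
    """Average per-animal CRPS over an (S, n) posterior-sample matrix."""
    samples = np.asarray(samples, dtype=float)
    truths = np.asarray(truths, dtype=float)
    return float(np.mean([crps(samples[:, j], truths[j])
                          for j in range(truths.size)]))


def crps_gaussian(mu: float, sigma: float, truth: float) -> float:
    """Closed-form CRPS of a N(mu, sigma^2) forecast (oracle for tests)."""
    z = (truth - mu) / sigma
    return float(sigma * (z * (2 * stats.norm.cdf(z) - 1)
                          + 2 * stats.norm.pdf(z) - 1 / np.sqrt(np.pi)))


def confounding_correlation(inferred_bv_mean: np.ndarray,
                            true_spatial_by_animal: np.ndarray) -> float:
    """Pearson correlation of EBV with the animal's true spatial effect."""
    return accuracy(true_spatial_by_animal, inferred_bv_mean)


@dataclass
class EvaluationReport:
    """Per-model evaluation of one replicate."""

    accuracy_ebv: float
    accuracy_pbv: float
    top100_spearman: float
    crps_ebv: float
    crps_pbv: float
    confound_corr: float

    def rows(self, **keys) -> pd.DataFrame:
        """Tidy rows: one per metric, tagged with the given key columns."""
        recs = [dict(keys, metric=k, value=v) for k, v in vars(self).items()]
        return pd.DataFrame(recs)


def evaluate(summary, true_bv_obs: np.ndarray, true_bv_pred: np.ndarray,
             true_spatial_obs: np.ndarray, top_k: int = 100) -> EvaluationReport:
    """Score a :class:`~spatialbv.inference.PosteriorSummary` against truth."""
    n = summary.n_obs
    k = min(top_k, n)
    spatial_sd = np.asarray(true_spatial_obs, dtype=float).std()
    return EvaluationReport(
        accuracy_ebv=accuracy(true_bv_obs, summary.ebv),
        accuracy_pbv=accuracy(true_bv_pred, summary.pbv),
        top100_spearman=top_k_rank_corr(true_bv_obs, summary.ebv, k=k),
        crps_ebv=mean_crps(summary.bv_samples[:, :n], true_bv_obs),
        crps_pbv=mean_crps(summary.bv_samples[:, n:], true_bv_pred),
        # undefined when the scenario carries no spatial variance
        confound_corr=confounding_correlation(summary.ebv, true_spatial_obs)
        if spatial_sd > 0 else np.nan,
    )
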