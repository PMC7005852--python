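"""Bootstrap selection of high-Phi samples.

Samples with a low fraction of informative reads (Phi) are noisy estimators
of clone number.  The selection step resamples the sample set with
replacement, records for each replicate the mean Phi and the standard
deviation of B_0.02 (the number of informative barcodes with VAF > 0.02),
builds a bias-corrected accelerated (BCa) 95% confidence interval for the
mean Phi, and classifies every sample with Phi at or above the lower CI
bound as high-Phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

DEFAULT_SEED = 20200207


@dataclass
class BootstrapResult:
    n_reps: int
    replicate_mean_phi: np.ndarray
    replicate_sd_B002: np.ndarray
    estimate_mean_phi: float
    ci_low: float
    ci_high: float
    pearson_r: float
    degenerate: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.estimate_mean_phi <= self.ci_high):
            raise ValueError("estimate outside its confidence interval")


def _bca_interval(data: np.ndarray, replicates: np.ndarray,
                  estimate: float, alpha: float = 0.05) -> Tuple[float, float]:
    """BCa interval endpoints from a bootstrap replicate distribution.

    Bias correction z0 comes from the fraction of replicates below the
    observed estimate; acceleration from the jackknife skewness of the
    statistic (here the mean).
    """
    B = replicates.size
    prop = np.clip(np.mean(replicates < estimate), 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(prop)
    n = data.size
    jack = (data.sum() - data) / (n - 1)  # leave-one-out means
    d = jack.mean() - jack
    denom = np.sum(d * d) ** 1.5
    a = np.sum(d ** 3) / (6.0 * denom) if denom > 0 else 0.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        out.append(float(np.quantile(replicates, stats.norm.cdf(adj))))
    return out[0], out[1]


def bootstrap_phi(samples: Sequence[Tuple[float, float]], n_reps: int = 1000,
                  seed: int = DEFAULT_SEED, alpha: float = 0.05) -> BootstrapResult:
    """Paired bootstrap over samples given as (Phi, B_0.02) tuples.

    Each replicate resamples the sample indices once and evaluates both the
    mean Phi and the sd of B_0.02 on the same resampled index set.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be (phi, B_0.02) pairs")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if n_reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    phi = arr[:, 0]
    b002 = arr[:, 1]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_reps, n))
    rep_phi = phi[idx].mean(axis=1)
    rep_sd = b002[idx].std(axis=1, ddof=1)
    estimate = float(phi.mean())
    if np.ptp(rep_phi) == 0 and np.ptp(phi) == 0:
        return BootstrapResult(n_reps, rep_phi, rep_sd, estimate,
                               estimate, estimate,
                               pearson_r=float("nan"), degenerate=True)
    lo, hi = _bca_interval(phi, rep_phi, estimate, alpha)
    lo = min(lo, estimate)
    hi = max(hi, estimate)
    if np.ptp(rep_sd) == 0 or np.ptp(rep_phi) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(rep_phi, rep_sd)[0, 1])
    return BootstrapResult(n_reps, rep_phi, rep_sd, estimate, lo, hi, r)


@dataclass
class Classification:
    high: List[str]
    low: List[str]
    mean_phi_high: float
    mean_phi_low: float
    ci_low: float


def classify_samples(sample_ids: Sequence[str], phi: Sequence[float],
                     ci_low: float) -> Classification:
    """Partition samples at the lower CI bound: high iff Phi >= ci_low."""
    phi = np.asarray(phi, dtype=float)
    ids = list(sample_ids)
    hi = [s for s, p in zip(ids, phi) if p >= ci_low]
    lo = [s for s, p in zip(ids, phi) if p < ci_low]
    return Classification(
        high=hi, low=lo,
        mean_phi_high=float(phi[phi >= ci_low].mean()) if hi else float("nan"),
        mean_phi_low=float(phi[phi < ci_low].mean()) if lo else float("nan"),
        ci_low=float(ci_low),
    )


def compare_distributions(high_B002: Sequence[float],
                          low_B002: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test of B_0.02 between classes."""
    if len(high_B002) < 2 or len(low_B002) < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.ks_2samp(high_B002, low_B002)
    return float(res.statistic), float(res.pvalue)
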