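"""Statistical analysis for the observer study.

AUC uncertainty uses a nonparametric placement-value (DeLong-type) estimator
with cluster-level aggregation: all samples derived from one subject share a
cluster id and are treated as a single resampling unit, which accounts for
the correlated nature of the data.  With every cluster of size one the
estimator reduces exactly to the standard DeLong variance.  The same
placement machinery gives the variance of a paired AUC difference between
two methods scored on the same samples.

Non-inferiority follows the fixed-margin rule: method A is non-inferior to
reference R when the lower 95% confidence bound of AUC_A - AUC_R lies above
-Delta with Delta = 5% of AUC_R.  Superiority tests against the no-AC arm
are Bonferroni-corrected.  Image fidelity is summarized by RMSE and SSIM
with cluster-resampled bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from skimage.metrics import structural_similarity

log = logging.getLogger(__name__)


@dataclass
class AUCResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    n_present: int
    n_absent: int
    method: str = "cluster-delong"


@dataclass
class ComparisonResult:
    delta_auc: float
    ci: tuple[float, float]
    margin: float
    decision: str                 # superior | non_inferior | inconclusive
    p_noninferiority: float
    p_superiority: float
    p_superiority_adjusted: float


def _placements(t: np.ndarray, labels: np.ndarray):
    """Per-sample placement values.

    For a defect-present sample, the fraction of defect-absent scores it
    exceeds (ties credited 0.5), and symmetrically for defect-absent samples.
    The mean placement on either side equals the Mann-Whitney AUC.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    t1, t0 = t[y == 1], t[y == 0]
    n1, n0 = len(t1), len(t0)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    s0 = np.sort(t0)
    v10 = (np.searchsorted(s0, t1, "left") + np.searchsorted(s0, t1, "right")) / (2.0 * n0)
    s1 = np.sort(t1)
    # fraction of present scores this absent sample is *below* (same AUC orientation)
    above = len(t1) - (np.searchsorted(s1, t0, "left") + np.searchsorted(s1, t0, "right")) / 2.0
    v01 = above / n1
    return v10, v01, y


def _cluster_var(values: np.ndarray, clusters: np.ndarray, mean: float, n_total: int) -> float:
    """Between-cluster variance of summed placements around the AUC.

    With singleton clusters this equals sample_var(values, ddof=1) / n_total.
    """
    uniq, inv = np.unique(clusters, return_inverse=True)
    c = len(uniq)
    if c < 2:
        raise ValueError("need at least 2 clusters per class")
    sums = np.bincount(inv, weights=values)
    sizes = np.bincount(inv)
    dev = sums - sizes * mean
    return float(c / (c - 1) * np.sum(dev**2) / n_total**2)


def auc_ci_correlated(t: np.ndarray, labels: np.ndarray, cluster_ids: np.ndarray,
                      alpha: float = 0.05) -> AUCResult:
    """AUC with a cluster-aggregated DeLong variance and normal-theory CI.

    Samples sharing ``cluster_ids`` are one resampling unit.  The CI is
    truncated to [0, 1].
    """
    v10, v01, y = _placements(t, labels)
    cl = np.asarray(cluster_ids)
    auc = float(v10.mean())
    var1 = _cluster_var(v10, cl[y == 1], auc, len(v10))
    var0 = _cluster_var(v01, cl[y == 0], auc, len(v01))
    var = var1 + var0
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return AUCResult(auc=auc, variance=var,
                     ci=(max(auc - half, 0.0), min(auc + half, 1.0)),
                     n_present=len(v10), n_absent=len(v01))


def paired_auc_difference(t_a: np.ndarray, t_b: np.ndarray, labels: np.ndarray,
                          cluster_ids: np.ndarray, alpha: float = 0.05):
    """AUC_A - AUC_B with cluster-aggregated variance (paired design).

    Returns (delta, variance, ci).  The two score vectors must come from the
    same samples in the same order.
    """
    if len(t_a) != len(t_b):
        raise ValueError("paired scores must align")
    va10, va01, y = _placements(t_a, labels)
    vb10, vb01, _ = _placements(t_b, labels)
    cl = np.asarray(cluster_ids)
    delta = float(va10.mean() - vb10.mean())
    d10, d01 = va10 - vb10, va01 - vb01
    var = (_cluster_var(d10, cl[y == 1], delta, len(d10))
           + _cluster_var(d01, cl[y == 0], delta, len(d01)))
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return delta, var, (delta - half, delta + half)


def noninferiority_test(auc_test: float, auc_ref: float, var_of_difference: float,
                        margin_frac: float = 0.05, alpha: float = 0.05,
                        n_comparisons: int = 1) -> ComparisonResult:
    """Fixed-margin non-inferiority of ``auc_test`` against ``auc_ref``.

    Delta = margin_frac * auc_ref; non-inferior iff the lower (1-alpha)
    confidence bound of the difference exceeds -Delta (strict).  Superiority
    additionally requires the lower bound to exceed 0; its p-value is
    Bonferroni-adjusted with ``n_comparisons``.
    """
    if margin_frac <= 0:
        raise ValueError("margin fraction must be > 0")
    delta = auc_test - auc_ref
    margin = margin_frac * auc_ref
    se = float(np.sqrt(max(var_of_difference, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    lo, hi = delta - z * se, delta + z * se
    if se > 0:
        p_ni = float(1 - norm.cdf((delta + margin) / se))
        p_sup = float(2 * (1 - norm.cdf(abs(delta) / se)))
    else:
        p_ni = 0.0 if delta > -margin else 1.0
        p_sup = 0.0 if delta != 0 else 1.0
    p_sup_adj = min(1.0, n_comparisons * p_sup)
    if lo > 0:
        decision = "superior"
    elif lo > -margin:
        decision = "non_inferior"
    else:
        decision = "inconclusive"
    return ComparisonResult(delta_auc=delta, ci=(lo, hi), margin=margin,
                            decision=decision, p_noninferiority=p_ni,
                            p_superiority=p_sup, p_superiority_adjusted=p_sup_adj)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Adjusted p = min(1, m * p); monotone in the raw p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)


def fidelity_metrics(image: np.ndarray, reference: np.ndarray,
                     mask: np.ndarray | None = None) -> tuple[float, float]:
    """(RMSE, SSIM) of ``image`` against ``reference``.

    RMSE is the root mean squared difference (over ``mask`` when given);
    SSIM uses the standard constants on the joint dynamic range of the two
    volumes (computed on the full arrays).
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    diff2 = (image - reference) ** 2
    if mask is not None:
        rmse = float(np.sqrt(diff2[mask].mean()))
    else:
        rmse = float(np.sqrt(diff2.mean()))
    lo = min(image.min(), reference.min())
    hi = max(image.max(), reference.max())
    data_range = hi - lo
    if data_range == 0:
        return rmse, 1.0
    ssim = float(structural_similarity(image, reference, data_range=data_range))
    return rmse, ssim


def bootstrap_diff(paired_differences: np.ndarray, cluster_ids: np.ndarray,
                   B: int = 2000, seed: int = 0, alpha: float = 0.05):
    """Cluster-resampled bootstrap of a mean paired difference.

    Resamples whole clusters with replacement, returns the percentile
    (1-alpha) CI and a two-sided p-value from CI inversion.  Seeded and
    deterministic.
    """
    if B < 100:
        warnings.warn(f"bootstrap with B={B} < 100 replicates is unreliable",
                      stacklevel=2)
    d = np.asarray(paired_differences, dtype=np.float64)
    cl = np.asarray(cluster_ids)
    uniq = np.unique(cl)
    groups = [d[cl == u] for u in uniq]
    rng = np.random.default_rng(seed)
    means = np.empty(B)
    for b in range(B):
        pick = rng.integers(0, len(groups), size=len(groups))
        means[b] = np.concatenate([groups[i] for i in pick]).mean()
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    if np.all(means == means[0]):
        p = 1.0 if means[0] == 0 else 0.0
    else:
        frac_le = (means <= 0).mean()
        frac_ge = (means >= 0).mean()
        p = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
    return {"mean": float(d.mean()), "ci": (float(lo), float(hi)), "p": p,
            "B": B, "seed": seed}
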