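"""Cluster-aware AUC inference, non-inferiority, fidelity metrics, bootstrap."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter
from scipy.stats import norm

from ctless.stats import (
    auc_ci_correlated,
    bonferroni,
    bootstrap_diff,
    fidelity_metrics,
    noninferiority_test,
    paired_auc_difference,
)


def _delong_var_oracle(t, y):
    """Textbook DeLong variance via explicit placement values."""
    t1, t0 = t[y == 1], t[y == 0]
    n1, n0 = len(t1), len(t0)
    psi = (t1[:, None] > t0[None, :]) + 0.5 * (t1[:, None] == t0[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0, psi.mean()


def test_singleton_clusters_reduce_to_delong():
    rng = np.random.default_rng(0)
    t = rng.normal(size=80) + np.r_[np.ones(40) * 0.8, np.zeros(40)]
    y = np.r_[np.ones(40, int), np.zeros(40, int)]
    res = auc_ci_correlated(t, y, cluster_ids=np.arange(80))
    var_oracle, auc_oracle = _delong_var_oracle(t, y)
    assert res.auc == pytest.approx(auc_oracle, abs=1e-12)
    assert res.variance == pytest.approx(var_oracle, abs=1e-10)
    assert res.variance >= 0
    assert 0 <= res.ci[0] <= res.ci[1] <= 1


def test_ci_coverage_with_independent_clusters():
    """95% CI coverage over 500 replicates at true AUC 0.8 is in [0.92, 0.98]."""
    true_auc = 0.8
    mu1 = np.sqrt(2) * norm.ppf(true_auc)
    rng = np.random.default_rng(123)
    hits = 0
    reps = 500
    n = 80  # per class; the normal-theory CI is asymptotic
    for _ in range(reps):
        t1 = rng.normal(mu1, 1, n)
        t0 = rng.normal(0, 1, n)
        t = np.r_[t1, t0]
        y = np.r_[np.ones(n, int), np.zeros(n, int)]
        res = auc_ci_correlated(t, y, cluster_ids=np.arange(2 * n))
        hits += res.ci[0] <= true_auc <= res.ci[1]
    assert 0.92 <= hits / reps <= 0.98


def test_cluster_aggregation_widens_ci_for_replicated_samples():
    """Duplicating every sample within a cluster must not shrink the CI."""
    rng = np.random.default_rng(5)
    t = rng.normal(size=60) + np.r_[np.ones(30) * 0.6, np.zeros(30)]
    y = np.r_[np.ones(30, int), np.zeros(30, int)]
    base = auc_ci_correlated(t, y, cluster_ids=np.arange(60))
    t_rep = np.repeat(t, 3)
    y_rep = np.repeat(y, 3)
    cl_rep = np.repeat(np.arange(60), 3)
    rep = auc_ci_correlated(t_rep, y_rep, cluster_ids=cl_rep)
    assert rep.auc == pytest.approx(base.auc, abs=1e-12)
    assert rep.variance == pytest.approx(base.variance, rel=1e-9)
    with pytest.raises(ValueError):
        auc_ci_correlated(t, y, cluster_ids=np.r_[np.zeros(30), np.arange(30)])


def test_paired_difference_accounts_for_correlation():
    """Paired variance is below the sum of the individual variances for
    positively correlated scores."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=100)
    y = np.r_[np.ones(50, int), np.zeros(50, int)]
    shift = np.where(y == 1, 0.9, 0.0)
    t_a = base + shift + rng.normal(0, 0.2, 100)
    t_b = base + shift + rng.normal(0, 0.2, 100)
    cl = np.arange(100)
    d, var, ci = paired_auc_difference(t_a, t_b, y, cl)
    va = auc_ci_correlated(t_a, y, cl).variance
    vb = auc_ci_correlated(t_b, y, cl).variance
    assert var < va + vb
    assert ci[0] <= d <= ci[1]
    with pytest.raises(ValueError):
        paired_auc_difference(t_a[:-1], t_b, y, cl)


# ---------------------------------------------------------------------------
# non-inferiority
# ---------------------------------------------------------------------------

def test_noninferiority_margin_arithmetic():
    res = noninferiority_test(0.88, 0.90, var_of_difference=1e-6, margin_frac=0.05)
    assert res.margin == pytest.approx(0.045)


def test_noninferiority_limit_cases():
    equal = noninferiority_test(0.85, 0.85, var_of_difference=0.0)
    assert equal.decision in ("non_inferior", "superior")
    at_margin = noninferiority_test(0.90 - 0.045, 0.90, var_of_difference=0.0)
    assert at_margin.decision == "inconclusive"  # strict inequality at -Delta
    sup = noninferiority_test(0.92, 0.85, var_of_difference=1e-6)
    assert sup.decision == "superior"
    with pytest.raises(ValueError):
        noninferiority_test(0.9, 0.9, 0.01, margin_frac=0.0)


def test_bonferroni_monotone_and_capped():
    p = np.array([0.01, 0.03, 0.6])
    adj = bonferroni(p, m=2)
    np.testing.assert_allclose(adj, [0.02, 0.06, 1.0])
    assert np.all(np.diff(adj) >= 0)


# ---------------------------------------------------------------------------
# fidelity metrics
# ---------------------------------------------------------------------------

def test_rmse_closed_forms():
    rng = np.random.default_rng(0)
    ref = rng.random((12, 12, 12))
    rmse, ssim = fidelity_metrics(ref, ref)
    assert rmse == 0.0 and ssim == 1.0
    rmse_c, _ = fidelity_metrics(ref + 0.37, ref)
    assert rmse_c == pytest.approx(0.37, rel=1e-12)
    with pytest.raises(ValueError):
        fidelity_metrics(ref, ref[:4])


def test_ssim_matches_direct_formula_oracle():
    """Cross-implementation check against an explicit sliding-window SSIM."""
    rng = np.random.default_rng(3)
    ref = rng.random((20, 20, 20))
    img = np.clip(ref + rng.normal(0, 0.15, ref.shape), 0, None)
    _, ssim = fidelity_metrics(img, ref)

    lo = min(img.min(), ref.min())
    dr = max(img.max(), ref.max()) - lo
    c1, c2 = (0.01 * dr) ** 2, (0.03 * dr) ** 2
    win = 7
    np_win = win**3
    cov_norm = np_win / (np_win - 1)
    ux = uniform_filter(img, win)
    uy = uniform_filter(ref, win)
    uxx = uniform_filter(img * img, win)
    uyy = uniform_filter(ref * ref, win)
    uxy = uniform_filter(img * ref, win)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    oracle = s[pad:-pad, pad:-pad, pad:-pad].mean()
    assert ssim == pytest.approx(oracle, abs=1e-6)


def test_rmse_mask_restriction():
    img = np.zeros((8, 8, 8))
    ref = np.zeros((8, 8, 8))
    img[0] = 1.0
    mask = np.zeros((8, 8, 8), bool)
    mask[1:] = True
    rmse, _ = fidelity_metrics(img, ref, mask=mask)
    assert rmse == 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_and_seeded():
    d = np.zeros(30)
    cl = np.arange(30)
    res = bootstrap_diff(d, cl, B=200, seed=1)
    assert res["ci"] == (0.0, 0.0) and res["p"] == 1.0
    rng = np.random.default_rng(0)
    d = rng.normal(0.2, 1.0, 40)
    r1 = bootstrap_diff(d, np.arange(40), B=300, seed=5)
    r2 = bootstrap_diff(d, np.arange(40), B=300, seed=5)
    assert r1 == r2
    with pytest.warns(UserWarning):
        bootstrap_diff(d, np.arange(40), B=50, seed=1)


def test_bootstrap_ci_coverage_gaussian():
    """~95% coverage of the percentile CI over 400 Gaussian replicates."""
    rng = np.random.default_rng(77)
    hits, reps = 0, 400
    for i in range(reps):
        d = rng.normal(0.5, 1.0, 40)
        res = bootstrap_diff(d, np.arange(40), B=300, seed=i)
        hits += res["ci"][0] <= 0.5 <= res["ci"][1]
    assert 0.90 <= hits / reps <= 0.98
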