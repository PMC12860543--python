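"""Channelized Hotelling observer: channels, template, LOO scores, ROC."""

import numpy as np
import pytest
from scipy.stats import norm

from ctless.observer import (
    apply_channels,
    cho_template,
    gaussian_cho_auc,
    grouped_loo_scores,
    loo_test_statistics,
    make_rsf_channels,
    roc_auc,
)

PIX = 0.68


def test_passband_edges_follow_octave_doubling():
    ch = make_rsf_channels(grid=32, pixel_cm=PIX, n_channels=4, f0=0.046)
    expected = [(0.046, 0.092), (0.092, 0.184), (0.184, 0.368), (0.368, 0.736)]
    for (lo, hi), (elo, ehi) in zip(ch.passbands, expected):
        assert abs(lo - elo) < 1e-12 and abs(hi - ehi) < 1e-12
    assert ch.U.shape == (1024, 4)


def test_channels_orthogonal_and_reject_dc():
    ch = make_rsf_channels()
    gram = ch.U.T @ ch.U
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-10  # disjoint passbands
    dc = np.full((32, 32), 7.3)
    np.testing.assert_allclose(apply_channels(dc, ch), 0.0, atol=1e-9)


def test_channel_construction_rejects_unrepresentable_band():
    with pytest.raises(ValueError):
        make_rsf_channels(grid=32, pixel_cm=PIX, n_channels=7)


def test_apply_channels_linear_and_matches_loop_oracle():
    ch = make_rsf_channels()
    rng = np.random.default_rng(4)
    img = rng.random((32, 32))
    v = apply_channels(img, ch)
    assert v.shape == (4,)
    np.testing.assert_allclose(apply_channels(3 * img, ch), 3 * v, rtol=1e-12)
    # brute-force per-pixel dot products
    oracle = np.array([sum(ch.U[p, k] * img.ravel()[p] for p in range(1024))
                       for k in range(4)])
    np.testing.assert_allclose(v, oracle, atol=1e-10)
    assert np.all(apply_channels(np.zeros((32, 32)), ch) == 0)
    with pytest.raises(ValueError):
        apply_channels(np.zeros((16, 16)), ch)


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def test_template_identity_covariance_and_equal_means():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(2000, 4))
    delta = np.array([1.0, -0.5, 0.25, 0.0])
    w = cho_template(base[:1000] + delta, base[1000:])
    # covariance ~ identity: w ~ delta (up to sampling error)
    assert np.linalg.norm(w - (base[:1000] + delta).mean(0) + base[1000:].mean(0)) < 0.2
    w0 = cho_template(base[:1000], base[:1000])
    np.testing.assert_allclose(w0, 0.0, atol=1e-12)


def test_template_matches_direct_linear_solve():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(4, 4))
    cov_true = A @ A.T + np.eye(4)
    vs = rng.multivariate_normal([1, 0, 2, -1], cov_true, size=300)
    vn = rng.multivariate_normal([0, 0, 0, 0], cov_true, size=300)
    w = cho_template(vs, vn)
    ds, dn = vs - vs.mean(0), vn - vn.mean(0)
    pooled = (ds.T @ ds + dn.T @ dn) / (len(vs) + len(vn) - 2)
    oracle = np.linalg.solve(pooled, vs.mean(0) - vn.mean(0))
    np.testing.assert_allclose(w, oracle, atol=1e-8)


def test_template_needs_enough_samples():
    with pytest.raises(ValueError):
        cho_template(np.ones((1, 4)), np.ones((10, 4)))


# ---------------------------------------------------------------------------
# leave-one-out scores
# ---------------------------------------------------------------------------

def _gaussian_classes(n, delta, seed=0, cov=None):
    rng = np.random.default_rng(seed)
    cov = np.eye(4) if cov is None else cov
    vs = rng.multivariate_normal(delta, cov, size=n)
    vn = rng.multivariate_normal(np.zeros(4), cov, size=n)
    feats = np.vstack([vs, vn])
    labels = np.r_[np.ones(n, int), np.zeros(n, int)]
    return feats, labels


def test_loo_outputs_one_score_per_sample_and_is_deterministic():
    feats, labels = _gaussian_classes(50, [0.5, 0, 0, 0])
    t1 = loo_test_statistics(feats, labels)
    t2 = loo_test_statistics(feats, labels)
    assert t1.shape == (100,)
    np.testing.assert_array_equal(t1, t2)


def test_loo_close_to_resubstitution_at_large_n():
    feats, labels = _gaussian_classes(1000, [0.8, -0.3, 0.2, 0.0], seed=7)
    t_loo = loo_test_statistics(feats, labels)
    w = cho_template(feats[labels == 1], feats[labels == 0])
    t_resub = feats @ w
    auc_loo = roc_auc(t_loo, labels).auc
    auc_res = roc_auc(t_resub, labels).auc
    assert abs(auc_loo - auc_res) < 0.01


def test_loo_cluster_exclusion_mode():
    feats, labels = _gaussian_classes(30, [1.0, 0, 0, 0], seed=3)
    clusters = np.arange(60) // 3
    t = loo_test_statistics(feats, labels, cluster_ids=clusters, exclude="cluster")
    assert t.shape == (60,)
    with pytest.raises(ValueError):
        loo_test_statistics(feats, labels, exclude="cluster")


def test_cho_converges_to_gaussian_closed_form():
    """Empirical LOO-CHO AUC approaches Phi(d_a / sqrt(2)) on matched
    Gaussian features (n = 5000 per class)."""
    rng = np.random.default_rng(42)
    A = rng.normal(size=(4, 4)) * 0.5
    cov = A @ A.T + np.eye(4)
    delta = np.array([0.6, -0.4, 0.3, 0.1])
    feats, labels = _gaussian_classes(5000, delta, seed=11, cov=cov)
    t = loo_test_statistics(feats, labels)
    auc = roc_auc(t, labels).auc
    expected = gaussian_cho_auc(delta, cov)
    # MC scatter of AUC at n=5000 is well below 0.015
    assert abs(auc - expected) < 0.015


def test_grouped_scores_preserve_per_group_ranking():
    feats, labels = _gaussian_classes(200, [0.8, 0, 0, 0], seed=5)
    groups = np.tile([0, 1], 200)
    t = grouped_loo_scores(feats, labels, groups)
    for g in (0, 1):
        sel = groups == g
        t_plain = loo_test_statistics(feats[sel], labels[sel])
        assert abs(roc_auc(t[sel], labels[sel]).auc - roc_auc(t_plain, labels[sel]).auc) < 1e-12


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_auc_perfect_separation_and_null():
    t = np.r_[np.zeros(50), np.ones(50)]
    y = np.r_[np.zeros(50, int), np.ones(50, int)]
    assert roc_auc(t, y).auc == 1.0
    rng = np.random.default_rng(0)
    t = rng.normal(size=4000)
    y = rng.integers(0, 2, 4000)
    auc = roc_auc(t, y).auc
    assert abs(auc - 0.5) < 3 * np.sqrt(1 / 12 / 1000)


def test_auc_matches_exhaustive_pairwise_oracle():
    rng = np.random.default_rng(9)
    t = np.round(rng.normal(size=100), 1)  # coarse values force ties
    y = np.r_[np.ones(50, int), np.zeros(50, int)]
    auc = roc_auc(t, y).auc
    t1, t0 = t[y == 1], t[y == 0]
    pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in t1 for b in t0]
    assert auc == pytest.approx(np.mean(pairs), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    t = rng.normal(size=200)
    y = rng.integers(0, 2, 200)
    a1 = roc_auc(t, y).auc
    a2 = roc_auc(np.exp(2 * t) + 5, y).auc
    assert a1 == a2


def test_roc_curve_endpoints_and_single_class_rejected():
    t = np.array([0.1, 0.4, 0.35, 0.8])
    y = np.array([0, 0, 1, 1])
    r = roc_auc(t, y)
    assert r.fpr[0] == 0 and r.tpr[0] == 0
    assert r.fpr[-1] == 1 and r.tpr[-1] == 1
    with pytest.raises(ValueError):
        roc_auc(t, np.ones(4, int))


def test_template_invariant_to_roi_rescaling():
    """Affinely rescaling all ROIs leaves the AUC unchanged."""
    feats, labels = _gaussian_classes(300, [0.7, -0.2, 0.1, 0.0], seed=13)
    a1 = roc_auc(loo_test_statistics(feats, labels), labels).auc
    a2 = roc_auc(loo_test_statistics(feats * 37.2, labels), labels).auc
    assert abs(a1 - a2) < 1e-10
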