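"""Channelized Hotelling observer (CHO) with rotationally symmetric
frequency (RSF) channels for the defect-detection task.

The observer reduces each 32x32 cardiac ROI to a 4-vector of channel
responses v = U^T f, learns the linear template w = K_v^{-1} (v_bar_s -
v_bar_n) from defect-present and defect-absent feature populations with a
leave-one-out strategy, and scores each sample with the test statistic
t = w^T v.  Detection performance is summarized by the empirical
(Mann-Whitney) ROC curve and its area.

The channels are annular band-pass indicators on the ROI's DFT grid with
octave spacing: the first channel starts at 0.046 cycles/cm with a width of
0.046 cycles/cm, and each subsequent channel doubles both the start
frequency and the width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ChannelMatrix:
    """Spatial-domain RSF channel templates, one column per channel."""

    U: np.ndarray                      # (grid*grid, n_channels)
    passbands: list[tuple[float, float]]  # cycles/cm, half-open [lo, hi)
    pixel_cm: float
    grid: int


@dataclass
class ScoreSet:
    """Feature vectors, labels and derived observer quantities for one arm."""

    features: np.ndarray               # (N, n_channels)
    labels: np.ndarray                 # 1 defect-present, 0 defect-absent
    cluster_ids: np.ndarray            # shared across samples of one subject
    defect_keys: list[str] | None = None
    t: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels).astype(int)
        self.cluster_ids = np.asarray(self.cluster_ids)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.cluster_ids):
            raise ValueError("features, labels and cluster_ids must align")


def make_rsf_channels(grid: int = 32, pixel_cm: float = 0.68, n_channels: int = 4,
                      f0: float = 0.046) -> ChannelMatrix:
    """Rotationally symmetric frequency channels on the ROI DFT grid.

    Channel k (1-based) passes radial frequencies in
    ``[f0 * 2**(k-1), f0 * 2**k)`` cycles/cm, realized as an indicator over
    DFT bin-center radial frequencies and returned as real spatial-domain
    templates (unit L2 norm).  Raises if a channel has no support on the
    grid (passband entirely beyond the representable frequencies).
    """
    if f0 <= 0:
        raise ValueError("start frequency must be positive")
    fx = np.fft.fftfreq(grid, d=pixel_cm)
    radial = np.hypot(fx[:, None], fx[None, :])
    nyquist = 0.5 / pixel_cm
    cols, passbands = [], []
    for k in range(1, n_channels + 1):
        lo, hi = f0 * 2 ** (k - 1), f0 * 2**k
        if lo >= nyquist * np.sqrt(2.0):
            raise ValueError(
                f"channel {k} passband [{lo:.3f}, {hi:.3f}) exceeds the grid's "
                f"maximum representable frequency")
        indicator = ((radial >= lo) & (radial < hi)).astype(np.float64)
        if indicator.sum() == 0:
            raise ValueError(f"channel {k} has empty support on the {grid}x{grid} DFT grid")
        u = np.real(np.fft.ifft2(indicator))
        u = u.ravel()
        u /= np.linalg.norm(u)
        cols.append(u)
        passbands.append((lo, hi))
    return ChannelMatrix(U=np.stack(cols, axis=1), passbands=passbands,
                         pixel_cm=pixel_cm, grid=grid)


def apply_channels(roi, channels: ChannelMatrix) -> np.ndarray:
    """Feature vector v = U^T f for one ROI (CardiacROI or 2-D array)."""
    img = roi.pixels if hasattr(roi, "pixels") else np.asarray(roi, dtype=np.float64)
    if img.shape != (channels.grid, channels.grid):
        raise ValueError(f"ROI shape {img.shape} does not match channel grid "
                         f"{channels.grid}")
    return channels.U.T @ img.ravel()


def cho_template(signal_features: np.ndarray, noise_features: np.ndarray,
                 training_indices: tuple | None = None,
                 ridge_rel: float = 1e-8) -> np.ndarray:
    """Hotelling template w solving K_v w = (v_bar_s - v_bar_n).

    ``K_v`` is the pooled within-class covariance of the training samples.
    A relative ridge is added when K_v is singular (logged).
    """
    vs = np.asarray(signal_features, dtype=np.float64)
    vn = np.asarray(noise_features, dtype=np.float64)
    if training_indices is not None:
        vs = vs[list(training_indices[0])]
        vn = vn[list(training_indices[1])]
    if len(vs) < 2 or len(vn) < 2:
        raise ValueError("need at least 2 samples per class")
    delta = vs.mean(axis=0) - vn.mean(axis=0)
    cov = _pooled_cov(vs, vn)
    try:
        return np.linalg.solve(cov, delta)
    except np.linalg.LinAlgError:
        p = cov.shape[0]
        lam = ridge_rel * np.trace(cov) / p
        log.warning("singular feature covariance; adding ridge %.3e", lam)
        return np.linalg.solve(cov + lam * np.eye(p), delta)


def _pooled_cov(vs: np.ndarray, vn: np.ndarray) -> np.ndarray:
    n1, n0 = len(vs), len(vn)
    ds = vs - vs.mean(axis=0)
    dn = vn - vn.mean(axis=0)
    return (ds.T @ ds + dn.T @ dn) / (n1 + n0 - 2)


def loo_test_statistics(features: np.ndarray, labels: np.ndarray,
                        cluster_ids: np.ndarray | None = None,
                        exclude: str = "sample",
                        ridge_rel: float = 1e-8) -> np.ndarray:
    """Leave-one-out CHO test statistics t_i = w_{(-i)}^T v_i.

    For each sample the template is learned from all other samples (its own
    feature vector excluded; with ``exclude='cluster'`` the whole subject
    cluster is excluded).  Uses O(1) sufficient-statistic downdates per
    sample, so thousands of samples are cheap.
    """
    v = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n, p = v.shape
    if exclude not in ("sample", "cluster"):
        raise ValueError("exclude must be 'sample' or 'cluster'")
    if exclude == "cluster" and cluster_ids is None:
        raise ValueError("cluster exclusion requires cluster_ids")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("need at least 2 samples per class")

    sums = {c: v[y == c].sum(axis=0) for c in (0, 1)}
    outers = {c: v[y == c].T @ v[y == c] for c in (0, 1)}
    ns = {c: int(counts[c]) for c in (0, 1)}
    eye = np.eye(p)

    if exclude == "cluster":
        cl = np.asarray(cluster_ids)
        groups = {}
        for i in range(n):
            groups.setdefault(cl[i], []).append(i)

    t = np.empty(n)
    for i in range(n):
        drop = groups[cl[i]] if exclude == "cluster" else [i]
        s = {c: sums[c].copy() for c in (0, 1)}
        o = {c: outers[c].copy() for c in (0, 1)}
        m = dict(ns)
        for j in drop:
            c = y[j]
            s[c] -= v[j]
            o[c] -= np.outer(v[j], v[j])
            m[c] -= 1
        if m[0] < 2 or m[1] < 2:
            raise ValueError("a class would be absent/degenerate in a training fold")
        mu1, mu0 = s[1] / m[1], s[0] / m[0]
        scatter = (o[1] - m[1] * np.outer(mu1, mu1)) + (o[0] - m[0] * np.outer(mu0, mu0))
        cov = scatter / (m[1] + m[0] - 2)
        delta = mu1 - mu0
        try:
            w = np.linalg.solve(cov, delta)
        except np.linalg.LinAlgError:
            lam = ridge_rel * np.trace(cov) / p
            w = np.linalg.solve(cov + lam * eye, delta)
        t[i] = w @ v[i]
    return t


def grouped_loo_scores(features: np.ndarray, labels: np.ndarray,
                       groups: np.ndarray, cluster_ids: np.ndarray | None = None,
                       exclude: str = "sample") -> np.ndarray:
    """Leave-one-out CHO scores for a location-known task, pooled across groups.

    The detection task fixes the defect location while extent and severity
    vary, so a separate template is learned within each group (one group per
    defect location).  Because the raw test statistic w^T v carries a
    group-dependent scale, each group's scores are standardized against its
    defect-absent score distribution before pooling — a monotone map within
    the group, so per-group ROC curves are unchanged while pooled scores
    share a common threshold axis.
    """
    groups = np.asarray(groups)
    t = np.empty(len(labels), dtype=np.float64)
    y = np.asarray(labels).astype(int)
    for g in np.unique(groups):
        sel = groups == g
        tg = loo_test_statistics(
            features[sel], y[sel],
            cluster_ids=None if cluster_ids is None else np.asarray(cluster_ids)[sel],
            exclude=exclude)
        absent = tg[y[sel] == 0]
        sd = absent.std(ddof=1)
        t[sel] = (tg - absent.mean()) / (sd if sd > 0 else 1.0)
    return t


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(t: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Empirical ROC curve and Mann-Whitney AUC (ties credited 0.5)."""
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(t)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-t, kind="mergesort")
    ys = y[order]
    ts = t[order]
    distinct = np.r_[np.nonzero(np.diff(ts))[0], len(ts) - 1]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(1 - ys)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr)


def gaussian_cho_auc(delta: np.ndarray, cov: np.ndarray) -> float:
    """Closed-form AUC of the ideal linear observer on Gaussian features.

    AUC = Phi(d_a / sqrt(2)) with d_a^2 = delta^T K^{-1} delta; the empirical
    CHO converges to this on matched Gaussian data.
    """
    from scipy.stats import norm

    da2 = float(np.asarray(delta) @ np.linalg.solve(cov, np.asarray(delta)))
    return float(norm.cdf(np.sqrt(da2 / 2.0)))
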