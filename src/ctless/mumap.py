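"""Attenuation-map utilities.

Three pieces: the bilinear CT-number-to-attenuation conversion used to turn
Hounsfield units into cm^-1 at the emission energy; a Markov-random-field
ground-truth segmentation of an attenuation volume into the K attenuation
regions (iterated conditional modes with a Potts smoothing prior over
6-neighborhoods); and the assembly of the final piecewise-constant
attenuation map by assigning each region its predefined coefficient,

    mu_hat = sum_k mu_k * Phi_hat_k ,

which equals a per-voxel table lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CoefficientTable

log = logging.getLogger(__name__)


@dataclass
class SegmentationMap:
    """Partition of the grid into K regions (integer label volume)."""

    labels: np.ndarray
    K: int
    source: str = "ground_truth"  # ground_truth | predicted

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("labels out of range for K regions")

    def one_hot(self) -> np.ndarray:
        """(K, ...) binary support vectors; per voxel exactly one is 1."""
        return np.stack([(self.labels == k) for k in range(self.K)]).astype(np.float64)

    def region_mask(self, k: int) -> np.ndarray:
        return self.labels == k


@dataclass
class AssembledMuMap:
    mu_hat: np.ndarray
    table: CoefficientTable
    segmentation_source: str


def ct_to_mu(hu_volume: np.ndarray, water_mu: float = 0.15,
             air_hu: float = -1000.0, bone_hu: float = 1000.0,
             bone_mu: float = 0.25) -> np.ndarray:
    """Bilinear HU -> attenuation (cm^-1) with a slope break at 0 HU.

    Anchored at ``mu(air_hu) = 0`` and ``mu(0) = water_mu`` (default 0.15
    cm^-1, water at the Tc-99m photopeak energy); the bone segment runs from
    the water anchor through ``(bone_hu, bone_mu)``.  Out-of-range HU values
    are clamped and logged.  Monotone non-decreasing provided
    ``bone_mu >= water_mu``.
    """
    hu = np.asarray(hu_volume, dtype=np.float64)
    if hu.min() < -1024 or hu.max() > 3000:
        n_bad = int(np.sum((hu < -1024) | (hu > 3000)))
        log.warning("%d HU values outside [-1024, 3000]; clamped", n_bad)
        hu = np.clip(hu, -1024.0, 3000.0)
    soft = water_mu * (hu - air_hu) / (0.0 - air_hu)
    bone = water_mu + hu * (bone_mu - water_mu) / bone_hu
    mu = np.where(hu <= 0.0, soft, bone)
    return np.maximum(mu, 0.0)


_NEIGHBOR_KERNEL = np.zeros((3, 3, 3))
_NEIGHBOR_KERNEL[1, 1, 0] = _NEIGHBOR_KERNEL[1, 1, 2] = 1
_NEIGHBOR_KERNEL[1, 0, 1] = _NEIGHBOR_KERNEL[1, 2, 1] = 1
_NEIGHBOR_KERNEL[0, 1, 1] = _NEIGHBOR_KERNEL[2, 1, 1] = 1


def segment_groundtruth(mu_volume: np.ndarray,
                        table: CoefficientTable | None = None,
                        means: np.ndarray | None = None,
                        method: str = "mrf",
                        beta: float = 1.0,
                        n_sweeps: int = 10,
                        noise_sd: float = 0.005) -> SegmentationMap:
    """Segment an attenuation volume into the K attenuation regions.

    ``method='threshold'`` assigns each voxel the nearest region mean;
    ``method='mrf'`` additionally regularizes with a Potts prior of strength
    ``beta`` over the 6-neighborhood, optimized by synchronous iterated
    conditional modes (``n_sweeps`` sweeps).  ``noise_sd`` is the Gaussian
    likelihood width (cm^-1).  Empty regions are retained with zero support
    (a warning is logged).
    """
    if means is None:
        table = table or CoefficientTable()
        means = table.as_array()
    means = np.asarray(means, dtype=np.float64)
    K = means.size
    mu = np.asarray(mu_volume, dtype=np.float64)

    d2 = (mu[None] - means[:, None, None, None]) ** 2 / (2.0 * noise_sd**2)
    labels = np.argmin(d2, axis=0)
    if method == "threshold":
        pass
    elif method == "mrf":
        for _ in range(n_sweeps):
            cost = d2.copy()
            for k in range(K):
                nbr = ndimage.convolve((labels == k).astype(np.float64),
                                       _NEIGHBOR_KERNEL, mode="constant")
                cost[k] -= beta * nbr
            new = np.argmin(cost, axis=0)
            if np.array_equal(new, labels):
                break
            labels = new
    else:
        raise ValueError(f"unknown method {method!r}")

    for k in range(K):
        if not np.any(labels == k):
            log.warning("region %d has zero support after segmentation", k)
    return SegmentationMap(labels=labels.astype(np.uint8), K=K, source="ground_truth")


def assemble_mu(segments: SegmentationMap, table: CoefficientTable | None = None) -> AssembledMuMap:
    """Piecewise-constant attenuation map: region k gets coefficient mu_k."""
    table = table or CoefficientTable()
    if segments.K != table.K:
        raise ValueError(f"segmentation has K={segments.K} but table has K={table.K}")
    mu_hat = table.as_array()[segments.labels]
    return AssembledMuMap(mu_hat=mu_hat, table=table,
                          segmentation_source=segments.source)
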