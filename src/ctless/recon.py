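"""OSEM reconstruction and clinical-protocol post-processing.

The reconstruction is the classical ordered-subsets expectation-maximization
multiplicative update (Hudson-Larkin) with interleaved view ordering and a
uniform positive initialization.  With the attenuation map supplied the
forward/back projections model attenuation (AC); without it the
reconstruction is NAC.  Post-processing follows the clinical protocol: a
zero-phase 3-D Butterworth filter (order 5, cutoff 0.44 cycles/cm) and
extraction of a 32x32 cardiac region of interest centered on the defect
centroid, windowed to the LV maximum and mapped to [0, 255].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .projector import ProjectionSet, SpectProjector


@dataclass
class ReconConfig:
    n_iterations: int = 8
    n_subsets: int = 6
    model_cdr: bool = True
    mu: np.ndarray | None = None
    dtype: type = np.float64


@dataclass
class ReconImage:
    volume: np.ndarray
    voxel_size: float
    window: str = "photopeak"          # which energy window was reconstructed
    mu_source: str = "none"            # none | true | ctless
    iterations: int = 8
    subsets: int = 6


def osem(g: np.ndarray, projector, n_iterations: int = 8, n_subsets: int = 6,
         eps: float = 1e-12, init: np.ndarray | None = None) -> np.ndarray:
    """OSEM estimate of the activity given sinogram(s) ``g``.

    ``g`` has shape ``(n_views, ...)`` or ``(batch, n_views, ...)``; all
    samples in a batch share the projector (same system model and attenuation
    map).  ``projector`` must expose ``project(f, views=...)`` and its exact
    adjoint ``backproject(g, views=...)``.  Subsets partition the views in
    interleaved order; denominators are floored at ``eps``.
    """
    n_views = projector.geometry.n_views
    g = np.asarray(g, dtype=float)
    if g.shape[0] == n_views:
        batch, squeeze = g[None], True
    elif g.ndim >= 2 and g.shape[1] == n_views:
        batch, squeeze = g, False
    else:
        raise ValueError(f"sinogram shape {g.shape} does not match {n_views} views")
    tol = 1e-9 * max(float(batch.max()), 1.0)
    if batch.min() < -tol:
        raise ValueError("projection data must be >= 0")
    batch = np.maximum(batch, 0.0)  # clear FFT rounding dust
    if n_views % n_subsets != 0:
        raise ValueError(f"{n_views} views not divisible by {n_subsets} subsets")
    subsets = [list(range(j, n_views, n_subsets)) for j in range(n_subsets)]

    vol_shape = getattr(projector, "volume_shape", None)
    if vol_shape is None:
        n = projector.n
        vol_shape = (n, n, n)
    B = batch.shape[0]
    if init is None:
        f = np.ones((B,) + vol_shape, dtype=float)
    else:
        f = np.broadcast_to(np.asarray(init, dtype=float), (B,) + vol_shape).copy()

    sens = []
    for sub in subsets:
        ones = np.ones((B, len(sub)) + batch.shape[2:], dtype=float)
        sens.append(np.maximum(projector.backproject(ones, views=sub), eps))
    for _ in range(n_iterations):
        for sub, s in zip(subsets, sens):
            fwd = projector.project(f, views=sub)
            ratio = batch[:, sub] / np.maximum(fwd, eps)
            f = f * projector.backproject(ratio, views=sub) / s
            f = np.maximum(f, 0.0)
    return f[0] if squeeze else f


def reconstruct(proj: ProjectionSet, window: str = "photopeak",
                config: ReconConfig | None = None,
                voxel_size_cm: float = 0.68,
                projector: SpectProjector | None = None) -> ReconImage:
    """Reconstruct one energy window of a projection set."""
    config = config or ReconConfig()
    data = getattr(proj, window)
    n = data.shape[1]
    if projector is None:
        projector = SpectProjector(proj.geometry, n, voxel_size_cm, mu=config.mu,
                                   model_cdr=config.model_cdr, dtype=config.dtype)
    vol = osem(data, projector, config.n_iterations, config.n_subsets)
    return ReconImage(volume=vol, voxel_size=voxel_size_cm, window=window,
                      mu_source="none" if config.mu is None else "given",
                      iterations=config.n_iterations, subsets=config.n_subsets)


def butterworth_filter(image: np.ndarray, order: int = 5,
                       cutoff_cycles_per_cm: float = 0.44,
                       voxel_size_cm: float = 0.68) -> np.ndarray:
    """Zero-phase 3-D Butterworth low-pass, |H(f)| = (1+(f/fc)^(2n))^(-1/2).

    DC gain is exactly 1; the gain at the cutoff frequency is 1/sqrt(2).
    Warns when the cutoff is at or above the Nyquist frequency.
    """
    nyquist = 0.5 / voxel_size_cm
    if cutoff_cycles_per_cm >= nyquist:
        warnings.warn(
            f"Butterworth cutoff {cutoff_cycles_per_cm} cycles/cm is at or above "
            f"Nyquist ({nyquist:.3f} cycles/cm)", stacklevel=2)
    freqs = [np.fft.fftfreq(s, d=voxel_size_cm) for s in image.shape[:-1]]
    freqs.append(np.fft.rfftfreq(image.shape[-1], d=voxel_size_cm))
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    radial = np.sqrt(fx**2 + fy**2 + fz**2)
    gain = 1.0 / np.sqrt(1.0 + (radial / cutoff_cycles_per_cm) ** (2 * order))
    spec = np.fft.rfftn(image) * gain
    return np.fft.irfftn(spec, s=image.shape, axes=range(image.ndim))


@dataclass
class CardiacROI:
    """32x32 short-axis cardiac region, windowed to [0, 255]."""

    pixels: np.ndarray
    x_lv: float
    center_voxel: tuple[int, int, int]
    padded: bool = False

    def __post_init__(self):
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("ROI pixel values must lie in [0, 255]")


def extract_cardiac_roi(image: np.ndarray, defect_centroid, lv_mask: np.ndarray,
                        roi_size: int = 32) -> CardiacROI:
    """Extract the short-axis ROI around the defect centroid.

    The slice is the single transaxial plane through the centroid (phantoms
    are built with the LV long axis grid-aligned, so short-axis reorientation
    is the identity); ties in the plane index break toward the lower index.
    Values are clipped to ``[0, x_LV]`` (the LV-wall maximum) and affinely
    mapped to ``[0, 255]``.  Regions outside the volume are zero-padded.
    """
    if not np.any(lv_mask):
        raise ValueError("empty LV mask")
    cx, cy, cz = defect_centroid
    nz = image.shape[2]
    iz = int(np.ceil(cz - 0.5))
    if not (0 <= iz < nz):
        raise ValueError("defect centroid outside the volume")
    x_lv = float(image[lv_mask].max())
    plane = image[:, :, iz]

    half = roi_size // 2
    ix = int(np.ceil(cx - 0.5))
    iy = int(np.ceil(cy - 0.5))
    out = np.zeros((roi_size, roi_size), dtype=float)
    x0, x1 = ix - half, ix + half
    y0, y1 = iy - half, iy + half
    sx0, sx1 = max(x0, 0), min(x1, image.shape[0])
    sy0, sy1 = max(y0, 0), min(y1, image.shape[1])
    padded = (sx0, sx1, sy0, sy1) != (x0, x1, y0, y1)
    if padded:
        warnings.warn("cardiac ROI extends past the volume edge; zero-padded",
                      stacklevel=2)
    out[sx0 - x0:sx1 - x0, sy0 - y0:sy1 - y0] = plane[sx0:sx1, sy0:sy1]
    if x_lv > 0:
        out = np.clip(np.clip(out, 0.0, x_lv) * (255.0 / x_lv), 0.0, 255.0)
    else:
        out = np.zeros_like(out)
    return CardiacROI(pixels=out, x_lv=x_lv, center_voxel=(ix, iy, iz), padded=padded)
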