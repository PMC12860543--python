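"""Synthetic perfusion-defect definition and projection-domain insertion.

The defect catalogue is the full factorial of three circumferential extents
(30, 60, 90 degrees around the LV wall), three severities (10%, 25%, 50%
activity reduction relative to normal myocardium) and three wall locations
(anterior, inferior, lateral): 27 defect types.

Defects are inserted into the *photopeak* projections only, by subtracting
the forward projection of the defect perturbation (severity x activity inside
the angular sector of the LV wall) from the noise-free sinogram; scatter
projections are never modified.  Noise is added after insertion, so
defect-present and defect-absent data are independent Poisson realizations.

Angular convention: the sector is measured in the short-axis (transaxial)
plane about the LV long axis.  With anterior at -y, the location center
directions are anterior (0, -1), lateral (+1, 0) (patient-left free wall)
and inferior (0, +1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .phantom import Phantom
from .projector import ProjectionSet, SpectProjector

EXTENTS_DEG = (30.0, 60.0, 90.0)
SEVERITIES = (0.10, 0.25, 0.50)
LOCATIONS = ("anterior", "inferior", "lateral")

_LOCATION_DIRECTION = {
    "anterior": np.array([0.0, -1.0]),
    "inferior": np.array([0.0, 1.0]),
    "lateral": np.array([1.0, 0.0]),
}

#: fraction of the wall's axial span covered by the (transmural) defect
AXIAL_FRACTION = 0.8


@dataclass(frozen=True)
class DefectSpec:
    extent_deg: float
    severity_frac: float
    location: str
    centroid: tuple[float, float, float] | None = None  # voxel coords, set on insertion

    def __post_init__(self):
        if not (0.0 <= self.severity_frac <= 1.0):
            raise ValueError("severity must be in [0, 1]")
        if self.extent_deg <= 0 or self.extent_deg > 360:
            raise ValueError("extent must be in (0, 360] degrees")
        if self.location not in _LOCATION_DIRECTION:
            raise ValueError(f"unknown location {self.location!r}")

    def key(self) -> str:
        return f"e{int(self.extent_deg)}_s{int(round(self.severity_frac * 100))}_{self.location}"


def enumerate_defect_types() -> list[DefectSpec]:
    """The 27 defect types, extent-major, then severity, then location."""
    return [DefectSpec(e, s, loc)
            for e, s, loc in product(EXTENTS_DEG, SEVERITIES, LOCATIONS)]


def defect_mask(phantom: Phantom, spec: DefectSpec) -> np.ndarray:
    """Boolean mask of the LV-wall sector the defect occupies (full thickness)."""
    wall = phantom.lv_wall_mask()
    if not wall.any():
        raise ValueError("phantom LV wall is empty")
    ax = phantom.world_axes()
    x, y, z = np.meshgrid(*ax, indexing="ij")
    lv = phantom.lv_geometry
    dx, dy = x - lv.center[0], y - lv.center[1]
    r = np.hypot(dx, dy)
    u = _LOCATION_DIRECTION[spec.location]
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(r > 0, (dx * u[0] + dy * u[1]) / np.maximum(r, 1e-12), 1.0)
    sector = cosang >= np.cos(np.deg2rad(spec.extent_deg / 2.0))

    zw = z[wall]
    z_lo, z_hi = zw.min(), zw.max()
    z_mid = 0.5 * (z_lo + z_hi)
    half = 0.5 * AXIAL_FRACTION * (z_hi - z_lo)
    band = (z >= z_mid - half) & (z <= z_mid + half)

    mask = wall & sector & band
    if not mask.any():
        raise ValueError("defect sector does not intersect the LV wall")
    return mask


def defect_perturbation(phantom: Phantom, spec: DefectSpec) -> np.ndarray:
    """Activity decrement volume: severity x activity inside the sector."""
    mask = defect_mask(phantom, spec)
    pert = np.zeros_like(phantom.activity, dtype=np.float64)
    pert[mask] = spec.severity_frac * phantom.activity[mask]
    return pert


def defect_centroid(phantom: Phantom, spec: DefectSpec) -> tuple[float, float, float]:
    """Centroid of the defect sector in (fractional) voxel coordinates."""
    mask = defect_mask(phantom, spec)
    idx = np.argwhere(mask)
    c = idx.mean(axis=0)
    return (float(c[0]), float(c[1]), float(c[2]))


def insert_defect(proj: ProjectionSet, phantom: Phantom, spec: DefectSpec,
                  projector: SpectProjector | None = None) -> ProjectionSet:
    """Subtract the forward-projected perturbation from the photopeak window.

    ``proj`` must be the noise-free projection of this phantom; the supplied
    ``projector`` (or a freshly built one) must model the same system,
    including the phantom's attenuation.  The scatter window is returned
    unchanged; the photopeak result is clipped at 0.
    """
    if spec.severity_frac == 0.0:
        return ProjectionSet(photopeak=proj.photopeak.copy(), scatter=proj.scatter,
                             geometry=proj.geometry)
    pert = defect_perturbation(phantom, spec)
    if projector is None:
        projector = SpectProjector(proj.geometry, phantom.shape[0], phantom.voxel_size,
                                   mu=phantom.mu, model_cdr=True)
    dproj = projector.project(pert)
    return ProjectionSet(
        photopeak=np.maximum(proj.photopeak - dproj, 0.0),
        scatter=proj.scatter,
        geometry=proj.geometry,
    )
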