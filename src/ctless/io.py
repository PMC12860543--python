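"""Volume (NIfTI) and projection-set (HDF5) persistence.

Volumes are written one per file as ``.nii``/``.nii.gz`` with an isotropic
affine carrying the voxel size; label volumes are stored as unsigned
integers.  Projection sets use an HDF5 container with datasets
``/photopeak`` and ``/scatter`` (views x bins x slices) and the acquisition
geometry stored as root attributes.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .projector import AcquisitionGeometry, ProjectionSet

_GEOM_ATTRS = (
    "n_views", "arc_deg", "start_deg", "n_bins", "bin_size_cm",
    "cdr_fwhm_intercept_cm", "cdr_fwhm_slope", "detector_standoff_cm",
)


def save_volume(volume: np.ndarray, path, voxel_size_cm: float = 0.68) -> None:
    data = volume
    if np.issubdtype(volume.dtype, np.integer) or volume.dtype == bool:
        data = volume.astype(np.uint16)
    affine = np.diag([voxel_size_cm * 10.0] * 3 + [1.0])  # NIfTI units: mm
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    """Returns (array, voxel_size_cm)."""
    img = nib.load(str(path))
    voxel_mm = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), voxel_mm / 10.0


def save_projection_set(proj: ProjectionSet, path) -> None:
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("photopeak", data=proj.photopeak)
        fh.create_dataset("scatter", data=proj.scatter)
        g = proj.geometry
        for name in _GEOM_ATTRS:
            fh.attrs[name] = getattr(g, name)
        fh.attrs["photopeak_window_kev"] = g.photopeak_window_kev
        fh.attrs["scatter_window_kev"] = g.scatter_window_kev
        fh.attrs["noise_realization"] = proj.noise_realization
        fh.attrs["count_scale"] = proj.count_scale
        if proj.seed is not None:
            fh.attrs["seed"] = proj.seed


def load_projection_set(path) -> ProjectionSet:
    with h5py.File(str(path), "r") as fh:
        kwargs = {name: fh.attrs[name] for name in _GEOM_ATTRS}
        kwargs["n_views"] = int(kwargs["n_views"])
        kwargs["n_bins"] = int(kwargs["n_bins"])
        geom = AcquisitionGeometry(
            **{k: (float(v) if k not in ("n_views", "n_bins") else v)
               for k, v in kwargs.items()},
            photopeak_window_kev=tuple(fh.attrs["photopeak_window_kev"]),
            scatter_window_kev=tuple(fh.attrs["scatter_window_kev"]),
        )
        return ProjectionSet(
            photopeak=fh["photopeak"][()],
            scatter=fh["scatter"][()],
            geometry=geom,
            noise_realization=bool(fh.attrs.get("noise_realization", False)),
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            count_scale=float(fh.attrs.get("count_scale", 1.0)),
        )
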