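"""Synthetic torso/cardiac phantoms for emission-tomography simulation.

Builds voxelized digital subjects from analytic solids (elliptic-cylinder
torso, ellipsoidal lungs and liver, cylindrical spine/sternum, a
half-ellipsoid left-ventricular wall, and a thin patient table) on an
axis-aligned grid.  Each subject carries three co-registered volumes:

* ``labels`` — one of six attenuation regions per voxel (skin and
  subcutaneous adipose, muscles and organs, lungs, bones, patient table,
  background),
* ``mu`` — the linear attenuation coefficient (cm^-1) at the emission
  energy, piecewise constant over the regions,
* ``activity`` — the tracer distribution, with elevated uptake in the LV
  myocardium and liver.

Cohorts add population variability: per-region attenuation coefficients are
drawn from the configured (mean, sd), and anatomy scale, LV pose and uptake
levels are jittered per subject.  Everything is deterministic given a seed.

Coordinate convention: 0-based voxel indices; the world coordinate of a
voxel center is ``(index + 0.5 - n/2) * voxel_size`` so the volume is
centered on the rotation axis (the z axis, the subject's long axis).
Anterior is the -y direction; the patient table lies posterior (+y).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

REGION_NAMES = (
    "skin_adipose",
    "muscles_organs",
    "lungs",
    "bones",
    "patient_table",
    "background",
)

#: label integers, in Table order
SKIN, MUSCLE, LUNG, BONE, TABLE, BACKGROUND = range(6)


@dataclass(frozen=True)
class CoefficientTable:
    """Predefined per-region attenuation coefficients (cm^-1).

    ``values[k]`` is the coefficient assigned to region ``names[k]`` when a
    piecewise-constant attenuation map is assembled.  ``population`` holds
    optional per-region (mean, sd) pairs describing the spread of the
    coefficient across a subject population; cohort generation samples from
    these when jitter is enabled.
    """

    names: tuple[str, ...] = REGION_NAMES
    values: tuple[float, ...] = (0.13, 0.16, 0.03, 0.22, 0.09, 0.0)
    population: tuple[tuple[float, float], ...] = (
        (0.1339, 0.0029),
        (0.1604, 0.0022),
        (0.0344, 0.0035),
        (0.2156, 0.0048),
        (0.0884, 0.0045),
        (0.0, 0.0),
    )

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("names and values length mismatch")
        if any(v < 0 for v in self.values):
            raise ValueError("attenuation coefficients must be >= 0")
        if self.values[self.names.index("background")] != 0.0:
            raise ValueError("background coefficient must be 0")

    @property
    def K(self) -> int:
        return len(self.names)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    @classmethod
    def from_yaml(cls, path) -> "CoefficientTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        regions = doc["regions"]
        return cls(
            names=tuple(r["name"] for r in regions),
            values=tuple(float(r["mu"]) for r in regions),
            population=tuple(
                (float(r.get("population_mean", r["mu"])), float(r.get("population_sd", 0.0)))
                for r in regions
            ),
        )

    @classmethod
    def default(cls) -> "CoefficientTable":
        with resources.as_file(resources.files("ctless.data") / "coefficients.yaml") as p:
            return cls.from_yaml(p)

    def to_yaml(self, path) -> None:
        doc = {
            "regions": [
                {
                    "name": n,
                    "mu": float(v),
                    "population_mean": float(m),
                    "population_sd": float(s),
                }
                for n, v, (m, s) in zip(self.names, self.values, self.population)
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


@dataclass(frozen=True)
class LVGeometry:
    """Pose and shape of the half-ellipsoid LV wall (cm, world coords)."""

    center: tuple[float, float, float] = (3.6, -3.0, 0.8)
    outer_radii: tuple[float, float, float] = (3.2, 3.2, 4.6)
    wall_thickness_cm: float = 1.0
    #: wall kept for z <= center_z + basal_cut * outer_radii_z (cup opens to +z)
    basal_cut: float = 0.55


@dataclass(frozen=True)
class GeometryParams:
    """Anatomical dimensions in cm; defaults sized for a 64-voxel, 0.68 cm grid."""

    torso_radii: tuple[float, float] = (14.0, 9.5)
    torso_z_margin_cm: float = 2.0
    skin_thickness_cm: float = 1.2
    lung_radii: tuple[float, float, float] = (4.0, 5.2, 8.0)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-5.4, -0.8, 3.2),
        (5.4, -0.8, 3.2),
    )
    spine_radius_cm: float = 1.7
    spine_center_y: float = 6.6
    sternum_radius_cm: float = 0.8
    sternum_center_y: float = -8.0
    liver_center: tuple[float, float, float] = (-4.8, 1.2, -4.8)
    liver_radii: tuple[float, float, float] = (5.6, 4.2, 4.2)
    table_gap_cm: float = 0.8
    table_thickness_cm: float = 1.4
    table_halfwidth_cm: float = 15.5
    lv: LVGeometry = field(default_factory=LVGeometry)

    def scaled(self, factor: float, lv_factor: float | None = None) -> "GeometryParams":
        """Shrink/grow the torso by ``factor`` (LV by ``lv_factor``, default sqrt).

        Used to fit the anatomy into smaller fields of view while keeping the
        heart near clinical size relative to the system resolution.
        """
        if lv_factor is None:
            lv_factor = float(np.sqrt(factor))
        s = factor
        lv = self.lv
        return replace(
            self,
            torso_radii=(self.torso_radii[0] * s, self.torso_radii[1] * s),
            skin_thickness_cm=self.skin_thickness_cm * s,
            lung_radii=tuple(r * s for r in self.lung_radii),
            lung_centers=tuple(tuple(c * s for c in ctr) for ctr in self.lung_centers),
            spine_radius_cm=self.spine_radius_cm * s,
            spine_center_y=self.spine_center_y * s,
            sternum_radius_cm=self.sternum_radius_cm * s,
            sternum_center_y=self.sternum_center_y * s,
            liver_center=tuple(c * s for c in self.liver_center),
            liver_radii=tuple(r * s for r in self.liver_radii),
            table_gap_cm=self.table_gap_cm * s,
            table_thickness_cm=self.table_thickness_cm * s,
            table_halfwidth_cm=self.table_halfwidth_cm * s,
            lv=replace(
                lv,
                center=tuple(c * s for c in lv.center),
                outer_radii=tuple(r * lv_factor for r in lv.outer_radii),
                wall_thickness_cm=lv.wall_thickness_cm * lv_factor,
            ),
        )


@dataclass(frozen=True)
class UptakeParams:
    """Relative tracer concentration per tissue (arbitrary count-rate units)."""

    lv_wall: float = 8.0
    liver: float = 2.5
    soft_tissue: float = 1.0
    skin_adipose: float = 0.5
    bones: float = 0.4
    lungs: float = 0.25


@dataclass(frozen=True)
class VariabilityParams:
    """Per-subject population jitter used by cohort generation.

    All-zero jitter yields identical subjects (degenerate distribution).
    ``mu_jitter`` switches the per-region attenuation coefficients from the
    predefined table values to draws from the table's population (mean, sd).
    """

    anatomy_scale_sd: float = 0.10
    lv_center_sd_cm: float = 0.7
    lv_size_sd: float = 0.08
    wall_thickness_sd: float = 0.10
    lv_uptake_sd: float = 1.0
    tissue_uptake_sd: float = 0.10
    liver_uptake_sd: float = 0.5
    #: anterior chest-wall adipose pad (breast/habitus analog): per-subject
    #: thickness ~ N(mean, sd) clipped to [0, 3.5] cm.  This differential
    #: attenuation across subjects is the main clinical driver of artifacts
    #: in reconstructions without attenuation compensation.
    chest_pad_mean_cm: float = 1.4
    chest_pad_sd_cm: float = 1.1
    lung_size_sd: float = 0.10
    #: diaphragm-position analog: per-subject axial shift of the lungs (cm);
    #: controls how much low-attenuation lung vs. high-attenuation abdomen
    #: lies under and behind the inferior LV wall.
    diaphragm_sd_cm: float = 1.2
    mu_jitter: bool = True

    @classmethod
    def none(cls) -> "VariabilityParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                   chest_pad_mean_cm=0.0, chest_pad_sd_cm=0.0,
                   lung_size_sd=0.0, diaphragm_sd_cm=0.0, mu_jitter=False)


@dataclass(frozen=True)
class PhantomParams:
    grid: int = 64
    voxel_size: float = 0.68
    geometry: GeometryParams = field(default_factory=GeometryParams)
    uptake: UptakeParams = field(default_factory=UptakeParams)
    table: CoefficientTable = field(default_factory=CoefficientTable)
    variability: VariabilityParams = field(default_factory=VariabilityParams.none)

    @classmethod
    def for_grid(cls, grid: int, voxel_size: float = 0.68, **kw) -> "PhantomParams":
        """Defaults with the torso rescaled to fit a ``grid`` voxel FOV.

        The LV keeps its clinical size (hearts do not shrink with the field
        of view); only its position scales with the torso.
        """
        fov = grid * voxel_size
        factor = min(1.0, fov / (64 * 0.68))
        return cls(grid=grid, voxel_size=voxel_size,
                   geometry=GeometryParams().scaled(factor, lv_factor=1.0), **kw)


@dataclass
class Phantom:
    """One synthetic subject: label, attenuation and activity volumes."""

    labels: np.ndarray
    mu: np.ndarray
    activity: np.ndarray
    voxel_size: float
    lv_geometry: LVGeometry
    subject_id: str
    table: CoefficientTable = field(default_factory=CoefficientTable)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world_axes(self):
        return _axes(self.labels.shape[0], self.voxel_size)

    def lv_wall_mask(self) -> np.ndarray:
        """Boolean mask of the LV myocardium (subset of the muscles region)."""
        x, y, z = np.meshgrid(*self.world_axes(), indexing="ij")
        return _lv_wall(x, y, z, self.lv_geometry)


def _axes(n: int, voxel: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = (np.arange(n) + 0.5 - n / 2) * voxel
    return c, c, c


def _ellipsoid(x, y, z, center, radii):
    return ((x - center[0]) / radii[0]) ** 2 + ((y - center[1]) / radii[1]) ** 2 + (
        (z - center[2]) / radii[2]
    ) ** 2 <= 1.0


def _lv_shell(x, y, z, lv: LVGeometry, inset: float):
    radii = tuple(max(r - inset, 1e-3) for r in lv.outer_radii)
    return _ellipsoid(x, y, z, lv.center, radii)


def _lv_wall(x, y, z, lv: LVGeometry) -> np.ndarray:
    outer = _lv_shell(x, y, z, lv, 0.0)
    inner = _lv_shell(x, y, z, lv, lv.wall_thickness_cm)
    cup = z <= lv.center[2] + lv.basal_cut * lv.outer_radii[2]
    return outer & ~inner & cup


def _lv_interior(x, y, z, lv: LVGeometry) -> np.ndarray:
    return _lv_shell(x, y, z, lv, 0.0)


def generate_phantom(params: PhantomParams | None = None, seed: int = 0) -> Phantom:
    """Build one phantom; bit-identical volumes for identical params and seed.

    Raises ``ValueError`` for grids below 32 voxels per axis or too small to
    contain the configured LV.
    """
    params = params or PhantomParams()
    n, voxel = params.grid, params.voxel_size
    if n < 32:
        raise ValueError(f"grid size {n} < 32 voxels per axis")
    rng = np.random.default_rng(seed)
    v = params.variability
    geo = params.geometry
    upt = params.uptake

    # --- per-subject jitter -------------------------------------------------
    sx = float(np.clip(1.0 + rng.normal(0.0, v.anatomy_scale_sd), 0.82, 1.18))
    sy = float(np.clip(1.0 + rng.normal(0.0, v.anatomy_scale_sd), 0.82, 1.18))
    lv0 = geo.lv
    lv = replace(
        lv0,
        center=(
            lv0.center[0] * sx + rng.normal(0.0, v.lv_center_sd_cm),
            lv0.center[1] * sy + rng.normal(0.0, v.lv_center_sd_cm),
            lv0.center[2] + rng.normal(0.0, v.lv_center_sd_cm),
        ),
        outer_radii=tuple(
            r * float(np.clip(1.0 + rng.normal(0.0, v.lv_size_sd), 0.8, 1.2))
            for r in lv0.outer_radii
        ),
        wall_thickness_cm=lv0.wall_thickness_cm
        * float(np.clip(1.0 + rng.normal(0.0, v.wall_thickness_sd), 0.75, 1.25)),
    )
    lv_uptake = max(float(upt.lv_wall + rng.normal(0.0, v.lv_uptake_sd)), 1.0)
    tissue_uptake = max(float(upt.soft_tissue + rng.normal(0.0, v.tissue_uptake_sd)), 0.05)
    liver_uptake = max(float(upt.liver + rng.normal(0.0, v.liver_uptake_sd)), 0.1)
    chest_pad = float(np.clip(rng.normal(v.chest_pad_mean_cm, v.chest_pad_sd_cm), 0.0, 3.5)) \
        if (v.chest_pad_mean_cm > 0 or v.chest_pad_sd_cm > 0) else 0.0
    lung_scale = float(np.clip(1.0 + rng.normal(0.0, v.lung_size_sd), 0.75, 1.25))

    fov_half = n * voxel / 2.0
    torso_ax = geo.torso_radii[0] * sx
    torso_ay = geo.torso_radii[1] * sy
    table_y1 = torso_ay + geo.table_gap_cm + geo.table_thickness_cm
    if torso_ax > fov_half - 0.5 or table_y1 > fov_half - 0.1:
        raise ValueError("anatomy does not fit in the field of view")
    margin = 0.3
    if (lv.outer_radii[0] + margin > torso_ax or lv.outer_radii[1] + margin > torso_ay
            or lv.outer_radii[2] + margin > n * voxel / 2.0):
        raise ValueError("grid/torso too small to contain the configured LV geometry")
    # clamp the jittered LV pose back inside the torso
    cx = float(np.clip(lv.center[0], -(torso_ax - lv.outer_radii[0] - margin),
                       torso_ax - lv.outer_radii[0] - margin))
    cy = float(np.clip(lv.center[1], -(torso_ay - lv.outer_radii[1] - margin),
                       torso_ay - lv.outer_radii[1] - margin))
    cz = float(np.clip(lv.center[2], -(n * voxel / 2.0 - lv.outer_radii[2] - margin),
                       n * voxel / 2.0 - lv.outer_radii[2] - margin))
    lv = replace(lv, center=(cx, cy, cz))

    ax = _axes(n, voxel)
    x, y, z = np.meshgrid(*ax, indexing="ij")

    labels = np.full((n, n, n), BACKGROUND, dtype=np.uint8)

    # patient table: thin slab posterior of the torso
    table_mask = (
        (y >= torso_ay + geo.table_gap_cm)
        & (y <= table_y1)
        & (np.abs(x) <= geo.table_halfwidth_cm)
    )
    labels[table_mask] = TABLE

    z_half = n * voxel / 2.0 - geo.torso_z_margin_cm
    torso = ((x / torso_ax) ** 2 + (y / torso_ay) ** 2 <= 1.0) & (np.abs(z) <= z_half)
    # the inner (muscle) ellipse is shifted posteriorly by half the anterior
    # adipose pad, so the skin/adipose shell is thicker over the chest wall
    t = geo.skin_thickness_cm
    inner_ay = max(torso_ay - t - chest_pad / 2.0, 0.5)
    inner = (
        (x / max(torso_ax - t, 0.5)) ** 2
        + ((y - chest_pad / 2.0) / inner_ay) ** 2
        <= 1.0
    ) & (np.abs(z) <= z_half)
    labels[torso] = SKIN
    labels[inner] = MUSCLE

    lung_radii = tuple(r * lung_scale for r in geo.lung_radii)
    diaphragm_shift = float(rng.normal(0.0, v.diaphragm_sd_cm))
    for ctr in geo.lung_centers:
        ctr = (ctr[0] * sx, ctr[1] * sy, ctr[2] + diaphragm_shift)
        lungs = _ellipsoid(x, y, z, ctr, lung_radii) & inner
        labels[lungs] = LUNG

    spine = (
        (x**2 + (y - geo.spine_center_y * sy) ** 2 <= geo.spine_radius_cm**2)
        & (np.abs(z) <= z_half)
        & inner
    )
    sternum = (
        (x**2 + (y - geo.sternum_center_y * sy) ** 2 <= geo.sternum_radius_cm**2)
        & (np.abs(z) <= z_half * 0.6)
        & inner
    )
    labels[spine | sternum] = BONE

    # carve the cardiac region back to muscle so the LV wall is always a
    # subset of the muscles-and-organs label (the heart may displace lung
    # or chest-wall adipose)
    heart = _lv_interior(x, y, z, lv) & torso
    labels[heart] = MUSCLE
    wall = _lv_wall(x, y, z, lv) & torso

    # force all six labels to be present even under extreme jitter
    for k in range(6):
        if not (labels == k).any():
            raise ValueError(f"region {REGION_NAMES[k]} empty; geometry invalid")

    # --- attenuation --------------------------------------------------------
    tbl = params.table
    if v.mu_jitter:
        mus = np.array(
            [
                max(rng.normal(m, s), 0.0) if k != BACKGROUND else 0.0
                for k, (m, s) in enumerate(tbl.population)
            ]
        )
    else:
        mus = tbl.as_array()
    mu = mus[labels].astype(np.float64)

    # --- activity -----------------------------------------------------------
    uptake_by_label = np.array(
        [upt.skin_adipose * tissue_uptake, tissue_uptake, upt.lungs * tissue_uptake,
         upt.bones * tissue_uptake, 0.0, 0.0]
    )
    activity = uptake_by_label[labels]
    liver_ctr = (geo.liver_center[0] * sx, geo.liver_center[1] * sy, geo.liver_center[2])
    liver = _ellipsoid(x, y, z, liver_ctr, geo.liver_radii) & (labels == MUSCLE) & ~heart
    activity[liver] = liver_uptake
    activity[heart] = 0.6 * tissue_uptake  # blood pool
    activity[wall] = lv_uptake
    activity = np.maximum(activity, 0.0)

    return Phantom(
        labels=labels,
        mu=mu,
        activity=activity,
        voxel_size=voxel,
        lv_geometry=lv,
        subject_id=f"subj-{seed:08d}",
        table=tbl,
    )


def generate_cohort(
    n: int,
    params: PhantomParams | None = None,
    variability: VariabilityParams | None = None,
    seed: int = 0,
) -> list[Phantom]:
    """Generate ``n`` independent subjects from one master seed."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    params = params or PhantomParams(variability=VariabilityParams())
    if variability is not None:
        params = replace(params, variability=variability)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    out = []
    for i, s in enumerate(child_seeds):
        ph = generate_phantom(params, seed=int(s))
        ph.subject_id = f"subj-{seed}-{i:04d}"
        out.append(ph)
    return out
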