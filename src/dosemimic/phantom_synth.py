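"""Seeded deformable thorax-phantom cohort with analytic dose styles.

The generator produces a cohort of left-breast radiotherapy phantoms:
a common template (elliptic-cylinder body, two ellipsoidal lungs, heart,
left-breast + chest-wall target, supraclavicular target, contralateral
breast, esophagus, spinal cord) warped per case by a smooth random
B-spline displacement field, carrying one of two analytic dose styles:

* ``tangential`` — prescription dose inside the targets, decaying with
  an exponential lateral falloff inside two oblique beam corridors
  through the breast target, and essentially no contralateral dose
  (emulating tangential partial-arc delivery);
* ``helical`` — prescription-conformal target dose plus an extended
  low-dose bath decaying exponentially with distance to the target
  everywhere in the body (emulating helical delivery's low-dose bath).

Cohort generation is a pure function of :class:`PhantomSpec` (seed
included): regenerating with the same spec is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .registration import apply_field
from .volumes_io import (
    BinaryMask,
    DeformationField,
    GridGeometry,
    ImageVolume,
    PatientCase,
    StructureSet,
)

__all__ = [
    "PhantomSpec",
    "PhantomCohort",
    "default_grid",
    "make_template_phantom",
    "sample_deformation",
    "synth_dose",
    "make_phantom_cohort",
]

# CT grid: 3 mm in-plane dose-grid resolution, 5 mm slice thickness
_DEFAULT_SHAPE = (96, 96, 48)
_DEFAULT_SPACING = (3.0, 3.0, 5.0)

_SOFT_TISSUE_HU = 20.0
_LUNG_HU = -700.0
_AIR_HU = -1000.0


def default_grid(
    shape: tuple[int, int, int] = _DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = _DEFAULT_SPACING,
) -> GridGeometry:
    """Default phantom grid, centered on the patient origin."""
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    return GridGeometry(origin=origin, spacing=spacing, shape=shape)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom-cohort generation run.

    ``deform_amplitude_mm`` scales the random inter-patient deformation;
    ``bath_dose_gy`` and ``bath_lambda_mm`` set the helical low-dose
    bath's peak and decay length; ``tangential_falloff_mm`` sets the
    lateral dose decay of the tangential corridors.
    """

    grid: GridGeometry = dc_field(default_factory=default_grid)
    seed: int = 0
    deform_amplitude_mm: float = 5.0
    dose_style: str = "tangential"  # {"tangential", "helical"}
    prescription_gy: float = 50.0
    bath_dose_gy: float = 6.0
    bath_lambda_mm: float = 40.0
    tangential_falloff_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.deform_amplitude_mm < 0:
            raise ValueError("deformation amplitude must be >= 0")
        if min(self.bath_dose_gy, self.bath_lambda_mm, self.tangential_falloff_mm) <= 0:
            raise ValueError("bath and falloff parameters must be positive")
        if self.dose_style not in ("tangential", "helical"):
            raise ValueError(f"unknown dose style {self.dose_style!r}")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")


@dataclass
class PhantomCohort:
    """A template, its deformed cases, and the generating true fields."""

    template: PatientCase
    cases: list[PatientCase]
    true_fields: list[DeformationField]
    spec: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# template anatomy
# ---------------------------------------------------------------------------

def _coordinate_grids(geom: GridGeometry):
    """Physical (x, y, z) mm coordinate grids in array order (z, y, x)."""
    xs, ys, zs = geom.axis_coordinates()
    z, y, x = np.meshgrid(zs, ys, xs, indexing="ij")
    return x, y, z


def _ellipsoid(x, y, z, center, semi_axes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def make_template_phantom(grid: GridGeometry | None = None) -> PatientCase:
    """Build the common template anatomy (structures only, no dose).

    LPS axes: +x is patient left (ipsilateral; the disease is left-
    sided), -y anterior, +z superior.  The breast target includes a
    chest-wall extension reaching the midline, as for post-mastectomy
    chest-wall irradiation.
    """
    geom = grid or default_grid()
    x, y, z = _coordinate_grids(geom)
    extent = [(n - 1) * s for n, s in zip(geom.shape, geom.spacing)]
    if extent[0] < 220 or extent[1] < 160 or extent[2] < 160:
        raise ValueError(f"grid extent {extent} mm too small to contain the anatomy")

    body = ((x / 130.0) ** 2 + (y / 95.0) ** 2) <= 1.0

    lung_ipsi = _ellipsoid(x, y, z, (68, 12, -10), (46, 60, 85)) & body
    lung_contra = _ellipsoid(x, y, z, (-45, -15, -10), (36, 50, 82)) & body
    lungs = lung_ipsi | lung_contra

    heart = _ellipsoid(x, y, z, (18, -6, -45), (46, 44, 50)) & body & ~lungs

    # left breast mound + chest-wall slab + parasternal (internal
    # mammary) strip: a locally-advanced target chain whose medial edge
    # overlies the mediastinum, so the contralateral lung sits a few cm
    # from the target and receives a tangible helical bath
    breast_mound = _ellipsoid(x, y, z, (72, -82, -30), (58, 40, 62))
    chest_wall = (
        (x >= -5)
        & (x <= 100)
        & (y <= -52)
        & (np.abs(z + 25) <= 62)
    )
    imn_strip = (
        (x >= -15) & (x <= 15) & (y >= -85) & (y <= -30) & (z >= -85) & (z <= 55)
    )
    ptv_breast = (breast_mound | chest_wall | imn_strip) & body & ~lungs & ~heart

    ptv_scf = _ellipsoid(x, y, z, (42, -25, 92), (32, 26, 28)) & body & ~lungs

    breast_contra = (
        _ellipsoid(x, y, z, (-62, -80, -28), (44, 30, 50)) & body & ~lungs
    )
    # keep the contralateral breast clear of the target
    breast_contra &= ~ptv_breast

    esophagus = (((x - 0.0) ** 2 + (y - 18.0) ** 2) <= 8.0**2) & (z >= -95) & (z <= 70)
    esophagus &= body & ~lungs
    cord = (((x - 0.0) ** 2 + (y - 62.0) ** 2) <= 6.0**2) & body

    hu = np.full(geom.array_shape, _AIR_HU)
    hu[body] = _SOFT_TISSUE_HU
    hu[lungs] = _LUNG_HU
    # mild smoothing gives the piecewise-constant phantom the soft edges
    # a real CT has (and a usable gradient for intensity registration)
    hu = ndimage.gaussian_filter(hu, sigma=1.0)

    structures = StructureSet()
    for name, m in [
        ("Body", body),
        ("Lung_Ipsi", lung_ipsi),
        ("Lung_Contra", lung_contra),
        ("Heart", heart),
        ("PTV_Breast", ptv_breast),
        ("PTV_SCF", ptv_scf),
        ("Breast_Contra", breast_contra),
        ("Esophagus", esophagus),
        ("SpinalCord", cord),
    ]:
        structures.add(name, BinaryMask(geom, m, name=name))
    ct = ImageVolume(geom, hu, modality="CT")
    return PatientCase(id="template", ct=ct, dose=None, structures=structures)


# ---------------------------------------------------------------------------
# random smooth deformations
# ---------------------------------------------------------------------------

def sample_deformation(
    grid: GridGeometry, seed: int, amplitude_mm: float = 5.0
) -> DeformationField:
    """Smooth random displacement field from B-spline-style coefficients.

    Random normal coefficients with standard deviation ``amplitude_mm``
    are drawn on a coarse 50 mm control grid and upsampled with cubic
    interpolation; the magnitude is clamped to ``2 * amplitude_mm``.
    Deterministic in ``seed``.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    nz, ny, nx = grid.array_shape
    if amplitude_mm == 0:
        return DeformationField(grid, np.zeros((nz, ny, nx, 3)))
    control_mm = 50.0
    rng = np.random.default_rng(seed)
    n_ctrl = [
        max(4, int(np.ceil((n - 1) * s / control_mm)) + 3)
        for n, s in zip(grid.array_shape, (grid.spacing[2], grid.spacing[1], grid.spacing[0]))
    ]
    coeffs = rng.normal(0.0, amplitude_mm, size=(3, *n_ctrl))
    vectors = np.empty((nz, ny, nx, 3))
    zoom = [nz / n_ctrl[0], ny / n_ctrl[1], nx / n_ctrl[2]]
    for c in range(3):
        vectors[..., c] = ndimage.zoom(coeffs[c], zoom, order=3, mode="nearest")
    mag = np.linalg.norm(vectors, axis=-1, keepdims=True)
    limit = 2.0 * amplitude_mm
    scale = np.where(mag > limit, limit / np.maximum(mag, 1e-12), 1.0)
    return DeformationField(grid, vectors * scale)


# ---------------------------------------------------------------------------
# analytic dose styles
# ---------------------------------------------------------------------------

def _distance_to_mm(mask: np.ndarray, geom: GridGeometry) -> np.ndarray:
    """Euclidean distance (mm) from each voxel to the nearest mask voxel."""
    sampling = (geom.spacing[2], geom.spacing[1], geom.spacing[0])
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=sampling)


def synth_dose(case: PatientCase, spec: PhantomSpec) -> ImageVolume:
    """Synthesize the analytic dose for ``case`` in its own geometry."""
    for required in ("PTV_Breast", "PTV_SCF", "Body"):
        if required not in case.structures:
            raise ValueError(f"case lacks required structure {required!r}")
    geom = case.ct.geometry
    body = case.structures["Body"].values
    ptv = case.structures["PTV_Breast"].values | case.structures["PTV_SCF"].values
    rx = spec.prescription_gy

    if spec.dose_style == "helical":
        d_ptv = _distance_to_mm(ptv, geom)
        dose = spec.bath_dose_gy * np.exp(-d_ptv / spec.bath_lambda_mm)
        dose[~body] = 0.0
        dose[ptv] = rx
    else:
        d_perp, in_extent = _tangential_corridor_distance(case, geom)
        falloff = spec.tangential_falloff_mm
        dose = np.where(
            in_extent & (d_perp <= 3.5 * falloff),
            rx * np.exp(-d_perp / falloff),
            0.0,
        )
        dose[~body] = 0.0
        dose[ptv] = rx
    dose = np.clip(dose, 0.0, 1.1 * rx)
    return ImageVolume(geom, dose, modality="DOSE")


def _tangential_corridor_distance(case: PatientCase, geom: GridGeometry):
    """Lateral distance to the two oblique beam corridors.

    The corridors stand in for the entrance/exit paths of tangential
    partial arcs: two planes at roughly +-45 degrees in the axial plane
    through the breast-target centroid.  Returns the perpendicular
    distance (mm) to the nearer plane and the corridor support mask
    (ipsilateral-anterior chest within the target's longitudinal
    extent), so the contralateral side stays unirradiated.
    """
    x, y, z = _coordinate_grids(geom)
    ptv_b = case.structures["PTV_Breast"].values
    idx = np.argwhere(ptv_b)
    # centroid in physical mm (idx columns are z, y, x)
    xs, ys, zs = geom.axis_coordinates()
    cx = float(xs[idx[:, 2]].mean())
    cy = float(ys[idx[:, 1]].mean())
    cz = float(zs[idx[:, 0]].mean())
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    d1 = np.abs(((x - cx) + (y - cy)) * inv_sqrt2)
    d2 = np.abs(((x - cx) - (y - cy)) * inv_sqrt2)
    d_perp = np.minimum(d1, d2)
    in_extent = (x >= 0.0) & (y <= 30.0) & (np.abs(z - cz) <= 75.0)
    return d_perp, in_extent


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def make_phantom_cohort(n: int, spec: PhantomSpec | None = None) -> PhantomCohort:
    """Generate ``n`` deformed template cases with synthesized doses.

    Case ``i`` is the template warped by a case-specific random field
    (CT linearly, masks nearest-neighbour), with the dose synthesized in
    the deformed geometry.  Case 0 is the designated reference.  The
    whole cohort is a pure function of ``(n, spec)``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 cases")
    spec = spec or PhantomSpec()
    template = make_template_phantom(spec.grid)
    cases: list[PatientCase] = []
    fields: list[DeformationField] = []
    for i in range(n):
        fld = sample_deformation(
            spec.grid, seed=spec.seed * 100003 + i, amplitude_mm=spec.deform_amplitude_mm
        )
        ct = apply_field(fld, template.ct, mode="linear")
        # outside-support fill is 0; restore air HU there
        outside = apply_field(
            fld,
            ImageVolume(spec.grid, np.ones(spec.grid.array_shape), modality="CT"),
            mode="nearest",
        ).values < 0.5
        ct.values[outside] = _AIR_HU
        structures = StructureSet()
        for name, mask in template.structures.items():
            structures.add(name, apply_field(fld, mask))
        case = PatientCase(
            id=f"case{i:02d}",
            ct=ct,
            dose=None,
            structures=structures,
            prescription_gy=spec.prescription_gy,
        )
        case.dose = synth_dose(case, spec)
        cases.append(case)
        fields.append(fld)
    return PhantomCohort(template=template, cases=cases, true_fields=fields, spec=spec)
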