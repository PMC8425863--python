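"""Synthetic deformable pelvis phantom.

Generates every input the accumulation study needs without patient data: a
planning CT with pelvis-like structures, smooth daily deformations with an
exact analytic ground truth, daily images restricted to a cylindrical
field of view (FOV) in two reconstruction-quality renderings of the same
anatomy, and simulated raters with known sensitivity/specificity.

Anatomy is analytic (ellipsoids and a tube); daily images are produced by
evaluating the analytic shapes at deformation-mapped voxel centers, so the
daily ground-truth masks are exact re-voxelizations rather than
interpolated warps.  World axes: x = left-right, y = anterior(-)/
posterior(+), z = inferior(-)/superior(+); the grid is centered on the
world origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_dilation, label as cc_label

from .core import ImageGrid, StructureSet, VectorField

__all__ = [
    "OrganShape",
    "ReconStyle",
    "PhantomSpec",
    "DailyInstance",
    "AnalyticDeformation",
    "FDK_LIKE",
    "ITERATIVE_LIKE",
    "build_anatomy",
    "daily_grid",
    "sample_daily_dvf",
    "render_daily_image",
    "make_daily_instance",
    "simulate_raters",
]

# fixed offsets carving independent RNG streams out of the master seed
_STREAM_DVF = 1
_STREAM_NOISE = 2
_STREAM_RATERS = 3
_STYLE_OFFSET = {"fdk_like": 11, "iterative_like": 12}


@dataclass(frozen=True)
class OrganShape:
    """One analytic structure: an ellipsoid, or a tube (cylinder along z)."""

    name: str
    kind: str                      # "ellipsoid" | "tube"
    center_mm: Tuple[float, float, float]
    radii_mm: Tuple[float, float, float]   # tube: (r_xy, r_xy, half_length_z)
    hu: float

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "tube"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"{self.name}: all radii must be positive, got {self.radii_mm}")

    def indicator(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of world points (..., 3)."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center_mm)
        r = np.asarray(self.radii_mm, dtype=float)
        if self.kind == "ellipsoid":
            return ((p / r) ** 2).sum(axis=-1) <= 1.0
        radial = (p[..., 0] / r[0]) ** 2 + (p[..., 1] / r[1]) ** 2 <= 1.0
        return radial & (np.abs(p[..., 2]) <= r[2])

    def expanded(self, margin_mm: float) -> "OrganShape":
        return replace(self, radii_mm=tuple(r + margin_mm for r in self.radii_mm))


@dataclass(frozen=True)
class ReconStyle:
    """Noise/artifact model of one CBCT reconstruction variant.

    Both variants render the *same* deformed anatomy; they differ only in
    the additive Gaussian noise, the parabolic radial cupping bias (center
    HU deficit, the dominant scatter artifact of filtered back-projection),
    and optional angular streaks.
    """

    label: str
    noise_sd_hu: float
    cupping_amplitude_hu: float = 0.0
    streak_count: int = 0
    streak_amplitude_hu: float = 0.0

    def __post_init__(self):
        if self.label not in _STYLE_OFFSET:
            raise ValueError(f"label must be one of {sorted(_STYLE_OFFSET)}, got {self.label!r}")
        if self.noise_sd_hu < 0 or self.cupping_amplitude_hu < 0:
            raise ValueError("noise and cupping amplitudes must be non-negative")


# Defaults chosen to emulate clinical CBCT: filtered back-projection images
# carry ~40 HU noise and tens of HU of cupping; iterative reconstructions
# with scatter correction are several-fold cleaner.
FDK_LIKE = ReconStyle("fdk_like", noise_sd_hu=40.0, cupping_amplitude_hu=50.0)
ITERATIVE_LIKE = ReconStyle("iterative_like", noise_sd_hu=10.0, cupping_amplitude_hu=5.0)


def _default_organs() -> Tuple[OrganShape, ...]:
    return (
        OrganShape("prostate", "ellipsoid", (0.0, 5.0, -10.0), (20.0, 18.0, 18.0), 45.0),
        OrganShape("seminal_vesicles", "ellipsoid", (0.0, 20.0, 18.0), (15.0, 5.0, 9.0), 35.0),
        OrganShape("bladder", "ellipsoid", (0.0, -28.0, 18.0), (26.0, 22.0, 18.0), 10.0),
        OrganShape("rectum", "tube", (0.0, 36.0, -5.0), (10.0, 10.0, 40.0), -30.0),
        OrganShape("penile_bulb", "ellipsoid", (0.0, 8.0, -38.0), (9.0, 8.0, 7.0), 35.0),
        OrganShape("femoral_head_l", "ellipsoid", (-54.0, 5.0, -5.0), (18.0, 18.0, 18.0), 700.0),
        OrganShape("femoral_head_r", "ellipsoid", (54.0, 5.0, -5.0), (18.0, 18.0, 18.0), 700.0),
    )


def _default_bones() -> Tuple[OrganShape, ...]:
    return (OrganShape("sacrum", "ellipsoid", (0.0, 56.0, 5.0), (26.0, 7.0, 28.0), 500.0),)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic pelvis and its daily imaging."""

    grid_shape: Tuple[int, int, int] = (64, 64, 48)
    spacing_mm: Tuple[float, float, float] = (2.5, 2.5, 2.5)
    organ_geometry: Tuple[OrganShape, ...] = dc_field(default_factory=_default_organs)
    bone_sites: Tuple[OrganShape, ...] = dc_field(default_factory=_default_bones)
    body_radius_mm: Tuple[float, float] = (75.0, 65.0)   # elliptical cylinder, full z
    body_hu: float = 0.0
    background_hu: float = -1000.0
    ctv_name: str = "prostate"
    ptv_margin_mm: float = 5.0
    fov_radius_mm: float = 60.0
    fov_length_mm: float = 100.0
    texture_amplitude_hu: float = 12.0   # smooth soft-tissue texture (moves with anatomy)
    texture_wavelength_mm: float = 40.0
    deformation_magnitude_mm: float = 4.0
    couch_shift_sd_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.fov_radius_mm <= 0 or self.fov_length_mm <= 0 or self.ptv_margin_mm < 0:
            raise ValueError("FOV dimensions and PTV margin must be positive")
        if self.fov_radius_mm >= min(self.body_radius_mm):
            raise ValueError("FOV cylinder must lie strictly inside the body")
        names = [o.name for o in self.organ_geometry]
        if len(set(names)) != len(names):
            raise ValueError("duplicate organ names")
        if self.ctv_name not in names:
            raise ValueError(f"CTV structure {self.ctv_name!r} not among organs")

    # --- lattices -----------------------------------------------------

    def planning_grid(self) -> ImageGrid:
        shape = np.array(self.grid_shape)
        spacing = np.array(self.spacing_mm)
        origin = -(shape - 1) / 2.0 * spacing
        return ImageGrid(np.zeros(tuple(shape), dtype=np.float32), spacing, origin)

    def body_indicator(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        rx, ry = self.body_radius_mm
        return (p[..., 0] / rx) ** 2 + (p[..., 1] / ry) ** 2 <= 1.0

    def fov_indicator(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        radial = p[..., 0] ** 2 + p[..., 1] ** 2 <= self.fov_radius_mm ** 2
        return radial & (np.abs(p[..., 2]) <= self.fov_length_mm / 2.0)

    def ptv_shape(self) -> OrganShape:
        ctv = next(o for o in self.organ_geometry if o.name == self.ctv_name)
        if ctv.kind != "ellipsoid":
            raise ValueError("CTV must be an ellipsoid")
        return replace(ctv.expanded(self.ptv_margin_mm), name="ptv")

    # --- analytic rendering -------------------------------------------

    def hu_at(self, points: np.ndarray) -> np.ndarray:
        """HU of the undeformed anatomy at arbitrary world points.

        Soft tissue carries a smooth sinusoidal texture (fixed in the
        anatomy's frame, so it deforms with it): real CT interiors are not
        flat, and without interior intensity structure deformable
        registration of the interior would be ill-posed.
        """
        pts = np.asarray(points, dtype=float)
        hu = np.full(pts.shape[:-1], self.background_hu)
        body = self.body_indicator(pts)
        hu[body] = self.body_hu
        bone = np.zeros(pts.shape[:-1], dtype=bool)
        for shape in self.organ_geometry + self.bone_sites:
            ind = shape.indicator(pts)
            hu[ind] = shape.hu
            if shape.hu >= 300:
                bone |= ind
        if self.texture_amplitude_hu > 0:
            k = 2 * np.pi / self.texture_wavelength_mm
            # three fixed, non-axis-aligned plane waves
            tex = (np.sin(k * (0.8 * pts[..., 0] + 0.5 * pts[..., 1] + 0.3 * pts[..., 2]))
                   + np.sin(k * (-0.4 * pts[..., 0] + 0.9 * pts[..., 1] - 0.6 * pts[..., 2]) + 1.3)
                   + np.sin(k * (0.3 * pts[..., 0] - 0.5 * pts[..., 1] + 0.9 * pts[..., 2]) + 2.1))
            hu = np.where(body & ~bone, hu + self.texture_amplitude_hu * tex, hu)
        return hu

    def masks_at(self, points: np.ndarray) -> Dict[str, np.ndarray]:
        """Structure indicator masks (incl. ptv and body) at world points."""
        pts = np.asarray(points, dtype=float)
        masks = {o.name: o.indicator(pts) for o in self.organ_geometry}
        masks["ptv"] = self.ptv_shape().indicator(pts)
        masks["body"] = self.body_indicator(pts)
        return masks


def build_anatomy(spec: PhantomSpec) -> Tuple[ImageGrid, StructureSet]:
    """Voxelize the planning CT and its structure set.

    Rejects specs whose organs overlap each other or a bone site, naming
    the offending pair.
    """
    grid = spec.planning_grid()
    pts = grid.voxel_centers()
    painted: List[Tuple[str, np.ndarray]] = []
    for shape in spec.organ_geometry + spec.bone_sites:
        ind = shape.indicator(pts)
        for prev_name, prev in painted:
            if np.any(ind & prev):
                raise ValueError(
                    f"overlapping structure definitions: {prev_name!r} and {shape.name!r}"
                )
        painted.append((shape.name, ind))
    pct = grid.like(spec.hu_at(pts).astype(np.float32))
    structures = StructureSet(spec.masks_at(pts), grid.spacing, grid.origin)
    return pct, structures


def daily_grid(spec: PhantomSpec) -> ImageGrid:
    """The daily-image lattice: the planning lattice cropped to the FOV
    cylinder's bounding box (same spacing — the daily image is an
    axis-aligned sub-volume of the planning frame)."""
    pg = spec.planning_grid()
    pad = 1.0  # one-voxel margin around the cylinder
    lo = np.array([-spec.fov_radius_mm, -spec.fov_radius_mm, -spec.fov_length_mm / 2]) - pad
    hi = -lo
    i0 = np.maximum(np.ceil((lo - pg.origin) / pg.spacing), 0).astype(int)
    i1 = np.minimum(np.floor((hi - pg.origin) / pg.spacing), np.array(pg.shape) - 1).astype(int)
    shape = tuple(i1 - i0 + 1)
    origin = pg.origin + i0 * pg.spacing
    return ImageGrid(np.zeros(shape, dtype=np.float32), pg.spacing, origin)


class AnalyticDeformation:
    """Couch shift plus Gaussian displacement bumps, day frame → pCT frame.

    Exact displacement is available at any continuous point, which is what
    makes phantom registrations scorable against ground truth.
    """

    def __init__(self, rigid_mm: np.ndarray, centers: np.ndarray,
                 amplitudes: np.ndarray, sigmas_mm: np.ndarray):
        self.rigid_mm = np.asarray(rigid_mm, dtype=float)
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(amplitudes, dtype=float).reshape(-1, 3)
        self.sigmas_mm = np.asarray(sigmas_mm, dtype=float).ravel()

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        u = np.broadcast_to(self.rigid_mm, pts.shape).copy()
        for c, a, s in zip(self.centers, self.amplitudes, self.sigmas_mm):
            d2 = ((pts - c) ** 2).sum(axis=-1)
            u = u + np.exp(-d2 / (2 * s * s))[..., None] * a
        return u

    def map_points(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self(points)

    def to_field(self, grid: ImageGrid) -> VectorField:
        f = VectorField(self(grid.voxel_centers()), grid.spacing.copy(), grid.origin.copy())
        f.analytic = self
        return f


def sample_daily_dvf(
    spec: PhantomSpec,
    day_index: int,
    magnitude_mm: Optional[float] = None,
) -> VectorField:
    """Draw the day's ground-truth deformation on the daily lattice.

    The field is a small rigid couch offset plus 2–4 Gaussian bumps
    centered near the bladder and rectum (the mobile soft tissue).  The
    analytic form is attached as ``.analytic``.  Rejects fields whose
    Jacobian determinant leaves [0.5, 2].
    """
    if magnitude_mm is None:
        magnitude_mm = spec.deformation_magnitude_mm
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be non-negative")
    if day_index < 1:
        raise ValueError("day_index must be >= 1")
    rng = np.random.default_rng([spec.seed, _STREAM_DVF, day_index])
    grid = daily_grid(spec)
    if magnitude_mm == 0:
        deform = AnalyticDeformation(np.zeros(3), np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0))
        return deform.to_field(grid)

    rigid = rng.normal(0.0, spec.couch_shift_sd_mm, size=3)
    n_bumps = int(rng.integers(2, 5))
    anchors = {o.name: np.array(o.center_mm) for o in spec.organ_geometry}
    sites = [anchors.get("bladder", np.zeros(3)), anchors.get("rectum", np.zeros(3))]
    centers, amps, sigmas = [], [], []
    for b in range(n_bumps):
        base = sites[b % len(sites)]
        centers.append(base + rng.normal(0.0, 8.0, size=3))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amps.append(direction * magnitude_mm * rng.uniform(0.5, 1.0))
        sigmas.append(rng.uniform(18.0, 28.0))
    deform = AnalyticDeformation(rigid, np.array(centers), np.array(amps), np.array(sigmas))
    fld = deform.to_field(grid)
    from .core import jacobian_determinant

    jac = jacobian_determinant(fld)
    if jac.min() < 0.5 or jac.max() > 2.0:
        where = np.unravel_index(int(np.argmax(np.abs(np.log(np.abs(jac) + 1e-12)))), jac.shape)
        raise ValueError(
            f"deformation too strong: Jacobian determinant {jac.min():.3f}..{jac.max():.3f} "
            f"outside [0.5, 2] (worst voxel {where})"
        )
    return fld


def render_daily_image(
    spec: PhantomSpec,
    dvf: VectorField,
    style: ReconStyle,
    seed: int,
) -> Tuple[ImageGrid, np.ndarray, StructureSet]:
    """Render one reconstruction variant of the deformed anatomy.

    ``dvf`` maps daily-frame points to pCT-frame points (couch shift
    included as its rigid component); the anatomy is re-evaluated
    analytically at the mapped points, cropped to the FOV cylinder, then
    degraded per the style.  Returns ``(image, fov_mask, truth_masks)``.
    Voxels outside the FOV hold 0 and are excluded by ``fov_mask`` (the
    dedicated out-of-FOV flag channel).
    """
    grid = dvf.grid
    pts = grid.voxel_centers()
    mapped = pts + dvf.data
    pg = spec.planning_grid()
    lo = pg.origin - pg.spacing / 2
    hi = pg.origin + (np.array(pg.shape) - 0.5) * pg.spacing
    if not np.all((mapped >= lo) & (mapped <= hi)):
        raise ValueError("FOV cylinder maps outside the source anatomy")

    hu = spec.hu_at(mapped)
    fov = spec.fov_indicator(pts)

    rng = np.random.default_rng([seed, _STREAM_NOISE, _STYLE_OFFSET[style.label]])
    if style.cupping_amplitude_hu > 0:
        r2 = (pts[..., 0] ** 2 + pts[..., 1] ** 2) / spec.fov_radius_mm ** 2
        hu = hu - style.cupping_amplitude_hu * np.clip(1.0 - r2, 0.0, None)
    if style.streak_count > 0 and style.streak_amplitude_hu > 0:
        theta = np.arctan2(pts[..., 1], pts[..., 0])
        phase = rng.uniform(0, 2 * np.pi)
        hu = hu + style.streak_amplitude_hu * np.cos(style.streak_count * theta + phase)
    if style.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, style.noise_sd_hu, size=hu.shape)

    hu = np.where(fov, hu, 0.0).astype(np.float32)
    truth = StructureSet(
        {k: v & fov for k, v in spec.masks_at(mapped).items()},
        grid.spacing, grid.origin,
    )
    return grid.like(hu), fov, truth


@dataclass
class DailyInstance:
    """One simulated treatment day: ground truth plus both renderings."""

    day_index: int
    truth_dvf: VectorField            # daily frame -> pCT frame (rigid part = couch shift)
    couch_shift_mm: np.ndarray
    images: Dict[str, ImageGrid]      # keyed by ReconStyle label
    fov_mask: np.ndarray
    truth_masks: StructureSet         # daily frame, FOV-cropped


def make_daily_instance(
    spec: PhantomSpec,
    day_index: int,
    styles: Sequence[ReconStyle] = (FDK_LIKE, ITERATIVE_LIKE),
    magnitude_mm: Optional[float] = None,
) -> DailyInstance:
    """Sample a day's deformation and render it in every requested style."""
    dvf = sample_daily_dvf(spec, day_index, magnitude_mm)
    images = {}
    fov = None
    truth = None
    for style in styles:
        img, fov, truth = render_daily_image(spec, dvf, style, seed=spec.seed * 100003 + day_index)
        images[style.label] = img
    rigid = dvf.analytic.rigid_mm if hasattr(dvf, "analytic") else np.zeros(3)
    return DailyInstance(day_index, dvf, rigid, images, fov, truth)


def simulate_raters(
    truth: np.ndarray,
    sensitivity: float,
    specificity: float,
    n_raters: int,
    seed: int,
    review_region: Optional[np.ndarray] = None,
    keep_largest_component: bool = False,
) -> List[np.ndarray]:
    """Simulate independent raters with known per-voxel performance.

    Inside the truth mask each voxel is labeled with probability
    ``sensitivity``; in the review region outside the truth, with
    probability ``1 - specificity``.  The review region defaults to the
    truth dilated by 3 voxels.  ``keep_largest_component`` optionally
    drops all but the largest 6-connected component (recorded choice:
    off by default so the nominal error rates are preserved).
    """
    truth = np.asarray(truth, dtype=bool)
    if not truth.any():
        raise ValueError("empty truth mask")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if not (0 < sensitivity <= 1 and 0 < specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in (0, 1]")
    if review_region is None:
        review_region = binary_dilation(truth, iterations=3)
    review_region = np.asarray(review_region, dtype=bool) | truth
    rng = np.random.default_rng([seed, _STREAM_RATERS])
    out: List[np.ndarray] = []
    outside = review_region & ~truth
    for _ in range(n_raters):
        draw = rng.random(truth.shape)
        mask = (truth & (draw < sensitivity)) | (outside & (draw < 1.0 - specificity))
        if keep_largest_component and mask.any():
            lab, n = cc_label(mask)
            if n > 1:
                sizes = np.bincount(lab.ravel())[1:]
                mask = lab == (1 + int(np.argmax(sizes)))
        out.append(mask)
    return out
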