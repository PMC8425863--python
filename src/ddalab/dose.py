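"""Parametric dose engine and the accumulation arithmetic.

The engine replaces a treatment planning system with a conformal pattern:
full prescription inside the target, Gaussian penumbra falloff with
distance outside.  It is deterministic and identical across fractions, so
every downstream difference between reconstruction variants is caused by
geometry (registration), mirroring the same-plan design of the study it
emulates.  Mapped dose uses plain trilinear interpolation of dose — no
mass/energy transfer — which is declared as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import distance_transform_edt

from .core import ImageGrid, VectorField, invert_dvf

__all__ = [
    "PlanModel",
    "DoseGrid",
    "DiffStats",
    "compute_daily_dose",
    "map_dose_to_planning",
    "accumulate",
    "normalize_dda",
    "voxel_difference_stats",
    "project_full_course",
]


@dataclass(frozen=True)
class PlanModel:
    """Prescription and penumbra of the stand-in conformal plan.

    Defaults follow one of the study's three schedules: 2.00 Gy per
    fraction in 39 fractions (78 Gy total); 1.80 × 44 and 1.80 × 25 are
    equally representable.
    """

    prescription_gy_per_fraction: float = 2.0
    n_fractions: int = 39
    target_name: str = "ptv"
    penumbra_sigma_mm: float = 5.0

    def __post_init__(self):
        if self.prescription_gy_per_fraction <= 0:
            raise ValueError("prescription must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be positive")

    @property
    def total_prescription_gy(self) -> float:
        return self.prescription_gy_per_fraction * self.n_fractions


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a lattice, with a per-voxel validity mask."""

    grid: ImageGrid                 # lattice carrier (data unused)
    dose_gy: np.ndarray
    frame: str = "daily"            # {"daily", "planning"}
    fraction_index: object = None   # int or "accumulated"
    valid: Optional[np.ndarray] = None
    n_valid_fractions: Optional[np.ndarray] = None   # set by accumulate()

    def __post_init__(self):
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.dose_gy.shape != self.grid.shape:
            raise ValueError("dose array does not match lattice")
        if not np.all(np.isfinite(self.dose_gy)):
            raise ValueError("dose contains non-finite values")
        if self.dose_gy.min() < 0:
            raise ValueError("dose must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)

    def same_lattice(self, other: "DoseGrid") -> bool:
        return self.grid.same_lattice(other.grid)


@dataclass(frozen=True)
class DiffStats:
    """Signed mean/SD and maximum absolute voxel difference over a region."""

    mean_gy: float
    sd_gy: float
    max_abs_gy: float
    n_voxels: int
    region: str = ""


def compute_daily_dose(
    dct: ImageGrid,
    target_mask: np.ndarray,
    plan: PlanModel,
    fraction_index: Optional[int] = None,
    frame: str = "daily",
    hu_image: Optional[ImageGrid] = None,
    hu_coupling: float = 0.05,
    hu_smoothing_mm: float = 10.0,
) -> DoseGrid:
    """Conformal dose on the given frame: prescription inside the target,
    ``Rx · exp(−d² / 2σ²)`` at distance ``d`` outside its surface.

    The target is the plan's target placed in this frame (for daily
    fractions: rigidly, by the treatment-record couch shift — the plan is
    fixed in machine coordinates).  If ``hu_image`` (the dCT) is given, a
    weak attenuation-like perturbation modulates the dose:
    ``× (1 − hu_coupling · smoothed(HU)/1000)``.  This mimics how a dose
    engine responds to density, so two dCTs that differ only in soft
    tissue produce nearly — but not exactly — identical daily doses.
    """
    target = np.asarray(target_mask, dtype=bool)
    if target.shape != dct.shape:
        raise ValueError("target mask does not match the dose lattice")
    if not target.any():
        raise ValueError(f"empty target mask {plan.target_name!r}")
    d_out = distance_transform_edt(~target, sampling=dct.spacing)
    dose = plan.prescription_gy_per_fraction * np.exp(
        -(d_out ** 2) / (2.0 * plan.penumbra_sigma_mm ** 2)
    )
    dose[target] = plan.prescription_gy_per_fraction
    if hu_image is not None and hu_coupling != 0.0:
        from scipy.ndimage import gaussian_filter
        sig = hu_smoothing_mm / np.asarray(dct.spacing)
        hu_s = gaussian_filter(np.asarray(hu_image.data, dtype=float), sigma=sig)
        dose = np.clip(dose * (1.0 - hu_coupling * hu_s / 1000.0), 0.0, None)
    return DoseGrid(dct.like(np.zeros(dct.shape, np.uint8)), dose, frame=frame,
                    fraction_index=fraction_index)


def map_dose_to_planning(
    daily_dose: DoseGrid,
    dvf: VectorField,
    pct_grid: ImageGrid,
    inverse: Optional[Tuple[VectorField, np.ndarray]] = None,
) -> DoseGrid:
    """Pull the daily dose onto the planning lattice through the inverse DVF.

    ``dvf`` is the registration field (daily → pCT); its numerical inverse
    v satisfies dose_pCT(y) = dose_daily(y + v(y)).  Planning voxels whose
    pre-image falls outside the daily dose grid — or where inversion is
    unreliable — are zero with ``valid = False``.
    """
    if inverse is None:
        inverse = invert_dvf(dvf, target=pct_grid)
    inv, reliable = inverse
    pts = pct_grid.voxel_centers() + inv.data
    idx = daily_dose.grid.world_to_index(pts)
    from scipy.ndimage import map_coordinates

    flat = idx.reshape(-1, 3).T
    vals = map_coordinates(daily_dose.dose_gy, flat, order=1, mode="constant", cval=0.0)
    eps = 1e-9
    hi = np.array(daily_dose.grid.shape) - 1
    inb = np.all((flat.T >= -eps) & (flat.T <= hi + eps), axis=1).reshape(pct_grid.shape)
    src_valid = map_coordinates(daily_dose.valid.astype(float), flat, order=0,
                                mode="constant", cval=0.0).reshape(pct_grid.shape) > 0.5
    valid = inb & reliable & src_valid
    dose = np.where(valid, vals.reshape(pct_grid.shape), 0.0)
    return DoseGrid(pct_grid.like(np.zeros(pct_grid.shape, np.uint8)), np.clip(dose, 0.0, None),
                    frame="planning", fraction_index=daily_dose.fraction_index, valid=valid)


def accumulate(mapped_doses: List[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of per-fraction doses on the planning lattice.

    The validity mask is the union of fraction masks; the per-voxel count
    of contributing fractions is retained on the result.
    """
    if not mapped_doses:
        raise ValueError("need at least one fraction to accumulate")
    first = mapped_doses[0]
    total = np.zeros(first.grid.shape)
    counts = np.zeros(first.grid.shape, dtype=int)
    for d in mapped_doses:
        if not d.same_lattice(first):
            raise ValueError("all fractions must share one lattice")
        total += d.dose_gy
        counts += d.valid.astype(int)
    out = DoseGrid(first.grid.like(np.zeros(first.grid.shape, np.uint8)), total,
                   frame=first.frame, fraction_index="accumulated",
                   valid=counts > 0)
    out.n_valid_fractions = counts
    return out


def normalize_dda(dda: DoseGrid, n_fractions: int) -> DoseGrid:
    """Accumulated dose per fraction: voxelwise dda / n_fractions."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if dda.fraction_index != "accumulated":
        raise ValueError("normalize_dda expects an accumulated dose grid")
    if dda.n_valid_fractions is not None and dda.n_valid_fractions.max() != n_fractions:
        raise ValueError(
            f"n_fractions={n_fractions} does not match accumulation metadata "
            f"(max count {int(dda.n_valid_fractions.max())})"
        )
    out = DoseGrid(dda.grid, dda.dose_gy / n_fractions, frame=dda.frame,
                   fraction_index="accumulated", valid=dda.valid.copy())
    out.n_valid_fractions = dda.n_valid_fractions
    return out


def project_full_course(dda: DoseGrid, analyzed_fractions: int, total_fractions: int) -> DoseGrid:
    """Scale an accumulation over the analyzed fractions to the full course."""
    if analyzed_fractions < 1:
        raise ValueError("analyzed_fractions must be >= 1")
    if total_fractions < analyzed_fractions:
        raise ValueError("total_fractions must be >= analyzed_fractions")
    out = DoseGrid(dda.grid, dda.dose_gy * (total_fractions / analyzed_fractions),
                   frame=dda.frame, fraction_index=dda.fraction_index,
                   valid=dda.valid.copy())
    out.n_valid_fractions = dda.n_valid_fractions
    return out


def voxel_difference_stats(a: DoseGrid, b: DoseGrid, region: np.ndarray,
                           region_name: str = "") -> DiffStats:
    """Signed mean/SD and max |a − b| over the region's mutually valid voxels."""
    if not a.same_lattice(b):
        raise ValueError("dose grids on different lattices")
    region = np.asarray(region, dtype=bool)
    eff = region & a.valid & b.valid
    if not eff.any():
        raise ValueError("empty effective region")
    d = a.dose_gy[eff] - b.dose_gy[eff]
    return DiffStats(
        mean_gy=float(d.mean()),
        sd_gy=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        max_abs_gy=float(np.abs(d).max()),
        n_voxels=int(eff.sum()),
        region=region_name,
    )
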