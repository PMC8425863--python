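"""Dose-volume histograms and clinical constraint metrics.

Implements the constraint vocabulary of prostate plan evaluation: Dmean,
DX% (dose covering X% of the structure volume), and the near-extreme
doses Dmin/Dmax defined over a small absolute volume (0.035 cc) rather
than a single voxel.  Extremes are computed from exactly sorted voxel
doses with linear interpolation at the fractional-voxel cut — the binned
DVH is never used for them, because the 0.035 cc convention demands
sub-bin precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import StructureSet
from .dose import DoseGrid

__all__ = [
    "DVHCurve",
    "ConstraintSpec",
    "cumulative_dvh",
    "dose_at_relative_volume",
    "dose_extreme_at_absolute_volume",
    "mean_dose",
    "evaluate_constraints",
    "default_prostate_constraints",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: volume (cc) receiving at least each dose edge."""

    dose_edges_gy: np.ndarray
    cum_volume_cc: np.ndarray
    structure: str
    total_volume_cc: float

    def __post_init__(self):
        self.dose_edges_gy = np.asarray(self.dose_edges_gy, dtype=float)
        self.cum_volume_cc = np.asarray(self.cum_volume_cc, dtype=float)
        if np.any(np.diff(self.dose_edges_gy) <= 0):
            raise ValueError("dose edges must be strictly increasing")
        if np.any(np.diff(self.cum_volume_cc) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_gy": self.dose_edges_gy,
            "volume_cc": self.cum_volume_cc,
            "structure": self.structure,
        })


@dataclass(frozen=True)
class ConstraintSpec:
    """One clinical goal, e.g. rectum D50% ≤ 40 Gy or PTV Dmean ≥ 100% Rx."""

    structure: str
    metric: str          # Dmean | Dmin_0.035cc | Dmax_0.035cc | D95% | D50% | D15% | D5%
    direction: str       # ">=" | "<="
    threshold: float
    percent_of_prescription: bool = False

    _METRICS = ("Dmean", "Dmin_0.035cc", "Dmax_0.035cc", "D95%", "D50%", "D15%", "D5%")

    def __post_init__(self):
        if self.metric not in self._METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.direction not in (">=", "<="):
            raise ValueError("direction must be '>=' or '<='")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def _masked_doses(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.grid.shape:
        raise ValueError("mask does not match the dose lattice")
    if not mask.any():
        raise ValueError("empty structure mask")
    return dose.dose_gy[mask]


def cumulative_dvh(dose: DoseGrid, mask: np.ndarray, bin_width_gy: float = 0.05,
                   structure: str = "") -> DVHCurve:
    """Exact voxel-counting cumulative DVH with uniform bin edges."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    vals = np.sort(_masked_doses(dose, mask))
    vox_cc = dose.grid.voxel_volume_mm3 / 1000.0
    top = max(float(vals.max()), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    # exact count of voxels receiving >= each edge
    cum = (vals.size - np.searchsorted(vals, edges, side="left")).astype(float) * vox_cc
    return DVHCurve(edges, cum, structure, total_volume_cc=vals.size * vox_cc)


def dose_at_relative_volume(dvh: DVHCurve, v_percent: float) -> float:
    """DX%: the largest dose d with cum_volume(d) ≥ X% of the structure,
    linearly interpolated between DVH edges."""
    if not (0 < v_percent <= 100):
        raise ValueError("v_percent must lie in (0, 100]")
    target = dvh.total_volume_cc * v_percent / 100.0
    v = dvh.cum_volume_cc
    e = dvh.dose_edges_gy
    if v[-1] >= target:
        return float(e[-1])
    # first edge whose volume drops below the target; v[0] = total >= target
    j = int(np.argmax(v < target))
    if j == 0:
        return float(e[0])
    frac = (v[j - 1] - target) / (v[j - 1] - v[j])
    return float(e[j - 1] + frac * (e[j] - e[j - 1]))


def dose_extreme_at_absolute_volume(
    dose: DoseGrid,
    mask: np.ndarray,
    volume_cc: float = 0.035,
    which: str = "max",
) -> float:
    """Dose to the hottest (``which='max'``) or coldest (``'min'``)
    ``volume_cc`` of the structure, from exactly sorted voxel doses with
    linear interpolation at the fractional-voxel cut."""
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    if volume_cc <= 0:
        raise ValueError("volume_cc must be positive")
    vals = np.sort(_masked_doses(dose, mask))
    vox_cc = dose.grid.voxel_volume_mm3 / 1000.0
    total_cc = vals.size * vox_cc
    if volume_cc > total_cc + 1e-12:
        raise ValueError(f"volume_cc={volume_cc} exceeds structure volume {total_cc:.4f} cc")
    # number of voxels in the tail of interest (continuous)
    k = volume_cc / vox_cc
    if which == "max":
        vals = vals[::-1]
    # dose exceeded by (received by) the first k voxels of the sorted tail:
    # interpolate the sorted-dose profile at position k
    pos = np.clip(k, 0.0, vals.size)
    i = int(np.floor(pos))
    if i >= vals.size:
        return float(vals[-1])
    if i == 0:
        return float(vals[0])
    frac = pos - i
    lo = vals[i - 1]
    hi = vals[min(i, vals.size - 1)]
    return float(lo + frac * (hi - lo))


def mean_dose(dose: DoseGrid, mask: np.ndarray) -> float:
    """Arithmetic mean voxel dose inside the mask (Gy)."""
    return float(_masked_doses(dose, mask).mean())


def _evaluate_metric(dose: DoseGrid, mask: np.ndarray, metric: str) -> float:
    if metric == "Dmean":
        return mean_dose(dose, mask)
    if metric == "Dmin_0.035cc":
        return dose_extreme_at_absolute_volume(dose, mask, 0.035, "min")
    if metric == "Dmax_0.035cc":
        return dose_extreme_at_absolute_volume(dose, mask, 0.035, "max")
    v = float(metric[1:-1])
    return dose_at_relative_volume(cumulative_dvh(dose, mask), v)


def evaluate_constraints(
    dose: DoseGrid,
    structures: StructureSet,
    specs: List[ConstraintSpec],
    prescription_gy: float,
) -> pd.DataFrame:
    """One row per goal: computed value, resolved threshold, pass flag.

    A structure absent from the set yields an NA row rather than an error
    (femoral heads are not always contoured)."""
    rows = []
    for s in specs:
        thr = s.threshold * prescription_gy / 100.0 if s.percent_of_prescription else s.threshold
        goal = f"{s.direction} {s.threshold:g}{'% Rx' if s.percent_of_prescription else ' Gy'}"
        if s.structure not in structures or not structures[s.structure].any():
            rows.append({"structure": s.structure, "metric": s.metric,
                         "value_gy": np.nan, "goal": goal, "threshold_gy": thr, "pass": pd.NA})
            continue
        val = _evaluate_metric(dose, structures[s.structure], s.metric)
        ok = val >= thr if s.direction == ">=" else val <= thr
        rows.append({"structure": s.structure, "metric": s.metric,
                     "value_gy": val, "goal": goal, "threshold_gy": thr, "pass": bool(ok)})
    return pd.DataFrame(rows)


def default_prostate_constraints() -> List[ConstraintSpec]:
    """The goal set evaluated in the study's constraint tables."""
    return [
        ConstraintSpec("ptv", "Dmean", ">=", 100.0, percent_of_prescription=True),
        ConstraintSpec("ptv", "Dmin_0.035cc", ">=", 95.0, percent_of_prescription=True),
        ConstraintSpec("ptv", "Dmax_0.035cc", "<=", 110.0, percent_of_prescription=True),
        ConstraintSpec("ptv", "D95%", ">=", 95.0, percent_of_prescription=True),
        ConstraintSpec("prostate", "Dmin_0.035cc", ">=", 95.0, percent_of_prescription=True),
        ConstraintSpec("prostate", "Dmax_0.035cc", "<=", 110.0, percent_of_prescription=True),
        ConstraintSpec("prostate", "D95%", ">=", 95.0, percent_of_prescription=True),
        ConstraintSpec("rectum", "Dmean", "<=", 40.0),
        ConstraintSpec("rectum", "D50%", "<=", 40.0),
        ConstraintSpec("rectum", "D15%", "<=", 75.0),
        ConstraintSpec("bladder", "Dmean", "<=", 50.0),
        ConstraintSpec("bladder", "D50%", "<=", 50.0),
        ConstraintSpec("penile_bulb", "Dmean", "<=", 50.0),
        ConstraintSpec("femoral_head_l", "D5%", "<=", 43.0),
        ConstraintSpec("femoral_head_r", "D5%", "<=", 43.0),
    ]
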