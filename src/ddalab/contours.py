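"""Contour-agreement analytics: DSC, center-of-mass distance, Hausdorff,
STAPLE consensus, paired differences, and the one-tailed t-test.

"Contour" here means the boundary voxel set of a binary mask (voxels in
the mask with at least one 6-connected neighbour outside), with distances
measured between boundary voxel centers in world millimetres.  The mean
contour distance follows the center-of-mass definition: the Euclidean
distance between the two masks' centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from scipy.stats import t as t_dist

__all__ = [
    "AgreementRecord",
    "StapleResult",
    "dice",
    "mean_contour_distance",
    "hausdorff",
    "metric_difference",
    "staple_consensus",
    "one_tailed_paired_t",
    "boundary_points",
]

_EPS = 1e-6   # clamp for degenerate rater performance estimates


@dataclass(frozen=True)
class AgreementRecord:
    """Per-structure agreement of a mapped contour with its consensus."""

    structure: str
    algorithm: str          # "bspline" | "demons"
    variant: str            # "fdk_like" | "iterative_like"
    dsc: float
    mcd_mm: float
    hd_mm: float
    hd_mode: str = "symmetric"

    def __post_init__(self):
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError("DSC must lie in [0, 1]")
        if self.mcd_mm < 0 or self.hd_mm < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class StapleResult:
    """Consensus probability map plus per-rater performance estimates."""

    consensus_prob: np.ndarray
    consensus_mask: np.ndarray
    sensitivity_per_rater: np.ndarray
    specificity_per_rater: np.ndarray
    log_likelihood_trace: np.ndarray
    iterations_run: int
    converged: bool


def _as_bool(m) -> np.ndarray:
    return np.asarray(m, dtype=bool)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) by voxel counting."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("masks on different lattices")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def _centroid_mm(mask: np.ndarray, spacing, origin) -> np.ndarray:
    idx = np.argwhere(mask)
    return np.asarray(origin) + idx.mean(axis=0) * np.asarray(spacing)


def mean_contour_distance(a, b, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> float:
    """Distance (mm) between the centers of mass of two masks."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("masks on different lattices")
    if not a.any() or not b.any():
        raise ValueError("MCD undefined for an empty mask")
    return float(np.linalg.norm(_centroid_mm(a, spacing, origin) - _centroid_mm(b, spacing, origin)))


def boundary_points(mask: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """World coordinates of the 6-connectivity surface voxels of a mask."""
    mask = _as_bool(mask)
    structure = np.zeros((3, 3, 3), bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    interior = binary_erosion(mask, structure=structure, border_value=0)
    surface = mask & ~interior
    idx = np.argwhere(surface)
    return np.asarray(origin) + idx * np.asarray(spacing)


def hausdorff(a, b, mode: str = "symmetric",
              spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> float:
    """Hausdorff distance (mm) between the masks' boundary voxel sets.

    ``directed``: max over a's boundary of the distance to b's nearest
    boundary point; ``symmetric``: max of the two directed values.
    """
    if mode not in ("directed", "symmetric"):
        raise ValueError("mode must be 'directed' or 'symmetric'")
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("masks on different lattices")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff undefined for an empty mask")
    pa = boundary_points(a, spacing, origin)
    pb = boundary_points(b, spacing, origin)
    d_ab = float(cKDTree(pb).query(pa)[0].max())
    if mode == "directed":
        return d_ab
    d_ba = float(cKDTree(pa).query(pb)[0].max())
    return max(d_ab, d_ba)


def metric_difference(metric_iter: float, metric_fdk: float) -> float:
    """Iterative-variant metric minus FDK-variant metric.

    Positive for DSC means improvement; negative for MCD/HD means
    improvement (a distance reduction)."""
    return float(metric_iter) - float(metric_fdk)


def staple_consensus(
    raters: Sequence[np.ndarray],
    review_region: Optional[np.ndarray] = None,
    init_vote_fraction: float = 0.5,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> StapleResult:
    """STAPLE: EM estimate of the latent consensus segmentation and each
    rater's sensitivity p_j and specificity q_j.

    The spatial prior is uniform, set to the mean rater foreground
    fraction over the review region (which must contain every rater's
    foreground; it defaults to their union).  The E-step computes the
    voxelwise posterior foreground probability W; the M-step re-estimates
    (p_j, q_j) from W.  The consensus mask thresholds W at 0.5.  A single
    rater is returned as its own consensus with undefined performance.
    """
    masks = [_as_bool(r) for r in raters]
    if not masks:
        raise ValueError("need at least one rater")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("rater masks on different lattices")
    union = np.zeros(shape, bool)
    for m in masks:
        union |= m
    if review_region is None:
        review_region = union
    region = _as_bool(review_region)
    if not np.all(union <= region):
        raise ValueError("review_region must contain every rater's foreground")

    if len(masks) == 1:
        warnings.warn("single rater: consensus is the rater itself; performance undefined")
        prob = masks[0].astype(float)
        return StapleResult(prob, masks[0].copy(), np.array([np.nan]), np.array([np.nan]),
                            np.array([]), 0, True)

    d = np.stack([m[region] for m in masks], axis=0)        # raters x voxels
    n_raters, n_vox = d.shape
    if n_vox == 0:
        raise ValueError("empty review region")
    prior = float(np.clip(d.mean(), _EPS, 1 - _EPS))

    # initialize the posterior from the vote fraction
    w = np.clip(d.mean(axis=0), _EPS, 1 - _EPS)
    if init_vote_fraction != 0.5:
        w = np.where(d.mean(axis=0) >= init_vote_fraction, 1 - _EPS, _EPS)
    p = np.full(n_raters, 0.9)
    q = np.full(n_raters, 0.9)
    loglik = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step from current posterior
        sw = w.sum()
        snw = (1.0 - w).sum()
        if sw < 1e-9 or snw < 1e-9:
            # a degenerate posterior (e.g. unanimous raters over the whole
            # region) leaves one performance parameter unidentified
            warnings.warn("STAPLE parameter degeneracy; clamping estimates")
        p_new = (np.clip((d * w).sum(axis=1) / sw, _EPS, 1 - _EPS)
                 if sw >= 1e-9 else np.full(n_raters, 1 - _EPS))
        q_new = (np.clip(((1 - d) * (1 - w)).sum(axis=1) / snw, _EPS, 1 - _EPS)
                 if snw >= 1e-9 else np.full(n_raters, 1 - _EPS))
        # a rater covering the whole review region carries no specificity
        # information (and an empty one no sensitivity information)
        all_pos = d.sum(axis=1) == n_vox
        all_neg = d.sum(axis=1) == 0
        if all_pos.any() or all_neg.any():
            warnings.warn("rater identical to review region or empty; clamping estimates")
            q_new[all_pos] = 1 - _EPS
            p_new[all_neg] = _EPS
        # E-step with the updated parameters
        log_f = (np.log(p_new)[:, None] * d + np.log1p(-p_new)[:, None] * (1 - d)).sum(axis=0)
        log_g = (np.log1p(-q_new)[:, None] * d + np.log(q_new)[:, None] * (1 - d)).sum(axis=0)
        a = np.log(prior) + log_f
        b = np.log1p(-prior) + log_g
        m = np.maximum(a, b)
        denom = m + np.log(np.exp(a - m) + np.exp(b - m))
        w = np.exp(a - denom)
        loglik.append(float(denom.sum()))
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    prob = np.zeros(shape)
    prob[region] = w
    consensus = prob >= 0.5
    return StapleResult(prob, consensus, p, q, np.array(loglik), it, converged)


def one_tailed_paired_t(differences: Sequence[float],
                        alternative: str = "greater") -> Tuple[float, float]:
    """One-tailed paired t-test on per-case metric differences.

    ``alternative='greater'`` tests mean > 0; ``'less'`` tests mean < 0.
    With zero variance the p-value degenerates to 0 when the mean strictly
    favors the alternative and 1 otherwise (a warning is emitted).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(list(differences), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 paired differences")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance in paired differences; degenerate t-test")
        favors = mean > 0 if alternative == "greater" else mean < 0
        return (np.inf if favors else (-np.inf if mean != 0 else 0.0),
                0.0 if favors else 1.0)
    t = mean / (sd / np.sqrt(x.size))
    p = t_dist.sf(t, x.size - 1) if alternative == "greater" else t_dist.cdf(t, x.size - 1)
    return float(t), float(p)
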