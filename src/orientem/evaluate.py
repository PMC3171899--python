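"""Post-EM evaluation: orientation assignment, snapshot reconstruction,
volume merging, and gauge-aware accuracy metrics.

The likelihood is invariant under one global rotation of all orientations
(and, because phantom intensities carry Friedel symmetry, under one global
inversion-equivalent flip), so recovered orientations can only be compared
with ground truth after fitting that gauge.  :func:`align_gauge` searches
gauges over the grid nodes, optionally with local simplex refinement, and
reports errors both in radians and in units of the grid's Shannon angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .detector import DetectorGeometry
from .emc import compress
from .geometry import (
    OrientationGrid,
    canonical_hemisphere,
    quat_conjugate,
    quat_multiply,
    rotation_angle,
)
from .simulate import SnapshotSet
from .volumes import IntensityVolume

__all__ = [
    "AssignmentResult",
    "assign_orientations",
    "class_average",
    "generate_model_snapshots",
    "merge_volume",
    "AccuracyReport",
    "align_gauge",
    "volume_correlation",
]

# 180-degree rotation about the beam axis: composing an orientation with this
# maps a (flat-mode) Ewald slice onto its Friedel mate, so it is the global
# flip that intensity data cannot distinguish.
_FLIP = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass
class AssignmentResult:
    """Max-posterior orientation assignment for each snapshot."""

    best_index: np.ndarray  # (N,)
    posterior: np.ndarray  # (N,) probability of the best node
    entropy: np.ndarray  # (N,) full-posterior entropy, in [0, ln K]
    grid: OrientationGrid

    @property
    def quaternions(self) -> np.ndarray:
        return self.grid.nodes[self.best_index]


def assign_orientations(responsibilities: np.ndarray, grid: OrientationGrid) -> AssignmentResult:
    """Per-snapshot argmax over nodes (lowest index wins ties)."""
    R = np.asarray(responsibilities, dtype=float)
    if np.any(np.abs(R.sum(axis=0) - 1.0) > 1e-8):
        raise ValueError("responsibility columns must sum to 1")
    idx = np.argmax(R, axis=0)
    post = R[idx, np.arange(R.shape[1])]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(R > 0, R * np.log(R), 0.0), axis=0)
    return AssignmentResult(best_index=idx, posterior=post, entropy=ent, grid=grid)


def class_average(data, assign: AssignmentResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean of the snapshots assigned to it.

    Returns (K, p) averages and length-K occupancy counts; empty nodes have
    zero average and zero occupancy.
    """
    X = data.counts if isinstance(data, SnapshotSet) else np.asarray(data, dtype=float)
    K = len(assign.grid)
    sums = np.zeros((K, X.shape[1]))
    np.add.at(sums, assign.best_index, X)
    occ = np.bincount(assign.best_index, minlength=K)
    out = sums / np.maximum(occ, 1)[:, None]
    return out, occ


def generate_model_snapshots(state) -> np.ndarray:
    """The model tomograms as the generative reconstruction.

    The tomograms synthesize the whole data set's information at each node,
    so they are less noisy than class averages, which only pool the snapshots
    assigned to that one node.
    """
    Y = getattr(state, "tomograms_", None)
    if Y is None:
        Y = getattr(state, "tomograms", None)
    if Y is None:
        raise ValueError("state has no tomograms; fit an orienter first")
    return np.asarray(Y, dtype=float)


def merge_volume(
    snapshots: np.ndarray,
    grid: OrientationGrid,
    geom: DetectorGeometry,
    L: int,
    voxel_spacing: float,
    gauge: np.ndarray | None = None,
    return_coverage: bool = False,
):
    """Grid K oriented snapshots into a Friedel-symmetrized intensity volume.

    Identical gridding kernel to the EMC compression step (it *is* that
    function).  ``gauge`` pre-rotates every node orientation, which aligns the
    merged volume with an external reference frame.
    """
    nodes = grid.nodes
    if gauge is not None:
        nodes = canonical_hemisphere(quat_multiply(np.asarray(gauge, float)[None, :], nodes))
    g = OrientationGrid(nodes=nodes, spec=grid.spec)
    return compress(snapshots, g, geom, L, voxel_spacing, friedel=True,
                    return_coverage=return_coverage)


@dataclass
class AccuracyReport:
    """Gauge-aligned orientation-recovery accuracy."""

    median_error_rad: float
    mean_error_rad: float
    median_error_shannon: float
    mean_error_shannon: float
    frac_within_one_shannon: float
    gauge: np.ndarray
    flipped: bool
    flip_fraction: float
    shannon_angle: float
    volume_correlation: float | None = None
    errors_rad: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "median_error_rad": self.median_error_rad,
            "mean_error_rad": self.mean_error_rad,
            "median_error_shannon": self.median_error_shannon,
            "mean_error_shannon": self.mean_error_shannon,
            "frac_within_one_shannon": self.frac_within_one_shannon,
            "gauge": [float(v) for v in self.gauge],
            "flipped": self.flipped,
            "flip_fraction": self.flip_fraction,
            "shannon_angle": self.shannon_angle,
            "volume_correlation": self.volume_correlation,
        }


def _axis_angle_quat(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    theta = float(np.linalg.norm(w))
    if theta < 1e-15:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = w / theta
    return np.concatenate([[np.cos(theta / 2.0)], np.sin(theta / 2.0) * axis])


def _errors(gauge: np.ndarray, est: np.ndarray, est_flip: np.ndarray | None,
            truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-snapshot geodesic errors, folding the flip branch when given."""
    err = rotation_angle(quat_multiply(gauge[None, :], est), truth)
    if est_flip is None:
        return err, np.zeros(len(err), dtype=bool)
    err_f = rotation_angle(quat_multiply(gauge[None, :], est_flip), truth)
    used = err_f < err
    return np.where(used, err_f, err), used


def align_gauge(
    est,
    truth: np.ndarray,
    grid: OrientationGrid | None = None,
    refine: bool = True,
    allow_flip: bool = True,
) -> AccuracyReport:
    """Fit the global rotation gauge, then report orientation errors.

    ``est`` is an :class:`AssignmentResult` or an (N, 4) quaternion array.
    Candidate gauges are all grid nodes; the best is refined by Nelder–Mead
    over a local axis-angle perturbation, minimizing the median geodesic
    error.  When ``allow_flip`` is set, each snapshot's error folds in the
    Friedel-flip branch (the orientation composed with a half-turn about the
    beam axis): a slice and its flipped mate deposit identical information
    in a Friedel-symmetric volume, so intensity data cannot tell the two
    apart snapshot by snapshot.  Errors come back in radians and in units of
    the grid's Shannon angle.
    """
    if isinstance(est, AssignmentResult):
        if grid is None:
            grid = est.grid
        est_q = est.quaternions
    else:
        est_q = np.atleast_2d(np.asarray(est, dtype=float))
    if grid is None:
        raise ValueError("grid is required when est is a quaternion array")
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if truth.shape != est_q.shape:
        raise ValueError("truth must match the estimated orientations in shape")

    est_flip = quat_multiply(est_q, _FLIP[None, :]) if allow_flip else None

    # vectorized scan over all node gauges: angle(g q_n, t_n)
    # |(g q) . t| = |g . (t q*)| so precompute t q* per snapshot and branch
    tq = quat_multiply(truth, quat_conjugate(est_q))
    dots = np.abs(grid.nodes @ tq.T)  # (K, N)
    if est_flip is not None:
        tqf = quat_multiply(truth, quat_conjugate(est_flip))
        dots = np.maximum(dots, np.abs(grid.nodes @ tqf.T))
    med = np.median(2.0 * np.arccos(np.clip(dots, -1.0, 1.0)), axis=1)
    k = int(np.argmin(med))
    med0, g0 = float(med[k]), grid.nodes[k].copy()

    gauge = g0
    if refine:
        def objective(w):
            g = quat_multiply(_axis_angle_quat(w), g0)
            return float(np.median(_errors(g, est_q, est_flip, truth)[0]))

        res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400})
        if res.fun <= med0:
            gauge = quat_multiply(_axis_angle_quat(res.x), g0)

    err, used_flip = _errors(gauge, est_q, est_flip, truth)
    dtheta = grid.spec.shannon_angle
    flip_fraction = float(np.mean(used_flip))
    return AccuracyReport(
        median_error_rad=float(np.median(err)),
        mean_error_rad=float(np.mean(err)),
        median_error_shannon=float(np.median(err) / dtheta),
        mean_error_shannon=float(np.mean(err) / dtheta),
        frac_within_one_shannon=float(np.mean(err <= dtheta)),
        gauge=canonical_hemisphere(gauge),
        flipped=flip_fraction > 0.5,
        flip_fraction=flip_fraction,
        shannon_angle=dtheta,
        errors_rad=err,
    )


def volume_correlation(
    a: IntensityVolume | np.ndarray,
    b: IntensityVolume | np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Voxelwise Pearson correlation, optionally restricted to a mask."""
    va = a.values if isinstance(a, IntensityVolume) else np.asarray(a, float)
    vb = b.values if isinstance(b, IntensityVolume) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError("volumes must share a lattice")
    if mask is not None:
        va = va[mask]
        vb = vb[mask]
    va = va.ravel() - va.mean()
    vb = vb.ravel() - vb.mean()
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    return float(va @ vb / denom) if denom > 0 else 0.0
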