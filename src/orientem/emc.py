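"""Expansion–maximization–compression (EMC) orientation recovery.

The model is a mixture over K discrete orientation nodes.  Each node k
carries a model snapshot ("tomogram") Y_k of p pixel intensities; a measured
snapshot T_n with hidden orientation has Poisson-distributed counts with
mean Y_k at node k.  One EM iteration:

  expand    tomograms <- Ewald slices of the current volume at the K nodes
  E-step    responsibilities R_kn ∝ p(x_k) prod_i Y_ki^T_ni exp(-Y_ki)
  M-step    Y_ki <- sum_n R_kn T_ni / sum_n R_kn
  compress  tomograms -> volume by trilinear local averaging

The compression–expansion cycle is a low-pass filter over orientation space:
it forces nearby nodes to carry similar tomograms (the contiguity
constraint) and is what makes the otherwise permutation-degenerate
likelihood identifiable.  With it disabled ("plain-EM mode") the iteration
is exact EM on the mixture and the log-likelihood is non-decreasing.

All E-step algebra is in the log domain with per-snapshot max subtraction;
at 10^-2 photons/pixel the raw likelihoods underflow double precision.  The
constant ln T! term is dropped from the log-likelihood (it does not depend
on the model), so traces are comparable across runs but offset from the
true log-probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.special import logsumexp

from .detector import DetectorGeometry, pixel_q_coordinates, shannon_pixel_check
from .geometry import OrientationGrid, build_grid, quat_to_matrix
from .simulate import SnapshotSet, required_L
from .volumes import IntensityVolume, friedel_symmetrize, trilinear_scatter

logger = logging.getLogger(__name__)

__all__ = [
    "expand",
    "estep_poisson",
    "mstep_emc",
    "compress",
    "seed_tomograms",
    "radial_profile_volume",
    "per_iteration_multiply_adds",
    "EMCOrienter",
    "run_emc",
]


def _as_counts(data) -> np.ndarray:
    X = data.counts if isinstance(data, SnapshotSet) else np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a SnapshotSet or an (N, p) array")
    return X


def expand(
    vol: IntensityVolume,
    grid: OrientationGrid,
    geom: DetectorGeometry,
    floor: float | None = None,
) -> np.ndarray:
    """Tomograms (K, p): Ewald slices of the volume at every grid node.

    Entries are floored at ``floor`` (default 1e-10 x mean volume intensity)
    so the Poisson log-likelihood ln Y stays finite.
    """
    from .volumes import trilinear_gather

    K = len(grid)
    pix = pixel_q_coordinates(geom)
    Y = np.empty((K, geom.p))
    half = vol.L // 2
    chunk = max(1, int(2e6) // geom.p)
    for a in range(0, K, chunk):
        b = min(a + chunk, K)
        rot = np.einsum("kij,pj->kpi", quat_to_matrix(grid.nodes[a:b]), pix)
        idx = rot.reshape(-1, 3) / vol.voxel_spacing + half
        vals, _ = trilinear_gather(vol.values, idx)
        Y[a:b] = np.clip(vals.reshape(b - a, geom.p), 0.0, None)
    if floor is None:
        floor = 1e-10 * max(float(np.mean(vol.values)), np.finfo(float).tiny)
    return np.maximum(Y, floor)


def estep_poisson(
    tomograms: np.ndarray,
    data,
    prior: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Poisson responsibilities and total log-likelihood.

    ``log p(T_n | Y_k) = sum_i [T_ni ln Y_ki - Y_ki]`` (the constant
    ``ln T_ni!`` is omitted).  Responsibilities are the per-snapshot softmax
    of log-prior + log-likelihood over nodes; every column of the returned
    (K, N) matrix sums to 1.  The scalar is
    ``sum_n ln sum_k p(x_k) p(T_n | Y_k)`` up to the omitted constant.
    """
    Y = np.asarray(tomograms, dtype=float)
    if np.any(Y <= 0) or not np.all(np.isfinite(Y)):
        raise ValueError("tomograms must be strictly positive and finite (floor them)")
    X = _as_counts(data)
    K = Y.shape[0]
    logp = _log_prior(prior, K)
    # (N, K): T @ ln(Y)^T - sum_i Y_ki
    ll = X @ np.log(Y).T - Y.sum(axis=1)[None, :] + logp[None, :]
    total = float(logsumexp(ll, axis=1).sum())
    ll -= ll.max(axis=1, keepdims=True)
    R = np.exp(ll)
    R /= R.sum(axis=1, keepdims=True)
    return R.T.copy(), total


def _log_prior(prior: np.ndarray | None, K: int) -> np.ndarray:
    if prior is None:
        return np.full(K, -np.log(K))
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (K,) or np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-8:
        raise ValueError("prior must be a length-K probability vector")
    return np.log(np.maximum(prior, 1e-300))


def mstep_emc(
    responsibilities: np.ndarray,
    data,
    previous: np.ndarray | None = None,
) -> np.ndarray:
    """Responsibility-weighted average of the data: the Poisson M-step.

    ``Y_ki = sum_n R_kn T_ni / sum_n R_kn``.  Rows whose total responsibility
    is below 1e-12 keep their previous values (if given) and are logged.
    """
    R = np.asarray(responsibilities, dtype=float)
    X = _as_counts(data)
    w = R.sum(axis=1)
    dead = w < 1e-12
    Y = (R @ X) / np.maximum(w, 1e-300)[:, None]
    if np.any(dead):
        logger.warning("mstep_emc: %d node(s) received ~zero responsibility", int(dead.sum()))
        if previous is not None:
            Y[dead] = previous[dead]
    return Y


def compress(
    tomograms: np.ndarray,
    grid: OrientationGrid,
    geom: DetectorGeometry,
    L: int,
    voxel_spacing: float,
    friedel: bool = True,
    return_coverage: bool = False,
):
    """Insert tomograms into reciprocal space and locally average onto a lattice.

    Every tomogram pixel is scattered with trilinear weights at its rotated
    q-coordinate; each voxel becomes the weight-normalized average.  Voxels
    that receive no weight are filled from their nearest filled neighbor (and
    counted in a log message).  The identical kernel also backs
    :func:`orientem.evaluate.merge_volume`.
    """
    Y = np.asarray(tomograms, dtype=float)
    pix = pixel_q_coordinates(geom)
    K = len(grid)
    if Y.shape != (K, geom.p):
        raise ValueError("tomograms must be (K, p) matching grid and geometry")
    acc = np.zeros((L, L, L))
    wacc = np.zeros((L, L, L))
    half = L // 2
    chunk = max(1, int(2e6) // geom.p)
    for a0 in range(0, K, chunk):
        b0 = min(a0 + chunk, K)
        rot = np.einsum("kij,pj->kpi", quat_to_matrix(grid.nodes[a0:b0]), pix)
        idx = rot.reshape(-1, 3) / voxel_spacing + half
        a, w = trilinear_scatter(idx, Y[a0:b0].reshape(-1), L)
        acc += a
        wacc += w
    if friedel:
        acc = acc + acc[::-1, ::-1, ::-1]
        wacc = wacc + wacc[::-1, ::-1, ::-1]
    filled = wacc > 0
    values = np.zeros((L, L, L))
    values[filled] = acc[filled] / wacc[filled]
    n_empty = int(np.sum(~filled))
    if n_empty:
        logger.info("compress: %d of %d voxels unobserved; nearest-neighbor filled",
                    n_empty, L ** 3)
        _, nearest = distance_transform_edt(~filled, return_indices=True)
        values = values[tuple(nearest)]
        if friedel:  # the fill is not inversion-symmetric; restore exactly
            values = friedel_symmetrize(values)
    vol = IntensityVolume(values=values, voxel_spacing=voxel_spacing)
    return (vol, filled) if return_coverage else vol


def seed_tomograms(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Initial tomograms: K snapshots chosen by distance-weighted seeding.

    The first seed is uniform-random; each further seed is drawn with
    probability proportional to its squared Euclidean distance from the
    nearest already-chosen seed (k-means++ style).  On clean data this picks
    one representative per distinct pattern; on sparse photon data it still
    yields a maximally diverse, data-scale start, which breaks the symmetry
    of the likelihood far more effectively than a perturbed isotropic model.
    """
    N = X.shape[0]
    idx = [int(rng.integers(N))]
    d2 = np.sum((X - X[idx[0]]) ** 2, axis=1)
    for _ in range(K - 1):
        total = d2.sum()
        if total <= 0:  # all snapshots identical
            idx.append(int(rng.integers(N)))
            continue
        i = int(rng.choice(N, p=d2 / total))
        idx.append(i)
        d2 = np.minimum(d2, np.sum((X - X[i]) ** 2, axis=1))
    return X[np.array(idx)].copy()


def radial_profile_volume(
    data,
    geom: DetectorGeometry,
    L: int,
    voxel_spacing: float,
    rng: np.random.Generator,
    noise_amplitude: float = 0.1,
) -> IntensityVolume:
    """Initial volume: the data's azimuthally averaged radial profile.

    The mean snapshot is binned by pixel |q| and interpolated at each voxel's
    |q|; multiplicative seeded noise (1 + ``noise_amplitude`` x N(0,1),
    clipped) breaks the spherical symmetry so EM can latch onto a gauge.
    """
    X = _as_counts(data)
    pix = pixel_q_coordinates(geom)
    qr = np.linalg.norm(pix, axis=1)
    mean_pix = X.mean(axis=0)
    nbins = max(8, geom.n_fast // 2)
    edges = np.linspace(0.0, qr.max() * (1 + 1e-9), nbins + 1)
    which = np.digitize(qr, edges) - 1
    prof = np.zeros(nbins)
    for b in range(nbins):
        sel = which == b
        prof[b] = mean_pix[sel].mean() if np.any(sel) else 0.0
    # backfill empty outer bins with the last populated value
    for b in range(1, nbins):
        if prof[b] == 0.0 and prof[b - 1] > 0.0:
            prof[b] = prof[b - 1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    c = (np.arange(L) - L // 2) * voxel_spacing
    gx, gy, gz = np.meshgrid(c, c, c, indexing="ij")
    vox_r = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
    vals = np.interp(vox_r.ravel(), centers, prof, left=prof[0], right=prof[-1])
    vals = vals.reshape(L, L, L)
    perturb = np.clip(1.0 + noise_amplitude * rng.standard_normal(vals.shape), 0.05, None)
    vals = vals * perturb
    floor = 1e-8 * max(float(vals.max()), np.finfo(float).tiny)
    return IntensityVolume(values=np.maximum(vals, floor), voxel_spacing=voxel_spacing)


def per_iteration_multiply_adds(K: int, N: int, p: int, L: int, compress_expand: bool = True) -> int:
    """Closed-form multiply–add count of one EM iteration.

    E-step: the (N x p)(p x K) likelihood product, K*p logs, and the softmax;
    M-step: the (K x N)(N x p) product and the row normalization; the
    compression and expansion interpolations touch 8 lattice corners per
    tomogram pixel (scatter accumulates values and weights).  The running
    estimators accumulate exactly this count per iteration.
    """
    ops = K * N * p + K * p + 3 * K * N  # E-step
    ops += K * N * p + K * p  # M-step
    if compress_expand:
        ops += 16 * K * p + 8 * K * p  # scatter (values + weights) + gather
    return int(ops)


@dataclass
class EMState:
    """Converged (or aborted) state of an EMC run."""

    tomograms: np.ndarray
    responsibilities: np.ndarray
    volume: IntensityVolume | None
    log_likelihood_trace: list[float]
    n_iter: int
    op_count: int
    converged: bool
    grid: OrientationGrid


class EMCOrienter:
    """Scikit-learn style estimator for EMC orientation recovery.

    Parameters
    ----------
    grid : OrientationGrid, optional
        Orientation nodes.  Built from ``n_nodes`` and ``random_state`` when
        omitted.
    n_nodes : int
        Grid size K when ``grid`` is None.
    geom : DetectorGeometry
        Pixel-to-q mapping; required at fit time.
    voxel_spacing : float, optional
        Volume lattice spacing; defaults to the detector's central pixel
        q-spacing (the oversampled Shannon spacing for a Shannon detector).
    L : int, optional
        Volume lattice side; defaults to the smallest odd value covering the
        rotated detector.
    compress_expand : bool
        Apply the compression–expansion contiguity constraint each iteration.
        False gives plain EM (monotone log-likelihood, permutation-degenerate).
    noise_model : {'poisson', 'gaussian'}
        Snapshot likelihood.  'gaussian' requires ``beta`` and exists mainly
        for the limit-equivalence analysis with the basis-function algorithm.
    tol, max_iter : float, int
        Stop when |delta logL| < tol * |logL| or after max_iter iterations.
    n_restarts : int
        Independent seeded restarts; the best final log-likelihood wins.

    Attributes (after fit)
    ----------------------
    tomograms_ : (K, p) model snapshots.
    responsibilities_ : (K, N) posterior node probabilities, columns sum to 1.
    volume_ : assembled IntensityVolume (None in plain-EM mode).
    log_likelihood_trace_ : list of per-iteration totals.
    labels_ : (N,) max-responsibility node index per snapshot.
    op_count_ : accumulated multiply–add count.
    """

    def __init__(
        self,
        grid: OrientationGrid | None = None,
        n_nodes: int = 200,
        geom: DetectorGeometry | None = None,
        voxel_spacing: float | None = None,
        L: int | None = None,
        prior: np.ndarray | None = None,
        compress_expand: bool = True,
        noise_model: str = "poisson",
        beta: float | None = None,
        tol: float = 1e-4,
        max_iter: int = 100,
        floor_frac: float = 1e-10,
        init: str = "data",
        init_noise: float = 0.1,
        n_restarts: int = 1,
        random_state: int = 0,
        init_tomograms: np.ndarray | None = None,
    ) -> None:
        self.grid = grid
        self.n_nodes = n_nodes
        self.geom = geom
        self.voxel_spacing = voxel_spacing
        self.L = L
        self.prior = prior
        self.compress_expand = compress_expand
        self.noise_model = noise_model
        self.beta = beta
        self.tol = tol
        self.max_iter = max_iter
        self.floor_frac = floor_frac
        self.init = init
        self.init_noise = init_noise
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.init_tomograms = init_tomograms

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "grid", "n_nodes", "geom", "voxel_spacing", "L", "prior",
            "compress_expand", "noise_model", "beta", "tol", "max_iter",
            "floor_frac", "init", "init_noise", "n_restarts", "random_state",
            "init_tomograms")}

    def set_params(self, **params) -> "EMCOrienter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core ---------------------------------------------------------------
    def _resolve(self, X: np.ndarray):
        geom = self.geom
        if geom is None:
            raise ValueError("geom is required")
        if X.shape[1] != geom.p:
            raise ValueError(f"X has {X.shape[1]} pixels but geometry has {geom.p}")
        grid = self.grid if self.grid is not None else build_grid(self.n_nodes, seed=self.random_state)
        spacing = self.voxel_spacing
        if spacing is None:
            spacing = shannon_pixel_check(geom, 1.0)["pixel_q_spacing"]
        L = self.L if self.L is not None else required_L(geom, spacing)
        return grid, geom, spacing, L

    def _estep(self, Y: np.ndarray, X: np.ndarray):
        if self.noise_model == "poisson":
            return estep_poisson(Y, X, self.prior)
        if self.noise_model == "gaussian":
            from .gtm import estep_gaussian

            if self.beta is None:
                raise ValueError("gaussian noise model requires beta")
            return estep_gaussian(Y, X, self.beta, self.prior)
        raise ValueError("noise_model must be 'poisson' or 'gaussian'")

    def _single_run(self, X: np.ndarray, grid, geom, spacing, L, seed) -> EMState:
        rng = np.random.default_rng(seed)
        K, N, p = len(grid), X.shape[0], X.shape[1]
        floor = self.floor_frac * max(float(X.mean()), np.finfo(float).tiny)
        if self.init_tomograms is not None:
            Y = np.maximum(np.asarray(self.init_tomograms, dtype=float), floor)
            vol = None
        elif self.init == "data":
            Y = np.maximum(seed_tomograms(X, K, rng), floor)
            vol = None
        elif self.init == "radial":
            vol = radial_profile_volume(X, geom, L, spacing, rng, self.init_noise)
            Y = expand(vol, grid, geom, floor=floor)
        else:
            raise ValueError("init must be 'data' or 'radial'")
        trace: list[float] = []
        ops = 0
        converged = False
        R = np.full((K, N), 1.0 / K)
        for _ in range(self.max_iter):
            R, ll = self._estep(Y, X)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"log-likelihood diverged at iteration {len(trace)}; state dumped to logger")
            trace.append(ll)
            Y = np.maximum(mstep_emc(R, X, previous=Y), floor)
            if self.compress_expand:
                vol = compress(Y, grid, geom, L, spacing)
                Y = expand(vol, grid, geom, floor=floor)
            ops += per_iteration_multiply_adds(K, N, p, L, self.compress_expand)
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < self.tol * abs(trace[-1]):
                converged = True
                break
        n_iter = len(trace)
        # final E-step so responsibilities match the stored tomograms
        R, ll = self._estep(Y, X)
        trace.append(ll)
        if not self.compress_expand:
            vol = None
        return EMState(tomograms=Y, responsibilities=R, volume=vol,
                       log_likelihood_trace=trace, n_iter=n_iter,
                       op_count=ops, converged=converged, grid=grid)

    def fit(self, X, y=None) -> "EMCOrienter":
        X = _as_counts(X)
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("X must be finite and non-negative")
        grid, geom, spacing, L = self._resolve(X)
        best: EMState | None = None
        for r in range(max(1, self.n_restarts)):
            state = self._single_run(X, grid, geom, spacing, L, self.random_state + r)
            if best is None or state.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]:
                best = state
        self.grid_ = best.grid
        self.tomograms_ = best.tomograms
        self.responsibilities_ = best.responsibilities
        self.volume_ = best.volume
        self.log_likelihood_trace_ = best.log_likelihood_trace
        self.n_iter_ = best.n_iter
        self.op_count_ = best.op_count
        self.converged_ = best.converged
        self.labels_ = np.argmax(best.responsibilities, axis=0)
        self.voxel_spacing_ = spacing
        self.L_ = L
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(N, K) posterior node probabilities under the fitted tomograms."""
        R, _ = self._estep(self.tomograms_, _as_counts(X))
        return R.T

    def predict(self, X) -> np.ndarray:
        """Max-posterior node index per snapshot."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of X under the fitted tomograms."""
        _, ll = self._estep(self.tomograms_, _as_counts(X))
        return ll


def run_emc(data, grid, geom, **config) -> EMCOrienter:
    """Thin functional wrapper: fit an :class:`EMCOrienter` on a SnapshotSet."""
    est = EMCOrienter(grid=grid, geom=geom, **config)
    return est.fit(data)
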