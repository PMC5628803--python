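"""Functional preprocessing: discard, slice timing, motion QC, smoothing,
intensity normalization, CompCor, and the 17-regressor nuisance GLM.

Spatial registration is out of scope — subjects arrive on a shared grid
(asserted via ``space_tag``) — but motion affines are still consumed for
quality control and as nuisance regressors.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, signal

from .errors import InvalidInputError, NumericalError
from .types import BoldSeries, MotionTrace, NuisanceDesign

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

MOTION_LABELS = ["tx", "ty", "tz", "rx", "ry", "rz"]


def discard_initial_volumes(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard < 0:
        raise InvalidInputError("n_discard must be non-negative")
    if n_discard >= series.n_volumes:
        raise InvalidInputError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    if n_discard == 0:
        return series
    return series.with_data(series.data[..., n_discard:])


def slice_timing_correct(
    series: BoldSeries,
    slice_axis: int = 2,
    slice_order: np.ndarray | None = None,
    ref_fraction: float = 0.5,
) -> BoldSeries:
    """Temporally align all slices to a common reference time within the TR.

    Slice ``s`` is acquired at offset ``rank(s)/n_slices * TR`` where rank
    is its position in ``slice_order`` (default sequential ascending).  Each
    slice's series is shifted to ``ref_fraction * TR`` by linear
    interpolation between neighboring volumes, clamping at the first and
    last volume.
    """
    n_slices = series.data.shape[slice_axis]
    if slice_order is None:
        slice_order = np.arange(n_slices)
    slice_order = np.asarray(slice_order)
    if sorted(slice_order.tolist()) != list(range(n_slices)):
        raise InvalidInputError(
            f"slice_order must be a permutation of 0..{n_slices - 1}"
        )
    if not (0.0 <= ref_fraction <= 1.0):
        raise InvalidInputError("ref_fraction must lie in [0, 1]")

    # rank of each slice in acquisition order -> acquisition time fraction
    rank = np.empty(n_slices, dtype=int)
    rank[slice_order] = np.arange(n_slices)
    acq_frac = rank / n_slices

    T = series.n_volumes
    out = np.empty_like(series.data)
    base = np.arange(T, dtype=float)
    for s in range(n_slices):
        # sample index at which the reference time falls for this slice
        shift = ref_fraction - acq_frac[s]
        sample_at = np.clip(base + shift, 0.0, T - 1.0)
        lo = np.floor(sample_at).astype(int)
        hi = np.minimum(lo + 1, T - 1)
        w = sample_at - lo
        sl = [slice(None)] * 4
        sl[slice_axis] = s
        block = series.data[tuple(sl)]
        out[tuple(sl)] = (1.0 - w) * block[..., lo] + w * block[..., hi]
    return series.with_data(out)


def motion_rms(
    affine_a: np.ndarray,
    affine_b: np.ndarray,
    radius: float = 80.0,
    center: np.ndarray | None = None,
) -> float:
    """RMS displacement (mm) between two rigid poses over a solid sphere.

    For points x uniform in a ball of the given radius about ``center``,
    the displacement is d(x) = (A - B) x; with Q the 3x3 difference of the
    rotation blocks and dt the translation difference,

        RMS^2 = (radius^2 / 5) tr(Q^T Q) + || Q c + dt ||^2 ,

    using E[u u^T] = (radius^2/5) I for the uniform ball.  Symmetric in
    (a, b) and zero iff the poses coincide.
    """
    affine_a = np.asarray(affine_a, dtype=float)
    affine_b = np.asarray(affine_b, dtype=float)
    for aff in (affine_a, affine_b):
        if aff.shape != (4, 4):
            raise InvalidInputError("affines must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise InvalidInputError("affine is not invertible")
    if center is None:
        center = np.zeros(3)
    Q = affine_a[:3, :3] - affine_b[:3, :3]
    dt = affine_a[:3, 3] - affine_b[:3, 3]
    mean_sq = (radius**2 / 5.0) * np.trace(Q.T @ Q) + np.sum((Q @ center + dt) ** 2)
    return float(np.sqrt(mean_sq))


def qc_filter(
    traces: dict[str, MotionTrace],
    threshold: float = 1.5,
    radius: float = 80.0,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Exclude subjects whose worst volume-to-reference RMS exceeds threshold.

    Returns (kept ids, excluded ids, per-subject max RMS in mm).  The
    reference pose is the identity (the trace is already expressed relative
    to the reference volume).
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    identity = np.eye(4)
    kept, excluded, max_rms = [], [], {}
    for sid, trace in traces.items():
        if trace.n_volumes == 0:
            raise InvalidInputError(f"empty motion trace for subject {sid!r}")
        rms = max(motion_rms(aff, identity, radius=radius) for aff in trace.affines)
        max_rms[sid] = rms
        (kept if rms <= threshold else excluded).append(sid)
    log.info("motion QC: kept %d, excluded %d at %.2f mm", len(kept), len(excluded), threshold)
    return kept, excluded, max_rms


def smooth_gaussian(series: BoldSeries, fwhm: float) -> BoldSeries:
    """Spatially smooth each volume with an isotropic (in mm) Gaussian.

    ``fwhm`` is in mm; per-axis sigma in voxels accounts for anisotropic
    voxel sizes.  Reflective boundaries keep constants exactly constant.
    ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise InvalidInputError("fwhm must be non-negative")
    if fwhm == 0:
        return series
    sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in series.voxel_size]
    out = ndimage.gaussian_filter(
        series.data, sigma=sigma_vox + [0.0], mode="reflect"
    )
    return series.with_data(out)


def normalize_intensity(
    series: BoldSeries, brain_mask: np.ndarray, target: float = 10000.0
) -> BoldSeries:
    """Grand-mean scaling: one global factor so the in-mask mean is ``target``."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise InvalidInputError("brain mask is empty")
    grand_mean = float(series.data[brain_mask].mean())
    if grand_mean <= 0:
        raise InvalidInputError(f"non-positive in-mask grand mean {grand_mean}")
    return series.with_data(series.data * (target / grand_mean))


def compcor_components(
    series: BoldSeries,
    noise_masks: list[np.ndarray],
    n_components: int = 5,
) -> np.ndarray:
    """CompCor: principal component time courses of noise-compartment voxels.

    Pools all noise-mask voxels; removes each voxel's mean and linear
    trend; scales each voxel to unit variance; returns the top left
    singular vectors of the resulting T x V matrix as (T, n_components)
    orthonormal columns ordered by singular value.  Sign convention: each
    component's largest-magnitude element is positive.
    """
    union = np.zeros(series.shape3d, dtype=bool)
    for m in noise_masks:
        union |= np.asarray(m, dtype=bool)
    X = series.data[union]  # (V, T)
    if X.shape[0] == 0:
        raise InvalidInputError("noise masks are empty")
    X = signal.detrend(X, axis=1, type="linear")
    sd = X.std(axis=1)
    valid = sd > 1e-12
    if int(valid.sum()) < n_components:
        raise InvalidInputError(
            f"only {int(valid.sum())} noise voxels with variance; need {n_components}"
        )
    X = X[valid] / sd[valid, None]
    U, s, _ = np.linalg.svd(X.T, full_matrices=False)  # U is (T, V')
    comps = U[:, :n_components].copy()
    for j in range(n_components):
        k = np.argmax(np.abs(comps[:, j]))
        if comps[k, j] < 0:
            comps[:, j] = -comps[:, j]
    return comps


def build_nuisance_design(trace: MotionTrace, components: np.ndarray) -> NuisanceDesign:
    """Assemble the 17-column nuisance design.

    Columns: 6 rigid-body parameters, their backward differences (first
    row zero — no prior volume), and the CompCor component time courses.
    """
    components = np.asarray(components, dtype=float)
    T = trace.n_volumes
    if components.shape[0] != T:
        raise InvalidInputError(
            f"motion trace has {T} rows but components have {components.shape[0]}"
        )
    deriv = np.zeros_like(trace.params)
    deriv[1:] = np.diff(trace.params, axis=0)
    matrix = np.hstack([trace.params, deriv, components])
    labels = (
        MOTION_LABELS
        + [f"d{l}" for l in MOTION_LABELS]
        + [f"compcor{i + 1}" for i in range(components.shape[1])]
    )
    return NuisanceDesign(matrix=matrix, labels=labels)


def _prune_design(design: NuisanceDesign) -> tuple[np.ndarray, list[str]]:
    """Drop all-zero and duplicate columns (legitimate for still phantoms)."""
    X = design.matrix
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.allclose(col, 0.0, atol=1e-14):
            dropped.append(design.labels[j])
            continue
        dup = any(np.allclose(col, X[:, k], atol=1e-14) for k in keep)
        if dup:
            dropped.append(design.labels[j])
            continue
        keep.append(j)
    if dropped:
        log.warning("pruned %d degenerate design columns: %s", len(dropped), dropped)
    return X[:, keep], [design.labels[j] for j in keep]


def regress_nuisance(
    series: BoldSeries, design: NuisanceDesign, brain_mask: np.ndarray
) -> BoldSeries:
    """Voxelwise OLS removal of nuisance regressors, preserving voxel means.

    An intercept is added internally (not counted among the 17 regressors);
    each in-mask voxel's residual gets its mean added back so downstream
    amplitude normalization stays well defined.  Out-of-mask voxels are
    zeroed.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    T = series.n_volumes
    X, labels = _prune_design(design)
    if T <= X.shape[1] + 1:
        raise InvalidInputError(
            f"{T} volumes insufficient for {X.shape[1]} regressors plus intercept"
        )
    Xi = np.column_stack([np.ones(T), X])
    rank = np.linalg.matrix_rank(Xi)
    if rank < Xi.shape[1]:
        raise NumericalError(
            f"nuisance design rank-deficient after pruning (rank {rank} < "
            f"{Xi.shape[1]}); columns: {['intercept'] + labels}"
        )
    Y = series.data[brain_mask].T  # (T, V)
    beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
    resid = Y - Xi @ beta
    resid += Y.mean(axis=0, keepdims=True)
    out = np.zeros_like(series.data)
    out[brain_mask] = resid.T
    return series.with_data(out)
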