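"""Voxelwise group inference on ALFF maps with Monte-Carlo cluster correction.

Within-group maps are tested against the normalized global mean (1) with
one-sample t-tests; between-group differences use a voxelwise ANCOVA
(group factor adjusted for age) followed by post-hoc two-sample t-tests
inside the significant mask.  Cluster-extent thresholds controlling
familywise error come from Monte-Carlo simulation of smoothed Gaussian
null fields on the analysis mask, in the style of AFNI's AlphaSim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InvalidInputError, NumericalError
from .types import AlffMap, ClusterTable, StatMap

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# face adjacency (6-connectivity), the classic nearest-neighbor clustering rule
STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class McThreshold:
    """Parameters of the Monte-Carlo cluster-extent calibration."""

    voxel_p: float = 0.05
    fwhm: float = 4.0
    alpha: float = 0.05
    n_iter: int = 10000
    seed: int = 0
    connectivity: int = 6
    sided: str = "two"  # "two" for t maps (signs clustered apart), "one" for F maps

    def __post_init__(self) -> None:
        if not (0.0 < self.voxel_p < 1.0) or not (0.0 < self.alpha < 1.0):
            raise InvalidInputError("voxel_p and alpha must lie in (0, 1)")
        if self.n_iter < 1000:
            raise InvalidInputError("n_iter must be at least 1000")
        if self.fwhm < 0:
            raise InvalidInputError("fwhm must be non-negative")
        if self.connectivity not in STRUCTURES:
            raise InvalidInputError("connectivity must be 6, 18 or 26")
        if self.sided not in ("one", "two"):
            raise InvalidInputError("sided must be 'one' or 'two'")


def _stack_maps(maps: list[AlffMap], mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise InvalidInputError(f"maps live on different grids: {shapes}")
    if next(iter(shapes)) != mask.shape:
        raise InvalidInputError("mask grid does not match the maps")
    return np.stack([m.data[mask] for m in maps])  # (n, V)


def one_sample_tmap(
    maps: list[AlffMap], null_value: float = 1.0, mask: np.ndarray | None = None
) -> StatMap:
    """Voxelwise one-sample t against a null value (default: global mean 1).

    Zero-variance voxels get a signed infinite statistic with a warning;
    they are excluded from clustering downstream.
    """
    if len(maps) < 3:
        raise InvalidInputError("one-sample t-test needs at least 3 maps")
    if mask is None:
        mask = maps[0].mask
    Y = _stack_maps(maps, mask)
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    degenerate = sd <= 1e-14
    if degenerate.any():
        log.warning("%d zero-variance voxels set to +/-inf", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - null_value) / (sd / np.sqrt(n))
    sign = np.sign(mean - null_value)
    with np.errstate(invalid="ignore"):
        t[degenerate] = np.where(sign[degenerate] == 0, 0.0, sign[degenerate] * np.inf)
    out = np.zeros(mask.shape)
    out[np.asarray(mask, dtype=bool)] = t
    return StatMap(
        data=out, df=(float(n - 1),), stat_kind="t", mask=mask,
        voxel_size=maps[0].voxel_size, affine=maps[0].affine,
    )


def _group_dummies(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(groups))
    # first level is the reference; remaining get indicator columns
    cols = [np.asarray(groups == g, dtype=float) for g in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(groups), 0)), levels


def ancova_fmap(
    maps: list[AlffMap],
    groups: np.ndarray,
    age: np.ndarray,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Voxelwise ANCOVA: F test for the group factor adjusting for age.

    Per voxel, OLS of ALFF on [intercept, group indicators, age]; the F
    statistic is the extra sum of squares of the group indicators over the
    age-only model, with df = (g - 1, n - g - 1).
    """
    groups = np.asarray(groups)
    age = np.asarray(age, dtype=float)
    levels = sorted(set(groups.tolist()))
    g = len(levels)
    n = len(maps)
    if g < 2 or any((groups == lv).sum() < 2 for lv in levels):
        raise InvalidInputError("need >= 2 groups with >= 2 subjects each")
    if n != len(groups) or n != len(age):
        raise InvalidInputError("maps, groups and age must align")
    if n <= g + 1:
        raise InvalidInputError(f"n={n} too small for {g} groups plus age")
    if mask is None:
        mask = maps[0].mask
    Y = _stack_maps(maps, mask)  # (n, V)

    dummies, _ = _group_dummies(groups)
    X_full = np.column_stack([np.ones(n), dummies, age])
    X_red = np.column_stack([np.ones(n), age])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise NumericalError(
            "voxelwise design is rank deficient: age is collinear with the "
            f"group indicators (groups {levels})"
        )

    def rss(X: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return np.einsum("ij,ij->j", r, r)

    rss_full = rss(X_full)
    rss_red = rss(X_red)
    df1, df2 = g - 1, n - g - 1
    degenerate = rss_full <= 1e-24
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    if degenerate.any():
        log.warning("%d voxels with zero residual variance set to F=0", int(degenerate.sum()))
        F[degenerate] = 0.0
    F = np.clip(F, 0.0, None)  # guard tiny negative rounding
    out = np.zeros(mask.shape)
    out[np.asarray(mask, dtype=bool)] = F
    return StatMap(
        data=out, df=(float(df1), float(df2)), stat_kind="F", mask=mask,
        voxel_size=maps[0].voxel_size, affine=maps[0].affine,
    )


def two_sample_t(a: np.ndarray, b: np.ndarray, pooled: bool = True) -> tuple[np.ndarray, float]:
    """Vectorized two-sample t over the first axis; returns (t, df)."""
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise InvalidInputError("both groups need >= 2 subjects")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(se2)
            df_arr = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        df = float(np.nanmedian(df_arr))
    t = np.where(np.isfinite(t), t, 0.0)
    return t, df


def posthoc_tmap(
    maps: list[AlffMap],
    groups: np.ndarray,
    group_a: str,
    group_b: str,
    significant_mask: np.ndarray,
    pooled: bool = True,
) -> StatMap:
    """Two-sample t map restricted to the ANCOVA-significant mask.

    Positive values mean ``group_a`` > ``group_b``.  An empty mask yields
    an all-zero map with a warning rather than an error.
    """
    groups = np.asarray(groups)
    significant_mask = np.asarray(significant_mask, dtype=bool)
    ia = np.nonzero(groups == group_a)[0]
    ib = np.nonzero(groups == group_b)[0]
    if len(ia) < 2 or len(ib) < 2:
        raise InvalidInputError(f"groups {group_a!r}/{group_b!r} need >= 2 subjects each")
    if not significant_mask.any():
        log.warning("post-hoc mask is empty; returning empty stat map")
        out = np.zeros(significant_mask.shape)
        return StatMap(
            data=out, df=(float(len(ia) + len(ib) - 2),), stat_kind="t",
            mask=significant_mask, voxel_size=maps[0].voxel_size, affine=maps[0].affine,
        )
    Y = _stack_maps(maps, significant_mask)
    t, df = two_sample_t(Y[ia], Y[ib], pooled=pooled)
    out = np.zeros(significant_mask.shape)
    out[significant_mask] = t
    return StatMap(
        data=out, df=(df,), stat_kind="t", mask=significant_mask,
        voxel_size=maps[0].voxel_size, affine=maps[0].affine,
    )


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def mc_cluster_threshold(
    mask: np.ndarray,
    mc: McThreshold,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> int:
    """Monte-Carlo cluster-extent threshold controlling familywise error.

    Each iteration fills the mask's bounding grid with unit Gaussian noise,
    smooths it to the stated FWHM (mm, converted per axis via
    ``voxel_size``), re-standardizes within the mask, applies the
    two-sided per-voxel threshold, and records the largest suprathreshold
    cluster (positive and negative excursions clustered separately).  The
    returned extent is the smallest k with empirical
    P(max cluster >= k) <= alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("analysis mask is empty")
    if mc.n_iter * mc.alpha < 5:
        raise InvalidInputError(
            f"n_iter={mc.n_iter} too small to resolve the alpha={mc.alpha} tail"
        )
    rng = np.random.default_rng(mc.seed)
    structure = STRUCTURES[mc.connectivity]
    two_sided = mc.sided == "two"
    zthr = stats.norm.ppf(1.0 - mc.voxel_p / (2.0 if two_sided else 1.0))
    sigma = [mc.fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
    maxima = np.empty(mc.n_iter, dtype=int)
    for i in range(mc.n_iter):
        field = rng.standard_normal(mask.shape)
        if any(s > 0 for s in sigma):
            field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        pos = (field > zthr) & mask
        if two_sided:
            neg = (field < -zthr) & mask
            maxima[i] = max(
                _max_cluster_size(pos, structure), _max_cluster_size(neg, structure)
            )
        else:
            maxima[i] = _max_cluster_size(pos, structure)
    # smallest k with P(max >= k) <= alpha
    for k in range(1, int(maxima.max()) + 2):
        if np.mean(maxima >= k) <= mc.alpha:
            log.info(
                "MC cluster threshold: %d voxels (voxel p=%.3g, fwhm=%.1f, alpha=%.3g)",
                k, mc.voxel_p, mc.fwhm, mc.alpha,
            )
            return k
    return int(maxima.max()) + 1  # unreachable; appeases type checkers


def _stat_threshold(stat: StatMap, voxel_p: float) -> tuple[float, bool]:
    """Per-voxel statistic cutoff for the stated p; returns (thr, two_sided)."""
    if stat.stat_kind == "t":
        return float(stats.t.ppf(1.0 - voxel_p / 2.0, stat.df[0])), True
    return float(stats.f.ppf(1.0 - voxel_p, stat.df[0], stat.df[1])), False


def extract_clusters(
    stat: StatMap,
    voxel_p: float,
    min_cluster_voxels: int,
    connectivity: int = 6,
) -> ClusterTable:
    """Threshold a statistic map and tabulate surviving clusters.

    t maps are thresholded two-sided with positive and negative clusters
    labeled separately; F maps one-sided.  Components below the extent
    threshold are dropped.  Non-finite voxels (degenerate variance policy)
    are excluded before clustering.
    """
    if min_cluster_voxels < 1:
        raise InvalidInputError("min_cluster_voxels must be >= 1")
    structure = STRUCTURES[connectivity]
    thr, two_sided = _stat_threshold(stat, voxel_p)
    data = stat.data
    finite = np.isfinite(data) & stat.mask
    n_bad = int((~np.isfinite(data) & stat.mask).sum())
    if n_bad:
        log.warning("excluding %d non-finite voxels from clustering", n_bad)

    voxel_volume = float(np.prod(stat.voxel_size))
    labels_out = np.zeros(data.shape, dtype=int)
    rows = []
    next_id = 1
    signs = [(+1, data > thr)] + ([(-1, data < -thr)] if two_sided else [])
    for sign, supra in signs:
        supra = supra & finite
        lab, n = ndimage.label(supra, structure=structure)
        for comp in range(1, n + 1):
            vox = lab == comp
            size = int(vox.sum())
            if size < min_cluster_voxels:
                continue
            vals = data[vox]
            idx = np.argwhere(vox)
            peak_ijk = idx[np.argmax(np.abs(vals))]
            peak_mm = (stat.affine @ np.append(peak_ijk, 1.0))[:3]
            labels_out[vox] = next_id
            rows.append(
                {
                    "cluster_id": next_id,
                    "sign": sign,
                    "size_voxels": size,
                    "size_mm3": size * voxel_volume,
                    "peak_i": int(peak_ijk[0]),
                    "peak_j": int(peak_ijk[1]),
                    "peak_k": int(peak_ijk[2]),
                    "peak_x_mm": float(peak_mm[0]),
                    "peak_y_mm": float(peak_mm[1]),
                    "peak_z_mm": float(peak_mm[2]),
                    "mean_stat": float(vals.mean()),
                }
            )
            next_id += 1
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "sign", "size_voxels", "size_mm3",
            "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "mean_stat",
        ],
    )
    return ClusterTable(table=table, labels=labels_out)


def cluster_mean_alff(amap: AlffMap, cluster_voxels: np.ndarray) -> float:
    """Mean ALFF over one cluster's voxels."""
    cluster_voxels = np.asarray(cluster_voxels, dtype=bool)
    if not cluster_voxels.any():
        raise InvalidInputError("cluster is empty")
    if cluster_voxels.shape != amap.data.shape:
        raise InvalidInputError("cluster grid does not match the map")
    return float(amap.data[cluster_voxels].mean())


def regional_alff_matrix(maps: list[AlffMap], clusters: ClusterTable) -> np.ndarray:
    """(subject x cluster) matrix of mean ALFF inside each cluster."""
    ids = clusters.table["cluster_id"].tolist()
    out = np.empty((len(maps), len(ids)))
    for j, cid in enumerate(ids):
        vox = clusters.voxels(cid)
        for i, m in enumerate(maps):
            out[i, j] = cluster_mean_alff(m, vox)
    return out


def wmh_subgroup_test(
    maps: list[AlffMap],
    wmh_flags: np.ndarray,
    clusters: ClusterTable,
    voxel_p: float = 0.05,
    min_cluster_voxels: int = 1,
    pooled: bool = True,
) -> pd.DataFrame:
    """Second-level test: lesion-positive vs lesion-negative subjects.

    Within each input cluster, a voxelwise two-sample t (flagged minus
    unflagged) is thresholded at the stated voxel p and extent rule; the
    returned sub-table reports, per parent cluster, each surviving
    sub-cluster's size and mean t.
    """
    wmh_flags = np.asarray(wmh_flags, dtype=bool)
    if len(wmh_flags) != len(maps):
        raise InvalidInputError("wmh_flags must align with maps")
    n_pos, n_neg = int(wmh_flags.sum()), int((~wmh_flags).sum())
    if n_pos < 2 or n_neg < 2:
        raise InvalidInputError(
            f"both lesion subgroups need >= 2 subjects (got {n_pos} / {n_neg})"
        )
    rows = []
    for cid in clusters.table["cluster_id"]:
        vox = clusters.voxels(cid)
        Y = np.stack([m.data[vox] for m in maps])
        t, df = two_sample_t(Y[wmh_flags], Y[~wmh_flags], pooled=pooled)
        tmap = np.zeros(vox.shape)
        tmap[vox] = t
        stat = StatMap(
            data=tmap, df=(df,), stat_kind="t", mask=vox,
            voxel_size=maps[0].voxel_size, affine=maps[0].affine,
        )
        sub = extract_clusters(stat, voxel_p, min_cluster_voxels)
        for _, r in sub.table.iterrows():
            rows.append(
                {
                    "parent_cluster": int(cid),
                    "sub_cluster": int(r["cluster_id"]),
                    "size_voxels": int(r["size_voxels"]),
                    "size_mm3": float(r["size_mm3"]),
                    "mean_t": float(r["mean_stat"]),
                    "sign": int(r["sign"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["parent_cluster", "sub_cluster", "size_voxels", "size_mm3", "mean_t", "sign"],
    )
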