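"""Core in-memory containers shared by every pipeline stage.

Images are plain numpy arrays with geometry carried alongside; NIfTI-1
serialization lives in :mod:`alffpipe.io`.  All arrays are indexed (x, y, z)
or (x, y, z, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

GROUPS = ("CTL", "ACTL", "SCD")


def default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Diagonal scaling affine mapping voxel indices to mm."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class BoldSeries:
    """A single subject's 4D BOLD signal with timing and voxel geometry.

    Attributes
    ----------
    data : (x, y, z, t) float array, arbitrary signal units.
    tr : repetition time in seconds.
    voxel_size : voxel edge lengths in mm.
    space_tag : label of the common grid the series lives on; stages that
        combine subjects assert matching tags rather than resampling.
    affine : 4x4 voxel-to-mm transform.
    """

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float]
    space_tag: str = "phantom"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidInputError(f"BOLD series must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 3:
            raise InvalidInputError("BOLD series needs at least 3 volumes")
        if self.tr <= 0:
            raise InvalidInputError(f"TR must be positive, got {self.tr}")
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidInputError(f"voxel sizes must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("BOLD series contains non-finite values")
        if self.affine is None:
            self.affine = default_affine(tuple(self.voxel_size))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 6 parameters plus equivalent affines.

    ``params`` columns are (tx, ty, tz) in mm then (rx, ry, rz) in radians;
    ``affines`` holds one 4x4 rigid transform per volume (to the reference).
    """

    params: np.ndarray
    affines: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        self.affines = np.asarray(self.affines, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise InvalidInputError(f"motion params must be (T, 6), got {self.params.shape}")
        if self.affines.shape != (self.params.shape[0], 4, 4):
            raise InvalidInputError(
                f"affines must be (T, 4, 4) matching params, got {self.affines.shape}"
            )
        rot = self.affines[:, :3, :3]
        gram = np.einsum("tij,tkj->tik", rot, rot)
        ortho = np.abs(gram - np.eye(3)).max(axis=(1, 2)) < 1e-6
        proper = np.abs(np.linalg.det(rot) - 1.0) < 1e-6
        bad = np.nonzero(~(ortho & proper))[0]
        if bad.size:
            raise InvalidInputError(f"affine {bad[0]} is not a proper rigid transform")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def drop_initial(self, n: int) -> "MotionTrace":
        if n >= self.n_volumes:
            raise InvalidInputError("cannot drop all volumes from a motion trace")
        return MotionTrace(self.params[n:], self.affines[n:])


@dataclass
class AlffMap:
    """A 3D ALFF image: band-limited fluctuation amplitude per voxel.

    After normalization the in-mask mean is 1 and values are unitless
    ratios to the whole-brain mean; outside the mask the map is zero.
    """

    data: np.ndarray
    band: tuple[float, float]
    mask: np.ndarray
    normalized: bool = False
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise InvalidInputError("ALFF map and mask shapes differ")
        if self.affine is None:
            self.affine = default_affine(tuple(self.voxel_size))


@dataclass
class StatMap:
    """Voxelwise test statistics (t or F) on the analysis mask."""

    data: np.ndarray
    df: tuple[float, ...]
    stat_kind: str  # "t" or "F"
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise InvalidInputError("stat map and mask shapes differ")
        if self.stat_kind not in ("t", "F"):
            raise InvalidInputError(f"stat_kind must be 't' or 'F', got {self.stat_kind!r}")
        if self.affine is None:
            self.affine = default_affine(tuple(self.voxel_size))


@dataclass
class ClusterTable:
    """Cluster-level summary of a thresholded statistic map.

    ``table`` has one row per cluster (cluster_id, sign, size_voxels,
    size_mm3, peak coordinates, mean_stat); ``labels`` is the integer label
    image whose values match ``cluster_id``.
    """

    table: "object"  # pandas.DataFrame; annotated loosely to avoid import cycle
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    def voxels(self, cluster_id: int) -> np.ndarray:
        """Boolean mask of one cluster's voxels."""
        return self.labels == cluster_id


@dataclass
class NuisanceDesign:
    """T x 17 nuisance regressor matrix with column labels."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise InvalidInputError("nuisance design must be 2D")
        if len(self.labels) != self.matrix.shape[1]:
            raise InvalidInputError("design labels must match column count")

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]
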