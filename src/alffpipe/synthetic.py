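"""Synthetic resting-state cohorts with known low-frequency amplitude truth.

The phantom emulates a resting-state acquisition (240 volumes at TR = 2 s,
band-limited oscillations in 0.008-0.09 Hz) on a small common grid.  Each
gray-matter voxel carries a sum of low-frequency oscillators whose amplitude
is set per anatomical region and multiplied by a group-specific factor: the
planted factor is the simulation truth every downstream stage is tested
against.  Noise-compartment voxels (white-matter-like, CSF-like,
out-of-brain) additionally share a confound waveform so that CompCor
component extraction has something real to recover.

Nothing here attempts realistic anatomy or scanner physics: the brain is an
ellipsoid, compartments are nested shells, and noise is AR(1) Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError
from .types import GROUPS, BoldSeries, MotionTrace

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ScoreModel:
    """Generative model of one neurocognitive score.

    ``coupling`` linearly ties the score to a subject's true oscillation
    amplitude in ``coupled_region`` (signal units -> score units); zero
    coupling gives a score independent of brain signal.
    """

    mean: float
    sd: float
    coupling: float = 0.0
    coupled_region: str | None = None


@dataclass
class PhantomSpec:
    """Geometry, timing and signal model of the BOLD phantom.

    Defaults mirror the emulated acquisition: 240 volumes at TR = 2 s
    (before the two-volume discard) and oscillators confined to the
    0.008-0.09 Hz ALFF band.  ``region_amplitudes`` assigns the baseline
    oscillation amplitude of each named gray-matter region; gray voxels in
    no named region use ``background_amplitude``.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 2.0
    n_volumes: int = 240
    baseline: float = 1000.0
    osc_band: tuple[float, float] = (0.008, 0.09)
    n_oscillators: int = 3
    background_amplitude: float = 5.0
    region_amplitudes: dict[str, float] = field(default_factory=dict)
    region_sizes: dict[str, int] = field(default_factory=lambda: {"ACC-like": 30})
    noise_sd: float = 2.0
    drift_slope: float = 0.01
    ar_coefficient: float = 0.3
    confound_sd: float = 3.0
    confound_gray_weight: float = 0.0
    amplitude_jitter_sd: float = 0.1
    bin_aligned: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML/JSON configs deliver sequences as lists
        self.grid_shape = tuple(self.grid_shape)
        self.voxel_size = tuple(self.voxel_size)
        self.osc_band = tuple(self.osc_band)
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be positive, got {self.grid_shape}")
        f_lo, f_hi = self.osc_band
        nyq = 1.0 / (2.0 * self.tr)
        if not (0.0 < f_lo < f_hi):
            raise ConfigurationError(f"need 0 < f_lo < f_hi, got band {self.osc_band}")
        if f_hi >= nyq:
            raise ConfigurationError(
                f"band upper edge {f_hi} Hz at or above Nyquist {nyq} Hz for TR={self.tr}s"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ConfigurationError("ar_coefficient must lie in [0, 1)")
        if self.n_oscillators < 1:
            raise ConfigurationError("need at least one oscillator per voxel")
        for name, amp in self.region_amplitudes.items():
            if amp <= 0:
                raise ConfigurationError(f"region {name!r} amplitude must be positive")


@dataclass
class GroupEffectSpec:
    """Planted contrast for one group: amplitude multipliers and covariates.

    ``amplitude_multiplier`` maps region id -> unitless factor (1.0 = no
    effect).  ``wmh_rate`` is the probability a subject carries more white
    matter lesions than one per decade of age (the pathological rule).
    """

    group: str
    n_subjects: int
    amplitude_multiplier: dict[str, float] = field(default_factory=dict)
    age_range: tuple[float, float] = (20.0, 40.0)
    score_models: dict[str, ScoreModel] = field(default_factory=dict)
    wmh_rate: float = 0.0

    def __post_init__(self) -> None:
        self.age_range = tuple(self.age_range)
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.n_subjects < 2:
            raise ConfigurationError("each group needs at least 2 subjects")
        if not (0.0 <= self.wmh_rate <= 1.0):
            raise ConfigurationError("wmh_rate must be a probability")
        for name, mult in self.amplitude_multiplier.items():
            if mult <= 0:
                raise ConfigurationError(f"multiplier for region {name!r} must be positive")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] <= 0:
            raise ConfigurationError(f"invalid age_range {self.age_range}")


@dataclass
class SubjectRecord:
    """One simulated subject's metadata plus withheld simulation truth."""

    subject_id: str
    group: str
    age: float
    wmh_count: int
    scores: dict[str, float]
    true_amplitudes: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.wmh_count < 0:
            raise InvalidInputError("wmh_count must be non-negative")


def _ellipsoid(shape: tuple[int, int, int], semiaxes: np.ndarray) -> np.ndarray:
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def make_phantom_masks(
    spec: PhantomSpec, min_compartment_voxels: int = 8
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Build brain, gray-matter, and three noise-compartment masks.

    The brain is a centered ellipsoid.  Gray matter is its outer shell;
    a white-matter-like core and a small CSF-like ventricle sit inside,
    disjoint from gray matter; the third noise compartment is everything
    outside a one-voxel dilation of the brain.

    Returns ``(brain_mask, gray_mask, [wm_mask, csf_mask, outside_mask])``.
    """
    shape = spec.grid_shape
    half = np.asarray(shape, dtype=float) / 2.0
    brain = _ellipsoid(shape, 0.80 * half)
    inner = _ellipsoid(shape, 0.52 * half)
    wm_outer = _ellipsoid(shape, 0.42 * half)
    csf = _ellipsoid(shape, 0.18 * half)

    gray = brain & ~inner
    wm = wm_outer & ~csf
    # out-of-brain compartment: a shell just beyond the brain boundary
    # (skull/air), separated from the brain by a one-voxel gap
    outside = ndimage.binary_dilation(brain, iterations=3) & ~ndimage.binary_dilation(
        brain, iterations=1
    )

    compartments = {
        "brain": brain,
        "gray": gray,
        "white-matter": wm,
        "csf": csf,
        "outside": outside,
    }
    for name, mask in compartments.items():
        if int(mask.sum()) < min_compartment_voxels:
            raise ConfigurationError(
                f"grid {shape} too small: compartment {name!r} has "
                f"{int(mask.sum())} voxels (< {min_compartment_voxels})"
            )
    return brain, gray, [wm, csf, outside]


def make_regions(
    gray_mask: np.ndarray, region_sizes: dict[str, int], seed: int = 0
) -> dict[str, np.ndarray]:
    """Carve named contiguous regions out of the gray-matter mask.

    Regions are grown by repeated face-adjacent dilation from deterministic
    seed voxels spread across gray matter, so the same spec always yields
    the same voxel sets.  Pairwise disjoint by construction.
    """
    rng = np.random.default_rng(seed)
    gray_idx = np.argwhere(gray_mask)
    if len(gray_idx) == 0:
        raise ConfigurationError("gray mask is empty")
    available = gray_mask.copy()
    regions: dict[str, np.ndarray] = {}
    struct = ndimage.generate_binary_structure(3, 1)  # face adjacency
    order = rng.permutation(len(gray_idx))
    seed_cursor = 0
    for name in sorted(region_sizes):
        size = region_sizes[name]
        if size > int(available.sum()):
            raise ConfigurationError(
                f"region {name!r} of {size} voxels does not fit in remaining gray matter"
            )
        # pick the next available seed voxel
        while seed_cursor < len(order):
            cand = tuple(gray_idx[order[seed_cursor]])
            seed_cursor += 1
            if available[cand]:
                break
        else:
            raise ConfigurationError("no seed voxel left for region growth")
        blob = np.zeros_like(gray_mask)
        blob[cand] = True
        while int(blob.sum()) < size:
            grown = ndimage.binary_dilation(blob, structure=struct) & available
            new = grown & ~blob
            n_new = int(new.sum())
            if n_new == 0:
                raise ConfigurationError(f"region {name!r} growth stalled before {size} voxels")
            excess = int(blob.sum()) + n_new - size
            if excess > 0:
                new_idx = np.argwhere(new)
                drop = new_idx[rng.permutation(n_new)[:excess]]
                new[tuple(drop.T)] = False
            blob |= new
        regions[name] = blob
        available &= ~blob
    return regions


def simulate_motion_trace(
    n_volumes: int,
    walk_sd: float,
    seed: int,
    clamp_mm: float = 1.0,
    clamp_deg: float = 1.0,
) -> MotionTrace:
    """Bounded random-walk rigid-body motion starting at zero.

    ``walk_sd`` is the per-volume step SD, interpreted in mm for the three
    translations and in degrees for the three rotations; the walk is
    clamped to +/- ``clamp_mm`` / ``clamp_deg``.  Rotations are reported in
    radians.  Deterministic given ``seed``.
    """
    if n_volumes < 2:
        raise InvalidInputError("motion trace needs at least 2 volumes")
    if walk_sd < 0:
        raise InvalidInputError("walk_sd must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, walk_sd, size=(n_volumes, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    params[:, :3] = np.clip(params[:, :3], -clamp_mm, clamp_mm)
    params[:, 3:] = np.clip(params[:, 3:], -clamp_deg, clamp_deg)
    params[:, 3:] = np.deg2rad(params[:, 3:])
    return MotionTrace(params=params, affines=rigid_affines(params))


def rigid_affine(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz), rotations in rad.

    Rotation convention: R = Rz @ Ry @ Rx applied about the grid origin.
    """
    return rigid_affines(np.asarray(params, dtype=float)[None, :])[0]


def rigid_affines(params: np.ndarray) -> np.ndarray:
    """Vectorized :func:`rigid_affine` for a (T, 6) parameter array."""
    params = np.asarray(params, dtype=float)
    T = params.shape[0]
    cx, sx = np.cos(params[:, 3]), np.sin(params[:, 3])
    cy, sy = np.cos(params[:, 4]), np.sin(params[:, 4])
    cz, sz = np.cos(params[:, 5]), np.sin(params[:, 5])
    R = np.empty((T, 3, 3))
    # rows of Rz @ Ry @ Rx, expanded symbolically
    R[:, 0, 0] = cz * cy
    R[:, 0, 1] = cz * sy * sx - sz * cx
    R[:, 0, 2] = cz * sy * cx + sz * sx
    R[:, 1, 0] = sz * cy
    R[:, 1, 1] = sz * sy * sx + cz * cx
    R[:, 1, 2] = sz * sy * cx - cz * sx
    R[:, 2, 0] = -sy
    R[:, 2, 1] = cy * sx
    R[:, 2, 2] = cy * cx
    aff = np.tile(np.eye(4), (T, 1, 1))
    aff[:, :3, :3] = R
    aff[:, :3, 3] = params[:, :3]
    return aff


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, ar: float) -> np.ndarray:
    """AR(1) noise with stationary marginal SD ``sd`` along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, sd, size=shape)
    if ar == 0:
        return white
    from scipy.signal import lfilter

    innov = white * np.sqrt(1.0 - ar**2)
    innov[..., 0] = white[..., 0]  # start at the stationary marginal
    return lfilter([1.0], [1.0, -ar], innov, axis=-1)


def _confound_waveform(rng: np.random.Generator, n_volumes: int, tr: float, sd: float) -> np.ndarray:
    """Smooth low-frequency confound shared across noise-compartment voxels."""
    t = np.arange(n_volumes) * tr
    wave = np.zeros(n_volumes)
    for _ in range(3):
        f = rng.uniform(0.01, 0.08)
        phase = rng.uniform(0, 2 * np.pi)
        wave += np.sin(2 * np.pi * f * t + phase)
    s = wave.std()
    if s > 0:
        wave *= sd / s
    return wave


def _oscillator_frequencies(
    rng: np.random.Generator, spec: PhantomSpec, n: int
) -> np.ndarray:
    f_lo, f_hi = spec.osc_band
    if spec.bin_aligned:
        duration = spec.n_volumes * spec.tr
        k_lo = int(np.ceil(f_lo * duration))
        k_hi = int(np.floor(f_hi * duration))
        if k_hi < k_lo:
            raise ConfigurationError("no Fourier bin inside osc_band for bin_aligned mode")
        ks = rng.integers(k_lo, k_hi + 1, size=n)
        return ks / duration
    return rng.uniform(f_lo, f_hi, size=n)


def simulate_bold_subject(
    spec: PhantomSpec,
    effect: GroupEffectSpec,
    subject_seed: int,
    subject_id: str | None = None,
    masks: tuple[np.ndarray, np.ndarray, list[np.ndarray]] | None = None,
    regions: dict[str, np.ndarray] | None = None,
) -> tuple[BoldSeries, SubjectRecord, MotionTrace]:
    """Simulate one subject's 4D series, metadata record and motion trace.

    Voxel model: baseline + sum of low-frequency oscillators (per-voxel
    random frequency/phase in ``osc_band``, amplitudes set by region truth
    x group multiplier x subject-level jitter) + linear drift + AR(1)
    noise.  Noise-compartment voxels carry a shared confound waveform;
    ``confound_gray_weight`` optionally leaks it into gray matter to
    exercise confound removal end to end.
    """
    rng = np.random.default_rng(subject_seed)
    if masks is None:
        masks = make_phantom_masks(spec)
    brain, gray, noise_masks = masks
    if regions is None:
        regions = make_regions(gray, spec.region_sizes, seed=spec.seed)
    for name, mask in regions.items():
        if not np.all(gray[mask]):
            raise ConfigurationError(f"region {name!r} extends outside gray matter")

    shape = spec.grid_shape
    T = spec.n_volumes
    t_idx = np.arange(T, dtype=float)

    # per-region true amplitudes: base * group multiplier * subject jitter
    true_amplitudes: dict[str, float] = {}
    amp_map = np.zeros(shape)
    bg_mult = effect.amplitude_multiplier.get("background", 1.0)
    bg_jitter = max(0.0, 1.0 + spec.amplitude_jitter_sd * rng.normal())
    bg_amp = spec.background_amplitude * bg_mult * bg_jitter
    amp_map[gray] = bg_amp
    true_amplitudes["background"] = bg_amp
    for name, region in regions.items():
        base = spec.region_amplitudes.get(name, spec.background_amplitude)
        mult = effect.amplitude_multiplier.get(name, 1.0)
        jitter = max(0.0, 1.0 + spec.amplitude_jitter_sd * rng.normal())
        amp = base * mult * jitter
        amp_map[region] = amp
        true_amplitudes[name] = amp

    data = np.full(shape + (T,), spec.baseline)
    active = brain | np.any(noise_masks, axis=0)
    vox = np.argwhere(active)
    n_vox = len(vox)
    # oscillators live in brain tissue only; noise compartments carry
    # noise + confound without a BOLD-like oscillation of their own
    ovox = np.argwhere(brain)
    n_ovox = len(ovox)
    n_osc = spec.n_oscillators
    freqs = _oscillator_frequencies(rng, spec, n_ovox * n_osc).reshape(n_ovox, n_osc)
    phases = rng.uniform(0, 2 * np.pi, size=(n_ovox, n_osc))
    amps = amp_map[tuple(ovox.T)][:, None] / n_osc
    # brain voxels outside gray matter oscillate weakly at background level
    amps[amps[:, 0] == 0] = 0.2 * spec.background_amplitude / n_osc
    # (n_ovox, T) oscillator sum, chunked to bound peak memory
    osc = np.empty((n_ovox, T))
    chunk = 4096
    t_sec = t_idx * spec.tr
    for start in range(0, n_ovox, chunk):
        sl = slice(start, min(start + chunk, n_ovox))
        arg = (2 * np.pi) * freqs[sl, :, None] * t_sec[None, None, :]
        arg += phases[sl, :, None]
        np.sin(arg, out=arg)
        arg *= amps[sl][:, :, None]
        osc[sl] = arg.sum(axis=1)
    data[tuple(ovox.T)] += osc

    drift = spec.drift_slope * (t_idx - t_idx.mean())
    data[tuple(vox.T)] += drift[None, :]

    if spec.noise_sd > 0:
        data[tuple(vox.T)] += _ar1_noise(rng, (n_vox, T), spec.noise_sd, spec.ar_coefficient)

    if spec.confound_sd > 0:
        wave = _confound_waveform(rng, T, spec.tr, spec.confound_sd)
        for mask in noise_masks:
            mvox = np.argwhere(mask)
            weights = 1.0 + 0.1 * rng.normal(size=len(mvox))
            data[tuple(mvox.T)] += weights[:, None] * wave[None, :]
        if spec.confound_gray_weight > 0:
            gvox = np.argwhere(gray)
            data[tuple(gvox.T)] += spec.confound_gray_weight * wave[None, :]

    series = BoldSeries(
        data=data, tr=spec.tr, voxel_size=tuple(spec.voxel_size), space_tag="phantom"
    )

    age = rng.uniform(*effect.age_range)
    decade_limit = age / 10.0
    if rng.uniform() < effect.wmh_rate:
        wmh_count = int(np.floor(decade_limit)) + 1 + int(rng.poisson(1.0))
    else:
        wmh_count = int(rng.integers(0, max(1, int(np.floor(decade_limit)) + 1)))
        wmh_count = min(wmh_count, int(np.floor(decade_limit)))

    scores: dict[str, float] = {}
    for score_name, model in sorted(effect.score_models.items()):
        value = model.mean + model.sd * rng.normal()
        if model.coupling != 0.0 and model.coupled_region is not None:
            value += model.coupling * true_amplitudes.get(model.coupled_region, 0.0)
        scores[score_name] = float(value)

    record = SubjectRecord(
        subject_id=subject_id or f"sub-{subject_seed:08d}",
        group=effect.group,
        age=float(age),
        wmh_count=wmh_count,
        scores=scores,
        true_amplitudes={k: float(v) for k, v in true_amplitudes.items()},
    )
    return series, record, simulate_motion_trace(T, walk_sd=0.02, seed=subject_seed + 1)


@dataclass
class Cohort:
    """All artifacts of one simulated cohort."""

    series: list[BoldSeries]
    motion: list[MotionTrace]
    records: list[SubjectRecord]
    table: pd.DataFrame
    brain_mask: np.ndarray
    gray_mask: np.ndarray
    noise_masks: list[np.ndarray]
    regions: dict[str, np.ndarray]


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (truth columns are withheld)."""
    score_names = sorted({name for r in records for name in r.scores})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "wmh_count": r.wmh_count,
        }
        for s in score_names:
            row[s] = r.scores.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: PhantomSpec, effects: list[GroupEffectSpec], master_seed: int
) -> Cohort:
    """Simulate a multi-group cohort with reproducible per-subject seeds."""
    if len(effects) < 2:
        raise InvalidInputError("a cohort needs at least 2 groups")
    masks = make_phantom_masks(spec)
    regions = make_regions(masks[1], spec.region_sizes, seed=spec.seed)
    ss = np.random.SeedSequence(master_seed)
    n_total = sum(e.n_subjects for e in effects)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_total)]

    series_list: list[BoldSeries] = []
    motion_list: list[MotionTrace] = []
    records: list[SubjectRecord] = []
    seen_ids: set[str] = set()
    i = 0
    for effect in effects:
        for j in range(effect.n_subjects):
            sid = f"sub-{effect.group}-{j:03d}"
            if sid in seen_ids:
                raise InvalidInputError(f"duplicate subject id {sid!r}")
            seen_ids.add(sid)
            series, record, motion = simulate_bold_subject(
                spec, effect, child_seeds[i], subject_id=sid, masks=masks, regions=regions
            )
            series_list.append(series)
            motion_list.append(motion)
            records.append(record)
            i += 1
    log.info("simulated cohort: %d subjects in %d groups", n_total, len(effects))
    return Cohort(
        series=series_list,
        motion=motion_list,
        records=records,
        table=cohort_table(records),
        brain_mask=masks[0],
        gray_mask=masks[1],
        noise_masks=masks[2],
        regions=regions,
    )
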