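"""ALFF: amplitude of low-frequency fluctuations.

Per voxel, the BOLD series is detrended and Fourier transformed; the
one-sided amplitude at bin k is a_k = 2 |X_k| / T at frequency
f_k = k / (T * TR), and ALFF is the mean of a_k over bins inside the
low-frequency band (default 0.008-0.09 Hz).  With this convention a pure
sinusoid of amplitude A contributes exactly A at its bin.  Each subject's
map is then normalized by its whole-brain mean, so the in-mask mean is 1
and global intensity scale cancels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import InvalidInputError
from .types import AlffMap, BoldSeries


def _check_band(tr: float, f_lo: float, f_hi: float) -> None:
    nyq = 1.0 / (2.0 * tr)
    if not (0.0 <= f_lo < f_hi):
        raise InvalidInputError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > nyq + 1e-12:
        raise InvalidInputError(
            f"band upper edge {f_hi} Hz exceeds Nyquist {nyq} Hz (TR = {tr} s)"
        )


def band_bins(n_volumes: int, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Indices k of positive-frequency DFT bins with f_lo <= k/(T*TR) <= f_hi."""
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    bins = np.nonzero((freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12) & (freqs > 0))[0]
    if len(bins) == 0:
        raise InvalidInputError(
            f"no Fourier bin in [{f_lo}, {f_hi}] Hz for T={n_volumes}, TR={tr}s"
        )
    return bins


def bandpass_filter(series: BoldSeries, f_lo: float, f_hi: float) -> BoldSeries:
    """Ideal frequency-domain band-pass: zero all bins outside [f_lo, f_hi].

    DC is always removed.  Linear and idempotent by construction.
    """
    _check_band(series.tr, f_lo, f_hi)
    T = series.n_volumes
    spec = np.fft.rfft(series.data, axis=-1)
    freqs = np.fft.rfftfreq(T, d=series.tr)
    keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12) & (freqs > 0)
    spec[..., ~keep] = 0.0
    return series.with_data(np.fft.irfft(spec, n=T, axis=-1))


def compute_alff(
    series: BoldSeries,
    f_lo: float,
    f_hi: float,
    brain_mask: np.ndarray,
    detrend: bool = True,
) -> AlffMap:
    """Unnormalized ALFF map: mean one-sided amplitude over in-band bins.

    In-mask voxels are mean-removed and linearly detrended before the
    transform (drift otherwise leaks into the lowest bins); out-of-mask
    voxels are zero.
    """
    _check_band(series.tr, f_lo, f_hi)
    if series.n_volumes < 8:
        raise InvalidInputError("need at least 8 volumes for a spectrum")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    T = series.n_volumes
    bins = band_bins(T, series.tr, f_lo, f_hi)
    Y = series.data[brain_mask]  # (V, T)
    if detrend:
        Y = signal.detrend(Y, axis=1, type="linear")
    else:
        Y = Y - Y.mean(axis=1, keepdims=True)
    amp = 2.0 * np.abs(np.fft.rfft(Y, axis=1)[:, bins]) / T
    out = np.zeros(series.shape3d)
    out[brain_mask] = amp.mean(axis=1)
    return AlffMap(
        data=out,
        band=(f_lo, f_hi),
        mask=brain_mask,
        normalized=False,
        voxel_size=tuple(series.voxel_size),
        affine=series.affine,
    )


def normalize_alff(amap: AlffMap, brain_mask: np.ndarray | None = None) -> AlffMap:
    """Divide by the in-mask mean so the whole-brain mean becomes 1."""
    mask = np.asarray(brain_mask, dtype=bool) if brain_mask is not None else amap.mask
    mean = float(amap.data[mask].mean())
    if mean <= 0:
        raise InvalidInputError("cannot normalize an ALFF map with non-positive mean")
    out = np.zeros_like(amap.data)
    out[mask] = amap.data[mask] / mean
    return AlffMap(
        data=out,
        band=amap.band,
        mask=mask,
        normalized=True,
        voxel_size=amap.voxel_size,
        affine=amap.affine,
    )
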