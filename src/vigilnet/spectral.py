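"""Brickwall band decomposition, relative power and peak frequency.

Band-pass filtering is done in the frequency domain: FFT of the raw epoch,
zeroing of every bin outside the passband, inverse FFT ("brickwall"
filter).  No taper is applied before the transform; spectral leakage of the
finite epoch is part of the method.

Band membership uses the half-open convention [f_lo, f_hi): the six default
bands share their printed boundaries (4, 8, 10, 13, 30 Hz), so each FFT bin
belongs to exactly one band; the boundary bin goes to the upper band.  The
DC bin is excluded everywhere (the lowest band starts at 0.5 Hz).

Relative power per band is the band's power divided by the summed power of
the six bands, i.e. by total 0.5-48 Hz power, so the six fractions of every
ROI close to 1.  Peak frequency is the frequency of the FFT bin with the
largest power in 4-13 Hz, at bin resolution, ties broken toward the lower
frequency.

All array operations accept 1-D series or 2-D (channels x samples) blocks
and act along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ArgumentError,
    BandDefinition,
    ConsistencyError,
    DegenerateInputError,
    DEFAULT_BANDS,
    Epoch,
    PipelineConfig,
)


def _band_mask(n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Boolean mask over rfft bins with f_lo <= f < f_hi."""
    if band.f_hi > fs / 2 + 1e-12:
        raise ArgumentError(
            f"band {band} exceeds Nyquist frequency {fs / 2} Hz"
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return (freqs >= band.f_lo) & (freqs < band.f_hi)


def brickwall_filter(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero all FFT bins outside [f_lo, f_hi) and inverse-transform.

    Output is real and has the same length as the input.  Applying the
    filter twice with the same band is identical to applying it once.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if not np.all(np.isfinite(x)):
        raise ArgumentError("input series contains non-finite values")
    mask = _band_mask(n, fs, band)
    spec = np.fft.rfft(x, axis=-1)
    spec = np.where(mask, spec, 0)
    return np.fft.irfft(spec, n=n, axis=-1)


def band_power(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Power of ``x`` inside the band: sum of squared retained-bin magnitudes.

    Normalized so that, by Parseval's theorem, the value equals the sum of
    squares of the brickwall-filtered series (its variance times n, the
    in-band mean being zero since DC is never retained).
    Returns a scalar for 1-D input, a per-channel vector for 2-D input.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    mask = _band_mask(n, fs, band)
    spec = np.fft.rfft(x, axis=-1)
    # double every bin except DC and (for even n) Nyquist to account for the
    # conjugate-symmetric half absent from the rfft
    w = np.full(mask.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    p = np.sum(w * mask * np.abs(spec) ** 2, axis=-1) / n
    return p


def relative_power(
    x: np.ndarray,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    fs: float = 312.5,
) -> np.ndarray:
    """Fraction of six-band total power in each band.

    Returns shape ``(..., n_bands)``; each row sums to 1.  Raises
    :class:`DegenerateInputError` when the epoch has no in-band power at all
    (e.g. an all-zero series).
    """
    x = np.asarray(x, dtype=float)
    powers = np.stack([band_power(x, b, fs) for b in bands], axis=-1)
    total = powers.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DegenerateInputError(
            "zero total in-band power: relative power undefined"
        )
    return powers / total


def peak_frequency(
    x: np.ndarray,
    fs: float,
    freq_range: tuple[float, float] = (4.0, 13.0),
) -> np.ndarray:
    """Frequency (Hz) of the FFT bin with maximal power in ``freq_range``.

    The range is inclusive at both ends; exact power ties resolve to the
    lower frequency.  Resolution is one FFT bin (fs/n Hz), no interpolation.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    lo, hi = freq_range
    if hi > fs / 2:
        raise ArgumentError(f"peak range {freq_range} exceeds Nyquist {fs / 2} Hz")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ArgumentError(f"no FFT bin inside {freq_range} at n={n}, fs={fs}")
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    sub = spec[..., sel]
    idx = np.argmax(sub, axis=-1)  # first maximum -> lowest frequency on ties
    return freqs[sel][idx]


@dataclass
class BandPowerTable:
    """Per-ROI relative band power and peak frequency for one epoch.

    ``rel_power`` is a (ROI x band) DataFrame of fractions summing to 1 per
    row; ``peak_freq`` a per-ROI Series in Hz.
    """

    rel_power: pd.DataFrame
    peak_freq: pd.Series
    epoch_ref: Epoch | None = None


def band_power_table(epoch: Epoch, config: PipelineConfig | None = None) -> BandPowerTable:
    """Compute the spectral summary of one epoch's ROI channels."""
    config = config or PipelineConfig()
    data = epoch.roi_data
    names = epoch.parent.roi_names
    rel = relative_power(data, config.bands, epoch.fs)
    peak = peak_frequency(data, epoch.fs, config.peak_range)
    return BandPowerTable(
        rel_power=pd.DataFrame(rel, index=names, columns=[b.name for b in config.bands]),
        peak_freq=pd.Series(peak, index=names, name="peak_freq"),
        epoch_ref=epoch,
    )


def aggregate_spectral(
    tables: Sequence[BandPowerTable],
) -> tuple[pd.DataFrame, pd.Series, pd.Series, float]:
    """Average spectral tables epochs-then-ROIs.

    Returns ``(regional_power, global_power, regional_peak, global_peak)``:
    regional values are means over epochs per ROI; global values the mean of
    the regional values over all ROIs.
    """
    if len(tables) == 0:
        raise ArgumentError("need at least one table to aggregate")
    index = tables[0].rel_power.index
    for t in tables[1:]:
        if not t.rel_power.index.equals(index):
            raise ConsistencyError("tables disagree on the ROI set")
    regional_power = sum(t.rel_power for t in tables) / len(tables)
    regional_peak = sum(t.peak_freq for t in tables) / len(tables)
    global_power = regional_power.mean(axis=0)
    global_peak = float(regional_peak.mean())
    return regional_power, global_power, regional_peak, global_peak
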