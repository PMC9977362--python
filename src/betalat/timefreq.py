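"""Morlet-wavelet time-frequency decomposition on a fixed analysis grid.

Single-trial power is computed with 7-cycle complex Morlet wavelets and
sampled onto a fixed grid (0.5 Hz frequency steps, 50 ms time steps by
default) independent of the recording sampling rate. Bins where the wavelet
(+-3 temporal standard deviations, sigma_t = cycles / (2 pi f)) extends
beyond the epoch are marked invalid (NaN power plus a boolean mask), not
zero-padded: downstream indices are power ratios and zeros would bias them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import EpochSet

BANDS = {"alpha": (7.0, 13.0), "beta": (14.0, 24.0), "gamma": (55.0, 75.0)}

DEFAULT_FREQ_STEP = 0.5
DEFAULT_TIME_STEP = 0.05
N_CYCLES = 7.0


@dataclass
class TFRArray:
    """Single-trial power: trials x channels x frequencies x time bins."""

    power: np.ndarray  # float32, NaN at invalid bins
    freqs: np.ndarray  # Hz
    times: np.ndarray  # seconds, fixed-step grid
    valid: np.ndarray  # (n_freqs, n_times) bool
    meta: object = None  # per-trial condition labels (DataFrame)
    layout: object = None

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def select(self, mask) -> "TFRArray":
        mask = np.asarray(mask)
        meta = None if self.meta is None else self.meta.loc[mask].reset_index(drop=True)
        return TFRArray(power=self.power[mask], freqs=self.freqs,
                        times=self.times, valid=self.valid, meta=meta,
                        layout=self.layout)


def default_freq_grid(fmin: float = 1.0, fmax: float = 90.0,
                      step: float = DEFAULT_FREQ_STEP) -> np.ndarray:
    return np.round(np.arange(fmin, fmax + step / 2, step), 6)


def band_freq_grid(band, step: float = DEFAULT_FREQ_STEP) -> np.ndarray:
    lo, hi = BANDS[band] if isinstance(band, str) else band
    return default_freq_grid(lo, hi, step)


def morlet_tfr(
    epochs: EpochSet,
    freqs=None,
    time_step: float = DEFAULT_TIME_STEP,
    n_cycles: float = N_CYCLES,
    chunk: int = 8,
) -> TFRArray:
    """Single-trial Morlet power on the fixed frequency x time grid.

    The wavelet transform runs at full sampling resolution (via MNE) and is
    then sampled at the nearest sample to each grid time, so the output grid
    depends only on ``time_step``, never on the sampling rate.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
    sfreq = epochs.sfreq
    if sfreq < 2 * freqs.max():
        raise ValueError(
            f"sampling rate {sfreq} Hz below twice the maximum requested "
            f"frequency {freqs.max()} Hz"
        )
    t = epochs.times
    duration = t[-1] - t[0]
    # frequencies with fewer than 3 cycles inside the epoch
    too_low = 3.0 / freqs > duration
    if too_low.any():
        warnings.warn(
            f"{int(too_low.sum())} frequencies below 3 wavelet cycles per "
            "epoch; their bins are invalidated",
            RuntimeWarning,
        )

    # fixed-step output grid covering the epoch
    grid = np.round(
        np.arange(np.ceil(t[0] / time_step) * time_step,
                  t[-1] + 1e-9, time_step),
        9,
    )
    grid_idx = np.round((grid - t[0]) * sfreq).astype(int)

    # validity: wavelet +-3 sigma_t inside the epoch
    sigma_t = n_cycles / (2 * np.pi * freqs)
    half = 3.0 * sigma_t
    valid = (
        (grid[None, :] - t[0] >= half[:, None])
        & (t[-1] - grid[None, :] >= half[:, None])
        & ~too_low[:, None]
    )

    n_ep = epochs.n_epochs
    out = np.empty((n_ep, epochs.layout.n_channels, len(freqs), len(grid)),
                   dtype=np.float32)
    for start in range(0, n_ep, chunk):
        sl = slice(start, min(start + chunk, n_ep))
        p = tfr_array_morlet(
            epochs.data[sl].astype(np.float64),
            sfreq=sfreq,
            freqs=freqs,
            n_cycles=n_cycles,
            output="power",
            verbose="error",
        )
        out[sl] = p[..., grid_idx].astype(np.float32)
    out[:, :, ~valid] = np.nan
    return TFRArray(power=out, freqs=freqs, times=grid, valid=valid,
                    meta=epochs.meta.copy(), layout=epochs.layout)


def band_average(tfr: TFRArray, band, window, closed: str = "both") -> np.ndarray:
    """Mean power over valid band x window bins: trials x channels.

    ``band`` is a name from BANDS or a (lo, hi) pair in Hz; ``window`` a
    (tmin, tmax) pair in seconds. ``closed`` controls endpoint inclusion
    ('both' or 'left'); a half-open selection window keeps a presequence
    window [-0.2, 0) bin-disjoint from the analysis window [0, 2.2]. Only
    valid bins enter the average; a fully invalid selection is an error.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fsel = (tfr.freqs >= lo - 1e-9) & (tfr.freqs <= hi + 1e-9)
    if not fsel.any():
        raise ValueError(f"band {(lo, hi)} outside the frequency grid")
    if closed == "both":
        tsel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    elif closed == "left":
        tsel = (tfr.times >= window[0] - 1e-9) & (tfr.times < window[1] - 1e-9)
    else:
        raise ValueError("closed must be 'both' or 'left'")
    if not tsel.any():
        raise ValueError(f"window {window} outside the time grid")
    if not tfr.valid[np.ix_(fsel, tsel)].any():
        raise ValueError("band/window selection contains no valid bins")
    block = tfr.power[:, :, fsel][:, :, :, tsel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=(2, 3))


def band_timecourse(tfr: TFRArray, band, window=None) -> tuple:
    """Band-mean power per time bin: (trials x channels x times, times).

    Averages over valid frequency bins only; time bins with no valid
    frequency bin come back as NaN.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fsel = (tfr.freqs >= lo - 1e-9) & (tfr.freqs <= hi + 1e-9)
    if not fsel.any():
        raise ValueError(f"band {(lo, hi)} outside the frequency grid")
    times = tfr.times
    tsel = np.ones_like(times, dtype=bool)
    if window is not None:
        tsel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    block = tfr.power[:, :, fsel][:, :, :, tsel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=2), times[tsel]
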