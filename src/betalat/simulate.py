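"""Synthetic multichannel EEG and behavioral responses for dichotic rhythms.

Signal model
------------
Each retained regular sequence yields one epoch spanning -1.0 to 3.5 s around
sequence onset. Per channel the signal is

    x_c(t) = n_c(t) + sqrt(g_c(t)) * b_c(t) + contamination,

where ``n_c`` is 1/f background noise (spectral shaping of white noise),
``b_c`` is an independent band-limited Gaussian carrier (14-24 Hz) scaled so
its variance equals ``snr`` times the background variance inside the beta
band, and the time-varying power gain

    g_c(t) = 1 + s_c * d * (1 + m * cos(2*pi*f_att*t + phi))

plants the attention effect: ``s_c`` is +1 for channels ipsilateral to the
attended ear, -1 contralateral, 0 on the midline; ``d`` is the
lateralization depth (ipsi-minus-contra fractional beta power difference),
``m`` the tempo modulation depth at the attended stream's rate ``f_att``,
and ``phi`` the planted phase. With d = m = 0 the left/right channel
statistics are exchangeable. Because the carrier is stochastic, power (not
phase-locked evoked activity) carries the effect.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import schedule as sched
from .layout import ChannelLayout, layout_from_frame, standard_layout

EPOCH_WINDOW = (-1.0, 3.5)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-EEG generator.

    All depths are unitless in [0, 1]; ``snr`` is the ratio of beta-carrier
    variance to background variance within 14-24 Hz; ``planted_phase`` is in
    radians. ``epochs_per_block`` caps the number of retained sequences
    simulated per block (None = all retained sequences).
    """

    sampling_rate: float = 512.0
    beta_center: float = 19.0
    beta_band: tuple = (14.0, 24.0)
    alpha_band: tuple = (7.0, 13.0)
    lateralization_depth: float = 0.3
    tempo_mod_depth: float = 0.6
    planted_phase: float = np.pi
    noise_exponent: float = 1.0
    snr: float = 1.0
    phase_jitter_sd: float = 0.0  # per-subject sd around planted_phase (rad)
    alpha_gain: float = 0.0
    contamination_gain: float = 0.0
    epoch_window: tuple = EPOCH_WINDOW
    epochs_per_block: Optional[int] = None
    channels: Optional[tuple] = None  # channel names; None = full 64-ch layout
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("lateralization_depth", "tempo_mod_depth", "alpha_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sampling_rate <= 2 * 90.0:
            raise ValueError(
                "sampling_rate must exceed twice the highest analysis "
                "frequency (90 Hz)"
            )
        if self.lateralization_depth * (1 + self.tempo_mod_depth) > 1.0:
            raise ValueError(
                "lateralization_depth * (1 + tempo_mod_depth) must not "
                "exceed 1 (power gains would go negative)"
            )
        if self.snr < 0 or self.contamination_gain < 0:
            raise ValueError("snr and contamination_gain must be nonnegative")

    def resolve_layout(self) -> ChannelLayout:
        full = standard_layout()
        if self.channels is None:
            return full
        return full.subset(list(self.channels))


@dataclass
class EpochSet:
    """Epoched voltages: trials x channels x samples, plus metadata.

    ``meta`` has one row per epoch with the block-level condition labels
    (attended_ear, predictability, dichotic_config, attended_tempo) and the
    sequence index the epoch is locked to.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_times), float32
    sfreq: float
    times: np.ndarray  # seconds relative to sequence onset
    layout: ChannelLayout
    meta: pd.DataFrame

    def __post_init__(self):
        n_ep, n_ch, n_t = self.data.shape
        if n_ch != self.layout.n_channels or n_t != len(self.times):
            raise ValueError("epoch array shape inconsistent with metadata")
        if len(self.meta) != n_ep:
            raise ValueError("metadata row count != epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            times=self.times,
            layout=self.layout,
            meta=self.meta.loc[mask].reset_index(drop=True),
        )

    def save(self, path) -> None:
        """Write the documented array container (zip of .npy + JSON)."""
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name, arr in (("data", self.data), ("times", self.times)):
                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(name + ".npy", buf.getvalue())
            zf.writestr(
                "meta.json",
                json.dumps(
                    {
                        "sfreq": self.sfreq,
                        "epoch_window": [float(self.times[0]), float(self.times[-1])],
                        "layout": self.layout.to_frame().to_dict("list"),
                        "epochs": self.meta.to_dict("list"),
                    }
                ),
            )

    @classmethod
    def load(cls, path) -> "EpochSet":
        with zipfile.ZipFile(path) as zf:
            data = np.load(io.BytesIO(zf.read("data.npy")))
            times = np.load(io.BytesIO(zf.read("times.npy")))
            meta = json.loads(zf.read("meta.json"))
        return cls(
            data=data,
            sfreq=meta["sfreq"],
            times=times,
            layout=layout_from_frame(pd.DataFrame(meta["layout"])),
            meta=pd.DataFrame(meta["epochs"]),
        )


@dataclass
class SyntheticSubject:
    epochs: EpochSet
    schedule: sched.SessionSchedule
    config: SimConfig
    behavior: list  # (response_time_s, block_index)
    musical_experience: float  # Gold-MSI-range scalar, 18..126


def _shaped_noise(rng, shape, n_times, sfreq, exponent):
    """1/f^exponent noise, unit variance, along the last axis."""
    freqs = np.fft.rfftfreq(n_times, 1 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2)
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),)))
    x = np.fft.irfft(spec * amp, n=n_times, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _band_noise(rng, shape, n_times, sfreq, band):
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n_times, 1 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),)))
    x = np.fft.irfft(spec * mask, n=n_times, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _band_variance_fraction(n_times, sfreq, exponent, band):
    """Fraction of 1/f background variance that lies inside ``band``."""
    freqs = np.fft.rfftfreq(n_times, 1 / sfreq)
    p = np.zeros_like(freqs)
    p[1:] = freqs[1:] ** (-exponent)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    return p[inside].sum() / p.sum()


def hemisphere_signs(layout: ChannelLayout, attended_ear: str) -> np.ndarray:
    """+1 ipsilateral to the attended ear, -1 contralateral, 0 midline."""
    ipsi = "L" if attended_ear == "left" else "R"
    contra = "R" if attended_ear == "left" else "L"
    return np.array(
        [1.0 if h == ipsi else (-1.0 if h == contra else 0.0)
         for h in layout.hemisphere]
    )


def simulate_eeg(
    schedule: sched.SessionSchedule,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> EpochSet:
    """Generate epochs for the retained regular sequences of a session."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    layout = cfg.resolve_layout()
    n_ch = layout.n_channels
    sfreq = cfg.sampling_rate
    t0, t1 = cfg.epoch_window
    n_t = int(round((t1 - t0) * sfreq))
    times = t0 + np.arange(n_t) / sfreq

    # beta-carrier scale: snr = carrier variance / background variance in-band
    beta_frac = _band_variance_fraction(n_t, sfreq, cfg.noise_exponent,
                                        cfg.beta_band)
    carrier_sd = np.sqrt(cfg.snr * beta_frac)

    # one phase per subject: planted phase plus inter-individual jitter
    phase = cfg.planted_phase
    if cfg.phase_jitter_sd > 0:
        phase = phase + cfg.phase_jitter_sd * rng.standard_normal()

    data, rows = [], []
    for bi, block in enumerate(schedule.blocks):
        keep = block.retained_regular_indices()
        if cfg.epochs_per_block is not None and len(keep) > cfg.epochs_per_block:
            keep = np.sort(rng.choice(keep, cfg.epochs_per_block, replace=False))
        n_ep = len(keep)
        signs = hemisphere_signs(layout, block.attended_ear)
        f_att = 1.0 / block.attended_soa
        env = 1.0 + cfg.tempo_mod_depth * np.cos(
            2 * np.pi * f_att * times + phase
        )
        gain = 1.0 + signs[:, None] * cfg.lateralization_depth * env[None, :]

        x = _shaped_noise(rng, (n_ep, n_ch), n_t, sfreq, cfg.noise_exponent)
        carrier = _band_noise(rng, (n_ep, n_ch), n_t, sfreq, cfg.beta_band)
        x += carrier_sd * np.sqrt(gain)[None] * carrier
        if cfg.alpha_gain > 0:
            alpha_frac = _band_variance_fraction(
                n_t, sfreq, cfg.noise_exponent, cfg.alpha_band
            )
            x += np.sqrt(cfg.alpha_gain * alpha_frac) * _band_noise(
                rng, (n_ep, n_ch), n_t, sfreq, cfg.alpha_band
            )
        if cfg.contamination_gain > 0:
            hf_band = (30.0, sfreq / 2)
            hf_frac = _band_variance_fraction(
                n_t, sfreq, cfg.noise_exponent, hf_band
            )
            hf = _band_noise(rng, (n_ep, n_ch), n_t, sfreq, hf_band)
            hf_gain = 1.0 + signs[:, None] * cfg.lateralization_depth
            x += np.sqrt(cfg.contamination_gain * hf_frac * hf_gain)[None] * hf

        data.append(x.astype(np.float32))
        for si in keep:
            rows.append(
                (bi, int(si), block.attended_ear, block.predictability,
                 block.dichotic_config, block.attended_tempo)
            )

    meta = pd.DataFrame(
        rows,
        columns=["block", "sequence_index", "attended_ear", "predictability",
                 "dichotic_config", "attended_tempo"],
    )
    return EpochSet(
        data=np.concatenate(data, axis=0),
        sfreq=sfreq,
        times=times,
        layout=layout,
        meta=meta,
    )


def simulate_behavior(
    schedule: sched.SessionSchedule,
    p_attended: float = 0.8,
    p_unattended: float = 0.15,
    false_alarm_rate: float = 0.02,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Button-press times: (time_s, block_index), sorted within block.

    Responses to deviants occur with per-ear probabilities and land within
    (0, 2] s after the deviant (0.2 s motor floor plus an exponential tail).
    ``false_alarm_rate`` is the per-sequence probability of a spurious press
    at a uniform time inside the sequence.
    """
    for p in (p_attended, p_unattended, false_alarm_rate):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for bi, block in enumerate(schedule.blocks):
        presses = []
        for e in block.deviant_events():
            p = p_attended if e.ear == block.attended_ear else p_unattended
            if rng.random() < p:
                rt = min(0.2 + rng.exponential(0.35), 2.0)
                presses.append(e.onset + rt)
        if false_alarm_rate > 0:
            for k in range(block.n_sequences):
                if rng.random() < false_alarm_rate:
                    presses.append((k + rng.random()) * sched.SEQUENCE_PERIOD)
        out.extend((t, bi) for t in sorted(presses))
    return out


def simulate_subject(
    cfg: SimConfig,
    seed: Optional[int] = None,
    p_attended: float = 0.8,
    p_unattended: float = 0.15,
    false_alarm_rate: float = 0.02,
) -> SyntheticSubject:
    """Schedule + EEG + behavior + covariates from one seeded generator."""
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    session = sched.build_session(rng)
    epochs = simulate_eeg(session, cfg, rng)
    behavior = simulate_behavior(
        session, p_attended, p_unattended, false_alarm_rate, rng
    )
    gmsi = float(np.clip(rng.normal(66.0, 17.6), 18, 126))
    return SyntheticSubject(
        epochs=epochs,
        schedule=session,
        config=cfg,
        behavior=behavior,
        musical_experience=gmsi,
    )
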