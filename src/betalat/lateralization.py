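"""Time-resolved lateralization index (LI) of ROI beta power.

LI = (power ipsi - power contra) / (power ipsi + power contra), per 50-ms
bin over 0-2.2 s. Ipsi/contra assignment follows the attended ear (attend
left -> left ROI is ipsilateral). Trial-mean ipsi and contra ROI power are
smoothed with a 250-ms centered moving average BEFORE forming the ratio,
averaged across the attend-left and attend-right conditions, and the LI is
computed per attended-tempo condition (high/low predictability pooled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .attention_index import ROIPair
from .layout import ChannelLayout

ANALYSIS_WINDOW = (0.0, 2.2)
SMOOTH_WINDOW = 0.25
CONDITIONS = ("attend_slow", "attend_fast")


def assign_ipsi_contra(roi_pair: ROIPair, attended_ear: str) -> tuple:
    """(ipsi ROI, contra ROI) channel tuples for the attended ear."""
    if attended_ear == "left":
        return roi_pair.left, roi_pair.right
    if attended_ear == "right":
        return roi_pair.right, roi_pair.left
    raise ValueError(f"bad attended_ear {attended_ear!r}")


def smooth_ma(series, window: float = SMOOTH_WINDOW, dt: float = 0.05) -> np.ndarray:
    """Centered moving average; edges use shrinking centered windows.

    ``window`` is in seconds and must round to an odd number of bins
    (5 bins at the default 50-ms grid).
    """
    x = np.asarray(series, float)
    n_bins = int(round(window / dt))
    if n_bins % 2 != 1:
        raise ValueError(
            f"window must span an odd number of bins, got {n_bins}"
        )
    kernel = np.ones(n_bins)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


@dataclass
class LITimeCourse:
    times: np.ndarray  # 50-ms bins over 0-2.2 s
    li: np.ndarray
    condition: str  # 'attend_slow' | 'attend_fast'
    subject: object = None
    smoothing_window: float = SMOOTH_WINDOW


def compute_li(ipsi_power, contra_power) -> np.ndarray:
    """Element-wise normalized ipsi-contra difference; both-zero bins NaN."""
    i = np.asarray(ipsi_power, float)
    c = np.asarray(contra_power, float)
    if i.shape != c.shape:
        raise ValueError("series must be aligned")
    if (i < 0).any() or (c < 0).any():
        raise ValueError("power must be nonnegative")
    denom = i + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (i - c) / denom, np.nan)


def li_timecourses(
    band_power,
    times,
    meta,
    roi_pair: ROIPair,
    layout: ChannelLayout,
    window=ANALYSIS_WINDOW,
    smooth_window: float = SMOOTH_WINDOW,
    subject=None,
) -> dict:
    """Per attended-tempo LI time courses from per-trial band power.

    ``band_power``: (n_trials, n_channels, n_times) beta-band power;
    ``meta``: per-trial DataFrame with ``attended_ear`` and
    ``attended_tempo`` columns. High/low predictability trials are pooled.
    Returns {condition: LITimeCourse} for 'attend_slow' and 'attend_fast'.
    """
    band_power = np.asarray(band_power, float)
    times = np.asarray(times, float)
    dt = float(np.median(np.diff(times)))
    # work on a margin around the analysis window so the moving average does
    # not pull in invalid epoch-edge bins, then crop
    margin = (times >= window[0] - smooth_window - 1e-9) & (
        times <= window[1] + smooth_window + 1e-9
    )
    band_power = band_power[:, :, margin]
    times = times[margin]
    if np.isnan(band_power).any():
        raise ValueError("band power contains invalid bins inside the window")
    tsel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    t_out = times[tsel]

    out = {}
    for condition in CONDITIONS:
        tempo = condition.split("_")[1]
        ipsi_courses, contra_courses = [], []
        for ear in ("left", "right"):
            mask = (meta["attended_tempo"] == tempo) & (meta["attended_ear"] == ear)
            if not mask.any():
                raise ValueError(
                    f"no trials for attended_tempo={tempo}, attended_ear={ear}"
                )
            trial_mean = band_power[np.asarray(mask)].mean(axis=0)  # ch x time
            ipsi_names, contra_names = assign_ipsi_contra(roi_pair, ear)
            ipsi = trial_mean[[layout.index(n) for n in ipsi_names]].mean(axis=0)
            contra = trial_mean[[layout.index(n) for n in contra_names]].mean(axis=0)
            ipsi_courses.append(smooth_ma(ipsi, smooth_window, dt))
            contra_courses.append(smooth_ma(contra, smooth_window, dt))
        ipsi_mean = np.mean(ipsi_courses, axis=0)[tsel]
        contra_mean = np.mean(contra_courses, axis=0)[tsel]
        li = compute_li(ipsi_mean, contra_mean)
        if np.isnan(li).any():
            warnings.warn("LI contains invalid (both-zero) bins", RuntimeWarning)
        out[condition] = LITimeCourse(
            times=t_out, li=li, condition=condition, subject=subject,
            smoothing_window=smooth_window,
        )
    return out


def li_frame(courses) -> "object":
    """Long-format table (subject, condition, time_s, li) from LI courses."""
    import pandas as pd

    rows = []
    for c in courses:
        for t, v in zip(c.times, c.li):
            rows.append((c.subject, c.condition, float(t), float(v)))
    return pd.DataFrame(rows, columns=["subject", "condition", "time_s", "li"])
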