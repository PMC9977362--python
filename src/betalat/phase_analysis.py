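"""FFT phase of LI time courses at the tempo frequencies; circular tests.

The demeaned LI series (50-ms grid, 0-2.2 s) is zero-padded to a 120-s
record, giving a frequency resolution of 1/120 Hz (~0.0083 Hz, finer than
0.01 Hz) on which both tempo frequencies - 1.25 Hz and 5/3 Hz - fall exactly
on the DFT grid. The phase is referenced to t = 0 (sequence onset):
cos(2 pi f t) has phase 0, sin has phase -pi/2.

Circular statistics: Rayleigh test of uniformity; the Harrison-Kanji
two-factor ANOVA for circular data (chi-squared statistics when the von
Mises concentration kappa < 2, F statistics otherwise); and a one-sided
permutation test on the difference of mean resultant vector lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

SLOW_FREQ = 1.25
FAST_FREQ = 1.0 / 0.6  # the "1.66 Hz" tempo, implemented exactly as 5/3 Hz
PAD_DURATION = 120.0  # seconds; 1/120 Hz grid holds both tempo frequencies
DEFAULT_N_PERMUTATIONS = 10_000


# ---------------------------------------------------------------------------
# phase extraction and labeling

def fft_phase_at(li, target_freq: float, dt: float = 0.05,
                 pad_duration: float = PAD_DURATION) -> float:
    """Phase angle (radians, (-pi, pi]) of a LI series at ``target_freq``.

    The series is demeaned, zero-padded to ``pad_duration`` seconds and the
    DFT phase is taken at the grid frequency nearest the target.
    """
    x = np.asarray(li, float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    nyquist = 0.5 / dt
    if target_freq > nyquist:
        raise ValueError(
            f"target {target_freq} Hz above the Nyquist frequency "
            f"{nyquist} Hz of the series grid"
        )
    n_pad = int(round(pad_duration / dt))
    if n_pad < x.size:
        raise ValueError("pad duration shorter than the series")
    spec = np.fft.rfft(x - x.mean(), n=n_pad)
    freqs = np.fft.rfftfreq(n_pad, dt)
    idx = int(np.argmin(np.abs(freqs - target_freq)))
    return float(np.angle(spec[idx]))


def label_attention(frequency: float, condition: str) -> str:
    """'attended' / 'unattended' label of a tempo frequency per condition.

    attend_slow -> 1.25 Hz attended, 5/3 Hz unattended; attend_fast the
    reverse. The map is a bijection per condition.
    """
    if condition not in ("attend_slow", "attend_fast"):
        raise ValueError(f"bad condition {condition!r}")
    is_slow_freq = abs(frequency - SLOW_FREQ) < abs(frequency - FAST_FREQ)
    attended = (condition == "attend_slow") == is_slow_freq
    return "attended" if attended else "unattended"


def phase_table(courses, dt: float = 0.05) -> pd.DataFrame:
    """Per-subject phase set: 2 frequencies x 2 labels from 2 LI courses.

    ``courses`` is an iterable of LITimeCourse (one per subject and
    condition). Each subject contributes exactly four rows.
    """
    rows = []
    for c in courses:
        for freq, freq_label in ((SLOW_FREQ, "1.25"), (FAST_FREQ, "1.66")):
            rows.append(
                (
                    c.subject,
                    c.condition,
                    freq_label,
                    label_attention(freq, c.condition),
                    fft_phase_at(c.li, freq, dt=dt),
                )
            )
    df = pd.DataFrame(
        rows, columns=["subject", "condition", "frequency", "label", "phase_rad"]
    )
    counts = df.groupby("subject").size()
    if (counts != 4).any():
        raise ValueError("each subject must contribute exactly 4 phase angles")
    return df


# ---------------------------------------------------------------------------
# circular descriptive statistics

def circ_r(angles) -> float:
    """Mean resultant vector length in [0, 1]."""
    z = np.exp(1j * np.asarray(angles, float))
    return float(abs(z.mean()))


def circ_mean(angles) -> float:
    """Circular mean angle in (-pi, pi]."""
    z = np.exp(1j * np.asarray(angles, float))
    return float(np.angle(z.mean()))


def circ_dist(a, b) -> np.ndarray:
    """Signed circular distance a - b wrapped to (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def circ_kappa(r: float, n: Optional[int] = None) -> float:
    """ML-style von Mises concentration from a resultant length.

    Fisher's approximation to the inverse of A(kappa) = I1/I0, with the
    standard small-sample (n <= 15) correction when ``n`` is given.
    """
    r = float(r)
    if r < 0.53:
        kappa = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    if n is not None and n <= 15:
        if kappa < 2:
            kappa = max(kappa - 2 / (n * kappa), 0.0)
        else:
            kappa = kappa * (n - 1) ** 3 / (n**3 + n)
    return float(kappa)


@dataclass(frozen=True)
class CircSummary:
    mean_angle: float
    resultant_length: float
    kappa: float
    n: int


def circ_summary(angles) -> CircSummary:
    angles = np.asarray(angles, float)
    r = circ_r(angles)
    return CircSummary(
        mean_angle=circ_mean(angles),
        resultant_length=r,
        kappa=circ_kappa(r, n=len(angles)),
        n=len(angles),
    )


# ---------------------------------------------------------------------------
# circular tests

@dataclass(frozen=True)
class CircTestResult:
    test: str  # rayleigh | harrison_kanji | resultant_diff_perm
    statistic: float
    kind: str  # 'Z' | 'chi2' | 'F' | 'observed-difference'
    p: float
    df: Optional[tuple] = None
    n: Optional[int] = None
    n_permutations: Optional[int] = None
    effect: Optional[str] = None


def rayleigh_test(angles) -> CircTestResult:
    """Rayleigh test of circular uniformity against unimodal concentration.

    Z = n * R^2 with the standard finite-n series approximation to p.
    """
    angles = np.asarray(angles, float)
    n = len(angles)
    if n < 3:
        raise ValueError("Rayleigh test requires n >= 3")
    r = circ_r(angles)
    z = n * r**2
    # standard finite-n corrected approximation (Zar / the circular-stats
    # toolbox convention): R = n * rbar
    R = n * r
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return CircTestResult(test="rayleigh", statistic=float(z), kind="Z",
                          p=float(p), n=n)


def _group_resultants(angles, labels):
    """(counts, n * resultant length) per unique label, plus the label order."""
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    counts = np.array([np.sum(labels == u) for u in uniq], float)
    res = np.array(
        [np.sum(labels == u) * circ_r(angles[labels == u]) for u in uniq]
    )
    return uniq, counts, res


def harrison_kanji_test(angles, factor_a, factor_b,
                        factor_names=("A", "B")) -> dict:
    """Two-factor ANOVA for circular data (Harrison-Kanji scheme).

    Returns {'<factor_a name>', '<factor_b name>', 'interaction'} mapped to
    CircTestResult. The reported statistic follows the concentration of the
    pooled sample: chi-squared (df 2(p-1) for main effects, (p-1)(q-1) for
    the interaction) when the von Mises kappa < 2, F statistics with a
    Stephens-type correction otherwise.
    """
    angles = np.asarray(angles, float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(angles) == len(fa) == len(fb)):
        raise ValueError("angles and factors must be aligned")
    n = len(angles)
    ua = list(pd.unique(fa))
    ub = list(pd.unique(fb))
    p, q = len(ua), len(ub)
    cell_n = np.zeros((p, q))
    cell_R = np.zeros((p, q))
    for i, a in enumerate(ua):
        for j, b in enumerate(ub):
            m = (fa == a) & (fb == b)
            if m.sum() < 2:
                raise ValueError("each factor cell needs >= 2 observations")
            cell_n[i, j] = m.sum()
            cell_R[i, j] = m.sum() * circ_r(angles[m])
    _, a_n, a_R = _group_resultants(angles, fa)
    _, b_n, b_R = _group_resultants(angles, fb)
    total_R = n * circ_r(angles)
    kappa = circ_kappa(total_R / n, n=n)

    ss_a = float(np.sum(a_R**2 / a_n) - total_R**2 / n)
    ss_b = float(np.sum(b_R**2 / b_n) - total_R**2 / n)
    ss_cells = float(np.sum(cell_R**2 / cell_n))
    ss_i = float(ss_cells - np.sum(a_R**2 / a_n) - np.sum(b_R**2 / b_n)
                 + total_R**2 / n)
    df_a, df_b, df_i = p - 1, q - 1, (p - 1) * (q - 1)

    names = (factor_names[0], factor_names[1], "interaction")
    out = {}
    if kappa >= 2:
        # high concentration: F ratios against the residual, with the
        # Stephens correction 1/(1 - 1/(5 kappa) - 1/(10 kappa^2))
        beta = 1.0 / (1 - 1 / (5 * kappa) - 1 / (10 * kappa**2))
        ss_r = float(n - ss_cells)
        df_r = n - p * q
        ms_r = ss_r / df_r
        for name, ss, df in zip(names, (ss_a, ss_b, ss_i), (df_a, df_b, df_i)):
            F = beta * (ss / df) / ms_r
            out[name] = CircTestResult(
                test="harrison_kanji", statistic=float(F), kind="F",
                p=float(stats.f.sf(F, df, df_r)), df=(df, df_r), n=n,
                effect=name,
            )
    else:
        # low concentration: chi-squared approximation, scale 2/(1 - rbar^2)
        rbar = special.i1(kappa) / special.i0(kappa)
        scale = 2.0 / (1 - rbar**2)
        chis = (scale * ss_a, scale * ss_b, scale * ss_i)
        dfs = (2 * df_a, 2 * df_b, df_i)
        for name, chi, df in zip(names, chis, dfs):
            chi = max(chi, 0.0)
            out[name] = CircTestResult(
                test="harrison_kanji", statistic=float(chi), kind="chi2",
                p=float(stats.chi2.sf(chi, df)), df=(df,), n=n, effect=name,
            )
    return out


def resultant_diff_perm_test(
    angles_f1,
    angles_f2,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng=None,
) -> CircTestResult:
    """One-sided permutation test on R(f1) - R(f2) for paired angle sets.

    The null distribution is built by swapping the two frequency labels
    within subjects; Monte-Carlo p uses the (b + 1)/(n + 1) correction. The
    alternative is directional: f1 (the attended frequency) more
    concentrated than f2.
    """
    a = np.asarray(angles_f1, float)
    b = np.asarray(angles_f2, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples of equal length required")
    n = len(a)
    if n < 5:
        warnings.warn("n < 5 pairs: permutation p resolution is coarse",
                      RuntimeWarning)
    if rng is None:
        rng = np.random.default_rng(0)
    observed = circ_r(a) - circ_r(b)
    za = np.exp(1j * a)
    zb = np.exp(1j * b)
    count = 0
    chunk = max(1, int(2e6 // max(n, 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        swap = rng.random((m, n)) < 0.5
        ra = np.abs(np.where(swap, zb, za).mean(axis=1))
        rb = np.abs(np.where(swap, za, zb).mean(axis=1))
        count += int(np.sum(ra - rb >= observed - 1e-12))
        done += m
    return CircTestResult(
        test="resultant_diff_perm",
        statistic=float(observed),
        kind="observed-difference",
        p=(count + 1) / (n_permutations + 1),
        n=n,
        n_permutations=n_permutations,
    )
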