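"""Activity-record analysis: onsets, phase angles, chi-square periodogram.

Activity onset follows the 30%-of-peak rule: within a 24 h scan window
the onset is the first bin whose count reaches 30% of the window's peak
bin and is confirmed by at least 3 of the following 6 bins reaching the
same threshold.  The phase angle of entrainment is the signed offset in
minutes between activity onset and dark onset (positive = onset precedes
darkness).  The free-running period is estimated with the chi-square
periodogram (Sokolove-Bushell): the series of N bins is folded at each
trial period P (in bins) into columns h = 1..P with n_h entries and
column means M_h, and

    Q_P = N * sum_h n_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

(the between-column sum of squares over the estimated variance) is
referred to a chi-square distribution with P - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import ActivitySeries
from .schedules import LightSchedule, Regime

__all__ = [
    "OnsetEstimate",
    "PhaseAngleResult",
    "PeriodogramResult",
    "daily_profile",
    "detect_onsets",
    "phase_angle",
    "chi_square_periodogram",
    "estimate_period",
]


@dataclass(frozen=True)
class OnsetEstimate:
    """Activity onset for one scan window (one per day)."""

    day_index: int
    onset_zt: float | None
    qualifying_bin_index: int | None
    valid: bool


@dataclass(frozen=True)
class PhaseAngleResult:
    """Phase angle of entrainment, minutes; positive = onset precedes dark."""

    per_day_min: tuple[float, ...]
    mean_min: float
    sem_min: float
    n_valid_days: int


@dataclass(frozen=True)
class PeriodogramResult:
    """Chi-square periodogram over a grid of integer bin-periods."""

    periods_h: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    threshold: np.ndarray
    alpha: float
    tau_hat_h: float | None
    significant: bool

    def peak_index(self) -> int | None:
        sig = self.qp > self.threshold
        if not sig.any():
            return None
        idx = np.flatnonzero(sig)
        return int(idx[np.argmax(self.qp[idx])])


def daily_profile(series: ActivitySeries, n_days: int = 5) -> np.ndarray:
    """Mean counts per bin-of-day over the first ``n_days`` full cycles."""
    bpd = series.bins_per_day
    if len(series.counts) < n_days * bpd:
        raise ValueError(
            f"series has {len(series.counts)} bins; need {n_days} full days "
            f"({n_days * bpd} bins)"
        )
    block = np.asarray(series.counts[: n_days * bpd], dtype=float)
    return block.reshape(n_days, bpd).mean(axis=0)


def _scan_onset(
    window: np.ndarray,
    threshold_frac: float,
    confirm_needed: int,
    confirm_window: int,
    tail: np.ndarray | None = None,
) -> int | None:
    """First qualifying bin index within ``window`` (None if no onset).

    ``tail`` supplies bins after the window end so confirmation can look
    past the window boundary.
    """
    peak = window.max()
    if peak <= 0:
        return None
    thr = threshold_frac * peak
    ext = window if tail is None or len(tail) == 0 else np.concatenate([window, tail])
    above = ext >= thr
    for i in range(len(window)):
        if not above[i]:
            continue
        nxt = above[i + 1 : i + 1 + confirm_window]
        if nxt.sum() >= confirm_needed:
            return i
    return None


def detect_onsets(
    series: ActivitySeries,
    threshold_frac: float = 0.30,
    confirm_needed: int = 3,
    confirm_window: int = 6,
    anchor_zt: float = 6.0,
) -> list[OnsetEstimate]:
    """Daily activity onsets by the 30%-of-peak rule.

    Each scan window spans 24 h starting at ``anchor_zt`` (default ZT6,
    six hours before dark onset, so nocturnal onsets sit mid-window and
    never wrap).  Within a window the peak is the maximum single bin;
    the onset is the first bin >= ``threshold_frac`` * peak confirmed by
    at least ``confirm_needed`` of the following ``confirm_window`` bins
    (confirmation may look past the window edge).  Windows with zero
    peak, or with no qualifying bin, yield an invalid estimate.
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must lie in (0, 1]")
    if confirm_needed > confirm_window:
        raise ValueError("confirm_needed must not exceed confirm_window")
    counts = np.asarray(series.counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    bpd = series.bins_per_day
    bph = bpd / series.schedule.cycle_length_h
    start = int(round(anchor_zt * bph))
    out: list[OnsetEstimate] = []
    day = 0
    while start + bpd <= len(counts):
        window = counts[start : start + bpd]
        tail = counts[start + bpd : start + bpd + confirm_window]
        i = _scan_onset(window, threshold_frac, confirm_needed, confirm_window, tail)
        if i is None:
            out.append(OnsetEstimate(day, None, None, False))
        else:
            bin_idx = start + i
            onset_zt = float(series.zt_of_bin(bin_idx))
            out.append(OnsetEstimate(day, onset_zt, bin_idx, True))
        start += bpd
        day += 1
    if not out:
        raise ValueError("series shorter than one scan window")
    return out


def phase_angle(
    onsets: list[OnsetEstimate],
    schedule: LightSchedule,
    min_valid_days: int = 3,
) -> PhaseAngleResult:
    """Phase angle of entrainment from daily onsets.

    Per day: ``(dark_onset_zt - onset_zt) * 60`` minutes, wrapped to
    (-720, 720]; positive when onset precedes dark onset.  The mean and
    SEM are over valid days; fewer than ``min_valid_days`` valid days
    raises (the subject cannot be scored).
    """
    if schedule.regime is not Regime.LD or schedule.dd_start_day == 0:
        raise ValueError("phase angle is defined only for LD schedules")
    half_cycle_min = schedule.cycle_length_h * 30.0
    angles = []
    for o in onsets:
        if not o.valid:
            continue
        ang = (schedule.dark_onset_zt - o.onset_zt) * 60.0
        ang = ang % (2 * half_cycle_min)  # wrap into (-720, 720]
        if ang > half_cycle_min:
            ang -= 2 * half_cycle_min
        angles.append(ang)
    if not angles:
        raise ValueError("no valid onsets")
    if len(angles) < min_valid_days:
        raise ValueError(
            f"only {len(angles)} valid onset day(s); need >= {min_valid_days}"
        )
    arr = np.asarray(angles)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return PhaseAngleResult(
        per_day_min=tuple(arr),
        mean_min=float(arr.mean()),
        sem_min=sem,
        n_valid_days=len(arr),
    )


def chi_square_periodogram(
    series: ActivitySeries,
    p_min_h: float = 20.0,
    p_max_h: float = 28.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Chi-square periodogram over integer bin-periods in [p_min, p_max].

    ``tau_hat_h`` is the period maximizing Q_P among periods whose Q_P
    exceeds the pointwise chi-square critical value at level ``alpha``;
    ``significant`` is False (and ``tau_hat_h`` None) when none does.
    Q_P is invariant under affine transforms of the counts.
    """
    x = np.asarray(series.counts, dtype=float)
    bw_h = series.bin_width_min / 60.0
    p_min_bins = int(np.ceil(p_min_h / bw_h))
    p_max_bins = int(np.floor(p_max_h / bw_h))
    if p_min_bins < 2:
        raise ValueError("p_min too small for this bin width")
    if len(x) < 2 * p_max_bins:
        raise ValueError("series must cover at least two times the longest period")
    grand = x.mean()
    denom = np.sum((x - grand) ** 2)
    if denom == 0:
        raise ValueError("constant series: periodogram undefined")
    n = len(x)
    idx = np.arange(n)
    periods = np.arange(p_min_bins, p_max_bins + 1)
    qp = np.empty(len(periods))
    for j, p in enumerate(periods):
        cols = idx % p
        sums = np.bincount(cols, weights=x, minlength=p)
        cnts = np.bincount(cols, minlength=p)
        means = sums / cnts
        qp[j] = n * np.sum(cnts * (means - grand) ** 2) / denom
    df = periods - 1
    threshold = stats.chi2.ppf(1 - alpha, df)
    sig = qp > threshold
    if sig.any():
        j = np.flatnonzero(sig)[np.argmax(qp[sig])]
        tau_hat = float(periods[j] * bw_h)
        significant = True
    else:
        tau_hat = None
        significant = False
    return PeriodogramResult(
        periods_h=periods * bw_h,
        qp=qp,
        df=df,
        threshold=threshold,
        alpha=alpha,
        tau_hat_h=tau_hat,
        significant=significant,
    )


def estimate_period(
    series: ActivitySeries,
    skip_days: int = 1,
    use_days: int = 12,
    p_min_h: float = 20.0,
    p_max_h: float = 28.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Free-running period over a DD analysis window.

    Crops the series to ``use_days`` full cycles of constant darkness
    commencing ``skip_days`` days after the DD transition, then applies
    :func:`chi_square_periodogram`.
    """
    sched = series.schedule
    dd_start = sched.dd_start_h()
    if dd_start is None:
        raise ValueError("series has no DD segment")
    bpd = series.bins_per_day
    start_bin = int(round(dd_start / sched.cycle_length_h + skip_days) * bpd)
    end_bin = start_bin + use_days * bpd
    if end_bin > len(series.counts):
        raise ValueError(
            f"series too short: needs {skip_days}+{use_days} DD days "
            f"({end_bin} bins), has {len(series.counts)}"
        )
    cropped = ActivitySeries(
        subject_id=series.subject_id,
        genotype=series.genotype,
        modality=series.modality,
        bin_width_min=series.bin_width_min,
        counts=series.counts[start_bin:end_bin],
        schedule=series.schedule,
    )
    return chi_square_periodogram(cropped, p_min_h=p_min_h, p_max_h=p_max_h, alpha=alpha)
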