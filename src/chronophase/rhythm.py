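"""Harmonic ("wave-curve") regression and circular phase estimation.

The wave fit is ordinary least squares on a truncated Fourier basis of
period T (default 24 h):

    y(t) = m + sum_{k=1..H} [ a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T) ]

The number of harmonics H is chosen by forward selection: the model
starts at H = 1 and each further sine/cosine pair is kept only if its
partial F-test is significant, up to ``max_harmonics``.  Rhythmicity is
the F-test of the one-harmonic model against the flat (intercept-only)
model.

The phase marker is the center of gravity (COG): the circular mean of
time weighted by the rhythm's mass above its minimum.  Dispersion is
the circular standard deviation sqrt(-2 ln R) (Mardia), with R the mean
resultant length, converted from radians to hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "HarmonicRegression",
    "CircularPhase",
    "fit_harmonic",
    "cog_of_fit",
    "cog_of_samples",
    "circular_sd_h",
]


@dataclass(frozen=True)
class CircularPhase:
    """Center-of-gravity phase with circular dispersion."""

    cog_zt: float  # hours in [0, period)
    resultant_length: float  # R in [0, 1]
    circular_sd_h: float  # sqrt(-2 ln R) in hours
    period_h: float = 24.0


def circular_sd_h(resultant_length: float, period_h: float = 24.0) -> float:
    """Mardia circular standard deviation, converted to hours."""
    r = float(resultant_length)
    if not (0 < r <= 1):
        raise ValueError("resultant length must lie in (0, 1]")
    return float(np.sqrt(max(-2.0 * np.log(r), 0.0)) * period_h / (2 * np.pi))


def _design(t: np.ndarray, period: float, n_harmonics: int) -> np.ndarray:
    w = 2 * np.pi * t / period
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(k * w))
        cols.append(np.sin(k * w))
    return np.column_stack(cols)


def _ls_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


class HarmonicRegression(BaseEstimator, RegressorMixin):
    """Least-squares Fourier ("wave-curve") fit with rhythmicity test.

    Parameters
    ----------
    period : float, default=24.0
        Base period T in hours (fixed; entrained data).
    max_harmonics : int, default=2
        Upper bound on the number of harmonics H.
    alpha : float, default=0.05
        Level of the partial F-test used by forward harmonic selection.
    select : bool, default=True
        If False, fit exactly ``max_harmonics`` harmonics.

    Attributes
    ----------
    mesor_ : float
        Fitted rhythm-adjusted mean.
    coef_cos_, coef_sin_ : ndarray of shape (n_harmonics_,)
        Cosine and sine coefficients a_k, b_k.
    n_harmonics_ : int
        Number of harmonics retained.
    amplitudes_ : ndarray
        Per-harmonic amplitudes sqrt(a_k^2 + b_k^2).
    acrophase_ : float
        Peak time of the fundamental harmonic, hours in [0, period).
    ss_residual_, ss_flat_ : float
        Residual sum of squares of the fit and of the flat model.
    f_stat_, p_value_ : float
        Rhythmicity F-test (one-harmonic model vs flat model),
        F = ((ss_flat - ss_res1) / 2) / (ss_res1 / (n - 3)).
    r_squared_ : float
        1 - ss_residual_/ss_flat_ of the selected model.

    Examples
    --------
    >>> t = np.arange(0, 24, 4.0)
    >>> y = 50 + 30 * np.cos(2 * np.pi * (t - 6) / 24)
    >>> fit = HarmonicRegression().fit(t, y)
    >>> round(fit.amplitudes_[0]), round(fit.acrophase_, 6)
    (30, 6.0)
    """

    def __init__(
        self,
        period: float = 24.0,
        max_harmonics: int = 2,
        alpha: float = 0.05,
        select: bool = True,
    ):
        self.period = period
        self.max_harmonics = max_harmonics
        self.alpha = alpha
        self.select = select

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("times and values must have equal length")
        if len(np.unique(t % self.period)) < 2:
            raise ValueError("need >= 2 distinct sampling times")
        n = len(y)
        if n <= 2 * 1 + 1:
            raise ValueError("need more than 3 observations")

        ss_flat = float(np.sum((y - y.mean()) ** 2))

        # One-harmonic fit: basis of the rhythmicity test.
        _, rss1 = _ls_rss(_design(t, self.period, 1), y)
        df_res1 = n - 3
        if ss_flat > 0 and rss1 > 0 and df_res1 > 0:
            f1 = ((ss_flat - rss1) / 2.0) / (rss1 / df_res1)
            p1 = float(stats.f.sf(f1, 2, df_res1))
        elif ss_flat == 0:
            f1, p1 = 0.0, 1.0
        else:  # perfect one-harmonic fit
            f1, p1 = np.inf, 0.0

        # Forward selection of further harmonics.
        h = 1
        rss_h = rss1
        if self.select:
            while h < self.max_harmonics:
                cand = h + 1
                if n <= 2 * cand + 1:
                    break
                _, rss_c = _ls_rss(_design(t, self.period, cand), y)
                df_res = n - (2 * cand + 1)
                if rss_c <= 0:
                    p_add = 0.0
                else:
                    f_add = ((rss_h - rss_c) / 2.0) / (rss_c / df_res)
                    p_add = float(stats.f.sf(f_add, 2, df_res))
                if p_add < self.alpha:
                    h, rss_h = cand, rss_c
                else:
                    break
        else:
            h = self.max_harmonics
            if n <= 2 * h + 1:
                raise ValueError("too few observations for requested harmonics")
            _, rss_h = _ls_rss(_design(t, self.period, h), y)

        beta, rss_h = _ls_rss(_design(t, self.period, h), y)
        self.n_harmonics_ = h
        self.mesor_ = float(beta[0])
        self.coef_cos_ = beta[1::2].copy()
        self.coef_sin_ = beta[2::2].copy()
        self.amplitudes_ = np.hypot(self.coef_cos_, self.coef_sin_)
        # Fundamental peak: m + A cos(2 pi (t - phi)/T), phi = atan2(b1, a1).
        phi = np.arctan2(self.coef_sin_[0], self.coef_cos_[0])
        self.acrophase_ = float((phi * self.period / (2 * np.pi)) % self.period)
        self.ss_residual_ = rss_h
        self.ss_flat_ = ss_flat
        self.f_stat_ = float(f1)
        self.p_value_ = p1
        self.r_squared_ = 1.0 - rss_h / ss_flat if ss_flat > 0 else 0.0
        self.n_obs_ = n
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "mesor_")
        t = np.asarray(X, dtype=float).reshape(-1)
        w = 2 * np.pi * t / self.period
        out = np.full(t.shape, self.mesor_)
        for k in range(1, self.n_harmonics_ + 1):
            out = out + self.coef_cos_[k - 1] * np.cos(k * w)
            out = out + self.coef_sin_[k - 1] * np.sin(k * w)
        return out

    @property
    def rhythmic_(self) -> bool:
        check_is_fitted(self, "p_value_")
        return self.p_value_ < self.alpha


def fit_harmonic(
    times,
    values,
    period: float = 24.0,
    h_max: int = 2,
    alpha: float = 0.05,
) -> HarmonicRegression:
    """Fit the wave curve to sampled data (thin estimator wrapper)."""
    return HarmonicRegression(
        period=period, max_harmonics=h_max, alpha=alpha
    ).fit(times, values)


def _circular_phase(
    times_h: np.ndarray, weights: np.ndarray, period: float
) -> CircularPhase:
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight: phase undefined")
    theta = 2 * np.pi * times_h / period
    c = float(np.sum(weights * np.cos(theta)) / total)
    s = float(np.sum(weights * np.sin(theta)) / total)
    r = float(np.hypot(c, s))
    if r == 0:
        raise ValueError("zero resultant: phase undefined")
    cog = (np.arctan2(s, c) * period / (2 * np.pi)) % period
    return CircularPhase(
        cog_zt=float(cog),
        resultant_length=r,
        circular_sd_h=circular_sd_h(r, period),
        period_h=period,
    )


def cog_of_fit(fit: HarmonicRegression, grid_step: float = 0.1) -> CircularPhase:
    """Center of gravity of a fitted wave curve.

    The curve is sampled on a regular grid over one period; the weights
    are the curve minus its minimum (non-negative for asymmetric waves);
    the COG is the weighted circular mean of grid time.
    """
    check_is_fitted(fit, "mesor_")
    t = np.arange(0.0, fit.period, grid_step)
    f = fit.predict(t)
    w = f - f.min()
    if np.allclose(w, 0):
        raise ValueError("constant fitted curve: center of gravity undefined")
    return _circular_phase(t, w, fit.period)


def cog_of_samples(times, values, period: float = 24.0) -> CircularPhase:
    """Center of gravity of raw samples (per-subject phase marker).

    As :func:`cog_of_fit` but with the observed values (minus their
    minimum) as weights at the observed sampling times.
    """
    t = np.asarray(times, dtype=float).reshape(-1)
    v = np.asarray(values, dtype=float).reshape(-1)
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    if len(np.unique(t % period)) < 2:
        raise ValueError("need >= 2 distinct sampling times")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    w = v - v.min()
    if np.allclose(w, 0):
        raise ValueError("all values equal: center of gravity undefined")
    return _circular_phase(t, w, period)
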