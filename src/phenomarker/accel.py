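"""Accelerometer biomarkers: distributional, varying-coefficient, spectral.

Three feature families are extracted per participant from the 1 Hz
magnitude series:

1. **Distribution features** (109 values): mean, median, mode, min, max,
   skewness, kurtosis, SD, RMSSD at lags 1 and 2, and the 1st-99th
   percentiles.
2. **Varying-coefficient dynamics** (DTVEM-style): the series is regressed
   on its own lagged values with the regression coefficient a smooth
   function f1(TD) of the time difference TD, estimated as a penalized
   natural-cubic smoothing spline over the lag axis.  Because TD takes the
   discrete values of the lag grid, the stacked regression collapses to
   per-lag sufficient statistics, which makes the fit exact and cheap.
3. **Spectral features**: Welch-averaged power spectral density on the
   native FFT frequency grid (identical across participants), one feature
   per positive frequency bin up to the 0.5 Hz Nyquist limit.

Sampling gaps: segments of the series separated by more than
``max_gap_s`` are treated as independent contiguous runs for the dynamic
and spectral families; distribution features always use every sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "DIST_FEATURE_NAMES",
    "DtvemFeatures",
    "SpectralFeatures",
    "DtvemOptions",
    "SpectralOptions",
    "distribution_features",
    "dtvem_features",
    "spectral_features",
    "period_of_feature",
    "split_runs",
]

DIST_FEATURE_NAMES: tuple[str, ...] = (
    "mean", "median", "mode", "min", "max", "skewness", "kurtosis", "sd",
    "rmssd_lag1", "rmssd_lag2",
) + tuple(f"q{q:02d}" for q in range(1, 100))

assert len(DIST_FEATURE_NAMES) == 109


class FeatureError(ValueError):
    """Raised when a feature family cannot be computed from the input."""


def _mode_fd(x: np.ndarray) -> float:
    """Mode of continuous data: midpoint of the densest Freedman-Diaconis bin."""
    if x.max() == x.min():
        return float(x[0])
    try:
        hist, edges = np.histogram(x, bins="fd")
    except (ValueError, MemoryError):
        hist, edges = np.histogram(x, bins="sturges")
    i = int(np.argmax(hist))  # ties -> lowest bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def _rmssd(x: np.ndarray, lag: int) -> float:
    if len(x) <= lag:
        return math.nan
    d = x[lag:] - x[:-lag]
    return float(np.sqrt(np.mean(d * d)))


def distribution_features(series: Sequence[float], *, relaxed: bool = False) -> np.ndarray:
    """109 distribution features of *series*, ordered as DIST_FEATURE_NAMES.

    ``relaxed=True`` permits n >= 1 (used for per-contact communication
    gaps), emitting NaN where a feature is undefined at that length and a
    population SD of 0 for a single value; the default contract requires at
    least three finite values.

    Zero-variance input has skewness and excess kurtosis defined as 0.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    min_n = 1 if relaxed else 3
    if len(x) < min_n:
        raise FeatureError(
            f"need at least {min_n} finite values, got {len(x)}")
    sd = float(np.std(x))  # population convention
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    out = np.empty(109)
    out[0] = float(np.mean(x))
    out[1] = float(np.median(x))
    out[2] = _mode_fd(x)
    out[3] = float(np.min(x))
    out[4] = float(np.max(x))
    out[5] = skew
    out[6] = kurt
    out[7] = sd
    out[8] = _rmssd(x, 1)
    out[9] = _rmssd(x, 2)
    out[10:] = np.quantile(x, np.arange(1, 100) / 100.0)  # linear interpolation
    return out


def split_runs(t: np.ndarray, x: np.ndarray, max_gap_s: float = 5.0) -> list[np.ndarray]:
    """Split a timestamped series into contiguous runs at gaps > max_gap_s."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    if len(t) == 0:
        return []
    cuts = np.nonzero(np.diff(t) > max_gap_s)[0] + 1
    return [seg for seg in np.split(x, cuts) if len(seg) > 0]


# ---------------------------------------------------------------------------
# Varying-coefficient dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DtvemOptions:
    """Fit options for the varying-coefficient dynamics features.

    ``n_windows``/``window_len_s`` control subsampling: at most n_windows
    windows of window_len_s seconds are drawn (seeded) from the series and
    all (value, lagged value) pairs within each window enter the stacked
    regression.  Series shorter than two windows are used whole.  The
    smoothing parameter is chosen by GCV over ``lambda_grid``.
    """

    max_lag_s: int = 60
    window_len_s: int = 600
    n_windows: int = 40
    seed: int = 0
    lambda_grid: tuple[float, ...] = tuple(float(10.0 ** e) for e in range(-2, 7))


@dataclass
class DtvemFeatures:
    """Varying coefficient f1(TD) on a grid of time differences."""

    td_grid: np.ndarray
    coef: np.ndarray
    lambda_: float = math.nan
    warning: str | None = None


def _natural_spline_penalty(knots: np.ndarray) -> np.ndarray:
    """Reinsch penalty K with f'Kf = integral of f''(t)^2 for the natural
    cubic spline interpolating f at *knots*."""
    h = np.diff(knots)
    n = len(knots)
    if n < 3:
        return np.zeros((n, n))
    # Delta: (n-2) x n second-difference matrix; W: (n-2) x (n-2) tridiagonal.
    delta = np.zeros((n - 2, n))
    w = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        delta[i, i] = 1.0 / h[i]
        delta[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        delta[i, i + 2] = 1.0 / h[i + 1]
        w[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            w[i, i + 1] = w[i + 1, i] = h[i + 1] / 6.0
    return delta.T @ np.linalg.solve(w, delta)


def _lag_sufficient_stats(runs: list[np.ndarray], lags: np.ndarray,
                          opts: DtvemOptions) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-lag sums over all stacked (y_t, y_{t-l}) pairs in sampled windows.

    Returns (s2, sxy, syy, n_pairs) with s2[l] = sum x^2, sxy[l] = sum x*y,
    syy = total sum y^2 over all stacked rows.
    """
    rng = np.random.default_rng(opts.seed)
    wl = opts.window_len_s
    windows: list[np.ndarray] = []
    total = sum(len(r) for r in runs)
    if total <= opts.n_windows * wl // 2 or total < 2 * wl:
        windows = [r for r in runs if len(r) > int(lags.max())]
    else:
        eligible = [r for r in runs if len(r) >= wl]
        if not eligible:
            windows = [r for r in runs if len(r) > int(lags.max())]
        else:
            weights = np.array([len(r) for r in eligible], float)
            weights /= weights.sum()
            for _ in range(opts.n_windows):
                r = eligible[rng.choice(len(eligible), p=weights)]
                start = rng.integers(0, len(r) - wl + 1)
                windows.append(r[start:start + wl])
    s2 = np.zeros(len(lags))
    sxy = np.zeros(len(lags))
    syy = 0.0
    n_pairs = 0.0
    for wdata in windows:
        y = wdata - wdata.mean()
        for j, lag in enumerate(lags):
            lag = int(lag)
            if len(y) <= lag:
                continue
            x = y[:-lag]
            yt = y[lag:]
            s2[j] += float(x @ x)
            sxy[j] += float(x @ yt)
            syy += float(yt @ yt)
            n_pairs += len(yt)
    return s2, sxy, syy, n_pairs


def dtvem_features(series_or_runs, max_lag_s: int | None = None,
                   td_grid: Sequence[float] | None = None,
                   opts: DtvemOptions | None = None) -> DtvemFeatures:
    """Estimate the varying lag coefficient f1(TD) of a series on itself.

    The stacked varying-coefficient regression y_t ~ f1(TD) * y_{t-TD}
    (series mean-centered, all integer lags TD = 1..max_lag_s) is solved as
    a weighted smoothing spline: minimize
    sum_l [ s2_l f_l^2 - 2 sxy_l f_l ] + lambda * f' K f,
    where s2_l, sxy_l are the per-lag stacked cross-products and K the
    natural-cubic-spline roughness penalty.  Equivalently this smooths the
    per-lag OLS slopes b_l = sxy_l / s2_l with precision weights s2_l, and
    lambda is chosen by weighted GCV at the lag level (one observation per
    lag), which keeps the estimate essentially unbiased where the stacked
    data are informative while still suppressing lag-to-lag noise.

    *series_or_runs* is a 1 Hz value array or a list of contiguous runs
    (gap handling is the caller's job, see :func:`split_runs`).

    A degenerate fit (constant series) yields zero coefficients with
    ``warning='degenerate'``.
    """
    opts = opts or DtvemOptions()
    if max_lag_s is None:
        max_lag_s = opts.max_lag_s
    if isinstance(series_or_runs, (list, tuple)):
        runs = [np.asarray(r, float) for r in series_or_runs]
    else:
        runs = [np.asarray(series_or_runs, float)]
    runs = [r[np.isfinite(r)] for r in runs]
    if td_grid is None:
        td_grid = np.arange(1.0, max_lag_s + 1.0)
    td_grid = np.asarray(td_grid, float)
    if td_grid.min() <= 0 or td_grid.max() > max_lag_s:
        raise FeatureError("td_grid must lie within (0, max_lag_s]")
    n_total = sum(len(r) for r in runs)
    if n_total < 10 * max_lag_s:
        raise FeatureError(
            f"series too short for max_lag_s={max_lag_s}: {n_total} samples")

    lags = np.unique(np.round(td_grid).astype(int))
    s2, sxy, syy, n_pairs = _lag_sufficient_stats(runs, lags, opts)
    if n_pairs == 0 or np.all(s2 <= 1e-12 * max(1.0, n_pairs)):
        return DtvemFeatures(td_grid=td_grid, coef=np.zeros(len(td_grid)),
                             warning="degenerate")

    knots = lags.astype(float)
    K = _natural_spline_penalty(knots)
    S2 = np.diag(s2)
    n_lag = len(lags)
    b_ols = np.where(s2 > 0, sxy / np.where(s2 > 0, s2, 1.0), 0.0)
    best = None
    for lam in opts.lambda_grid:
        try:
            A = S2 + lam * K
            f = np.linalg.solve(A, sxy)
            # trace of the lag-level hat matrix: tr((S2 + lam K)^-1 S2)
            edf = float(np.trace(np.linalg.solve(A, S2)))
        except np.linalg.LinAlgError:
            continue
        wrss = float(np.sum(s2 * (b_ols - f) ** 2))
        denom = max(1.0 - edf / n_lag, 1.0 / n_lag)
        gcv = (wrss / n_lag) / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, f)
    if best is None:
        return DtvemFeatures(td_grid=td_grid, coef=np.zeros(len(td_grid)),
                             warning="degenerate")
    _, lam, f_at_knots = best
    if np.array_equal(knots, td_grid):
        coef = f_at_knots
    else:
        coef = np.interp(td_grid, knots, f_at_knots)
    if not np.all(np.isfinite(coef)):
        return DtvemFeatures(td_grid=td_grid, coef=np.zeros(len(td_grid)),
                             warning="degenerate")
    return DtvemFeatures(td_grid=td_grid, coef=coef, lambda_=lam)


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralOptions:
    """Welch estimator options.

    segment_len_s sets both the taper length and the frequency resolution;
    the feature grid is the segment's positive FFT frequencies (spacing
    1/segment_len_s Hz up to 0.5 Hz), identical for every participant.
    Default 4096 s yields 2048 spectral features.  ``n_freq`` optionally
    truncates the grid to the first n_freq bins.
    """

    segment_len_s: int = 4096
    overlap: float = 0.5
    n_freq: int | None = None
    max_gap_s: float = 5.0
    sample_rate: float = 1.0


@dataclass
class SpectralFeatures:
    """One-sided Welch PSD on a fixed frequency grid (units^2/Hz)."""

    freq_grid: np.ndarray
    power: np.ndarray


def spectral_features(series_or_runs, opts: SpectralOptions | None = None) -> SpectralFeatures:
    """Welch-averaged power spectral density of a 1 Hz magnitude series.

    Contiguous runs (lists of arrays) are Welch-estimated separately with a
    Hann taper at ``overlap`` and pooled by a segment-count-weighted
    average, so the normalization keeps integral(PSD df) ~ series variance.
    Runs shorter than one segment are skipped; if no run is long enough a
    FeatureError instructs the caller to shorten segment_len_s.
    """
    opts = opts or SpectralOptions()
    if isinstance(series_or_runs, (list, tuple)):
        runs = [np.asarray(r, float) for r in series_or_runs]
    else:
        runs = [np.asarray(series_or_runs, float)]
    nper = int(round(opts.segment_len_s * opts.sample_rate))
    nover = int(round(nper * opts.overlap))
    step = nper - nover
    acc = None
    freqs = None
    total_segments = 0
    for r in runs:
        if len(r) < nper:
            continue
        f, p = signal.welch(r, fs=opts.sample_rate, window="hann",
                            nperseg=nper, noverlap=nover, detrend="constant")
        nseg = 1 + (len(r) - nper) // step
        acc = p * nseg if acc is None else acc + p * nseg
        freqs = f
        total_segments += nseg
    if acc is None:
        raise FeatureError(
            f"no contiguous run reaches one segment of {nper} samples; "
            "shorten segment_len_s")
    psd = acc / total_segments
    # drop the zero-frequency bin; keep (0, Nyquist]
    freqs = freqs[1:]
    psd = psd[1:]
    if opts.n_freq is not None:
        freqs = freqs[: opts.n_freq]
        psd = psd[: opts.n_freq]
    return SpectralFeatures(freq_grid=freqs, power=np.maximum(psd, 0.0))


def period_of_feature(freq_grid: np.ndarray, index: int) -> float:
    """Oscillation period (seconds) of the spectral feature at *index*."""
    f = float(np.asarray(freq_grid)[index])
    if f <= 0:
        raise ValueError("period undefined at zero frequency")
    return 1.0 / f
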