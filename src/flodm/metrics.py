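"""Response-kinetics estimators.

Quantifies a fractional-change trace (percent vs minutes, injection at t=0)
by the estimands the group analyses report:

* peak amplitude and time ``(A, t_p)`` — extremum located on a 3-sample
  median-smoothed trace (noise robustness), with the amplitude read from the
  raw trace within one sample of that location so narrow peaks are not
  clipped by the filter;
* return-to-baseline time ``t_r`` — first re-entry of the smoothed trace
  into the baseline band ``±k·SD_baseline`` sustained for ``min_dwell``
  samples, refined to the zero crossing of a local linear fit so the
  estimate tracks the curve's actual baseline crossing rather than the band
  edge; right-censored when the trace never returns inside the window;
* per-minute rate — ordinary least-squares slope over the rising phase
  ``[0, min(t_p, 30)]`` (the printed "averaged per minute increase");
* FWHM — width between the half-maximum crossings bracketing the peak,
  linearly interpolated between samples;
* undershoot depth — magnitude of the opposite-polarity excursion after
  ``t_r``.

All estimators are polarity-aware (``max`` for Ca²⁺ increases, ``min`` for
CBFv drops, ``auto`` picks the larger excursion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import medfilt

DEFAULT_BASELINE = (-10.0, 0.0)
RATE_WINDOW_MAX = 30.0


@dataclass(frozen=True)
class PeakResult:
    amplitude: float
    t_peak: Optional[float]


@dataclass(frozen=True)
class ReturnResult:
    t_return: Optional[float]
    censored: bool = False


@dataclass(frozen=True)
class FwhmResult:
    fwhm: Optional[float]
    t_up: Optional[float] = None
    t_down: Optional[float] = None
    censored: bool = False


def _smooth(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        return y.copy()
    return medfilt(y, kernel_size=3)


def _resolve_polarity(x: np.ndarray, polarity: str) -> int:
    if polarity == "max":
        return 1
    if polarity == "min":
        return -1
    if polarity == "auto":
        return 1 if abs(np.nanmax(x)) >= abs(np.nanmin(x)) else -1
    raise ValueError(f"polarity must be 'max', 'min' or 'auto', got '{polarity}'")


def peak_metric(
    t: np.ndarray,
    y: np.ndarray,
    search_window: Optional[Tuple[float, float]] = None,
    polarity: str = "auto",
) -> PeakResult:
    """Signed extremum of the median-smoothed trace within a window.

    The extremum is *located* on the smoothed trace and its amplitude read
    from the raw trace within ±1 sample of that location.  An all-flat trace
    yields amplitude 0 with undefined peak time.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sm = _smooth(y)
    if search_window is not None:
        sel = (t >= search_window[0]) & (t <= search_window[1])
        if not np.any(sel):
            raise ValueError(f"empty search window {search_window}")
    else:
        sel = np.ones_like(t, dtype=bool)
    idx = np.flatnonzero(sel)
    if np.ptp(sm[idx]) == 0.0 and np.ptp(y[idx]) == 0.0:
        return PeakResult(amplitude=0.0, t_peak=None)
    sign = _resolve_polarity(sm[idx], polarity)
    i_sm = idx[int(np.argmax(sign * sm[idx]))]
    lo = max(i_sm - 1, idx[0])
    hi = min(i_sm + 1, idx[-1])
    local = np.arange(lo, hi + 1)
    i_raw = local[int(np.argmax(sign * y[local]))]
    return PeakResult(amplitude=float(y[i_raw]), t_peak=float(t[i_raw]))


def return_time(
    t: np.ndarray,
    y: np.ndarray,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE,
    k: float = 2.0,
    min_dwell: int = 2,
    peak: Optional[PeakResult] = None,
    polarity: str = "auto",
    fit_halfwidth_min: float = 5.0,
) -> ReturnResult:
    """Return-to-baseline time of the response peak.

    Detection: first ``t > t_peak`` at which the smoothed trace re-enters
    the baseline band ``±k·SD_baseline`` and stays for ``min_dwell``
    samples.  The reported time is then refined to the zero crossing of a
    least-squares line fitted to the preceding ``fit_halfwidth_min`` minutes
    of decay, which is unbiased for a transversal baseline crossing.  If the
    trace never re-enters, the result is right-censored at the window end.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sm = _smooth(y)
    if peak is None:
        peak = peak_metric(t, y, search_window=(0.0, t[-1]), polarity=polarity)
    if peak.t_peak is None:
        return ReturnResult(t_return=None)
    sign = 1 if peak.amplitude >= 0 else -1
    x = sign * sm
    base = (t >= baseline_window[0]) & (t <= baseline_window[1])
    sd = float(np.std(x[base], ddof=0)) if np.any(base) else 0.0
    band = k * sd
    if sign * peak.amplitude <= band:
        return ReturnResult(t_return=None)  # peak not outside baseline band

    after = np.flatnonzero(t > peak.t_peak)
    hit = None
    for i in after:
        j_hi = min(i + min_dwell, len(t))
        if np.all(x[i:j_hi] <= band):
            hit = i
            break
    if hit is None:
        return ReturnResult(t_return=float(t[-1]), censored=True)

    fit_sel = (t >= t[hit] - fit_halfwidth_min) & (t <= t[hit]) & (t > peak.t_peak)
    if fit_sel.sum() >= 3:
        slope, intercept = np.polyfit(t[fit_sel], x[fit_sel], 1)
        if slope < 0:
            t_zero = -intercept / slope
            if peak.t_peak < t_zero <= t[-1] + (t[1] - t[0]):
                return ReturnResult(t_return=float(min(t_zero, t[-1])))
    # fallback: interpolated band crossing
    if hit > 0 and x[hit - 1] > band >= x[hit] and x[hit - 1] != x[hit]:
        frac = (x[hit - 1] - band) / (x[hit - 1] - x[hit])
        return ReturnResult(t_return=float(t[hit - 1] + frac * (t[hit] - t[hit - 1])))
    return ReturnResult(t_return=float(t[hit]))


def rate_metric(
    t: np.ndarray,
    y: np.ndarray,
    window_max: float = RATE_WINDOW_MAX,
    peak: Optional[PeakResult] = None,
    polarity: str = "auto",
    min_samples: int = 5,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE,
    rise_end: str = "attain",
) -> float:
    """OLS slope (percent/min) over the rising phase [0, min(t_peak, 30)].

    With ``rise_end="attain"`` (default) the rising-phase end is the *first
    attainment* of the peak level: the earliest post-injection time at
    which the smoothed trace comes within the baseline noise band of the
    peak value.  Under noise the plain argmax of a plateau-shaped response
    is uniformly smeared over the plateau, which drags the fitted window
    into the decay and biases the slope low; first attainment is unbiased
    for ramp-plateau shapes and coincides with t_peak on noiseless traces.
    ``rise_end="peak"`` ends the window at the located peak time itself —
    preferable for low-noise (pooled) curves, where the attainment trigger
    would correlate with residual noise.  A flat or pre-injection peak
    falls back to the full [0, window_max] window; if the rising phase
    holds fewer than ``min_samples`` samples the window is extended to the
    first ``min_samples`` post-injection samples.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if rise_end not in ("attain", "peak"):
        raise ValueError("rise_end must be 'attain' or 'peak'")
    if peak is None:
        peak = peak_metric(t, y, search_window=(0.0, t[-1]), polarity=polarity)
    if peak.t_peak is None or peak.t_peak <= 0:
        hi = window_max
    elif rise_end == "peak":
        hi = min(peak.t_peak, window_max)
    else:
        hi = min(peak.t_peak, window_max)
        sm = _smooth(y)
        sign = 1 if peak.amplitude >= 0 else -1
        x = sign * sm
        base = (t >= baseline_window[0]) & (t <= baseline_window[1])
        band = 2.0 * float(np.std(x[base], ddof=0)) if np.any(base) else 0.0
        i_pk = int(np.argmin(np.abs(t - peak.t_peak)))
        rise = np.flatnonzero((t > 0) & (t <= peak.t_peak) & (x >= x[i_pk] - band))
        if rise.size:
            hi = min(float(t[rise[0]]), window_max)
    sel = (t >= 0) & (t <= hi)
    if sel.sum() < min_samples:
        post = np.flatnonzero(t >= 0)
        if post.size < min_samples:
            raise ValueError(f"need >= {min_samples} post-injection samples")
        sel = np.zeros_like(sel)
        sel[post[:min_samples]] = True
    return float(np.polyfit(t[sel], y[sel], 1)[0])


def fwhm(
    t: np.ndarray,
    y: np.ndarray,
    peak: Optional[PeakResult] = None,
    polarity: str = "auto",
) -> FwhmResult:
    """Full width at half maximum of the response peak.

    The half-level crossings bracketing the peak are found on the smoothed
    trace (scanning outward from the peak, immune to distant noise) and
    linearly interpolated between samples.  A half level never down-crossed
    is right-censored at the window end.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sm = _smooth(y)
    if peak is None:
        peak = peak_metric(t, y, search_window=(0.0, t[-1]), polarity=polarity)
    if peak.t_peak is None or peak.amplitude == 0:
        return FwhmResult(fwhm=None)
    sign = 1 if peak.amplitude >= 0 else -1
    x = sign * sm
    half = sign * peak.amplitude / 2.0
    i_pk = int(np.argmin(np.abs(t - peak.t_peak)))

    t_up = None
    for j in range(i_pk, 0, -1):
        if x[j - 1] < half <= x[j]:
            frac = (half - x[j - 1]) / (x[j] - x[j - 1])
            t_up = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    if t_up is None:
        t_up = t[0]

    t_down = None
    for j in range(i_pk, len(t) - 1):
        if x[j] >= half > x[j + 1]:
            frac = (x[j] - half) / (x[j] - x[j + 1])
            t_down = t[j] + frac * (t[j + 1] - t[j])
            break
    if t_down is None:
        return FwhmResult(fwhm=float(t[-1] - t_up), t_up=float(t_up),
                          t_down=float(t[-1]), censored=True)
    return FwhmResult(
        fwhm=float(t_down - t_up), t_up=float(t_up), t_down=float(t_down)
    )


def undershoot_depth(
    t: np.ndarray,
    y: np.ndarray,
    t_return: Optional[float],
    peak: PeakResult,
) -> float:
    """Magnitude of the opposite-polarity excursion after the return time."""
    if t_return is None or peak.t_peak is None:
        return 0.0
    sign = 1 if peak.amplitude >= 0 else -1
    sel = np.asarray(t, dtype=float) > t_return
    if not np.any(sel):
        return 0.0
    x = sign * _smooth(np.asarray(y, dtype=float))
    return float(max(0.0, -np.min(x[sel])))


# ---------------------------------------------------------------------------
# cohort-level metrics tables
# ---------------------------------------------------------------------------

def trace_metrics(
    t: np.ndarray,
    y: np.ndarray,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE,
    polarity: str = "auto",
    k: float = 2.0,
    min_dwell: int = 2,
    rise_end: str = "attain",
) -> dict:
    """All kinetics estimands of one trace as a flat record."""
    pk = peak_metric(t, y, search_window=(0.0, float(np.max(t))), polarity=polarity)
    ret = return_time(t, y, baseline_window=baseline_window, k=k,
                      min_dwell=min_dwell, peak=pk)
    rt = rate_metric(t, y, peak=pk, rise_end=rise_end,
                     baseline_window=baseline_window)
    fw = fwhm(t, y, peak=pk)
    return {
        "peak_amplitude": pk.amplitude,
        "t_peak": pk.t_peak,
        "t_return": ret.t_return,
        "return_censored": ret.censored,
        "rate": rt,
        "fwhm": fw.fwhm,
        "fwhm_censored": fw.censored,
        "undershoot_depth": undershoot_depth(t, y, ret.t_return, pk),
    }


def compute_metrics(
    traces: pd.DataFrame,
    baseline_window: Tuple[float, float] = DEFAULT_BASELINE,
    per: str = "animal",
    **kwargs,
) -> pd.DataFrame:
    """Kinetics metrics per (animal, signal) or per (animal, signal, roi).

    ``per="animal"`` first averages the m ROI traces of each animal into one
    curve (the unit the group analyses operate on); ``per="roi"`` keeps
    individual ROI traces.
    """
    if per == "animal":
        work = (
            traces.groupby(["animal", "signal", "t_min"], sort=True)["value"]
            .mean()
            .reset_index()
        )
        keys = ["animal", "signal"]
    elif per == "roi":
        work = traces
        keys = ["animal", "signal", "roi"]
    else:
        raise ValueError("per must be 'animal' or 'roi'")
    rows = []
    for key_vals, sub in work.groupby(keys, sort=True):
        sub = sub.sort_values("t_min")
        rec = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        rec.update(
            trace_metrics(
                sub.t_min.to_numpy(), sub.value.to_numpy(),
                baseline_window=baseline_window, **kwargs,
            )
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def group_rollup(metrics: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± s.e.m. per signal; n counts animals, never ROIs."""
    fields = [
        "peak_amplitude", "t_peak", "t_return", "rate", "fwhm", "undershoot_depth",
    ]
    rows = []
    for signal, sub in metrics.groupby("signal", sort=True):
        per_animal = sub.groupby("animal")[fields].mean()
        n = len(per_animal)
        rec = {"signal": signal, "n_animals": n}
        for f in fields:
            vals = per_animal[f].dropna()
            rec[f"{f}_mean"] = float(vals.mean()) if len(vals) else np.nan
            rec[f"{f}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)
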