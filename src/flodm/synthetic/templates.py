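"""Parametric response templates.

A :class:`ResponseTemplate` is the noiseless time course of one signal
(ΔF/F of astrocytic or neuronal Ca²⁺, ΔCBFv/CBFv, or Δφ of vessel diameter,
all in percent) under one condition, fully determined by the printed group
kinetics: peak amplitude, onset, peak time, return-to-baseline time and an
optional undershoot.  The template is piecewise smooth:

* ``t <= t_onset`` — zero;
* rise lobe on ``[t_onset, t_peak]`` — raised cosine
  ``A * (1 - cos(pi*u)) / 2`` (smooth takeoff and peak), or a linear ramp
  when ``rate_override`` is given;
* decay lobe on ``[t_peak, t_return]`` — quarter cosine
  ``A * cos(pi/2 * u)``, which leaves the peak smoothly and crosses zero
  *transversally* at ``t_return`` so that the return-to-baseline time is an
  identifiable feature of the curve;
* optional undershoot lobe on ``[t_return, undershoot_end]`` — sine lobe of
  depth ``undershoot_depth`` opposing the main lobe, zero at both ends;
* zero afterwards.

When ``rate_override`` (percent/min) is present the rising phase is a linear
ramp from ``t_onset = 0``; the ordinary-least-squares slope of the noiseless
template over ``[0, min(t_peak, 30)]`` then equals ``rate_override`` exactly,
and the peak amplitude is the implied ``rate_override * t_peak``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ResponseTemplate", "build_template", "TemplateConstraintError"]

#: window cap (minutes) for the per-minute rate estimand
RATE_WINDOW_MAX_MIN = 30.0


class TemplateConstraintError(ValueError):
    """An ordering constraint between template breakpoints is violated."""


@dataclass(frozen=True)
class ResponseTemplate:
    """Noiseless response time course for one signal under one condition.

    Attributes
    ----------
    amplitude:
        Signed peak fractional change, percent. The template equals
        ``amplitude`` at ``t_peak``.
    t_onset, t_peak, t_return:
        Breakpoints in minutes (injection at t=0); the template is zero up to
        ``t_onset`` and crosses zero at ``t_return``.
    undershoot_depth:
        Depth (>= 0, percent) of the post-return lobe opposing the main
        response; 0 means none.
    undershoot_end:
        Minute at which the undershoot has resolved (required iff depth > 0).
    rate_override:
        Percent/min; when present the rise is a linear ramp whose
        least-squares slope over [0, min(t_peak, 30)] equals it exactly.
    """

    amplitude: float
    t_onset: float
    t_peak: float
    t_return: float
    undershoot_depth: float = 0.0
    undershoot_end: Optional[float] = None
    rate_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.t_onset < self.t_peak:
            raise TemplateConstraintError(
                f"t_onset ({self.t_onset}) must be < t_peak ({self.t_peak})"
            )
        if not self.t_peak < self.t_return:
            raise TemplateConstraintError(
                f"t_peak ({self.t_peak}) must be < t_return ({self.t_return})"
            )
        if self.undershoot_depth < 0:
            raise TemplateConstraintError("undershoot_depth must be >= 0")
        if self.undershoot_depth > 0:
            if self.undershoot_end is None:
                raise TemplateConstraintError(
                    "undershoot_depth > 0 requires undershoot_end"
                )
            if not self.t_return < self.undershoot_end:
                raise TemplateConstraintError(
                    f"t_return ({self.t_return}) must be < undershoot_end "
                    f"({self.undershoot_end})"
                )
        if self.rate_override is not None:
            if self.t_onset != 0.0:
                raise TemplateConstraintError(
                    "rate_override requires t_onset == 0 (the rate is defined "
                    "as the per-minute increase from injection)"
                )
            implied = self.rate_override * self.t_peak
            if abs(self.amplitude - implied) > 1e-9:
                raise TemplateConstraintError(
                    f"amplitude ({self.amplitude}) inconsistent with "
                    f"rate_override * t_peak ({implied})"
                )

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t) -> np.ndarray:
        """Evaluate the template at times ``t`` (minutes), vectorized."""
        t = np.asarray(t, dtype=float)
        y = np.zeros_like(t)
        a = self.amplitude
        if a == 0.0 and self.undershoot_depth == 0.0:
            return y

        rise = (t > self.t_onset) & (t <= self.t_peak)
        if np.any(rise):
            u = (t[rise] - self.t_onset) / (self.t_peak - self.t_onset)
            if self.rate_override is not None:
                y[rise] = self.rate_override * t[rise]
            else:
                y[rise] = a * 0.5 * (1.0 - np.cos(np.pi * u))

        decay = (t > self.t_peak) & (t <= self.t_return)
        if np.any(decay):
            u = (t[decay] - self.t_peak) / (self.t_return - self.t_peak)
            y[decay] = a * np.cos(0.5 * np.pi * u)

        if self.undershoot_depth > 0:
            under = (t > self.t_return) & (t < self.undershoot_end)
            if np.any(under):
                w = (t[under] - self.t_return) / (self.undershoot_end - self.t_return)
                sign = 1.0 if a >= 0 else -1.0
                y[under] = -sign * self.undershoot_depth * np.sin(np.pi * w)
        return y

    # -- analytic estimands -------------------------------------------------

    @property
    def is_null(self) -> bool:
        """True for the identically-zero template."""
        return self.amplitude == 0.0 and self.undershoot_depth == 0.0

    @property
    def fwhm_min(self) -> Optional[float]:
        """Full width at half maximum of the main lobe, minutes.

        Half-level crossings: the rise lobe (raised cosine or linear ramp)
        crosses A/2 at the midpoint of [t_onset, t_peak]; the quarter-cosine
        decay crosses A/2 at u = (2/pi) * arccos(1/2) = 2/3.
        """
        if self.is_null:
            return None
        up = self.t_onset + 0.5 * (self.t_peak - self.t_onset)
        down = self.t_peak + (2.0 / 3.0) * (self.t_return - self.t_peak)
        return down - up

    @property
    def rate_pct_per_min(self) -> float:
        """OLS slope of the noiseless template over [0, min(t_peak, 30)]."""
        if self.rate_override is not None:
            return self.rate_override
        if self.is_null:
            return 0.0
        t_hi = min(self.t_peak, RATE_WINDOW_MAX_MIN)
        t = np.linspace(0.0, t_hi, 2001)
        return float(np.polyfit(t, self(t), 1)[0])

    @property
    def span(self) -> tuple[float, float]:
        """[t_onset, end-of-response] interval the window must contain."""
        end = self.undershoot_end if self.undershoot_depth > 0 else self.t_return
        return (self.t_onset, float(end))


def build_template(
    amplitude: Optional[float] = None,
    t_onset: float = 0.5,
    t_peak: float = 10.0,
    t_return: float = 30.0,
    undershoot_depth: float = 0.0,
    undershoot_end: Optional[float] = None,
    rate_override: Optional[float] = None,
) -> ResponseTemplate:
    """Construct and validate a :class:`ResponseTemplate`.

    ``amplitude`` may be omitted when ``rate_override`` is given; it is then
    the implied ``rate_override * t_peak``.

    Raises
    ------
    TemplateConstraintError
        If an ordering constraint is violated (the message names the
        offending pair).
    """
    if rate_override is not None and amplitude is None:
        amplitude = rate_override * t_peak
    if amplitude is None:
        raise TemplateConstraintError("amplitude is required without rate_override")
    return ResponseTemplate(
        amplitude=amplitude,
        t_onset=t_onset,
        t_peak=t_peak,
        t_return=t_return,
        undershoot_depth=undershoot_depth,
        undershoot_end=undershoot_end,
        rate_override=rate_override,
    )


def zero_template(window_end: float = 70.0) -> ResponseTemplate:
    """An identically-zero template (e.g. Ca²⁺_N under clozapine baseline)."""
    return ResponseTemplate(
        amplitude=0.0, t_onset=0.0, t_peak=window_end / 2, t_return=window_end
    )
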