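"""Phase-resolved Doppler velocimetry.

Reconstructs signed axial velocity from wrapped inter-A-scan phase via the
standard phase-resolved relation

    v_z = lambda0 * phi / (4*pi * n_tissue * t_ascan),

and fractional flow change (ΔCBFv/CBFv, percent) ratio volumes against a
baseline window.  No phase unwrapping is performed: phantom velocities are
kept sub-Nyquist by construction and super-Nyquist flow reconstructs
wrapped (aliased) — a documented failure mode the validity mask never hides.
Voxels whose phase magnitude sits below ``k`` times the phase noise floor
are excluded from downstream means rather than zero-filled (zero-filling
would bias ΔCBFv toward −100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from flodm.acquisition import AcquisitionSpec


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class VelocityVolume:
    """Signed axial velocity field (mm/s) with a validity mask."""

    v_mm_s: np.ndarray
    valid: np.ndarray
    timestamp_min: float = 0.0


def phase_to_velocity(
    phase: np.ndarray,
    acq: AcquisitionSpec,
    sigma_phi: Optional[float] = None,
    k: float = 3.0,
    timestamp_min: float = 0.0,
    n_average: int = 1,
) -> VelocityVolume:
    """Convert a wrapped phase volume to axial velocity.

    Parameters
    ----------
    phase:
        Wrapped phase, radians in (-pi, pi].
    sigma_phi:
        Phase noise SD; defaults to ``acq.sigma_phi_rad``.  The validity
        mask keeps voxels with ``|phi| > k * sigma_phi`` (after averaging).
    n_average:
        Kasai-style averaging depth: when the input carries a leading repeat
        axis of length ``n_average`` the repeats are combined by complex
        (autocorrelation) averaging before conversion.
    """
    if acq is None:
        raise ConfigurationError("an AcquisitionSpec is required")
    phi = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase volume contains non-finite values")
    if n_average > 1:
        if phi.shape[0] != n_average:
            raise ValueError(
                f"n_average={n_average} but leading axis is {phi.shape[0]}"
            )
        phi = np.angle(np.mean(np.exp(1j * phi), axis=0))
    sigma = acq.sigma_phi_rad if sigma_phi is None else float(sigma_phi)
    sigma_eff = sigma / np.sqrt(max(n_average, 1))
    v = acq.nyquist_velocity_mm_s * phi / np.pi
    valid = np.abs(phi) > k * sigma_eff
    return VelocityVolume(v_mm_s=v, valid=valid, timestamp_min=timestamp_min)


def velocity_sensitivity(acq: AcquisitionSpec, sigma_phi: float) -> float:
    """Smallest resolvable axial velocity (mm/s): lambda0*sigma/(4*pi*n*T)."""
    if sigma_phi < 0:
        raise ValueError("sigma_phi must be >= 0")
    return acq.nyquist_velocity_mm_s * sigma_phi / np.pi


def ratio_series(
    volumes: Sequence[VelocityVolume],
    baseline_window: Tuple[float, float],
    k: float = 3.0,
    sigma_v: Optional[float] = None,
    acq: Optional[AcquisitionSpec] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative flow change volumes: 100*(v(t) - v_base)/v_base, percent.

    The signed baseline denominator makes the ratio a relative change of
    flow *speed* irrespective of flow direction: a slowdown is negative in
    arteries (v > 0) and veins (v < 0) alike.

    Parameters
    ----------
    volumes:
        Velocity volumes with timestamps (minutes).
    baseline_window:
        (t0, t1) minutes; the per-voxel baseline is the mean over volumes in
        this window (at least one required).
    sigma_v:
        Velocity noise floor; voxels whose |baseline| is below
        ``k * sigma_v`` are marked invalid.  Derived from ``acq`` when not
        given.

    Returns
    -------
    ratios : (T, ...) percent change array (NaN where invalid)
    valid : boolean mask of voxels with a usable baseline
    times : (T,) timestamps in minutes
    """
    times = np.array([v.timestamp_min for v in volumes], dtype=float)
    in_base = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not np.any(in_base):
        raise ValueError(
            f"no volumes inside baseline window {baseline_window}"
        )
    stack = np.stack([v.v_mm_s for v in volumes])
    v_base = stack[in_base].mean(axis=0)
    if sigma_v is None:
        if acq is None:
            raise ConfigurationError("provide sigma_v or an AcquisitionSpec")
        sigma_v = velocity_sensitivity(acq, acq.sigma_phi_rad)
    valid = np.abs(v_base) > k * sigma_v
    base_valid = np.all(np.stack([v.valid for v in volumes])[in_base], axis=0)
    valid &= base_valid
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = 100.0 * (stack - v_base[None]) / v_base[None]
    ratios[:, ~valid] = np.nan
    return ratios, valid, times


def reconstruct_series(
    phases: np.ndarray,
    times_min: np.ndarray,
    acq: AcquisitionSpec,
    sigma_phi: Optional[float] = None,
    k: float = 3.0,
) -> list[VelocityVolume]:
    """Convert a (T, ...) wrapped-phase series to velocity volumes."""
    return [
        phase_to_velocity(
            phases[i], acq, sigma_phi=sigma_phi, k=k,
            timestamp_min=float(times_min[i]),
        )
        for i in range(len(times_min))
    ]
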