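"""Acquisition parameters shared by the fluorescence and Doppler arms.

The Doppler arm follows the standard phase-resolved relation between the
inter-A-scan phase shift ``phi`` of light backscattered by moving red blood
cells and the axial velocity component ``v_z``::

    phi = 4 * pi * n * v_z * T / lambda0

with ``lambda0`` the centre wavelength in vacuum, ``n`` the tissue refractive
index and ``T`` the inter-A-scan time.  The largest unambiguous velocity
(Nyquist velocity) is ``lambda0 / (4 * n * T)``; faster flow wraps.
"""

from __future__ import annotations

import math
from typing import Tuple

from pydantic import BaseModel, field_validator, model_validator

Matrix2 = Tuple[Tuple[float, float], Tuple[float, float]]


class AcquisitionSpec(BaseModel):
    """Optical/temporal acquisition parameters.

    Parameters
    ----------
    lambda0_um:
        Source centre wavelength, micrometres (near-infrared OCT source).
    n_tissue:
        Tissue refractive index.
    t_ascan_s:
        Inter-A-scan time, seconds. Sets the Doppler phase-velocity scale.
    frame_rate_fluor_hz:
        Fluorescence camera frame rate for interleaved two-channel imaging.
    volume_period_min:
        Minutes per Doppler volume of the time-lapse series.
    crosstalk:
        2x2 row-stochastic channel mixing matrix (rows: detected green/red;
        columns: true green/red emission).
    bleach_rate_per_min:
        Fractional fluorescence loss per minute, per channel (green, red).
    sigma_phi_rad:
        Background Doppler phase noise (standard deviation, radians). The
        default reproduces a velocity sensitivity of 20 um/s at the default
        inter-A-scan time.
    """

    lambda0_um: float = 1.3
    n_tissue: float = 1.35
    t_ascan_s: float = 10e-6
    frame_rate_fluor_hz: float = 80.0
    volume_period_min: float = 0.75
    crosstalk: Matrix2 = ((0.9, 0.1), (0.1, 0.9))
    bleach_rate_per_min: Tuple[float, float] = (0.0, 0.0)
    sigma_phi_rad: float = 0.0026

    model_config = {"frozen": True}

    @field_validator("lambda0_um", "n_tissue", "t_ascan_s",
                     "frame_rate_fluor_hz", "volume_period_min")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("acquisition periods and optical constants must be > 0")
        return v

    @model_validator(mode="after")
    def _check_crosstalk(self) -> "AcquisitionSpec":
        for i, row in enumerate(self.crosstalk):
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"crosstalk row {i} is not row-stochastic: {row}")
            if row[i] < 0.8:
                raise ValueError(
                    f"crosstalk diagonal element {i} must be >= 0.8, got {row[i]}"
                )
            if any(c < 0 for c in row):
                raise ValueError("crosstalk entries must be non-negative")
        return self

    @property
    def nyquist_velocity_mm_s(self) -> float:
        """Maximum unambiguous axial velocity, mm/s: lambda0 / (4 n T)."""
        lambda0_mm = self.lambda0_um * 1e-3
        return lambda0_mm / (4.0 * self.n_tissue * self.t_ascan_s)

    @property
    def phase_per_mm_s(self) -> float:
        """Doppler phase shift per unit axial velocity, rad / (mm/s)."""
        return math.pi / self.nyquist_velocity_mm_s
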