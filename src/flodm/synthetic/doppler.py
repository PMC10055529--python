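"""Doppler-phase forward model.

Renders a time series of wrapped phase volumes from a vessel phantom: each
voxel inside a vessel carries the phase of the standard phase-resolved
Doppler relation

    phi = 4*pi * n_tissue * v_z(t) * t_ascan / lambda0,

with ``v_z = v_axial * cos(doppler_angle) * (1 + dCBFv(t)/100)`` and
Gaussian background phase noise; phases are wrapped to (-pi, pi].  Flow
modulation is supplied per segment (or per compartment) as percent ΔCBFv
traces; vessel radii can additionally be modulated by a diameter (Δφ,
percent) trace to emulate vasodilation/constriction.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from flodm.acquisition import AcquisitionSpec
from flodm.synthetic.phantom import VesselPhantom
from flodm.synthetic.presets import CohortPreset


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phases onto (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


def velocity_to_phase(v_mm_s, acq: AcquisitionSpec) -> np.ndarray:
    """Wrapped Doppler phase for an axial velocity (mm/s)."""
    v = np.asarray(v_mm_s, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity contains non-finite values")
    return wrap_phase(v * acq.phase_per_mm_s)


def phantom_flow_traces(
    preset: CohortPreset, phantom: VesselPhantom, times_min: np.ndarray
) -> np.ndarray:
    """Per-segment ΔCBFv traces (percent), shape (n_segments, T).

    Each segment follows its compartment's template scaled by the preset's
    per-vessel gain pattern (cycled within the compartment).
    """
    times_min = np.asarray(times_min, dtype=float)
    out = np.zeros((len(phantom.segments), times_min.size))
    counters: Dict[str, int] = {}
    for i, seg in enumerate(phantom.segments):
        tmpl = preset.compartment_template(seg.compartment)
        gains = (preset.compartment_gains or {}).get(seg.compartment, [1.0])
        k = counters.get(seg.compartment, 0)
        counters[seg.compartment] = k + 1
        out[i] = gains[k % len(gains)] * tmpl(times_min)
    return out


def render_doppler_series(
    phantom: VesselPhantom,
    flow_traces: np.ndarray,
    acq: AcquisitionSpec,
    times_min: np.ndarray,
    seed: int = 0,
    diameter_traces: Optional[np.ndarray] = None,
    noise: bool = True,
    dtype=np.float32,
) -> tuple[np.ndarray, dict]:
    """Render wrapped phase volumes, shape (T, Z, Y, X), float32.

    Parameters
    ----------
    flow_traces:
        (n_segments, T) percent ΔCBFv per segment, or (T,) applied to all.
    diameter_traces:
        Optional (n_segments, T) percent Δφ radius modulation.
    noise:
        Add Gaussian phase noise of SD ``phantom.background_phase_sd``.

    Returns
    -------
    phases, sidecar
        The volume series and a JSON-serializable sidecar (axis order,
        timestamps, voxel size, acquisition parameters).
    """
    times_min = np.asarray(times_min, dtype=float)
    T = times_min.size
    n_seg = len(phantom.segments)
    flow = np.asarray(flow_traces, dtype=float)
    if flow.ndim == 1:
        flow = np.broadcast_to(flow, (n_seg, T))
    if flow.shape != (n_seg, T):
        raise ValueError(f"flow_traces shape {flow.shape} != ({n_seg}, {T})")
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow traces contain non-finite values")

    rng = np.random.default_rng(seed)
    dfields = phantom.distance_fields
    phases = np.empty((T,) + tuple(phantom.shape), dtype=dtype)
    for ti in range(T):
        if noise and phantom.background_phase_sd > 0:
            vol = rng.normal(
                0.0, phantom.background_phase_sd, size=phantom.shape
            ).astype(dtype)
        else:
            vol = np.zeros(phantom.shape, dtype=dtype)
        for si, seg in enumerate(phantom.segments):
            r_vox = seg.radius_um / phantom.voxel_um
            if diameter_traces is not None:
                r_vox *= 1.0 + diameter_traces[si, ti] / 100.0
            mask = dfields[si] <= r_vox
            v_z = seg.v_z_mm_s * (1.0 + flow[si, ti] / 100.0)
            vol[mask] += dtype(v_z * acq.phase_per_mm_s)
        phases[ti] = wrap_phase(vol)
    sidecar = {
        "axis_order": "t,z,y,x",
        "timestamps_min": times_min.tolist(),
        "voxel_um": phantom.voxel_um,
        "acquisition": acq.model_dump(),
        "n_segments": n_seg,
        "background_phase_sd": phantom.background_phase_sd,
        "seed": seed,
    }
    return phases, sidecar
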