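"""Interleaved two-channel epifluorescence movie rendering.

Emulates time-sharing spectral-multiplex imaging of astrocytic GCaMP6f
(green) and neuronal jRGECO1a (red) fluorescence: per time point one green
and one red frame are exposed back to back at the camera frame rate, so
consecutive same-channel frames are 2/frame_rate apart.  Pixel intensity is

    baseline_map * (1 + dFF_of_owning_ROI/100) * bleaching_decay,

mixed across channels by the row-stochastic crosstalk matrix, with optional
Poisson photon noise.  A JSON-serializable manifest records each frame's
channel and timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from flodm.acquisition import AcquisitionSpec

CHANNELS = ("green", "red")
#: signal carried by each fluorescence channel
CHANNEL_SIGNAL = {"green": "Ca_A", "red": "Ca_N"}


@dataclass(frozen=True)
class ExpressionField:
    """Per-channel ROI label maps and baseline intensity maps."""

    shape: Tuple[int, int]
    labels: Dict[str, np.ndarray]  # channel -> int label map (0 = background)
    baseline: Dict[str, np.ndarray]  # channel -> photon-count baseline map
    pixel_size_um: float = 25.0

    def roi_mask(self, channel: str, roi: int) -> np.ndarray:
        return self.labels[channel] == roi

    def n_rois(self, channel: str) -> int:
        return int(self.labels[channel].max())


def make_expression_field(
    shape: Tuple[int, int] = (120, 160),
    n_rois: int = 5,
    roi_radius_px: int = 8,
    background_counts: float = 100.0,
    roi_counts: float = 900.0,
    pixel_size_um: float = 25.0,
    seed: int = 0,
) -> ExpressionField:
    """Seeded random disjoint circular expression territories per channel."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    # clamp the radius so n_rois disjoint disks are guaranteed to fit
    max_r = max(2, int(0.5 * min(ny, nx) / np.ceil(np.sqrt(n_rois)) / 1.1) - 1)
    roi_radius_px = min(roi_radius_px, max_r)
    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = {}
    baseline = {}
    for channel in CHANNELS:
        lab = np.zeros(shape, dtype=np.int16)
        centers = []
        attempts = 0
        sep = 2.5  # separation factor, relaxed if placement stalls
        while len(centers) < n_rois:
            attempts += 1
            if attempts % 2000 == 0:
                sep = max(2.05, sep - 0.2)
            if attempts > 20_000:
                raise RuntimeError("could not place ROIs; reduce radius or count")
            cy = rng.integers(roi_radius_px + 1, ny - roi_radius_px - 1)
            cx = rng.integers(roi_radius_px + 1, nx - roi_radius_px - 1)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (sep * roi_radius_px) ** 2
                   for y, x in centers):
                centers.append((cy, cx))
                lab[(yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius_px**2] = len(centers)
        labels[channel] = lab
        baseline[channel] = background_counts + roi_counts * (lab > 0)
    return ExpressionField(
        shape=shape, labels=labels, baseline=baseline, pixel_size_um=pixel_size_um
    )


def interleaved_schedule(n_pairs: int, acq: AcquisitionSpec,
                         t_start_s: float = 0.0) -> list[dict]:
    """Frame schedule for ``n_pairs`` green/red pairs at the camera rate."""
    dt = 1.0 / acq.frame_rate_fluor_hz
    frames = []
    for k in range(n_pairs):
        for ci, channel in enumerate(CHANNELS):
            frames.append(
                {
                    "index": 2 * k + ci,
                    "channel": channel,
                    "t_sec": t_start_s + (2 * k + ci) * dt,
                }
            )
    return frames


def render_two_channel_movie(
    dff: Dict[str, np.ndarray],
    field: ExpressionField,
    acq: AcquisitionSpec,
    times_min: np.ndarray,
    seed: int = 0,
    noise: bool = True,
) -> tuple[np.ndarray, dict]:
    """Render an interleaved two-channel movie on the minute-scale grid.

    Parameters
    ----------
    dff:
        ``{"green": (m, T), "red": (m, T)}`` percent ΔF/F per ROI; row ``i``
        drives ROI label ``i+1`` of that channel.
    times_min:
        T time points (minutes); each yields one green and one red frame
        1/frame_rate apart.

    Returns
    -------
    frames, manifest
        ``frames`` is (2T, ny, nx) float32 (photon counts; Poisson-sampled
        when ``noise``); the manifest records per-frame channel/timestamp,
        the crosstalk matrix and pixel size.
    """
    times_min = np.asarray(times_min, dtype=float)
    T = times_min.size
    for channel in CHANNELS:
        arr = np.asarray(dff[channel])
        if arr.shape != (field.n_rois(channel), T):
            raise ValueError(
                f"dff[{channel}] shape {arr.shape} != "
                f"({field.n_rois(channel)}, {T}) (mask/field mismatch)"
            )
        if field.labels[channel].shape != field.shape:
            raise ValueError("label map shape differs from field shape")

    rng = np.random.default_rng(seed)
    M = np.asarray(acq.crosstalk, dtype=float)
    dt_frame = 1.0 / acq.frame_rate_fluor_hz
    t0 = times_min[0]
    frames = np.empty((2 * T,) + field.shape, dtype=np.float32)
    manifest_frames = []
    for ti in range(T):
        unmixed = {}
        for ci, channel in enumerate(CHANNELS):
            gain = np.ones(field.shape, dtype=np.float64)
            lab = field.labels[channel]
            for roi in range(1, field.n_rois(channel) + 1):
                gain[lab == roi] = 1.0 + dff[channel][roi - 1, ti] / 100.0
            decay = np.exp(
                -acq.bleach_rate_per_min[ci] * (times_min[ti] - t0)
            )
            unmixed[channel] = field.baseline[channel] * gain * decay
        mixed_g = M[0, 0] * unmixed["green"] + M[0, 1] * unmixed["red"]
        mixed_r = M[1, 0] * unmixed["green"] + M[1, 1] * unmixed["red"]
        for ci, (channel, img) in enumerate(
            zip(CHANNELS, (mixed_g, mixed_r))
        ):
            if noise:
                img = rng.poisson(np.maximum(img, 0.0)).astype(np.float32)
            frames[2 * ti + ci] = img
            manifest_frames.append(
                {
                    "index": 2 * ti + ci,
                    "channel": channel,
                    "t_min": float(times_min[ti]),
                    "t_sec": float(times_min[ti] * 60.0 + ci * dt_frame),
                }
            )
    manifest = {
        "frames": manifest_frames,
        "frame_rate_hz": acq.frame_rate_fluor_hz,
        "pixel_size_um": field.pixel_size_um,
        "crosstalk": [list(row) for row in acq.crosstalk],
        "bleach_rate_per_min": list(acq.bleach_rate_per_min),
        "seed": seed,
    }
    return frames, manifest


def movie_dff_from_cohort(
    traces: pd.DataFrame, animal: int, n_rois: int
) -> tuple[Dict[str, np.ndarray], np.ndarray]:
    """Arrange one animal's Ca traces as per-channel (m, T) ΔF/F arrays."""
    out = {}
    times = None
    for channel, signal in CHANNEL_SIGNAL.items():
        sub = traces[(traces.animal == animal) & (traces.signal == signal)]
        piv = sub.pivot_table(index="roi", columns="t_min", values="value", sort=True)
        out[channel] = piv.to_numpy()[:n_rois]
        times = piv.columns.to_numpy(dtype=float)
    return out, times
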