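"""Two-channel fluorescence processing: demultiplexing, ΔF/F, ratio images.

ΔF/F is computed against the per-ROI (or per-pixel) mean over a baseline
window, ``100*(F - F0)/F0``, optionally after dividing out a mono-exponential
bleaching trend fitted on the baseline.  ROI traces are spatial means per
frame; crosstalk unmixing (linear inversion of the declared 2x2 matrix) is
available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CHANNELS = ("green", "red")


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class CircularRoi:
    name: str
    channel: str
    cy: float
    cx: float
    radius_px: float

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.radius_px**2


@dataclass(frozen=True)
class RoiSet:
    """Named regions of interest; circular regions or a label map.

    ``provenance`` records whether ROIs were drawn manually or taken from
    phantom ground truth.
    """

    rois: Tuple[CircularRoi, ...] = ()
    label_map: Optional[np.ndarray] = None
    label_channel: str = "green"
    provenance: str = "manual"

    @classmethod
    def from_labels(cls, label_map: np.ndarray, channel: str,
                    provenance: str = "phantom-truth") -> "RoiSet":
        return cls(label_map=np.asarray(label_map), label_channel=channel,
                   provenance=provenance)

    def masks(self, shape: Tuple[int, int]) -> List[Tuple[str, str, np.ndarray]]:
        """(name, channel, mask) triples; validates ROIs lie in the field."""
        out = []
        for roi in self.rois:
            if not (0 <= roi.cy < shape[0] and 0 <= roi.cx < shape[1]):
                raise ValueError(f"ROI '{roi.name}' lies outside the field")
            out.append((roi.name, roi.channel, roi.mask(shape)))
        if self.label_map is not None:
            if self.label_map.shape != shape:
                raise ValueError("label map shape differs from movie frames")
            for lab in range(1, int(self.label_map.max()) + 1):
                out.append(
                    (f"roi{lab}", self.label_channel, self.label_map == lab)
                )
        return out


def demultiplex(frames: np.ndarray, manifest: dict) -> Dict[str, dict]:
    """Split an interleaved movie into per-channel movies.

    Returns ``{channel: {"frames": array, "t_min": array, "t_sec": array}}``
    preserving timestamps; frame counts sum to the input count.
    """
    schedule = manifest.get("frames")
    if schedule is None or len(schedule) != len(frames):
        missing = [] if schedule is None else [
            i for i in range(len(frames))
            if i not in {f["index"] for f in schedule}
        ]
        raise ManifestError(
            f"channel schedule does not cover every frame; missing {missing or 'all'}"
        )
    out = {}
    for channel in CHANNELS:
        idx = [f["index"] for f in schedule if f["channel"] == channel]
        entries = [f for f in schedule if f["channel"] == channel]
        out[channel] = {
            "frames": frames[idx],
            "t_min": np.array([f.get("t_min", f["t_sec"] / 60.0) for f in entries]),
            "t_sec": np.array([f["t_sec"] for f in entries]),
        }
        if len(idx) == 0:
            warnings.warn(f"no frames scheduled for channel '{channel}'")
    return out


def unmix(green: np.ndarray, red: np.ndarray, crosstalk) -> tuple[np.ndarray, np.ndarray]:
    """Linear crosstalk inversion of the declared 2x2 mixing matrix."""
    Minv = np.linalg.inv(np.asarray(crosstalk, dtype=float))
    g = Minv[0, 0] * green + Minv[0, 1] * red
    r = Minv[1, 0] * green + Minv[1, 1] * red
    return g, r


def fit_baseline_bleach(
    frames: np.ndarray, t_min: np.ndarray, baseline: np.ndarray
) -> float:
    """Mono-exponential bleach rate (per minute) fitted on baseline frames.

    Fits ``log(mean frame intensity) ~ -rate * t`` over the baseline window;
    returns the decay rate (0 for a constant movie).
    """
    y = frames[baseline].mean(axis=(1, 2))
    if np.any(y <= 0) or y.size < 3:
        return 0.0
    slope = np.polyfit(t_min[baseline], np.log(y), 1)[0]
    return float(-slope)


def compute_dff(
    frames: np.ndarray,
    t_min: np.ndarray,
    baseline_window: Tuple[float, float] = (-10.0, 0.0),
    bleach_correct: bool = False,
) -> np.ndarray:
    """Per-pixel ΔF/F movie, percent.

    ``F0`` is the per-pixel mean over the baseline window (>= 3 frames
    required); pixels with ``F0 <= 0`` are masked NaN with a warning.  When
    ``bleach_correct``, a mono-exponential fitted on the baseline is divided
    out first.
    """
    t_min = np.asarray(t_min, dtype=float)
    base = (t_min >= baseline_window[0]) & (t_min <= baseline_window[1])
    if base.sum() < 3:
        raise ValueError(
            f"need >= 3 baseline frames in {baseline_window}, got {int(base.sum())}"
        )
    work = np.asarray(frames, dtype=float)
    if bleach_correct:
        rate = fit_baseline_bleach(work, t_min, base)
        work = work / np.exp(-rate * (t_min - t_min[base][0]))[:, None, None]
    f0 = work[base].mean(axis=0)
    bad = f0 <= 0
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} pixels have non-positive baseline; masked")
        f0 = np.where(bad, np.nan, f0)
    return 100.0 * (work - f0[None]) / f0[None]


def compute_dff_trace(
    trace: np.ndarray,
    t_min: np.ndarray,
    baseline_window: Tuple[float, float] = (-10.0, 0.0),
) -> np.ndarray:
    """ΔF/F of a raw-intensity ROI trace (baseline = window mean)."""
    t_min = np.asarray(t_min, dtype=float)
    base = (t_min >= baseline_window[0]) & (t_min <= baseline_window[1])
    if base.sum() < 3:
        raise ValueError("need >= 3 baseline samples")
    f0 = float(np.mean(trace[base]))
    if f0 <= 0:
        raise ValueError("non-positive baseline mean")
    return 100.0 * (np.asarray(trace, dtype=float) - f0) / f0


def ratio_image(
    frames: np.ndarray,
    t_min: np.ndarray,
    t_post: float,
    baseline_window: Tuple[float, float] = (-10.0, 0.0),
    post_halfwidth_min: float = 1.0,
) -> np.ndarray:
    """Post/baseline percent-change map: 100*(F(t_post) - F0)/F0.

    The post image is the mean of frames within ``post_halfwidth_min`` of
    ``t_post``.  Negative values indicate suppression (signed colour scale
    convention).
    """
    t_min = np.asarray(t_min, dtype=float)
    if not (t_min.min() <= t_post <= t_min.max()):
        raise ValueError(
            f"t_post={t_post} outside movie span [{t_min.min()}, {t_min.max()}]"
        )
    base = (t_min >= baseline_window[0]) & (t_min <= baseline_window[1])
    if base.sum() < 3:
        raise ValueError("need >= 3 baseline frames")
    near = np.abs(t_min - t_post) <= post_halfwidth_min
    if not np.any(near):
        near = np.abs(t_min - t_post) == np.abs(t_min - t_post).min()
    f0 = frames[base].mean(axis=0).astype(float)
    post = frames[near].mean(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (post - f0) / f0
    out[f0 <= 0] = np.nan
    return out


def extract_roi_traces(
    dff_movie: np.ndarray,
    t_min: np.ndarray,
    rois: RoiSet,
    signal_by_channel: Optional[Dict[str, str]] = None,
    grid: Optional[np.ndarray] = None,
    animal: int = 1,
) -> pd.DataFrame:
    """Per-ROI spatial mean per frame, optionally resampled to a minute grid.

    Returns a tidy frame (animal, signal, roi, t_min, value).
    """
    signal_by_channel = signal_by_channel or {"green": "Ca_A", "red": "Ca_N"}
    shape = dff_movie.shape[1:]
    rows = []
    for i, (name, channel, mask) in enumerate(rois.masks(shape), start=1):
        if not mask.any():
            raise ValueError(f"ROI '{name}' is empty")
        tr = np.nanmean(dff_movie[:, mask], axis=1)
        tt = np.asarray(t_min, dtype=float)
        if grid is not None:
            tr = np.interp(grid, tt, tr)
            tt = np.asarray(grid, dtype=float)
        rows.append(
            pd.DataFrame(
                {
                    "animal": animal,
                    "signal": signal_by_channel.get(channel, channel),
                    "roi": i,
                    "t_min": tt,
                    "value": tr,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def save_ratio_map(path, ratio: np.ndarray, vlim: Optional[float] = None) -> None:
    """Export a ratio map as single-page TIFF plus a PNG preview with a
    signed (blue = suppression) colour scale."""
    import tifffile

    tifffile.imwrite(path, ratio.astype(np.float32))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        v = vlim or float(np.nanmax(np.abs(ratio))) or 1.0
        fig, ax = plt.subplots(figsize=(4, 3))
        im = ax.imshow(ratio, cmap="RdBu_r", vmin=-v, vmax=v)
        fig.colorbar(im, ax=ax, label="% change")
        ax.set_axis_off()
        fig.savefig(str(path) + ".png", dpi=120, bbox_inches="tight")
        plt.close(fig)
    except Exception:  # preview is best-effort
        pass
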