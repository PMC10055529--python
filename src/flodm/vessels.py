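"""Vessel segmentation, diameter tracking and compartment flow extraction.

Vessels are segmented from a velocity (or intensity) volume, thinned to a
medial-axis skeleton, and split into segments at skeleton branch points.
Diameters come from the Euclidean distance transform sampled along the
centerline (diameter = 2 x mean distance x voxel size); compartments follow
the diameter/velocity rule: capillary if diameter < 10 µm, otherwise artery
for flow toward the probe (positive axial velocity by convention) and vein
for flow away.  The artery/vein disambiguation by velocity sign is a phantom
convention — in vivo the distinction is anatomical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

CAPILLARY_MAX_DIAMETER_UM = 10.0
MIN_COMPONENT_VOXELS = 5


class SegmentationError(ValueError):
    pass


@dataclass
class Segmentation:
    """Binary mask, skeleton, per-voxel segment assignment and records."""

    mask: np.ndarray
    skeleton: np.ndarray
    segment_labels: np.ndarray  # skeleton voxels labelled by segment id
    assignment: np.ndarray  # every mask voxel -> nearest segment id
    records: pd.DataFrame  # id, centerline stats, diameter, velocity
    voxel_um: float


def segment_vessels(
    volume: np.ndarray,
    voxel_um: float,
    velocity_floor: Optional[float] = None,
    policy: str = "velocity",
    min_skeleton_voxels: int = 5,
) -> Segmentation:
    """Segment vessels and split the skeleton into branch-free segments.

    Parameters
    ----------
    volume:
        Signed velocity volume (``policy="velocity"``: mask is |v| above
        ``velocity_floor``) or intensity volume (``policy="otsu"``).
    velocity_floor:
        Validity floor in the volume's units (required for velocity policy).
    """
    vol = np.asarray(volume)
    if not np.all(np.isfinite(vol)):
        vol = np.nan_to_num(vol, nan=0.0)
    if policy == "velocity":
        if velocity_floor is None:
            raise ValueError("velocity policy requires velocity_floor")
        mask = np.abs(vol) > velocity_floor
    elif policy == "otsu":
        thr = threshold_otsu(vol)
        mask = vol > thr
    else:
        raise ValueError(f"unknown threshold policy '{policy}'")

    comp_labels, n_comp = ndi.label(mask, structure=np.ones((3, 3, 3)))
    sizes = np.bincount(comp_labels.ravel())
    small = np.flatnonzero(sizes < MIN_COMPONENT_VOXELS)
    mask &= ~np.isin(comp_labels, small[small > 0])
    if not mask.any():
        raise SegmentationError("no vessels detected")

    skel = skeletonize(mask)
    # split at branch points: remove skeleton voxels with >2 skeleton
    # neighbours (26-connectivity), then label the remaining branches
    neigh = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3, 3)), mode="constant")
    branch_pts = skel & (neigh > 3)  # self + >2 neighbours
    pruned = skel & ~branch_pts
    labels, n_seg = ndi.label(pruned, structure=np.ones((3, 3, 3)))
    # drop stubs
    for lab in range(1, n_seg + 1):
        if (labels == lab).sum() < min_skeleton_voxels:
            labels[labels == lab] = 0
    kept = np.unique(labels)
    kept = kept[kept > 0]
    relabel = {old: new for new, old in enumerate(kept, start=1)}
    seg_labels = np.zeros_like(labels)
    for old, new in relabel.items():
        seg_labels[labels == old] = new
    if seg_labels.max() == 0:
        raise SegmentationError("no vessels detected (all skeleton stubs)")

    edt = ndi.distance_transform_edt(mask)
    # nearest-centerline assignment for every voxel
    _, idx = ndi.distance_transform_edt(seg_labels == 0, return_indices=True)
    nearest = seg_labels[tuple(idx)]
    assignment = np.where(mask, nearest, 0)

    rows = []
    for lab in range(1, int(seg_labels.max()) + 1):
        core = seg_labels == lab
        coords = np.argwhere(core)
        diam_um = 2.0 * float(edt[core].mean()) * voxel_um
        vel = float(vol[core].mean()) if policy == "velocity" else np.nan
        rows.append(
            {
                "segment": lab,
                "n_centerline": int(core.sum()),
                "mean_diameter_um": diam_um,
                "baseline_velocity": vel,
                "centroid_z": float(coords[:, 0].mean()),
                "centroid_y": float(coords[:, 1].mean()),
                "centroid_x": float(coords[:, 2].mean()),
            }
        )
    records = pd.DataFrame(rows)
    return Segmentation(
        mask=mask,
        skeleton=skel,
        segment_labels=seg_labels,
        assignment=assignment,
        records=records,
        voxel_um=voxel_um,
    )


def measure_diameter(
    mask: np.ndarray, centerline: np.ndarray, voxel_um: float
) -> float:
    """Diameter (µm) of one segment: 2 x mean EDT along the centerline.

    ``centerline`` is an (N, 3) integer voxel coordinate array (>= 5 points);
    raises if any centerline voxel falls outside the mask.
    """
    cl = np.asarray(centerline, dtype=int)
    if cl.shape[0] < 5:
        raise ValueError("centerline needs >= 5 points")
    inside = mask[cl[:, 0], cl[:, 1], cl[:, 2]]
    if not inside.all():
        raise ValueError("centerline leaves the vessel mask (integrity error)")
    edt = ndi.distance_transform_edt(mask)
    return 2.0 * float(edt[cl[:, 0], cl[:, 1], cl[:, 2]].mean()) * voxel_um


def diameter_series(
    volumes: np.ndarray,
    times_min: np.ndarray,
    seg: Segmentation,
    velocity_floor: float,
    baseline_window: Tuple[float, float] = (-10.0, 0.0),
) -> pd.DataFrame:
    """Per-segment diameter vs time and percent change Δφ(t).

    Each volume is re-thresholded at the validity floor and the distance
    transform re-sampled along the *baseline* centerline (segments are
    assumed stationary; dilation/constriction changes the radius only).
    """
    times_min = np.asarray(times_min, dtype=float)
    rows = []
    for ti, t in enumerate(times_min):
        mask_t = np.abs(np.nan_to_num(volumes[ti])) > velocity_floor
        edt = ndi.distance_transform_edt(mask_t)
        for lab in seg.records.segment:
            core = seg.segment_labels == int(lab)
            d = 2.0 * float(edt[core].mean()) * seg.voxel_um
            rows.append({"segment": int(lab), "t_min": float(t), "diameter_um": d})
    out = pd.DataFrame(rows)
    base = (out.t_min >= baseline_window[0]) & (out.t_min <= baseline_window[1])
    d0 = out[base].groupby("segment").diameter_um.mean()
    out["dphi_pct"] = out.apply(
        lambda r: 100.0 * (r.diameter_um - d0[r.segment]) / d0[r.segment], axis=1
    )
    return out


def classify_compartment(
    records: pd.DataFrame,
    capillary_max_um: float = CAPILLARY_MAX_DIAMETER_UM,
) -> pd.DataFrame:
    """Deterministic compartment labels from diameter and velocity sign."""
    out = records.copy()
    comp = []
    for _, row in out.iterrows():
        if row.mean_diameter_um < capillary_max_um:
            comp.append("capillary")
        elif np.isfinite(row.baseline_velocity) and row.baseline_velocity > 0:
            comp.append("artery")
        elif np.isfinite(row.baseline_velocity):
            comp.append("vein")
        else:
            comp.append("unknown")
    out["compartment"] = comp
    if (out.compartment == "unknown").any():
        warnings.warn(
            f"{int((out.compartment == 'unknown').sum())} unclassifiable segments"
        )
    return out


def compartment_flow_traces(
    ratios: np.ndarray,
    times_min: np.ndarray,
    seg: Segmentation,
    records: Optional[pd.DataFrame] = None,
    core_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-segment and per-compartment ΔCBFv/CBFv traces.

    A segment's trace is the mean ratio over its *core* voxels (within
    ``core_fraction`` of its radius of the centerline, avoiding
    partial-volume edges); a compartment's trace is the mean of its member
    segment traces, and a pooled vascular trace averages all segments.

    Returns
    -------
    per_segment : tidy frame (segment, compartment, t_min, value)
    per_compartment : tidy frame (compartment, t_min, value) including a
        ``pooled`` pseudo-compartment
    """
    records = records if records is not None else seg.records
    if "compartment" not in records:
        records = classify_compartment(records)
    times_min = np.asarray(times_min, dtype=float)

    dist_to_cl, idx = ndi.distance_transform_edt(
        seg.segment_labels == 0, return_indices=True
    )
    nearest = seg.segment_labels[tuple(idx)]

    seg_rows = []
    for _, rec in records.iterrows():
        lab = int(rec.segment)
        r_vox = rec.mean_diameter_um / 2.0 / seg.voxel_um
        core = (nearest == lab) & (dist_to_cl <= core_fraction * r_vox) & seg.mask
        if not core.any():
            core = seg.segment_labels == lab
        vals = np.nanmean(ratios[:, core], axis=1)
        seg_rows.append(
            pd.DataFrame(
                {
                    "segment": lab,
                    "compartment": rec.compartment,
                    "t_min": times_min,
                    "value": vals,
                }
            )
        )
    per_segment = pd.concat(seg_rows, ignore_index=True)

    comp_rows = []
    for comp in ("artery", "vein", "capillary"):
        sub = per_segment[per_segment.compartment == comp]
        if sub.empty:
            warnings.warn(f"no segments in compartment '{comp}'; omitted")
            continue
        mean = sub.groupby("t_min").value.mean().reset_index()
        mean["compartment"] = comp
        comp_rows.append(mean)
    pooled = per_segment.groupby("t_min").value.mean().reset_index()
    pooled["compartment"] = "pooled"
    comp_rows.append(pooled)
    per_compartment = pd.concat(comp_rows, ignore_index=True)[
        ["compartment", "t_min", "value"]
    ]
    return per_segment, per_compartment
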