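"""Vessel phantoms for the Doppler forward model.

A phantom is a labelled set of cylindrical vessel segments (polyline
centerline, radius, compartment, axial velocity, Doppler angle) embedded in a
voxel grid.  Compartments follow the diameter rule used downstream: capillary
diameter < 10 µm <= artery/vein diameter.  Segments must not overlap except
at declared branch points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import List, Optional, Sequence, Tuple

import numpy as np

CAPILLARY_MAX_DIAMETER_UM = 10.0


@dataclass(frozen=True)
class VesselSegment:
    """One cylindrical vessel segment.

    ``centerline`` is an (N, 3) polyline in voxel coordinates, axis order
    (z, y, x) matching the volume layout.  ``v_axial_mm_s`` is the signed
    speed along the vessel axis; the beam (z) projection is
    ``v_axial * cos(doppler_angle)``.
    """

    centerline: np.ndarray
    radius_um: float
    compartment: str
    v_axial_mm_s: float
    doppler_angle_deg: float = 80.0

    def __post_init__(self):
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise ValueError("centerline must be an (N>=2, 3) polyline")
        object.__setattr__(self, "centerline", cl)
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.compartment not in ("artery", "vein", "capillary"):
            raise ValueError(f"unknown compartment '{self.compartment}'")
        d = 2 * self.radius_um
        if self.compartment == "capillary" and d >= CAPILLARY_MAX_DIAMETER_UM:
            raise ValueError(f"capillary diameter {d} um must be < 10 um")
        if self.compartment != "capillary" and d < CAPILLARY_MAX_DIAMETER_UM:
            raise ValueError(f"{self.compartment} diameter {d} um must be >= 10 um")

    @property
    def v_z_mm_s(self) -> float:
        """Axial (beam) velocity component, mm/s."""
        return self.v_axial_mm_s * np.cos(np.deg2rad(self.doppler_angle_deg))


@dataclass
class VesselPhantom:
    """3D labelled vessel tree on a voxel grid.

    ``shape`` is (z, y, x) in voxels; ``voxel_um`` the isotropic voxel size.
    """

    shape: Tuple[int, int, int]
    voxel_um: float
    segments: List[VesselSegment]
    background_phase_sd: float = 0.0026
    branch_points: Sequence[Tuple[float, float, float]] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be a 3-tuple of >= 4 voxels")
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be > 0")
        self._check_overlaps()

    # -- geometry -----------------------------------------------------------

    def _check_overlaps(self) -> None:
        """Segments may only touch near declared branch points."""
        for i in range(len(self.segments)):
            for j in range(i + 1, len(self.segments)):
                si, sj = self.segments[i], self.segments[j]
                d = _polyline_min_distance(si.centerline, sj.centerline)
                gap = d - (si.radius_um + sj.radius_um) / self.voxel_um
                if gap < 0 and not self.branch_points:
                    raise ValueError(
                        f"segments {i} and {j} overlap without a declared branch point"
                    )

    def distance_field(self, segment: VesselSegment) -> np.ndarray:
        """Distance (voxels) of every voxel centre to the segment centerline."""
        zz, yy, xx = np.meshgrid(
            *(np.arange(s, dtype=np.float32) for s in self.shape), indexing="ij"
        )
        pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
        d = np.full(pts.shape[0], np.inf, dtype=np.float32)
        cl = segment.centerline
        for k in range(cl.shape[0] - 1):
            d = np.minimum(d, _point_segment_distance(pts, cl[k], cl[k + 1]))
        return d.reshape(self.shape)

    @cached_property
    def distance_fields(self) -> List[np.ndarray]:
        return [self.distance_field(seg) for seg in self.segments]

    def segment_mask(self, index: int, radius_scale: float = 1.0) -> np.ndarray:
        seg = self.segments[index]
        r_vox = seg.radius_um * radius_scale / self.voxel_um
        return self.distance_fields[index] <= r_vox

    def label_volume(self) -> np.ndarray:
        """Volume of segment ids (1-based; 0 = background)."""
        labels = np.zeros(self.shape, dtype=np.int16)
        for i in range(len(self.segments)):
            labels[self.segment_mask(i)] = i + 1
        return labels

    def truth_records(self) -> "np.ndarray":
        import pandas as pd

        return pd.DataFrame(
            {
                "segment": np.arange(1, len(self.segments) + 1),
                "compartment": [s.compartment for s in self.segments],
                "radius_um": [s.radius_um for s in self.segments],
                "diameter_um": [2 * s.radius_um for s in self.segments],
                "v_axial_mm_s": [s.v_axial_mm_s for s in self.segments],
                "v_z_mm_s": [s.v_z_mm_s for s in self.segments],
            }
        )


def _point_segment_distance(pts: np.ndarray, a, b) -> np.ndarray:
    a = np.asarray(a, dtype=np.float32)
    b = np.asarray(b, dtype=np.float32)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    tt = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    proj = a + tt[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def _polyline_min_distance(cl_a: np.ndarray, cl_b: np.ndarray) -> float:
    """Minimum distance between two polylines (sampled; adequate for
    phantom-construction sanity checks)."""
    dense_a = _densify(cl_a)
    dense_b = _densify(cl_b)
    d = np.inf
    for k in range(cl_b.shape[0] - 1):
        d = min(d, float(_point_segment_distance(dense_a, cl_b[k], cl_b[k + 1]).min()))
    for k in range(cl_a.shape[0] - 1):
        d = min(d, float(_point_segment_distance(dense_b, cl_a[k], cl_a[k + 1]).min()))
    return d


def _densify(cl: np.ndarray, step: float = 1.0) -> np.ndarray:
    out = []
    for k in range(cl.shape[0] - 1):
        n = max(2, int(np.ceil(np.linalg.norm(cl[k + 1] - cl[k]) / step)))
        tt = np.linspace(0, 1, n, endpoint=False)
        out.append(cl[k] + tt[:, None] * (cl[k + 1] - cl[k]))
    out.append(cl[-1:])
    return np.vstack(out).astype(np.float32)


def default_phantom(
    shape: Tuple[int, int, int] = (48, 96, 96),
    voxel_um: float = 3.0,
    n_per_compartment: int = 4,
    doppler_angle_deg: float = 80.0,
    background_phase_sd: float = 0.0026,
    tilt: Tuple[float, float] = (2.0, 4.0),
) -> VesselPhantom:
    """Default 4-vessels-per-compartment phantom.

    Straight, slightly tilted cylinders run along x at distinct (z, y)
    stations: arteries (radius 21 µm, positive axial flow), veins (radius
    24 µm, negative flow) and capillaries (radius 4.5 µm, mixed signs).  The
    tilt de-aligns the cylinders from the grid so diameter estimates average
    over sub-voxel phases.  Axial speeds keep the beam projection well below
    the Nyquist velocity at the default acquisition.
    """
    nz, ny, nx = shape
    dz, dy = tilt
    rows = {
        "artery": dict(z=nz * 0.25, radius_um=21.0,
                       speeds=[5.0, 6.0, 7.0, 8.0, 5.5, 6.5]),
        "capillary": dict(z=nz * 0.5, radius_um=4.5,
                          speeds=[0.8, -1.0, 1.2, -1.5, 0.9, -1.1]),
        "vein": dict(z=nz * 0.75, radius_um=24.0,
                     speeds=[-4.0, -5.0, -5.5, -6.0, -4.5, -5.2]),
    }
    segments = []
    for comp, cfg in rows.items():
        ys = np.linspace(0.15 * ny, 0.85 * ny, n_per_compartment)
        for i in range(n_per_compartment):
            p0 = np.array([cfg["z"] - dz / 2, ys[i] - dy / 2, 0.0])
            p1 = np.array([cfg["z"] + dz / 2, ys[i] + dy / 2, nx - 1.0])
            segments.append(
                VesselSegment(
                    centerline=np.stack([p0, p1]),
                    radius_um=cfg["radius_um"],
                    compartment=comp,
                    v_axial_mm_s=cfg["speeds"][i % len(cfg["speeds"])],
                    doppler_angle_deg=doppler_angle_deg,
                )
            )
    return VesselPhantom(
        shape=shape,
        voxel_um=voxel_um,
        segments=segments,
        background_phase_sd=background_phase_sd,
    )
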