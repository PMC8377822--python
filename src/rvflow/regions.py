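"""Two-plane division of the RV mask into RVOT, inflow and apex regions.

The RV is cut by two static planes defined from end-diastolic landmarks:

* **Cut 1** passes through the antero-septal commissure of the tricuspid
  annulus with the 4-chamber plane normal, separating the outflow tract
  (the side containing the pulmonary valve) from the RV body.
* **Cut 2** bisects the remaining body half-way down the long axis
  (tricuspid-annulus centroid to apex), separating inflow from apex.

Planes are computed once on the end-diastolic mask and held static across
the cycle.  Voxel membership is decided by the voxel-centre position; the
assignment error is bounded by a one-voxel shell at each plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import Landmarks, SegmentationMask

__all__ = [
    "RVOT", "RV_INFLOW", "RV_APEX", "REGION_NAMES",
    "Plane", "DivisionPlanes", "build_planes", "divide_rv", "region_volume",
]

RVOT = 1
RV_INFLOW = 2
RV_APEX = 3
REGION_NAMES: dict[int, str] = {RVOT: "RVOT", RV_INFLOW: "RV_INFLOW", RV_APEX: "RV_APEX"}


@dataclass
class Plane:
    """An oriented plane in physical (mm) space."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("plane normal is zero")
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of point(s) from the plane, mm."""
        return np.asarray(points) @ self.normal - self.point @ self.normal


@dataclass
class DivisionPlanes:
    cut1: Plane  # RVOT separator
    cut2: Plane  # inflow/apex separator


def build_planes(landmarks: Landmarks) -> DivisionPlanes:
    """Construct the two cutting planes from the landmark set."""
    axis = landmarks.apex_point - landmarks.tricuspid_centroid
    axis_len = np.linalg.norm(axis)
    if axis_len < 1e-9:
        raise ValueError("degenerate long axis: apex coincides with tricuspid centroid")
    cut1 = Plane(point=landmarks.commissure_point.copy(),
                 normal=landmarks.four_chamber_normal.copy())
    midpoint = 0.5 * (landmarks.tricuspid_centroid + landmarks.apex_point)
    cut2 = Plane(point=midpoint, normal=axis / axis_len)
    return DivisionPlanes(cut1=cut1, cut2=cut2)


def divide_rv(
    rv_mask: SegmentationMask,
    planes: DivisionPlanes,
    landmarks: Landmarks,
) -> tuple[SegmentationMask, dict[str, float]]:
    """Assign every RV voxel to RVOT, RV_INFLOW or RV_APEX.

    Side assignment uses the signed distance from each cut, with the
    region-defining landmark fixing the positive side: voxels on the
    pulmonary-valve side of cut 1 become RVOT; the remaining voxels on the
    tricuspid side of cut 2 become RV_INFLOW, the rest RV_APEX.  Voxel
    centres lying exactly on a plane go to RVOT (cut 1) or RV_INFLOW
    (cut 2) — a deterministic tie-break.

    Returns the region label volume and each region's volume in mL.
    """
    inside = rv_mask.labels > 0
    if not inside.any():
        raise ValueError("RV mask is empty")

    nz, ny, nx = rv_mask.labels.shape
    dz, dy, dx = rv_mask.spacing
    z = rv_mask.origin[2] + np.arange(nz) * dz
    y = rv_mask.origin[1] + np.arange(ny) * dy
    x = rv_mask.origin[0] + np.arange(nx) * dx
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([X[inside], Y[inside], Z[inside]], axis=-1)

    s_pv = planes.cut1.signed_distance(landmarks.pv_centroid)
    if s_pv == 0:
        raise ValueError("pulmonary valve centroid lies exactly on cut 1: ambiguous side")
    d1 = planes.cut1.signed_distance(pts) * np.sign(s_pv)
    is_rvot = d1 >= 0  # exact ties go to the RVOT

    s_tv = planes.cut2.signed_distance(landmarks.tricuspid_centroid)
    if s_tv == 0:
        raise ValueError("tricuspid centroid lies exactly on cut 2: ambiguous side")
    d2 = planes.cut2.signed_distance(pts) * np.sign(s_tv)
    is_inflow = ~is_rvot & (d2 >= 0)  # exact ties go to the inflow

    assign = np.full(pts.shape[0], RV_APEX, dtype=np.int32)
    assign[is_inflow] = RV_INFLOW
    assign[is_rvot] = RVOT

    labels = np.zeros_like(rv_mask.labels, dtype=np.int32)
    labels[inside] = assign

    voxvol = rv_mask.voxel_volume
    volumes = {}
    for lab, name in REGION_NAMES.items():
        n = int(np.count_nonzero(labels == lab))
        if n == 0:
            raise ValueError(f"region {name} is empty after plane division")
        volumes[name] = n * voxvol / 1000.0  # mm^3 -> mL

    region_labels = SegmentationMask(labels=labels, label_names=dict(REGION_NAMES),
                                     spacing=rv_mask.spacing, origin=rv_mask.origin)
    return region_labels, volumes


def region_volume(labels: SegmentationMask, region: int | str) -> float:
    """Volume of one region in mL (voxel count x voxel volume)."""
    lab = labels.label_of(region) if isinstance(region, str) else int(region)
    if lab not in labels.label_names:
        raise KeyError(f"unknown region {region!r}")
    n = labels.region_voxel_count(lab)
    if n == 0:
        raise ValueError(f"region {labels.label_names[lab]} has no voxels")
    return n * labels.voxel_volume / 1000.0
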