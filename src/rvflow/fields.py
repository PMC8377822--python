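"""Data model, NIfTI I/O and preprocessing for 4D phase-contrast velocity fields.

Conventions used throughout the package
---------------------------------------
* Velocity arrays are indexed ``(phase, z, y, x, component)`` with the
  component axis ordered ``(vx, vy, vz)`` in physical axes, units m/s.
* ``spacing`` follows the array axis order, ``(dz, dy, dx)`` in mm.
* Physical coordinates are millimetres from the volume origin; the voxel at
  index ``(iz, iy, ix)`` has centre ``origin + (ix*dx, iy*dy, iz*dz)`` in
  ``(x, y, z)`` order.  Landmarks and cutting planes live in this frame.
* On disk, each velocity component is one 4D NIfTI volume stored in the
  nibabel ``(i, j, k, t)`` order with a diagonal affine; the last header
  dimension (cardiac phase) is mapped to the first in-memory index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("rvflow")

__all__ = [
    "VelocityField4D",
    "SegmentationMask",
    "Landmarks",
    "AcquisitionMeta",
    "read_velocity_field",
    "write_velocity_field",
    "read_labels",
    "write_labels",
    "load_landmarks",
    "save_landmarks",
    "load_meta",
    "background_phase_correction",
    "noise_screen",
    "write_metrics",
    "read_metrics",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VelocityField4D:
    """A sampled velocity vector field over one cardiac cycle.

    Parameters
    ----------
    velocities : ndarray, shape (n_phases, nz, ny, nx, 3)
        Velocity in m/s; last axis is (vx, vy, vz) in physical axes.
    spacing : ndarray, shape (3,)
        Voxel edge lengths (dz, dy, dx) in mm, matching the array axes.
    phase_times : ndarray, shape (n_phases,)
        Trigger time of each reconstructed phase, ms, strictly increasing.
    venc : float
        Velocity-encoding limit of the acquisition, m/s.
    rr_interval : float
        Cardiac cycle length, ms.
    origin : ndarray, shape (3,)
        Physical (x, y, z) position of voxel (0, 0, 0), mm.
    """

    velocities: np.ndarray
    spacing: np.ndarray
    phase_times: np.ndarray
    venc: float
    rr_interval: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.velocities.ndim != 5 or self.velocities.shape[-1] != 3:
            raise ValueError(
                f"velocities must have shape (T, Z, Y, X, 3), got {self.velocities.shape}"
            )
        if self.n_phases < 2:
            raise ValueError("at least 2 cardiac phases are required")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 strictly positive edge lengths (mm)")
        if self.phase_times.shape != (self.n_phases,):
            raise ValueError("phase_times length must equal the number of phases")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        if not (self.venc > 0 and self.rr_interval > 0):
            raise ValueError("venc and rr_interval must be positive")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocity field contains non-finite voxels")

    # -- geometry -----------------------------------------------------------

    @property
    def n_phases(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocities.shape[1:4]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical (X, Y, Z) coordinate arrays of voxel centres, each (Z, Y, X), mm."""
        nz, ny, nx = self.grid_shape
        dz, dy, dx = self.spacing
        z = self.origin[2] + np.arange(nz) * dz
        y = self.origin[1] + np.arange(ny) * dy
        x = self.origin[0] + np.arange(nx) * dx
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        return X, Y, Z

    def clip_to_venc(self) -> tuple["VelocityField4D", int]:
        """Clip velocity components to +/- venc; returns (field, n_clipped).

        Aliased voxels are flagged in the log, not unwrapped: phase-unwrapping
        is out of scope for this pipeline.
        """
        over = np.abs(self.velocities) > self.venc
        n = int(over.sum())
        if n:
            log.warning("%d velocity samples exceed venc=%.2f m/s; clipped", n, self.venc)
            v = np.clip(self.velocities, -self.venc, self.venc)
            return replace(self, velocities=v), n
        return self, 0


@dataclass
class SegmentationMask:
    """Integer label volume co-registered to one velocity phase.

    Label 0 is background; each nonzero label defines one integration
    domain V.  ``voxel_volume`` is in mm^3 and must match the field geometry.
    """

    labels: np.ndarray
    label_names: dict[int, str]
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (Z, Y, X) volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def label_of(self, name: str) -> int:
        for k, v in self.label_names.items():
            if v == name:
                return k
        raise KeyError(f"unknown region {name!r}")


@dataclass
class Landmarks:
    """Anatomical landmarks picked in physical (mm) space."""

    commissure_point: np.ndarray
    four_chamber_normal: np.ndarray
    tricuspid_centroid: np.ndarray
    apex_point: np.ndarray
    pv_centroid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("commissure_point", "four_chamber_normal", "tricuspid_centroid",
                     "apex_point", "pv_centroid"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        if abs(np.linalg.norm(self.four_chamber_normal) - 1.0) > 1e-9:
            raise ValueError("four_chamber_normal must have unit length")
        if np.allclose(self.tricuspid_centroid, self.apex_point):
            raise ValueError("tricuspid centroid and apex coincide: long axis undefined")


@dataclass
class AcquisitionMeta:
    """Per-subject acquisition bookkeeping (phase windows, static-tissue label)."""

    subject_id: str = "anonymous"
    systole_phase_range: tuple[int, int] | None = None
    diastole_phase_range: tuple[int, int] | None = None
    static_tissue_label: int | None = None

    def __post_init__(self) -> None:
        s, d = self.systole_phase_range, self.diastole_phase_range
        if s is not None:
            self.systole_phase_range = (int(s[0]), int(s[1]))
        if d is not None:
            self.diastole_phase_range = (int(d[0]), int(d[1]))
        if s is not None and d is not None:
            sa, sb = self.systole_phase_range
            da, db = self.diastole_phase_range
            if sa > sb or da > db:
                raise ValueError("phase ranges must be non-empty inclusive intervals")
            if not (sb < da or db < sa):
                raise ValueError("systole and diastole phase ranges overlap")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _check_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract (spacing_xyz, origin_xyz) from a near-diagonal affine.

    The pipeline operates on orthogonal, axis-aligned grids; oblique
    acquisitions must be resampled upstream.
    """
    R = affine[:3, :3]
    off = R - np.diag(np.diag(R))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(np.diag(R)))):
        raise ValueError("oblique affine: only axis-aligned grids are supported")
    spacing = np.abs(np.diag(R))
    if np.any(spacing <= 0):
        raise ValueError("affine has a zero or missing voxel spacing")
    return spacing, affine[:3, 3].copy()


def write_velocity_field(fld: VelocityField4D, component_paths: Sequence[str | Path]) -> None:
    """Write the three velocity components as 4D NIfTI volumes (m/s)."""
    if len(component_paths) != 3:
        raise ValueError("expected exactly three component paths (vx, vy, vz)")
    dz, dy, dx = fld.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = fld.origin
    for c, path in enumerate(component_paths):
        # (T, Z, Y, X) -> (X, Y, Z, T) for the nibabel (i, j, k, t) convention
        data = np.transpose(fld.velocities[..., c], (3, 2, 1, 0))
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
        img.header.set_xyzt_units("mm", "msec")
        dt = float(np.mean(np.diff(fld.phase_times)))
        img.header["pixdim"][4] = dt
        nib.save(img, str(path))


def read_velocity_field(
    component_paths: Sequence[str | Path],
    meta: AcquisitionMeta | None = None,
    *,
    venc: float = 2.0,
    phase_times: np.ndarray | None = None,
    rr_interval: float | None = None,
) -> VelocityField4D:
    """Read three per-component 4D NIfTI volumes into a validated field.

    ``venc``, ``phase_times`` and ``rr_interval`` may be supplied when the
    headers do not carry them; phase timing defaults to the header's temporal
    pixdim (uniform spacing starting at half an interval).
    """
    if len(component_paths) != 3:
        raise ValueError("expected exactly three component paths (vx, vy, vz)")
    vols, affines, dts = [], [], []
    for path in component_paths:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
        vols.append(data)
        affines.append(img.affine)
        dts.append(float(img.header["pixdim"][4]))
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        if len({v.shape[3] for v in vols}) != 1:
            raise ValueError(f"phase count mismatch across components: {sorted(shapes)}")
        raise ValueError(f"grid shape mismatch across components: {sorted(shapes)}")
    spacing_xyz, origin = _check_affine(affines[0])
    for a in affines[1:]:
        if not np.allclose(a, affines[0], atol=1e-6):
            raise ValueError("component affines disagree")
    n_phases = vols[0].shape[3]
    if phase_times is None:
        dt = dts[0] if dts[0] > 0 else 40.0
        phase_times = (np.arange(n_phases) + 0.5) * dt
    phase_times = np.asarray(phase_times, dtype=float)
    if rr_interval is None:
        dt = float(np.mean(np.diff(phase_times)))
        rr_interval = float(phase_times[-1] + dt / 2.0)
    # (X, Y, Z, T) per component -> (T, Z, Y, X, 3)
    stacked = np.stack(
        [np.transpose(v, (3, 2, 1, 0)) for v in vols], axis=-1
    )
    if not np.all(np.isfinite(stacked)):
        raise ValueError("velocity volumes contain non-finite voxels")
    n_over = int((np.abs(stacked) > venc).sum())
    if n_over:
        # flagged here; clipping happens once in the pipeline after
        # background correction so file and in-memory paths agree
        log.warning("%d velocity samples exceed venc=%.2f m/s at read time",
                    n_over, venc)
    return VelocityField4D(
        velocities=stacked,
        spacing=spacing_xyz[::-1],  # (dx,dy,dz) -> (dz,dy,dx)
        phase_times=phase_times,
        venc=venc,
        rr_interval=rr_interval,
        origin=origin,
    )


def write_labels(mask: SegmentationMask, path: str | Path) -> None:
    dz, dy, dx = mask.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = mask.origin
    data = np.transpose(mask.labels, (2, 1, 0)).astype(np.int16)
    img = nib.Nifti1Image(data, affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_labels(path: str | Path, label_names: Mapping[int, str] | None = None) -> SegmentationMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume")
    spacing_xyz, origin = _check_affine(img.affine)
    labels = np.transpose(np.rint(data).astype(np.int32), (2, 1, 0))
    names = dict(label_names) if label_names else {
        int(v): f"label_{int(v)}" for v in np.unique(labels) if v != 0
    }
    return SegmentationMask(labels=labels, label_names=names,
                            spacing=spacing_xyz[::-1], origin=origin)


def save_landmarks(lm: Landmarks, path: str | Path) -> None:
    doc = {k: [float(x) for x in getattr(lm, k)] for k in
           ("commissure_point", "four_chamber_normal", "tricuspid_centroid",
            "apex_point", "pv_centroid")}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_landmarks(path: str | Path) -> Landmarks:
    doc = yaml.safe_load(Path(path).read_text())
    return Landmarks(**{k: np.asarray(v, dtype=float) for k, v in doc.items()})


def load_meta(path: str | Path) -> AcquisitionMeta:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("systole_phase_range", "diastole_phase_range"):
        if doc.get(key) is not None:
            doc[key] = tuple(doc[key])
    return AcquisitionMeta(**doc)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _poly_design(X: np.ndarray, Y: np.ndarray, Z: np.ndarray, order: int,
                 center: np.ndarray, scale: float) -> np.ndarray:
    """Monomial design matrix up to total degree `order` in scaled coordinates."""
    xs = (X - center[0]) / scale
    ys = (Y - center[1]) / scale
    zs = (Z - center[2]) / scale
    cols = []
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append(xs**a * ys**b * zs**c)
    return np.stack(cols, axis=-1)


def background_phase_correction(
    fld: VelocityField4D,
    static_mask: SegmentationMask,
    order: int = 1,
) -> tuple[VelocityField4D, dict]:
    """Remove eddy-current background offsets using presumed-static tissue.

    A spatial polynomial of total degree ``order`` is least-squares fit, per
    velocity component, to the *time-averaged* velocity over static voxels and
    the fitted surface is subtracted from every phase.  Fitting the temporal
    mean rather than each phase follows standard stationary-tissue correction
    practice: the eddy-current offset is static while genuine flow averages
    toward zero over the cycle.

    Returns the corrected field and a report with the fitted coefficients and
    the residual RMS over static voxels.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    static = static_mask.labels > 0
    n_static = int(static.sum())
    X, Y, Z = fld.voxel_coords()
    center = np.array([X[static].mean(), Y[static].mean(), Z[static].mean()]) \
        if n_static else np.zeros(3)
    scale = max(float(np.max(fld.spacing) * max(fld.grid_shape)), 1.0)
    n_terms = (order + 1) * (order + 2) * (order + 3) // 6
    if n_static < max(n_terms, 4):
        raise ValueError(
            f"static mask has {n_static} voxels; at least {max(n_terms, 4)} "
            f"needed for an order-{order} polynomial (rank deficiency)"
        )
    A = _poly_design(X[static], Y[static], Z[static], order, center, scale)
    if np.linalg.matrix_rank(A) < n_terms:
        raise ValueError("static voxel layout is rank-deficient for the requested order")
    tmean = fld.velocities.mean(axis=0)  # (Z, Y, X, 3)
    A_full = _poly_design(X, Y, Z, order, center, scale)
    corrected = fld.velocities.copy()
    coeffs, resid_rms = [], []
    for c in range(3):
        beta, *_ = np.linalg.lstsq(A, tmean[..., c][static], rcond=None)
        surface = A_full @ beta
        corrected[..., c] -= surface[None, ...]
        coeffs.append(beta)
        resid_rms.append(float(np.sqrt(np.mean((tmean[..., c][static] - A @ beta) ** 2))))
    report = {
        "order": order,
        "n_static_voxels": n_static,
        "coefficients": np.stack(coeffs),
        "basis_center_mm": center,
        "basis_scale_mm": scale,
        "static_residual_rms_m_per_s": resid_rms,
    }
    log.info("background correction order=%d on %d static voxels; residual RMS %s",
             order, n_static, [f"{r:.2e}" for r in resid_rms])
    return replace(fld, velocities=corrected), report


def auto_static_mask(fld: VelocityField4D, rv_mask: SegmentationMask,
                     percentile: float = 10.0) -> SegmentationMask:
    """Fallback static-tissue selector: voxels outside the RV whose temporal
    speed SD is below the given percentile.  Off by default in the pipeline;
    an explicit static label is more reproducible."""
    speed = np.linalg.norm(fld.velocities, axis=-1)
    sd = speed.std(axis=0)
    outside = rv_mask.labels == 0
    thr = np.percentile(sd[outside], percentile)
    static = outside & (sd <= thr)
    return SegmentationMask(labels=static.astype(np.int32),
                            label_names={1: "STATIC"},
                            spacing=rv_mask.spacing, origin=rv_mask.origin)


def noise_screen(
    fld: VelocityField4D,
    mask: SegmentationMask,
    sd_fraction: float = 0.3,
) -> tuple[SegmentationMask, dict[str, int]]:
    """Screen noisy voxels out of each labelled region.

    A voxel is removed when the temporal standard deviation of its speed
    exceeds ``sd_fraction * venc`` — random phase noise makes a voxel's speed
    fluctuate across the cycle far more than physiological flow does.
    Removal applies across all phases (the mask is static).

    Returns the screened mask and the per-region removed-voxel counts.
    """
    if not (0.0 < sd_fraction < 1.0):
        raise ValueError("sd_fraction must lie strictly between 0 and 1")
    speed = np.linalg.norm(fld.velocities, axis=-1)
    sd = speed.std(axis=0, ddof=0)
    noisy = sd > sd_fraction * fld.venc
    new_labels = mask.labels.copy()
    removed: dict[str, int] = {}
    for lab, name in sorted(mask.label_names.items()):
        region = mask.labels == lab
        kill = region & noisy
        removed[name] = int(kill.sum())
        new_labels[kill] = 0
        if removed[name] and not np.any(region & ~noisy):
            raise ValueError(f"region {name} emptied by screening")
    if any(removed.values()):
        log.info("noise screening removed voxels: %s", removed)
    return (
        SegmentationMask(labels=new_labels, label_names=dict(mask.label_names),
                         spacing=mask.spacing, origin=mask.origin),
        removed,
    )


# ---------------------------------------------------------------------------
# metrics output
# ---------------------------------------------------------------------------

def write_metrics(metrics, timeseries, out_dir: str | Path,
                  prefix: str = "subject") -> tuple[Path, Path]:
    """Write a FlowMetrics JSON record and the region time-series CSV.

    The JSON is key-sorted and fixed-format so identical inputs produce
    byte-identical files; round-tripping reproduces values to full precision.
    """
    rec = metrics.to_dict()
    for k, v in rec.items():
        if not np.isfinite(v):
            raise ValueError(f"metric {k} is not finite; refusing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{prefix}_metrics.json"
    csv_path = out_dir / f"{prefix}_timeseries.csv"
    json_path.write_text(json.dumps(rec, sort_keys=True, indent=2) + "\n")
    df = timeseries.to_dataframe() if hasattr(timeseries, "to_dataframe") else timeseries
    cols = ["phase", "time_ms", "region", "omega_per_s", "vel_mW"]
    if len(df) == 0:
        df = pd.DataFrame(columns=cols)
    df.to_csv(csv_path, index=False, float_format="%.12g", columns=cols)
    return json_path, csv_path


def read_metrics(json_path: str | Path) -> dict:
    return json.loads(Path(json_path).read_text())
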