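"""Vorticity, viscous energy loss, peak metrics and the quotient biomarkers.

The flow operators act on a masked voxel grid.  Spatial derivatives use
central differences on interior voxels and fall back to first-order
one-sided differences where a 6-neighbour leaves the mask, so out-of-domain
(zero-filled) voxels never contaminate a gradient.  All internal computation
is SI; the reporting layer converts to the conventional units — normalized
vorticity in 1/s, absolute vorticity in L/s, region volume in mL and viscous
energy loss in mW.

Definitions
-----------
* vorticity               ``omega = curl(u)``            [1/s]
* absolute vorticity      ``int_V ||omega|| dV``         [L/s]
* normalized vorticity    ``abs. vorticity / volume(V)`` [1/s]
* viscous energy loss     ``VEL = int_V (mu/2) * sum_ij (du_i/dx_j + du_j/dx_i)^2 dV`` [mW]
  with dynamic blood viscosity mu = 0.004 Pa*s by default, and the sum over
  all nine ordered index pairs (i, j).

Quotient biomarkers
-------------------
* RV-DVQ  = peak diastolic RVOT vorticity / peak diastolic inflow vorticity
* RVOT-VQ = peak diastolic / peak systolic RVOT vorticity
* RVOT-EQ = peak diastolic / peak systolic RVOT viscous energy loss
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .fields import AcquisitionMeta, Landmarks, SegmentationMask, VelocityField4D
from .regions import REGION_NAMES, RVOT, RV_APEX, RV_INFLOW, DivisionPlanes

log = logging.getLogger("rvflow")

BLOOD_VISCOSITY_PA_S = 0.004

__all__ = [
    "BLOOD_VISCOSITY_PA_S",
    "VorticityField", "RegionTimeSeries", "PhaseWindows", "FlowMetrics",
    "velocity_gradient", "curl", "absolute_vorticity", "normalized_vorticity",
    "viscous_energy_loss", "compute_timeseries", "detect_phase_windows",
    "peak_metrics", "advect_particles", "pathlines_to_dataframe",
    "export_vorticity_map",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class VorticityField:
    """Per-voxel vorticity vectors for one cardiac phase, 1/s.

    Zero outside the mask by convention.
    """

    vorticity: np.ndarray          # (Z, Y, X, 3)
    mask: np.ndarray               # (Z, Y, X) bool
    spacing: np.ndarray            # (dz, dy, dx) mm
    origin: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vorticity, axis=-1)


@dataclass
class PhaseWindows:
    """Inclusive systolic and diastolic phase-index intervals."""

    systole: tuple[int, int]
    diastole: tuple[int, int]

    def __post_init__(self) -> None:
        self.systole = (int(self.systole[0]), int(self.systole[1]))
        self.diastole = (int(self.diastole[0]), int(self.diastole[1]))
        for name, (a, b) in (("systole", self.systole), ("diastole", self.diastole)):
            if a > b or a < 0:
                raise ValueError(f"{name} window [{a}, {b}] is empty or negative")
        sa, sb = self.systole
        da, db = self.diastole
        if not (sb < da or db < sa):
            raise ValueError("systole and diastole windows overlap")

    def phases(self, which: str) -> np.ndarray:
        a, b = getattr(self, which)
        return np.arange(a, b + 1)


@dataclass
class RegionTimeSeries:
    """Per-phase, per-region vorticity and energy-loss curves."""

    phase_times: np.ndarray                       # (T,) ms
    regions: tuple[str, ...]
    absolute_vorticity: dict[str, np.ndarray]     # L/s
    normalized_vorticity: dict[str, np.ndarray]   # 1/s
    vel_mw: dict[str, np.ndarray]                 # mW
    volume_ml: dict[str, float]

    def __post_init__(self) -> None:
        for r in self.regions:
            av = self.absolute_vorticity[r]
            nv = self.normalized_vorticity[r]
            vol_l = self.volume_ml[r] * 1e-3
            if not np.allclose(nv * vol_l, av, rtol=1e-9, atol=1e-15):
                raise ValueError(f"vorticity normalization inconsistent for region {r}")
            if np.any(av < 0) or np.any(self.vel_mw[r] < 0):
                raise ValueError(f"negative vorticity or energy loss in region {r}")

    @property
    def n_phases(self) -> int:
        return len(self.phase_times)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            for p in range(self.n_phases):
                rows.append({
                    "phase": p,
                    "time_ms": float(self.phase_times[p]),
                    "region": r,
                    "omega_per_s": float(self.normalized_vorticity[r][p]),
                    "vel_mW": float(self.vel_mw[r][p]),
                    "absolute_vorticity_L_per_s": float(self.absolute_vorticity[r][p]),
                    "volume_mL": float(self.volume_ml[r]),
                })
        return pd.DataFrame(rows)


@dataclass
class FlowMetrics:
    """Peak regional metrics and the three quotient biomarkers for one subject."""

    omega_rvot_systole: float    # 1/s
    omega_rvot_diastole: float   # 1/s
    omega_inflow_diastole: float # 1/s
    vel_rvot_systole: float      # mW
    vel_rvot_diastole: float     # mW
    rv_dvq: float
    rvot_vq: float
    rvot_eq: float

    def __post_init__(self) -> None:
        peaks = (self.omega_rvot_systole, self.omega_rvot_diastole,
                 self.omega_inflow_diastole, self.vel_rvot_systole,
                 self.vel_rvot_diastole)
        if any(p < 0 for p in peaks):
            raise ValueError("peak metrics must be non-negative")
        for name, num, den, q in (
            ("RV-DVQ", self.omega_rvot_diastole, self.omega_inflow_diastole, self.rv_dvq),
            ("RVOT-VQ", self.omega_rvot_diastole, self.omega_rvot_systole, self.rvot_vq),
            ("RVOT-EQ", self.vel_rvot_diastole, self.vel_rvot_systole, self.rvot_eq),
        ):
            if den <= 0:
                raise ValueError(f"{name} denominator is zero")
            if abs(q - num / den) > 1e-12 * max(1.0, abs(q)):
                raise ValueError(f"{name} does not equal its defining ratio")

    def to_dict(self) -> dict[str, float]:
        return {
            "omega_rvot_systole_per_s": self.omega_rvot_systole,
            "omega_rvot_diastole_per_s": self.omega_rvot_diastole,
            "omega_inflow_diastole_per_s": self.omega_inflow_diastole,
            "vel_rvot_systole_mw": self.vel_rvot_systole,
            "vel_rvot_diastole_mw": self.vel_rvot_diastole,
            "rv_dvq": self.rv_dvq,
            "rvot_vq": self.rvot_vq,
            "rvot_eq": self.rvot_eq,
        }


# ---------------------------------------------------------------------------
# differential operators
# ---------------------------------------------------------------------------

def _shift(arr: np.ndarray, axis: int, step: int) -> np.ndarray:
    """Shift along `axis` by `step`, zero-filling the vacated slab."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    else:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _masked_derivative(values: np.ndarray, mask: np.ndarray, axis: int,
                       h_m: float) -> np.ndarray:
    """d(values)/d(axis) on mask voxels; central where both neighbours are in
    the mask, one-sided where only one is; raises if a mask voxel has neither.
    """
    v_f = _shift(values, axis, +1)
    v_b = _shift(values, axis, -1)
    m_f = _shift(mask, axis, +1)
    m_b = _shift(mask, axis, -1)
    both = mask & m_f & m_b
    fwd = mask & m_f & ~m_b
    bwd = mask & m_b & ~m_f
    orphan = mask & ~m_f & ~m_b
    if orphan.any():
        raise ValueError(
            f"region thinner than 2 voxels along axis {('z','y','x')[axis]}: "
            "no valid finite-difference stencil"
        )
    d = np.zeros_like(values)
    d[both] = (v_f[both] - v_b[both]) / (2.0 * h_m)
    d[fwd] = (v_f[fwd] - values[fwd]) / h_m
    d[bwd] = (values[bwd] - v_b[bwd]) / h_m
    return d


def _as_bool_mask(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.labels > 0
    return np.asarray(mask).astype(bool)


def velocity_gradient(fld: VelocityField4D, phase: int, mask) -> np.ndarray:
    """Velocity-gradient tensor G[..., i, j] = du_i/dx_j in 1/s, one phase.

    i, j index the physical axes (x, y, z).  Zero outside the mask.
    """
    m = _as_bool_mask(mask)
    if not m.any():
        raise ValueError("mask is empty")
    if not (0 <= phase < fld.n_phases):
        raise IndexError(f"phase {phase} out of range [0, {fld.n_phases})")
    u = fld.velocities[phase]  # (Z, Y, X, 3)
    h_m = fld.spacing * 1e-3   # mm -> m, (dz, dy, dx)
    # physical axis x -> array axis 2, y -> 1, z -> 0
    axis_for = {0: 2, 1: 1, 2: 0}
    G = np.zeros(u.shape[:3] + (3, 3))
    for i in range(3):         # velocity component
        for j in range(3):     # derivative direction (physical)
            ax = axis_for[j]
            G[..., i, j] = _masked_derivative(u[..., i], m, ax, h_m[ax])
    return G


def curl(fld: VelocityField4D, phase: int, mask) -> VorticityField:
    """Vorticity omega = curl(u) on the masked grid for one phase."""
    m = _as_bool_mask(mask)
    G = velocity_gradient(fld, phase, m)
    w = np.empty(G.shape[:3] + (3,))
    w[..., 0] = G[..., 2, 1] - G[..., 1, 2]   # dw/dy - dv/dz
    w[..., 1] = G[..., 0, 2] - G[..., 2, 0]   # du/dz - dw/dx
    w[..., 2] = G[..., 1, 0] - G[..., 0, 1]   # dv/dx - du/dy
    w[~m] = 0.0
    return VorticityField(vorticity=w, mask=m, spacing=fld.spacing.copy(),
                          origin=fld.origin.copy())


# ---------------------------------------------------------------------------
# regional integrals
# ---------------------------------------------------------------------------

def absolute_vorticity(vort: VorticityField, labels: SegmentationMask,
                       region: int | str) -> float:
    """Integral of ||omega|| over the region, in L/s."""
    lab = labels.label_of(region) if isinstance(region, str) else int(region)
    if lab not in labels.label_names:
        raise KeyError(f"unknown region {region!r}")
    sel = labels.labels == lab
    if not sel.any():
        raise ValueError(f"region {labels.label_names[lab]} is empty")
    voxvol_l = labels.voxel_volume * 1e-6  # mm^3 -> L
    return float(vort.magnitude[sel].sum() * voxvol_l)


def normalized_vorticity(abs_vort_l_per_s: float, volume_ml: float) -> float:
    """Volume-normalized vorticity in 1/s (the volume-weighted mean of ||omega||)."""
    if volume_ml <= 0:
        raise ValueError("region volume must be positive")
    return abs_vort_l_per_s / (volume_ml * 1e-3)


def _dissipation_density(fld: VelocityField4D, phase: int, mask,
                         mu: float) -> np.ndarray:
    """Viscous dissipation density (mu/2) sum_ij (du_i/dx_j + du_j/dx_i)^2, W/m^3."""
    G = velocity_gradient(fld, phase, mask)
    S2 = G + np.swapaxes(G, -1, -2)
    return 0.5 * mu * np.sum(S2 ** 2, axis=(-1, -2))


def viscous_energy_loss(fld: VelocityField4D, phase: int,
                        labels: SegmentationMask, region: int | str,
                        mu: float = BLOOD_VISCOSITY_PA_S) -> float:
    """Viscous energy loss over the region for one phase, in mW.

    Gradients are evaluated on the union of all labelled voxels so region
    boundaries interior to the RV keep their central stencils; the
    dissipation density is then integrated over the requested region only.
    """
    if mu <= 0:
        raise ValueError("viscosity mu must be positive")
    lab = labels.label_of(region) if isinstance(region, str) else int(region)
    if lab not in labels.label_names:
        raise KeyError(f"unknown region {region!r}")
    sel = labels.labels == lab
    if not sel.any():
        raise ValueError(f"region {labels.label_names[lab]} is empty")
    phi = _dissipation_density(fld, phase, labels.labels > 0, mu)
    voxvol_m3 = labels.voxel_volume * 1e-9
    return float(phi[sel].sum() * voxvol_m3 * 1e3)  # W -> mW


def compute_timeseries(fld: VelocityField4D, labels: SegmentationMask,
                       mu: float = BLOOD_VISCOSITY_PA_S) -> RegionTimeSeries:
    """Per-phase normalized vorticity and VEL for RVOT, RV_INFLOW and RV_APEX.

    One gradient evaluation per phase (on the union mask) feeds both the
    vorticity magnitude and the dissipation density for all regions.
    """
    union = labels.labels > 0
    if not union.any():
        raise ValueError("label volume is empty")
    region_sel = {}
    volume_ml = {}
    voxvol_mm3 = labels.voxel_volume
    for lab, name in REGION_NAMES.items():
        sel = labels.labels == lab
        if not sel.any():
            raise ValueError(f"region {name} is empty")
        region_sel[name] = sel
        volume_ml[name] = sel.sum() * voxvol_mm3 / 1000.0

    names = tuple(REGION_NAMES.values())
    av = {r: np.zeros(fld.n_phases) for r in names}
    vel = {r: np.zeros(fld.n_phases) for r in names}
    h_m = fld.spacing * 1e-3
    axis_for = {0: 2, 1: 1, 2: 0}
    voxvol_l = voxvol_mm3 * 1e-6
    voxvol_m3 = voxvol_mm3 * 1e-9
    for p in range(fld.n_phases):
        u = fld.velocities[p]
        G = np.zeros(u.shape[:3] + (3, 3))
        for i in range(3):
            for j in range(3):
                ax = axis_for[j]
                G[..., i, j] = _masked_derivative(u[..., i], union, ax, h_m[ax])
        wmag = np.sqrt(
            (G[..., 2, 1] - G[..., 1, 2]) ** 2
            + (G[..., 0, 2] - G[..., 2, 0]) ** 2
            + (G[..., 1, 0] - G[..., 0, 1]) ** 2
        )
        S2 = G + np.swapaxes(G, -1, -2)
        phi = 0.5 * mu * np.sum(S2 ** 2, axis=(-1, -2))
        for r in names:
            sel = region_sel[r]
            av[r][p] = wmag[sel].sum() * voxvol_l
            vel[r][p] = phi[sel].sum() * voxvol_m3 * 1e3
    nv = {r: av[r] / (volume_ml[r] * 1e-3) for r in names}
    return RegionTimeSeries(
        phase_times=fld.phase_times.copy(), regions=names,
        absolute_vorticity=av, normalized_vorticity=nv,
        vel_mw=vel, volume_ml=volume_ml,
    )


# ---------------------------------------------------------------------------
# phase windows and peaks
# ---------------------------------------------------------------------------

def _longest_run(flags: np.ndarray) -> tuple[int, int] | None:
    best = None
    start = None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    return best


def detect_phase_windows(
    fld: VelocityField4D,
    labels: SegmentationMask,
    meta: AcquisitionMeta | None = None,
    planes: DivisionPlanes | None = None,
    landmarks: Landmarks | None = None,
) -> PhaseWindows:
    """Determine the systolic and diastolic phase windows.

    Explicit ranges in ``meta`` win and are returned after validation.
    Otherwise windows are detected from the sign of the mean RVOT velocity
    along the outflow axis (cut-1 normal oriented toward the pulmonary
    valve): systole is the longest contiguous run of forward flow, diastole
    the longest contiguous run of the complement.
    """
    if fld.n_phases < 4:
        raise ValueError("phase-window detection needs at least 4 phases")
    if meta is not None and meta.systole_phase_range and meta.diastole_phase_range:
        w = PhaseWindows(systole=meta.systole_phase_range,
                         diastole=meta.diastole_phase_range)
        for a, b in (w.systole, w.diastole):
            if b >= fld.n_phases:
                raise ValueError("phase window exceeds the number of phases")
        log.info("phase windows from metadata: systole %s diastole %s",
                 w.systole, w.diastole)
        return w
    if planes is None or landmarks is None:
        raise ValueError("auto-detection needs the division planes and landmarks")
    n = planes.cut1.normal * np.sign(planes.cut1.signed_distance(landmarks.pv_centroid))
    rvot = labels.labels == RVOT
    if not rvot.any():
        raise ValueError("RVOT region is empty")
    mean_axial = fld.velocities[:, rvot, :] @ n  # (T, n_vox)
    signal = mean_axial.mean(axis=1)
    sys_run = _longest_run(signal > 0)
    dia_run = _longest_run(signal <= 0)
    if sys_run is None or dia_run is None:
        raise ValueError("phase-window auto-detection produced an empty window")
    w = PhaseWindows(systole=sys_run, diastole=dia_run)
    log.info("phase windows auto-detected from RVOT through-plane flow: "
             "systole %s diastole %s", w.systole, w.diastole)
    return w


def peak_metrics(ts: RegionTimeSeries, windows: PhaseWindows,
                 mu: float = BLOOD_VISCOSITY_PA_S,
                 smooth_width: int = 0) -> FlowMetrics:
    """Extract per-window peaks and form the quotient biomarkers.

    The peak is the per-window maximum of the discrete series; no temporal
    smoothing is applied unless ``smooth_width`` (odd moving-average width)
    is given.
    """
    for a, b in (windows.systole, windows.diastole):
        if b >= ts.n_phases:
            raise ValueError("phase window exceeds the time series length")

    def series(d: np.ndarray) -> np.ndarray:
        if smooth_width and smooth_width > 1:
            k = np.ones(smooth_width) / smooth_width
            return np.convolve(d, k, mode="same")
        return d

    def peak(region: str, which: str, what: str) -> float:
        data = series(ts.normalized_vorticity[region] if what == "omega"
                      else ts.vel_mw[region])
        return float(data[windows.phases(which)].max())

    w_rvot_sys = peak("RVOT", "systole", "omega")
    w_rvot_dia = peak("RVOT", "diastole", "omega")
    w_infl_dia = peak("RV_INFLOW", "diastole", "omega")
    vel_sys = peak("RVOT", "systole", "vel")
    vel_dia = peak("RVOT", "diastole", "vel")

    for name, den in (("RV-DVQ", w_infl_dia), ("RVOT-VQ", w_rvot_sys),
                      ("RVOT-EQ", vel_sys)):
        if den <= 0:
            raise ValueError(f"zero denominator peak for quotient {name}")
    return FlowMetrics(
        omega_rvot_systole=w_rvot_sys,
        omega_rvot_diastole=w_rvot_dia,
        omega_inflow_diastole=w_infl_dia,
        vel_rvot_systole=vel_sys,
        vel_rvot_diastole=vel_dia,
        rv_dvq=w_rvot_dia / w_infl_dia,
        rvot_vq=w_rvot_dia / w_rvot_sys,
        rvot_eq=vel_dia / vel_sys,
    )


# ---------------------------------------------------------------------------
# particle advection (qualitative output)
# ---------------------------------------------------------------------------

def advect_particles(
    fld: VelocityField4D,
    seeds: np.ndarray,
    mask,
    n_steps: int = 200,
    cycles: float = 1.0,
    colors: list | None = None,
) -> dict:
    """Integrate pathlines through the time-resolved field.

    Classic 4th-order Runge-Kutta in time with trilinear spatial and linear
    temporal interpolation of the velocity; the field is periodic in the
    cardiac cycle.  Positions are mm and times ms (1 m/s = 1 mm/ms, so no
    unit factor appears in the update).  Particles whose nearest voxel
    leaves the mask are frozen in place and flagged.

    Returns a dict with ``positions`` (n_particles, n_steps+1, 3),
    ``times_ms``, ``frozen`` flags and ``colors``.
    """
    if fld.n_phases < 2:
        raise ValueError("advection needs at least 2 phases")
    m = _as_bool_mask(mask)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.shape[1] != 3:
        raise ValueError("seeds must be (n, 3) physical points in mm")

    nz, ny, nx = fld.grid_shape
    dz, dy, dx = fld.spacing
    zc = fld.origin[2] + np.arange(nz) * dz
    yc = fld.origin[1] + np.arange(ny) * dy
    xc = fld.origin[0] + np.arange(nx) * dx
    interps = [
        RegularGridInterpolator((zc, yc, xc), fld.velocities[p],
                                bounds_error=False, fill_value=0.0)
        for p in range(fld.n_phases)
    ]

    def in_mask(pts: np.ndarray) -> np.ndarray:
        iz = np.rint((pts[:, 2] - fld.origin[2]) / dz).astype(int)
        iy = np.rint((pts[:, 1] - fld.origin[1]) / dy).astype(int)
        ix = np.rint((pts[:, 0] - fld.origin[0]) / dx).astype(int)
        ok = ((iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny)
              & (ix >= 0) & (ix < nx))
        res = np.zeros(len(pts), dtype=bool)
        res[ok] = m[iz[ok], iy[ok], ix[ok]]
        return res

    if not in_mask(seeds).all():
        raise ValueError("one or more seed points lie outside the mask")

    T = fld.rr_interval
    times = fld.phase_times

    def velocity(pts: np.ndarray, t_ms: float) -> np.ndarray:
        t = t_ms % T
        idx = np.searchsorted(times, t) - 1
        if idx < 0:
            p0, p1 = fld.n_phases - 1, 0
            t0 = times[-1] - T
        elif idx >= fld.n_phases - 1:
            p0, p1 = fld.n_phases - 1, 0
            t0 = times[-1]
        else:
            p0, p1 = idx, idx + 1
            t0 = times[p0]
        t1 = times[p1] if p1 != 0 else (times[0] + T if t >= times[-1] else times[0])
        frac = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        q = pts[:, ::-1]  # (x,y,z) -> (z,y,x)
        return (1 - frac) * interps[p0](q) + frac * interps[p1](q)

    total_t = cycles * T
    dt = total_t / n_steps
    pos = np.empty((len(seeds), n_steps + 1, 3))
    pos[:, 0] = seeds
    frozen = np.zeros(len(seeds), dtype=bool)
    t_out = np.arange(n_steps + 1) * dt
    for s in range(n_steps):
        p = pos[:, s]
        t = t_out[s]
        k1 = velocity(p, t)
        k2 = velocity(p + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = velocity(p + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = velocity(p + dt * k3, t + dt)
        step = dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        new = p + step
        leaving = ~in_mask(new) & ~frozen
        frozen |= leaving
        new[frozen] = pos[frozen, s]
        pos[:, s + 1] = new
    if colors is None:
        colors = [0] * len(seeds)
    return {"positions": pos, "times_ms": t_out, "frozen": frozen,
            "colors": list(colors)}


def pathlines_to_dataframe(result: dict) -> pd.DataFrame:
    pos = result["positions"]
    t = result["times_ms"]
    rows = []
    for pid in range(pos.shape[0]):
        for s in range(pos.shape[1]):
            rows.append({
                "particle_id": pid, "step": s,
                "x": pos[pid, s, 0], "y": pos[pid, s, 1], "z": pos[pid, s, 2],
                "t_ms": t[s], "region_color": result["colors"][pid],
            })
    return pd.DataFrame(rows)


def export_vorticity_map(vort: VorticityField, path, points_csv=None) -> None:
    """Write ||omega|| as a 3D NIfTI volume (optionally a point cloud CSV)."""
    import nibabel as nib

    dz, dy, dx = vort.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = vort.origin
    data = np.transpose(vort.magnitude, (2, 1, 0))
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    if points_csv is not None:
        Z, Y, X = np.nonzero(vort.mask)
        df = pd.DataFrame({
            "x": vort.origin[0] + X * dx,
            "y": vort.origin[1] + Y * dy,
            "z": vort.origin[2] + Z * dz,
            "omega_mag_per_s": vort.magnitude[vort.mask],
        })
        df.to_csv(points_csv, index=False)
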