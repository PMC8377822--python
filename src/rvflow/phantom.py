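"""Synthetic velocity fields with known ground truth.

Three tiers of phantom:

* ``make_analytic_field`` — classical flows (uniform, rigid rotation,
  Poiseuille, Lamb-Oseen, ring vortex) whose vorticity and viscous energy
  loss are known in closed form; these are the verification oracles for the
  finite-difference operators.
* ``make_rv_phantom`` — a two-compartment, RV-like field on a voxel grid:
  a systolic outflow jet through a tubular outflow tract, a diastolic
  toroidal ring vortex around the tricuspid inflow, and a diastolic
  regurgitant swirling jet in the outflow tract whose strength scales with
  a pulmonary-regurgitation severity parameter ``s`` in [0, 1].  The inflow
  vortex is attenuated by the factor ``(1 - 0.5 s)``, modelling disruption
  of the inflow ring vortex by the regurgitant jet.  Gaussian velocity
  noise (scaled to venc) and a smooth static background phase offset can be
  superimposed; a static-tissue slab is provided for background correction.
* ``make_cohort`` — synthetic per-subject tables whose flow metrics and
  clinical covariates are driven by ``s`` through a linear effect model,
  emulating the statistical structure of a mixed cohort of repaired
  tetralogy-of-Fallot patients (severity bands on the regurgitant
  fraction), shunt-driven RV dilation and normal controls.

Everything is deterministic under the provided seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import AcquisitionMeta, Landmarks, SegmentationMask, VelocityField4D
from .hemodynamics import BLOOD_VISCOSITY_PA_S, PhaseWindows
from .regions import REGION_NAMES, build_planes, divide_rv

__all__ = [
    "GridSpec", "PhantomSpec", "CohortSpec", "RVPhantom",
    "make_analytic_field", "make_rv_phantom", "make_cohort",
    "make_correlated_pairs", "GROUPS",
]

GROUPS = ("severe_pr", "moderate_pr", "mild_pr", "rv_dilation", "control")

# Lamb-Oseen constant: u_theta peaks at d = r_c when the exponent carries alpha
_ALPHA = 1.2564312086261697


@dataclass
class GridSpec:
    """Regular voxel grid for analytic phantoms."""

    shape: tuple[int, int, int] = (32, 32, 32)   # (nz, ny, nx)
    spacing: float | tuple[float, float, float] = 1.0  # mm
    n_phases: int = 4
    rr_interval: float = 800.0   # ms
    venc: float = 2.5            # m/s

    def spacing3(self) -> np.ndarray:
        s = self.spacing
        return np.asarray(s if np.ndim(s) else (s, s, s), dtype=float)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing3()
        z = np.arange(nz) * dz
        y = np.arange(ny) * dy
        x = np.arange(nx) * dx
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        return X, Y, Z

    def phase_times(self) -> np.ndarray:
        dt = self.rr_interval / self.n_phases
        return (np.arange(self.n_phases) + 0.5) * dt


def _field_from_u(u: np.ndarray, grid: GridSpec) -> VelocityField4D:
    v = np.broadcast_to(u, (grid.n_phases,) + u.shape).copy()
    return VelocityField4D(
        velocities=v, spacing=grid.spacing3(), phase_times=grid.phase_times(),
        venc=grid.venc, rr_interval=grid.rr_interval,
    )


def _mask_obj(mask: np.ndarray, grid: GridSpec, name: str = "REGION") -> SegmentationMask:
    return SegmentationMask(labels=mask.astype(np.int32), label_names={1: name},
                            spacing=grid.spacing3())


# ---------------------------------------------------------------------------
# analytic flows
# ---------------------------------------------------------------------------

def make_analytic_field(kind: str, params: dict, grid: GridSpec
                        ) -> tuple[VelocityField4D, SegmentationMask, dict]:
    """Build a time-constant analytic flow replicated over the cardiac phases.

    Returns ``(field, mask, truth)`` where ``truth`` holds the closed-form
    normalized vorticity (1/s) and viscous energy loss (mW) where available,
    plus analytic per-point formulas for spatially varying fields.
    """
    X, Y, Z = grid.coords()
    nz, ny, nx = grid.shape
    dz, dy, dx = grid.spacing3()
    cx = (nx - 1) * dx / 2.0
    cy = (ny - 1) * dy / 2.0
    cz = (nz - 1) * dz / 2.0
    u = np.zeros(grid.shape + (3,))
    truth: dict = {"kind": kind, "params": dict(params)}

    if kind == "uniform":
        vec = np.asarray(params.get("u", (0.1, 0.0, 0.0)), dtype=float)
        u[...] = vec
        mask = np.ones(grid.shape, dtype=bool)
        truth.update(omega_norm_per_s=0.0, vel_mw=0.0)

    elif kind == "rigid_rotation":
        om = float(params["omega_rad_s"])      # rotation rate about z
        radius = float(params.get("radius_mm", min(cx, cy, cz) * 0.8))
        # u = Omega x r, in m/s with r in m
        u[..., 0] = -om * (Y - cy) * 1e-3
        u[..., 1] = om * (X - cx) * 1e-3
        r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        mask = r2 <= radius ** 2
        truth.update(omega_norm_per_s=2.0 * om, vel_mw=0.0)

    elif kind == "poiseuille":
        U = float(params["U"])                 # centreline velocity m/s
        R = float(params["R_mm"])              # tube radius mm
        L = float(params["L_mm"])              # tube length mm
        mu = float(params.get("mu", BLOOD_VISCOSITY_PA_S))
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        inside_r = r2 <= R ** 2
        z0 = cz - L / 2.0
        inside_z = (Z >= z0) & (Z < z0 + L)
        mask = inside_r & inside_z
        u[..., 2] = np.where(inside_r, U * (1.0 - r2 / R ** 2), 0.0)
        # closed form: VEL = 2 pi mu U^2 L  (SI) -> mW
        truth.update(vel_mw=2.0 * np.pi * mu * U ** 2 * (L * 1e-3) * 1e3,
                     mu=mu)

    elif kind == "lamb_oseen":
        gamma = float(params["gamma_m2_s"])    # circulation m^2/s
        rc = float(params["rc_mm"])            # core radius mm
        R = float(params.get("radius_mm", min(cx, cy) * 0.9))
        r2_mm = (X - cx) ** 2 + (Y - cy) ** 2
        r_m = np.sqrt(r2_mm) * 1e-3
        rc_m = rc * 1e-3
        with np.errstate(divide="ignore", invalid="ignore"):
            utheta = gamma / (2.0 * np.pi * r_m) * (1.0 - np.exp(-r2_mm / rc ** 2))
        utheta = np.nan_to_num(utheta)
        r_safe = np.where(r_m > 0, r_m, 1.0)
        u[..., 0] = -utheta * (Y - cy) * 1e-3 / r_safe
        u[..., 1] = utheta * (X - cx) * 1e-3 / r_safe
        mask = r2_mm <= R ** 2
        truth.update(
            omega_z_analytic=lambda r_mm: gamma / (np.pi * rc_m ** 2)
            * np.exp(-np.asarray(r_mm) ** 2 / rc ** 2),
            center_mm=(cx, cy),
        )

    elif kind == "ring_vortex":
        u = _ring_vortex_velocity(
            X, Y, Z,
            center=np.asarray(params.get("center_mm", (cx, cy, cz))),
            ring_radius=float(params["ring_radius_mm"]),
            rc=float(params["rc_mm"]),
            u_peak=float(params["u_peak"]),
        )
        mask = np.ones(grid.shape, dtype=bool)
        truth.update(note="ring vortex: numeric ground truth only")

    else:
        raise ValueError(f"unknown analytic field kind {kind!r}")

    return _field_from_u(u, grid), _mask_obj(mask, grid), truth


def _lamb_oseen_profile(d_mm: np.ndarray, rc_mm: float) -> np.ndarray:
    """Tangential speed profile normalized to peak 1 at d = rc."""
    d = np.where(d_mm > 1e-9, d_mm, 1e-9)
    g = (rc_mm / d) * (1.0 - np.exp(-_ALPHA * d ** 2 / rc_mm ** 2))
    return g / (1.0 - np.exp(-_ALPHA))


def _ring_vortex_velocity(X, Y, Z, center, ring_radius, rc, u_peak) -> np.ndarray:
    """Velocity of a toroidal vortex: a Lamb-Oseen cross-section swept
    around a circle of radius ``ring_radius`` about the z axis through
    ``center``.  Peak swirl speed in the (rho, z) plane is ``u_peak``."""
    dxp = X - center[0]
    dyp = Y - center[1]
    rho = np.sqrt(dxp ** 2 + dyp ** 2)
    drho = rho - ring_radius
    dz = Z - center[2]
    d = np.sqrt(drho ** 2 + dz ** 2)
    q = u_peak * _lamb_oseen_profile(d, rc)
    d_safe = np.where(d > 1e-9, d, 1.0)
    # tangent to the circle around the core in the (rho, z) half-plane
    u_rho = -dz / d_safe * q
    u_z = drho / d_safe * q
    rho_safe = np.where(rho > 1e-9, rho, 1.0)
    u = np.zeros(X.shape + (3,))
    u[..., 0] = u_rho * dxp / rho_safe
    u[..., 1] = u_rho * dyp / rho_safe
    u[..., 2] = u_z
    return u


# ---------------------------------------------------------------------------
# RV-like phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the RV-like phantom.

    ``pr_severity`` (s) is the single disease dial: the diastolic
    regurgitant jet scales with ``outflow_amplitude * s`` while the inflow
    ring vortex is attenuated by ``(1 - 0.5 s)``.
    """

    shape: tuple[int, int, int] = (48, 32, 32)    # (nz, ny, nx)
    spacing: float = 2.0                          # mm
    n_phases: int = 20
    rr_interval: float = 800.0                    # ms
    venc: float = 2.5                             # m/s
    pr_severity: float = 0.0                      # s in [0, 1]
    inflow_amplitude: float = 0.8                 # m/s, peak inflow-vortex swirl
    outflow_amplitude: float = 1.0                # m/s, peak outflow-jet speed
    noise_sd: float = 0.0                         # fraction of venc
    background_offset: dict | None = None         # {"constant": (3,), "linear": (3,3) per mm}
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pr_severity <= 1.0):
            raise ValueError("pr_severity must lie in [0, 1]")
        if not (0.0 <= self.noise_sd <= 1.0):
            raise ValueError("noise_sd must lie in [0, 1]")
        if not (0 < self.inflow_amplitude < self.venc
                and 0 < self.outflow_amplitude < self.venc):
            raise ValueError("amplitudes must be positive and below venc")


@dataclass
class RVPhantom:
    field: VelocityField4D
    rv_mask: SegmentationMask
    regions: SegmentationMask
    static_mask: SegmentationMask
    landmarks: Landmarks
    windows: PhaseWindows
    meta: AcquisitionMeta
    truth: dict = dc_field(default_factory=dict)


def _prune_orphan_voxels(mask: np.ndarray) -> np.ndarray:
    """Iteratively drop voxels with no in-mask 6-neighbour along some axis
    (one-voxel spurs on the discretized surface), so every mask voxel
    supports a finite-difference stencil in every direction."""
    m = mask.copy()
    while True:
        ok = np.ones_like(m)
        for ax in range(3):
            fwd = np.zeros_like(m)
            bwd = np.zeros_like(m)
            sl_f = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_f[ax] = slice(None, -1)
            sl_b[ax] = slice(1, None)
            fwd[tuple(sl_f)] = m[tuple(sl_b)]
            bwd[tuple(sl_b)] = m[tuple(sl_f)]
            ok &= fwd | bwd
        new = m & ok
        if np.array_equal(new, m):
            return new
        m = new


def _gauss_jet(X, Y, Z, p0, p1, width, amp, swirl_ratio=0.0) -> np.ndarray:
    """Confined jet along the segment p0->p1: axial Gaussian profile of
    1/e-width ``width`` mm plus an optional azimuthal swirl component."""
    a = p1 - p0
    L = np.linalg.norm(a)
    a = a / L
    px = X - p0[0]
    py = Y - p0[1]
    pz = Z - p0[2]
    t = px * a[0] + py * a[1] + pz * a[2]
    rx = px - t * a[0]
    ry = py - t * a[1]
    rz = pz - t * a[2]
    r = np.sqrt(rx ** 2 + ry ** 2 + rz ** 2)
    end_fall = np.exp(-(np.maximum(0.0, -t) ** 2 + np.maximum(0.0, t - L) ** 2) / 8.0 ** 2)
    profile = amp * np.exp(-r ** 2 / width ** 2) * end_fall
    u = np.zeros(X.shape + (3,))
    for c in range(3):
        u[..., c] = profile * a[c]
    if swirl_ratio:
        r_safe = np.where(r > 1e-9, r, 1.0)
        # azimuthal direction a x r_hat
        ex = (a[1] * rz - a[2] * ry) / r_safe
        ey = (a[2] * rx - a[0] * rz) / r_safe
        ez = (a[0] * ry - a[1] * rx) / r_safe
        sw = abs(amp) * swirl_ratio * (r / width) * np.exp(-r ** 2 / width ** 2) * end_fall
        u[..., 0] += sw * ex
        u[..., 1] += sw * ey
        u[..., 2] += sw * ez
    return u


def make_rv_phantom(spec: PhantomSpec) -> RVPhantom:
    """Generate the RV-like phantom (field, masks, landmarks, windows).

    Geometry (mm, 2 mm voxels by default): an ellipsoidal RV body whose long
    axis runs along z, with a tubular outflow tract rising obliquely from
    the body to a pulmonary-valve marker.  Landmarks are placed so the
    standard two-plane division yields non-empty RVOT / inflow / apex
    regions.  Systole carries a forward outflow jet; diastole carries the
    inflow ring vortex and, for s > 0, the regurgitant swirling jet.
    """
    nz, ny, nx = spec.shape
    grid = GridSpec(shape=spec.shape, spacing=spec.spacing,
                    n_phases=spec.n_phases, rr_interval=spec.rr_interval,
                    venc=spec.venc)
    X, Y, Z = grid.coords()
    sp3 = grid.spacing3()

    # --- anatomy ----------------------------------------------------------
    body_center = np.array([26.0, 31.0, 34.0])
    body_semi = np.array([20.0, 20.0, 28.0])
    tube_p0 = np.array([40.0, 31.0, 50.0])
    tube_p1 = np.array([48.0, 31.0, 86.0])
    tube_radius = 9.0

    body = (((X - body_center[0]) / body_semi[0]) ** 2
            + ((Y - body_center[1]) / body_semi[1]) ** 2
            + ((Z - body_center[2]) / body_semi[2]) ** 2) <= 1.0
    a = tube_p1 - tube_p0
    L = np.linalg.norm(a)
    ah = a / L
    t = (X - tube_p0[0]) * ah[0] + (Y - tube_p0[1]) * ah[1] + (Z - tube_p0[2]) * ah[2]
    tcl = np.clip(t, 0.0, L)
    dist2 = ((X - (tube_p0[0] + tcl * ah[0])) ** 2
             + (Y - (tube_p0[1] + tcl * ah[1])) ** 2
             + (Z - (tube_p0[2] + tcl * ah[2])) ** 2)
    tube = dist2 <= tube_radius ** 2
    rv = _prune_orphan_voxels(body | tube)

    landmarks = Landmarks(
        commissure_point=np.array([38.0, 31.0, 52.0]),
        four_chamber_normal=np.array([0.8, 0.0, 0.6]) / np.linalg.norm([0.8, 0.0, 0.6]),
        tricuspid_centroid=np.array([26.0, 31.0, 58.0]),
        apex_point=np.array([26.0, 31.0, 10.0]),
        pv_centroid=tube_p1.copy(),
    )

    rv_mask = SegmentationMask(labels=rv.astype(np.int32), label_names={1: "RV"},
                               spacing=sp3)
    planes = build_planes(landmarks)
    regions, _vols = divide_rv(rv_mask, planes, landmarks)

    static = np.zeros(spec.shape, dtype=np.int32)
    static[:, :3, :] = 1  # slab of presumed-stationary tissue away from the RV
    static_mask = SegmentationMask(labels=static, label_names={1: "STATIC"},
                                   spacing=sp3)

    # --- flow -------------------------------------------------------------
    s = spec.pr_severity
    n_sys = max(2, int(round(0.4 * spec.n_phases)))
    windows = PhaseWindows(systole=(0, n_sys - 1),
                           diastole=(n_sys, spec.n_phases - 1))

    u_sys = _gauss_jet(X, Y, Z, tube_p0, tube_p1, width=6.0,
                       amp=spec.outflow_amplitude)
    u_ring = _ring_vortex_velocity(
        X, Y, Z, center=np.array([26.0, 31.0, 48.0]),
        ring_radius=11.0, rc=4.5,
        u_peak=spec.inflow_amplitude * (1.0 - 0.5 * s),
    )
    u_regurg = _gauss_jet(X, Y, Z, tube_p1, tube_p0, width=5.0,
                          amp=spec.outflow_amplitude * s, swirl_ratio=1.0) \
        if s > 0 else np.zeros(spec.shape + (3,))
    u_dia = u_ring + u_regurg

    for name, u in (("systolic", u_sys), ("diastolic", u_dia)):
        vmax = float(np.linalg.norm(u[rv], axis=-1).max()) if rv.any() else 0.0
        if vmax > spec.venc:
            raise ValueError(
                f"{name} phantom speed {vmax:.2f} m/s exceeds venc {spec.venc}"
            )

    v = np.zeros((spec.n_phases,) + spec.shape + (3,))
    rv4 = rv[..., None]
    for p in range(spec.n_phases):
        if p < n_sys:
            env = np.sin(np.pi * (p + 0.5) / n_sys)
            v[p] = np.where(rv4, env * u_sys, 0.0)
        else:
            j = p - n_sys
            n_dia = spec.n_phases - n_sys
            env = np.sin(np.pi * (j + 0.5) / n_dia)
            v[p] = np.where(rv4, env * u_dia, 0.0)

    # static background phase offset (smooth, phase-independent)
    if spec.background_offset:
        const = np.asarray(spec.background_offset.get("constant", np.zeros(3)), float)
        lin = np.asarray(spec.background_offset.get("linear", np.zeros((3, 3))), float)
        for c in range(3):
            off = const[c] + lin[c, 0] * X + lin[c, 1] * Y + lin[c, 2] * Z
            v[..., c] += off[None, ...]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd * spec.venc, size=v.shape)

    fld = VelocityField4D(velocities=v, spacing=sp3, phase_times=grid.phase_times(),
                         venc=spec.venc, rr_interval=spec.rr_interval)
    meta = AcquisitionMeta(subject_id=f"phantom_s{s:.2f}",
                           systole_phase_range=windows.systole,
                           diastole_phase_range=windows.diastole,
                           static_tissue_label=1)
    truth = {
        "pr_severity": s,
        "windows": windows,
        "inflow_vortex_peak_m_s": spec.inflow_amplitude * (1.0 - 0.5 * s),
        "regurgitant_jet_peak_m_s": spec.outflow_amplitude * s,
        "outflow_jet_peak_m_s": spec.outflow_amplitude,
        "tube_axis": (tube_p0, tube_p1),
    }
    return RVPhantom(field=fld, rv_mask=rv_mask, regions=regions,
                     static_mask=static_mask, landmarks=landmarks,
                     windows=windows, meta=meta, truth=truth)


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

# severity bands: the regurgitant fraction is PR% = 60 s, so s > 2/3 is
# severe (PR > 40%), 1/3..2/3 moderate (20-40%), below mild (< 20%).
_S_BANDS = {
    "severe_pr": (0.68, 1.00),
    "moderate_pr": (0.34, 0.66),
    "mild_pr": (0.01, 0.32),
    "rv_dilation": (0.0, 0.02),
    "control": (0.0, 0.02),
}

# linear effect model: covariate -> (intercept, slope on s, noise SD);
# magnitudes chosen to resemble a mixed congenital cohort.
DEFAULT_EFFECTS = {
    "rvedvi": (95.0, 55.0, 15.0),      # mL/m^2
    "rvesvi": (38.0, 35.0, 9.0),       # mL/m^2
    "rvef": (60.0, -11.0, 4.0),        # %
    "qrs_ms": (100.0, 55.0, 12.0),
    "vo2max": (42.0, -12.0, 5.0),      # mL/kg/min
    "pct_predicted_vo2max": (95.0, -25.0, 8.0),
}

# shunt-driven dilation offsets for the RV-dilation group (dilated RV at
# near-zero regurgitant fraction)
_RVD_OFFSETS = {"rvedvi": 45.0, "rvesvi": 20.0}

# flow-metric response curves: metric -> (intercept, slope on s, noise SD)
DEFAULT_METRIC_EFFECTS = {
    "omega_rvot_systole": (95.0, 0.0, 12.0),
    "omega_rvot_diastole": (50.0, 55.0, 10.0),
    "omega_inflow_diastole": (58.0, -8.0, 9.0),
    "vel_rvot_systole": (2.0, 0.0, 0.4),
    "vel_rvot_diastole": (0.5, 2.0, 0.3),
}
_RVD_METRIC_OFFSETS = {"omega_inflow_diastole": 20.0}


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``n_per_group`` defaults to the study's group sizes (20 severe, 18
    moderate, 20 mild regurgitation, 28 RV dilation, 12 controls).
    ``target_r`` optionally maps a covariate or metric column to a desired
    population Pearson correlation with the severity s; the column is then
    generated as a linear response with the noise SD solved from the
    empirical spread of s.
    """

    n_per_group: dict[str, int] = dc_field(default_factory=lambda: {
        "severe_pr": 20, "moderate_pr": 18, "mild_pr": 20,
        "rv_dilation": 28, "control": 12,
    })
    effects: dict[str, tuple[float, float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    metric_effects: dict[str, tuple[float, float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_METRIC_EFFECTS))
    target_r: dict[str, float] = dc_field(default_factory=dict)
    mode: str = "fast"            # "fast": analytic response curves; "full": run phantoms
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 3:
                raise ValueError(f"group {g} needs n >= 3 for ANOVA, got {n}")
        for name, (_, _, sd) in {**self.effects, **self.metric_effects}.items():
            if sd < 0:
                raise ValueError(f"negative noise SD for {name}")
        if self.mode not in ("fast", "full"):
            raise ValueError("mode must be 'fast' or 'full'")


def _linear_response(s: np.ndarray, coeffs, rng, target_r: float | None) -> np.ndarray:
    b0, b1, sd = coeffs
    if target_r is not None:
        if not (0 < abs(target_r) <= 1):
            raise ValueError("target correlation must be in (0, 1]")
        if b1 == 0:
            b1 = 1.0
        spread = float(np.std(s))
        sd = 0.0 if abs(target_r) == 1 else abs(b1) * spread * np.sqrt(1.0 / target_r ** 2 - 1.0)
        b1 = abs(b1) * np.sign(target_r)
    y = b0 + b1 * s
    if sd > 0:
        y = y + rng.normal(0.0, sd, size=s.shape)
    return y


def make_cohort(cspec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table (one row per subject).

    Fast mode generates flow metrics from the analytic response curves;
    full mode runs each subject's phantom through the measurement pipeline
    (slow; intended for small n).  Quotients are always computed from the
    generated peak metrics so the defining ratios hold by construction.
    Exercise-test covariates are present for roughly half of the repaired
    patients and missing elsewhere, mirroring listwise availability.
    """
    rng = np.random.default_rng(cspec.seed)
    rows = []
    sid = 0
    for group in GROUPS:
        n = cspec.n_per_group.get(group, 0)
        lo, hi = _S_BANDS[group]
        for _ in range(n):
            s = float(rng.uniform(lo, hi))
            rows.append({"subject_id": f"S{sid:03d}", "group": group, "s": s})
            sid += 1
    df = pd.DataFrame(rows)
    s = df["s"].to_numpy()

    # regurgitant fraction defines the severity bands exactly
    df["pr_pct"] = 60.0 * s

    for name, coeffs in cspec.effects.items():
        y = _linear_response(s, coeffs, rng, cspec.target_r.get(name))
        off = _RVD_OFFSETS.get(name, 0.0)
        if off:
            y = y + off * (df["group"] == "rv_dilation").to_numpy()
        df[name] = y

    if cspec.mode == "fast":
        for name, coeffs in cspec.metric_effects.items():
            y = _linear_response(s, coeffs, rng, cspec.target_r.get(name))
            off = _RVD_METRIC_OFFSETS.get(name, 0.0)
            if off:
                y = y + off * (df["group"] == "rv_dilation").to_numpy()
            floor = 0.05 if name.startswith("vel") else 1.0
            df[name] = np.maximum(y, floor)
    else:
        from .pipeline import measure_phantom_subject
        mets = []
        for i, row in df.iterrows():
            m = measure_phantom_subject(
                PhantomSpec(pr_severity=min(row["s"], 1.0),
                            seed=int(rng.integers(0, 2**31 - 1))))
            mets.append(m.to_dict())
        md = pd.DataFrame(mets, index=df.index)
        df["omega_rvot_systole"] = md["omega_rvot_systole_per_s"]
        df["omega_rvot_diastole"] = md["omega_rvot_diastole_per_s"]
        df["omega_inflow_diastole"] = md["omega_inflow_diastole_per_s"]
        df["vel_rvot_systole"] = md["vel_rvot_systole_mw"]
        df["vel_rvot_diastole"] = md["vel_rvot_diastole_mw"]

    have_omega = {"omega_rvot_diastole", "omega_inflow_diastole",
                  "omega_rvot_systole"} <= set(df.columns)
    if "rv_dvq" in cspec.target_r:
        df["rv_dvq"] = np.maximum(
            _linear_response(s, (0.85, 1.15, 0.15), rng, cspec.target_r["rv_dvq"]),
            0.05)
    elif have_omega:
        df["rv_dvq"] = df["omega_rvot_diastole"] / df["omega_inflow_diastole"]
    if have_omega:
        df["rvot_vq"] = df["omega_rvot_diastole"] / df["omega_rvot_systole"]
    if {"vel_rvot_diastole", "vel_rvot_systole"} <= set(df.columns):
        df["rvot_eq"] = df["vel_rvot_diastole"] / df["vel_rvot_systole"]

    # subgroup flags: primary patch repair and exercise-test availability
    is_tof = df["group"].isin(["severe_pr", "moderate_pr", "mild_pr"]).to_numpy()
    df["primary_repair"] = is_tof & (rng.uniform(size=len(df)) < 0.62)
    has_ex = is_tof & (rng.uniform(size=len(df)) < 0.53)
    for col in ("vo2max", "pct_predicted_vo2max"):
        df.loc[~has_ex, col] = np.nan
    return df


def make_correlated_pairs(r: float, n: int, rng: np.random.Generator,
                          loc=(0.0, 0.0), scale=(1.0, 1.0)) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs from a bivariate normal with population correlation r."""
    if not (-1.0 < r < 1.0):
        raise ValueError("r must lie strictly inside (-1, 1)")
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = r * z[:, 0] + np.sqrt(1.0 - r ** 2) * z[:, 1]
    return loc[0] + scale[0] * x, loc[1] + scale[1] * y
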