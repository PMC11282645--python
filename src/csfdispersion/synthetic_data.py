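"""Synthetic stand-in for the physical dispersion experiment.

This module plays the role of the bench: it simulates ground-truth 1D
solute transport in the CSF phantom under a lumbar injection protocol and
renders the dual-exposure camera frames that the quantification pipeline
consumes.

Transport model
---------------
The CSF space is collapsed to a 1D finite-volume grid with per-slice
volume V(z) and cross-sectional area A(z) = V(z)/dz.  The oscillatory
flow Q(t) has zero net component, so over the 30 s frame cadence its
contribution to transport is dispersive, not advective: the default
("cycle_averaged") mode models it as an effective axial dispersion

    D_eff(z) = D_mol + k * <|u(z,.)|> * h(z),

where u(z,t) = Q(t)/A(z) is the cross-section-averaged oscillatory
velocity, h(z) = sqrt(A(z)) a local hydraulic length scale, and k a
dimensionless dispersion factor calibrated once against the qualitative
arrival timing of a flushed lumbar injection (see docs/methods.md).  An
optional "resolved" mode advects with the instantaneous Q(t) directly and
uses molecular diffusivity only; it is a cross-check, not the default.

Slow net flows — the injected bolus and flush, CSF production and
absorption — are advective.  The domain is rigid, so the net volume input
leaves through the two domain ends in proportion to the end areas;
absorbed fluid carries the local tracer concentration, produced fluid is
tracer-free.  The scheme is conservative: injected tracer mass equals
domain mass plus cumulative absorbed and end-outflow mass at every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.linalg import solve_banded

from .geometry import VolumeProfile
from .waveform import FlowWaveform

__all__ = [
    "InjectionProtocol",
    "TransportParams",
    "ConcentrationField",
    "CameraConfig",
    "ImageStack",
    "DEFAULT_PROTOCOLS",
    "LOW_CAMERA",
    "HIGH_CAMERA",
    "simulate_transport",
    "injected_mass",
    "render_frames",
    "calibration_stacks",
    "protocols_from_csv",
    "protocols_to_csv",
]

# Default injection-site axial coordinates (mm, z<0 is spinal).  The L4/L5
# interspace sits near the caudal end of the canal; L3/L4 is one vertebral
# spacing (8 mm) cranial of it.  Both are free parameters of the phantom.
L4_L5_Z = -250.0
L3_L4_Z = -242.0
_SITE_Z = {"L4/L5": L4_L5_Z, "L3/L4": L3_L4_Z}


@dataclass(frozen=True)
class InjectionProtocol:
    """One lumbar injection protocol: a tracer bolus, optionally flushed.

    The flush is tracer-free fluid pushed through the same needle after the
    bolus.  Within a study the tracer dose (concentration x bolus volume)
    is held constant across protocols.
    """

    name: str
    site_z: float  # mm
    tracer_concentration: float  # uM
    bolus_volume: float  # ml
    bolus_rate: float  # ml/min
    flush_volume: float = 0.0  # ml
    flush_rate: float = 0.0  # ml/min

    def __post_init__(self) -> None:
        if self.tracer_concentration <= 0:
            raise ValueError("tracer concentration must be positive")
        if self.bolus_volume < 0 or self.flush_volume < 0:
            raise ValueError("volumes must be non-negative")
        if self.bolus_volume > 0 and self.bolus_rate <= 0:
            raise ValueError("bolus rate must be positive when bolus volume > 0")
        if self.flush_volume > 0 and self.flush_rate <= 0:
            raise ValueError("flush rate must be positive when flush volume > 0")


def _p(name, site, conc, bv, br, fv=0.0, fr=0.0) -> InjectionProtocol:
    return InjectionProtocol(name, _SITE_Z[site], conc, bv, br, fv, fr)


#: The eight-protocol study design: five single-parameter contrasts over
#: injection location, bolus volume/rate and flush volume/rate, all at a
#: constant tracer dose of 165.5 uM*ml.
DEFAULT_PROTOCOLS: dict[str, InjectionProtocol] = {
    p.name: p
    for p in [
        _p("2NHP2", "L4/L5", 331.0, 0.5, 1.0, 1.5, 1.0),
        _p("3G1", "L3/L4", 331.0, 0.5, 1.0, 1.5, 1.0),
        _p("1NHP1", "L3/L4", 165.5, 1.0, 1.0),
        _p("3G2", "L3/L4", 82.75, 2.0, 1.0),
        _p("1NHP3", "L4/L5", 165.5, 1.0, 0.1),
        _p("1NHP2", "L4/L5", 165.5, 1.0, 1.0),
        _p("2G2", "L4/L5", 165.5, 1.0, 1.0, 1.5, 1.0),
        _p("5NHP1", "L4/L5", 165.5, 1.0, 1.0, 1.5, 0.5),
    ]
}

_PROTOCOL_COLUMNS = [
    "name",
    "location",
    "tracer_concentration_uM",
    "bolus_volume_ml",
    "bolus_rate_ml_min",
    "flush_volume_ml",
    "flush_rate_ml_min",
]


def protocols_to_csv(protocols: dict[str, InjectionProtocol], path) -> None:
    site_names = {v: k for k, v in _SITE_Z.items()}
    rows = [
        {
            "name": p.name,
            "location": site_names.get(p.site_z, f"z={p.site_z}"),
            "tracer_concentration_uM": p.tracer_concentration,
            "bolus_volume_ml": p.bolus_volume,
            "bolus_rate_ml_min": p.bolus_rate,
            "flush_volume_ml": p.flush_volume,
            "flush_rate_ml_min": p.flush_rate,
        }
        for p in protocols.values()
    ]
    pd.DataFrame(rows, columns=_PROTOCOL_COLUMNS).to_csv(path, index=False)


def protocols_from_csv(path) -> dict[str, InjectionProtocol]:
    df = pd.read_csv(path)
    missing = set(_PROTOCOL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"protocol CSV missing columns: {sorted(missing)}")
    out: dict[str, InjectionProtocol] = {}
    for row in df.itertuples(index=False):
        loc = str(row.location)
        site = _SITE_Z.get(loc)
        if site is None:
            if not loc.startswith("z="):
                raise ValueError(f"unknown injection location {loc!r}")
            site = float(loc[2:])
        out[str(row.name)] = InjectionProtocol(
            name=str(row.name),
            site_z=site,
            tracer_concentration=float(row.tracer_concentration_uM),
            bolus_volume=float(row.bolus_volume_ml),
            bolus_rate=float(row.bolus_rate_ml_min),
            flush_volume=float(row.flush_volume_ml),
            flush_rate=float(row.flush_rate_ml_min),
        )
    return out


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of the 1D transport model.

    ``dispersion_factor`` multiplies the oscillatory enhancement
    <|u|> * sqrt(A); its default was calibrated once so that a flushed
    L4/L5 injection first delivers >= 1 uM to the foramen magnum between
    15 and 45 min, and is frozen thereafter.
    """

    molecular_diffusivity: float = 5e-4  # mm^2/s, small-molecule in water
    dispersion_factor: float = 0.006
    production_rate: float = 0.018  # ml/min, tracer-free inflow
    absorption_rate: float = 0.018  # ml/min, bulk fluid removal
    production_site_z: float = 40.0  # mm, ventricular (cranial) port
    absorption_site_z: float = 50.0  # mm, intracranial port
    mode: str = "cycle_averaged"  # or "resolved"

    def __post_init__(self) -> None:
        if self.molecular_diffusivity <= 0:
            raise ValueError("molecular diffusivity must be positive")
        if self.dispersion_factor < 0:
            raise ValueError("dispersion factor must be non-negative")
        if self.production_rate < 0 or self.absorption_rate < 0:
            raise ValueError("production/absorption rates must be non-negative")
        if self.mode not in ("cycle_averaged", "resolved"):
            raise ValueError("mode must be 'cycle_averaged' or 'resolved'")


@dataclass(frozen=True)
class ConcentrationField:
    """Ground-truth tracer concentration C(z, t) in uM.

    ``c`` has shape (n_slices, n_frames) on the geometry's z grid and a
    uniform frame-time grid.  Also carries the simulator's mass budget per
    frame for conservation checks.
    """

    z_centers: np.ndarray
    t_frames: np.ndarray  # s
    c: np.ndarray  # uM
    injected_mass_per_frame: np.ndarray = field(repr=False, default=None)  # uM*ml
    absorbed_mass_per_frame: np.ndarray = field(repr=False, default=None)
    outflow_mass_per_frame: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.c.shape != (self.z_centers.size, self.t_frames.size):
            raise ValueError("c must have shape (n_slices, n_frames)")
        if np.any(self.c < -1e-9):
            raise ValueError("concentration field has negative entries")

    def frame_index(self, at_time_s: float) -> int:
        return int(np.argmin(np.abs(self.t_frames - at_time_s)))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.c, index=self.z_centers, columns=self.t_frames
        ).to_csv(path, index_label="z_mm")


def injected_mass(protocol: InjectionProtocol) -> float:
    """Injected tracer mass in uM*ml (the flush carries no tracer)."""
    return protocol.tracer_concentration * protocol.bolus_volume


def _stability_dt(volumes: np.ndarray, face_flux_max: np.ndarray,
                  sink_max: np.ndarray) -> float:
    """Largest stable dt for the explicit upwind drift step."""
    out_max = face_flux_max[1:] + face_flux_max[:-1] + sink_max
    with np.errstate(divide="ignore"):
        bounds = np.where(out_max > 0, volumes / np.maximum(out_max, 1e-300), np.inf)
    return float(np.min(bounds))


def simulate_transport(
    geometry: VolumeProfile,
    waveform: FlowWaveform,
    protocol: InjectionProtocol,
    params: TransportParams | None = None,
    duration: float = 3 * 3600.0,
    dt: float = 0.5,
    frame_interval: float = 30.0,
    injection_start: float = 0.0,
    initial_c: np.ndarray | None = None,
) -> ConcentrationField:
    """Simulate 1D tracer transport and sample it at the frame cadence.

    Operator-split finite-volume scheme on the geometry's 1 mm grid:
    explicit first-order upwind for the slow net drift (injection,
    production, absorption, end outflow) with a CFL guard, then
    unconditionally stable backward-Euler diffusion with the effective
    dispersion coefficient.  Boundary faces are closed to diffusion; net
    volume leaves through the two end faces in proportion to end areas.
    """
    params = params or TransportParams()
    z = geometry.z_centers
    dz = geometry.slice_thickness
    vols = geometry.volumes.copy()
    # guard against zero-volume cells (areas appear in denominators)
    vols = np.maximum(vols, 1e-9)
    areas = vols / dz  # ml/mm
    n = z.size
    z_lo, z_hi = z[0] - dz / 2, z[-1] + dz / 2
    for label, site in [
        ("injection", protocol.site_z),
        ("production", params.production_site_z),
        ("absorption", params.absorption_site_z),
    ]:
        if not (z_lo <= site <= z_hi):
            raise ValueError(f"{label} site z={site} mm outside domain "
                             f"[{z_lo}, {z_hi}] mm")
    i_inj = int(np.argmin(np.abs(z - protocol.site_z)))
    i_prod = int(np.argmin(np.abs(z - params.production_site_z)))
    i_abs = int(np.argmin(np.abs(z - params.absorption_site_z)))

    # effective dispersion at interior faces
    if params.mode == "cycle_averaged":
        mean_abs_q = float(np.mean(np.abs(waveform.q)))  # ml/s
        u_mag = mean_abs_q / areas  # mm/s
        h = np.sqrt(1000.0 * areas)  # hydraulic length ~ sqrt(A [mm^2]), mm
        d_eff = params.molecular_diffusivity + params.dispersion_factor * u_mag * h
    else:
        d_eff = np.full(n, params.molecular_diffusivity)
    d_face = 0.5 * (d_eff[:-1] + d_eff[1:])
    a_face = 0.5 * (areas[:-1] + areas[1:])
    # diffusion conductance per interior face, ml/s
    g_face = d_face * a_face / dz

    # backward-Euler diffusion matrix in banded form (built once; dt fixed)
    lower = np.zeros(n)
    upper = np.zeros(n)
    diag = vols / dt
    diag[:-1] += g_face
    diag[1:] += g_face
    upper[1:] = -g_face
    lower[:-1] = -g_face
    ab = np.vstack([upper, diag, lower])

    prod = params.production_rate / 60.0  # ml/s
    absr = params.absorption_rate / 60.0
    bolus_q = protocol.bolus_rate / 60.0 if protocol.bolus_volume > 0 else 0.0
    flush_q = protocol.flush_rate / 60.0 if protocol.flush_volume > 0 else 0.0
    t_bolus0 = injection_start
    t_bolus1 = t_bolus0 + (protocol.bolus_volume / bolus_q if bolus_q else 0.0)
    t_flush1 = t_bolus1 + (protocol.flush_volume / flush_q if flush_q else 0.0)

    a_ends = areas[0] + areas[-1]
    frac_lo = areas[0] / a_ends

    def _steady_faces(inj_q: float) -> np.ndarray:
        src_ = np.zeros(n)
        src_[i_inj] += inj_q
        src_[i_prod] += prod
        src_[i_abs] -= absr
        net = inj_q + prod - absr
        out_lo_ = max(net, 0.0) * frac_lo
        f = np.empty(n + 1)
        f[0] = -out_lo_
        np.cumsum(src_, out=f[1:])
        f[1:] -= out_lo_
        return f

    # CFL guard for the drift step: exact steady face fluxes per injection
    # regime (bolus / flush / neither), plus the oscillatory flow if resolved
    face_max = np.max(
        [np.abs(_steady_faces(q)) for q in (bolus_q, flush_q, 0.0)], axis=0
    )
    if params.mode == "resolved":
        face_max = face_max + np.max(np.abs(waveform.q))
    sink_max = np.zeros(n)
    sink_max[i_abs] += absr
    dt_max = _stability_dt(vols, face_max, sink_max)
    if dt > dt_max:
        raise ValueError(
            f"dt={dt} s unstable for the explicit drift step; "
            f"stability bound is dt <= {dt_max:.4g} s"
        )

    n_steps = int(round(duration / dt))
    stride = max(int(round(frame_interval / dt)), 1)
    n_frames = n_steps // stride + 1
    t_frames = np.arange(n_frames) * stride * dt

    if initial_c is not None:
        c = np.asarray(initial_c, dtype=float).copy()
        if c.shape != (n,):
            raise ValueError("initial_c must match the z grid")
        if np.any(c < 0):
            raise ValueError("initial_c must be non-negative")
    else:
        c = np.zeros(n)
    frames = np.zeros((n, n_frames))
    frames[:, 0] = c
    inj_cum = np.zeros(n_frames)
    abs_cum = np.zeros(n_frames)
    out_cum = np.zeros(n_frames)
    injected = 0.0
    absorbed = 0.0
    outflow = 0.0

    q_wave = None
    if params.mode == "resolved":
        # instantaneous oscillatory flow at step midpoints, periodic reuse
        t_mid = (np.arange(n_steps) + 0.5) * dt
        q_wave = np.interp(t_mid % waveform.duration, waveform.t, waveform.q)

    src = np.zeros(n)
    frame_ptr = 1
    for step in range(n_steps):
        t0 = step * dt
        # --- net fluid sources this step (ml/s) ---
        src[:] = 0.0
        inj_q = 0.0
        inj_c = 0.0
        if t_bolus0 <= t0 < t_bolus1:
            inj_q = bolus_q
            inj_c = protocol.tracer_concentration
        elif t_bolus1 <= t0 < t_flush1:
            inj_q = flush_q
        src[i_inj] += inj_q
        src[i_prod] += prod
        src[i_abs] -= absr
        net_in = inj_q + prod - absr
        out_lo = max(net_in, 0.0) * frac_lo
        out_hi = max(net_in, 0.0) * (1 - frac_lo)
        # face fluxes from continuity (positive = cranial); boundary faces
        # carry only the distributed end outflow
        face = np.empty(n + 1)
        face[0] = -out_lo
        np.cumsum(src, out=face[1:])
        face[1:] -= out_lo
        if q_wave is not None:
            face += q_wave[step]

        # --- explicit upwind drift ---
        interior = face[1:-1]
        up_c = np.where(interior >= 0, c[:-1], c[1:])
        adv = interior * up_c  # uM*ml/s through interior faces
        dm = np.zeros(n)
        dm[:-1] -= adv
        dm[1:] += adv
        # boundary faces: outflow carries local concentration; inflow (in
        # resolved mode the oscillatory flux) carries tracer-free fluid
        out_lo_flux = max(-face[0], 0.0) * c[0]
        out_hi_flux = max(face[-1], 0.0) * c[-1]
        dm[0] -= out_lo_flux
        dm[-1] -= out_hi_flux
        # injected tracer and absorbed fluid
        dm[i_inj] += inj_q * inj_c
        dm[i_abs] -= absr * c[i_abs]
        mass = vols * c + dm * dt
        injected += inj_q * inj_c * dt
        absorbed += absr * c[i_abs] * dt
        outflow += (out_lo_flux + out_hi_flux) * dt
        c = mass / vols

        # --- implicit diffusion ---
        c = solve_banded((1, 1), ab, vols * c / dt)
        np.clip(c, 0.0, None, out=c)

        if (step + 1) % stride == 0 and frame_ptr < n_frames:
            frames[:, frame_ptr] = c
            inj_cum[frame_ptr] = injected
            abs_cum[frame_ptr] = absorbed
            out_cum[frame_ptr] = outflow
            frame_ptr += 1

    return ConcentrationField(
        z_centers=z,
        t_frames=t_frames,
        c=frames,
        injected_mass_per_frame=inj_cum,
        absorbed_mass_per_frame=abs_cum,
        outflow_mass_per_frame=out_cum,
    )


# ---------------------------------------------------------------------------
# synthetic dual-exposure cameras


@dataclass(frozen=True)
class CameraConfig:
    """A linear synthetic camera with additive Gaussian noise and clipping.

    Row intensity = clip(offset + gain * C + N(0, noise_sd), 0, saturation).
    The low-exposure camera keeps the full 0-50 uM span unsaturated; the
    high-exposure camera saturates near 20 uM, trading range for
    sensitivity below the 10 uM exposure-merge threshold.
    """

    exposure_label: str  # "low" | "high"
    gain: float  # intensity per uM
    offset: float = 100.0  # background intensity
    saturation_level: float = 4095.0  # 12-bit full scale
    noise_sd: float = 4.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.saturation_level <= self.offset:
            raise ValueError("saturation level must exceed the offset")

    @property
    def saturation_concentration(self) -> float:
        """Concentration (uM) at which the mean response clips."""
        return (self.saturation_level - self.offset) / self.gain


LOW_CAMERA = CameraConfig("low", gain=72.0)  # unsaturated to ~55 uM
HIGH_CAMERA = CameraConfig("high", gain=200.0)  # saturates near 20 uM


@dataclass(frozen=True)
class ImageStack:
    """Frames from one camera: (n_frames, n_rows, n_cols) intensities."""

    frames: np.ndarray
    camera_label: str
    frame_interval: float = 30.0  # s

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, camera_label: str, frame_interval: float = 30.0):
        return cls(
            frames=np.asarray(tifffile.imread(path), dtype=float),
            camera_label=camera_label,
            frame_interval=frame_interval,
        )


def render_frames(
    field: ConcentrationField,
    geometry: VolumeProfile,
    camera: CameraConfig,
    seed: int | np.random.SeedSequence = 0,
    n_cols: int = 32,
    rows_per_slice: int = 1,
) -> ImageStack:
    """Render a ground-truth field through a synthetic camera.

    Each axial slice maps to ``rows_per_slice`` image rows whose pixels
    share the slice concentration; pixel noise is i.i.d. Gaussian and the
    result is deterministic for a fixed seed.
    """
    if field.z_centers.size != geometry.z_centers.size:
        raise ValueError("field and geometry z grids differ")
    rng = np.random.default_rng(seed)
    n_rows = field.z_centers.size * rows_per_slice
    n_frames = field.t_frames.size
    signal = camera.offset + camera.gain * np.repeat(field.c.T, rows_per_slice, axis=1)
    frames = signal[:, :, None] + rng.normal(
        0.0, camera.noise_sd, size=(n_frames, n_rows, n_cols)
    ) if camera.noise_sd > 0 else np.broadcast_to(
        signal[:, :, None], (n_frames, n_rows, n_cols)
    ).copy()
    np.clip(frames, 0.0, camera.saturation_level, out=frames)
    dt_frame = float(field.t_frames[1] - field.t_frames[0]) if n_frames > 1 else 30.0
    return ImageStack(frames=frames, camera_label=camera.exposure_label,
                      frame_interval=dt_frame)


def calibration_stacks(
    camera: CameraConfig,
    levels: np.ndarray,
    geometry: VolumeProfile,
    seed: int | np.random.SeedSequence = 0,
    n_cols: int = 32,
) -> tuple[list[ImageStack], np.ndarray]:
    """Render one uniform-concentration calibration frame per known level."""
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("calibration levels must be non-negative")
    if levels.size > 1 and np.any(np.diff(levels) <= 0):
        raise ValueError("calibration levels must be strictly increasing")
    seeds = np.random.SeedSequence(seed).spawn(levels.size) if isinstance(
        seed, int
    ) else seed.spawn(levels.size)
    stacks = []
    for level, s in zip(levels, seeds):
        uniform = ConcentrationField(
            z_centers=geometry.z_centers,
            t_frames=np.array([0.0]),
            c=np.full((geometry.z_centers.size, 1), level),
        )
        stacks.append(render_frames(uniform, geometry, camera, seed=s, n_cols=n_cols))
    return stacks, levels
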