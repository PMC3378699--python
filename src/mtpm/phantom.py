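"""Synthetic cine phase-contrast phantoms with analytic ground truth.

The cardiac phantom is a contracting, twisting, longitudinally moving
annulus (the left-ventricular wall in one short-axis slice) plus a small
static signal block standing in for the external agarose reference tube.
Its kinematics are smooth closed-form functions of time, so every derived
quantity of the analysis chain (voxel velocities, segmental time courses,
twist, torsion) has an exact reference value.

Kinematic model (period = one cardiac cycle, systolic fraction ``sf``):

* Wall radii: ``R(t) = R_ed - dR * s(t)`` for the endo- and epicardial
  borders, with ``s`` a raised-cosine pulse rising 0 -> 1 over systole and
  returning 1 -> 0 over diastole.  Endocardial excursion exceeds the
  epicardial one, so the wall thickens in systole as in vivo.
* Rotation: angular velocity with a linear transmural profile between
  ``omega_endo(t)`` and ``omega_epi(t)``; positive = clockwise in the
  foot-to-head view.  Its time course is a sine lobe over systole and a
  counter-lobe over diastole that returns the net rotation to zero
  (optionally piecewise-constant for closed-form checks).
* Longitudinal velocity ``vz(t)``: same lobe shape; positive = base to
  apex.

Signal model: tissue magnitude 1 (anti-aliased at the borders by
sub-voxel area weighting), exterior 0; the reference scan carries zero
phase, each motion-encoded scan carries ``-pi * v_axis / venc_axis`` so
that phase subtraction (reference minus encoded) reconstructs prescribed
positive velocities as positive.  A linear background phase plane,
emulating eddy-current offsets, may be added to the encoded scans only.
Complex Gaussian noise is seeded and reproducible.  K-space data are
produced by forward FFT of the image stacks.

A second generator provides the flow-tube used for in-silico flow-rate
validation (plug or parabolic profile, known volume flow).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
from scipy.integrate import quad

from .dataio import AcquisitionMeta, CineEncodingSet, LVSegmentation, \
    ccw_angle_deg
from .recon import fft2c

_SUPERSAMPLE = 4   # sub-voxel factor for anti-aliased magnitude borders


def _default_meta(slice_level: str = "mid", n_frames: int = 20,
                  matrix: int = 128) -> AcquisitionMeta:
    """Acquisition regime of the emulated scan: 25.6 mm FOV, 128 matrix,
    4.6 ms frame interval, venc 6 cm/s in-plane / 8 cm/s through-plane."""
    return AcquisitionMeta(fov_mm=25.6, matrix=matrix,
                           frame_interval_ms=4.6, n_frames=n_frames,
                           venc_inplane_cm_s=6.0, venc_through_cm_s=8.0,
                           slice_level=slice_level)


# per-slice kinematic defaults: (omega_endo, omega_epi) peak rad/s, vz peak
# cm/s, end-diastolic radii mm.  Signs follow the in vivo pattern: the base
# turns clockwise and the apex counterclockwise during systole, and the
# transmural profile is endocardium-heavier.  Amplitudes are sized to give
# peak mean radial velocities near +0.8 cm/s (systole) / -1.3 cm/s
# (diastole), twists near +2.5 deg (base), 0.4 deg (mid) and -2.6 deg
# (apex), i.e. the healthy-mouse regime.
_SLICE_KINEMATICS = {
    "basal": dict(omega_endo_peak_rad_s=1.55, omega_epi_peak_rad_s=1.00,
                  vz_peak_cm_s=1.0, r_endo_ed_mm=1.6, r_epi_ed_mm=2.6),
    "mid": dict(omega_endo_peak_rad_s=0.26, omega_epi_peak_rad_s=0.16,
                vz_peak_cm_s=0.6, r_endo_ed_mm=1.6, r_epi_ed_mm=2.6),
    "apical": dict(omega_endo_peak_rad_s=-1.60, omega_epi_peak_rad_s=-1.05,
                   vz_peak_cm_s=0.2, r_endo_ed_mm=1.0, r_epi_ed_mm=2.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinematics and acquisition model of the synthetic LV."""

    meta: AcquisitionMeta
    center_mm: tuple | None = None        # None -> FOV centre
    r_endo_ed_mm: float = 1.6
    r_epi_ed_mm: float = 2.6
    dr_endo_mm: float = 0.45              # end-diastole -> end-systole
    dr_epi_mm: float = 0.15
    systolic_fraction: float = 0.6
    omega_endo_peak_rad_s: float = 1.55
    omega_epi_peak_rad_s: float = 1.00
    omega_waveform: str = "sine"          # sine | constant
    vz_peak_cm_s: float = 1.0
    noise_sd: float = 0.05                # complex noise SD / tissue signal
    background_plane: tuple = (0.0, 0.0, 0.0)   # rad, rad/mm, rad/mm
    reference_block_mm: tuple = (19.0, 3.0, 3.5, 3.5)   # x0, y0, w, h
    artifact_sector: tuple | None = None  # (start_deg, end_deg, phase_sd)
    seed: int = 0

    def __post_init__(self):
        if self.r_epi_ed_mm <= self.r_endo_ed_mm:
            raise ValueError("epicardial radius must exceed endocardial")
        if (self.r_epi_ed_mm - self.dr_epi_mm
                <= self.r_endo_ed_mm - self.dr_endo_mm):
            raise ValueError("wall collapses at end-systole")
        if self.r_endo_ed_mm - self.dr_endo_mm <= 0:
            raise ValueError("endocardial radius must stay positive")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic_fraction must be in (0, 1)")
        if self.omega_waveform not in ("sine", "constant"):
            raise ValueError("omega_waveform must be sine|constant")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def default(cls, slice_level: str = "mid", n_frames: int = 20,
                noise_sd: float = 0.05, seed: int = 0,
                **overrides) -> "PhantomSpec":
        """Study-condition phantom for one slice level."""
        kin = dict(_SLICE_KINEMATICS[slice_level])
        kin.update(overrides)
        meta = kin.pop("meta", None) or _default_meta(slice_level, n_frames)
        return cls(meta=meta, noise_sd=noise_sd, seed=seed, **kin)

    # -- derived geometry ---------------------------------------------------

    @property
    def center(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=float)
        c = (self.meta.matrix - 1) / 2.0 * self.meta.voxel_mm
        return np.array([c, c])

    @property
    def cycle_ms(self) -> float:
        return self.meta.cycle_ms

    @property
    def t_sys_ms(self) -> float:
        return self.systolic_fraction * self.cycle_ms

    # -- kinematic time functions ------------------------------------------

    def _phase_split(self, t_ms):
        # systole is the closed interval [0, t_sys]: every kinematic
        # waveform is continuous at end-systole except the piecewise-
        # constant rotation mode, whose end-systolic sample belongs to
        # the systolic plateau
        t = np.asarray(t_ms, dtype=float) % self.cycle_ms
        return t, t <= self.t_sys_ms

    def contraction(self, t_ms):
        """s(t) in [0, 1]: 0 at end-diastole, 1 at end-systole."""
        t, sys = self._phase_split(t_ms)
        ts, td = self.t_sys_ms, self.cycle_ms - self.t_sys_ms
        return np.where(sys,
                        0.5 * (1 - np.cos(np.pi * t / ts)),
                        0.5 * (1 + np.cos(np.pi * (t - ts) / td)))

    def contraction_rate(self, t_ms):
        """ds/dt in 1/ms."""
        t, sys = self._phase_split(t_ms)
        ts, td = self.t_sys_ms, self.cycle_ms - self.t_sys_ms
        return np.where(sys,
                        0.5 * np.pi / ts * np.sin(np.pi * t / ts),
                        -0.5 * np.pi / td * np.sin(np.pi * (t - ts) / td))

    def radii(self, t_ms):
        """(R_endo, R_epi) in mm at time t."""
        s = self.contraction(t_ms)
        return (self.r_endo_ed_mm - self.dr_endo_mm * s,
                self.r_epi_ed_mm - self.dr_epi_mm * s)

    def wall_rates_cm_s(self, t_ms):
        """(dR_endo/dt, dR_epi/dt) in cm/s (mm/ms * 100)."""
        sdot = self.contraction_rate(t_ms)
        return (-self.dr_endo_mm * sdot * 100.0,
                -self.dr_epi_mm * sdot * 100.0)

    def omega_timecourse(self, t_ms):
        """Dimensionless rotation waveform g(t); integral over the full
        cycle is zero (no net rotation per beat)."""
        t, sys = self._phase_split(t_ms)
        ts, td = self.t_sys_ms, self.cycle_ms - self.t_sys_ms
        if self.omega_waveform == "constant":
            return np.where(sys, 1.0, -ts / td)
        return np.where(sys,
                        np.sin(np.pi * t / ts),
                        -(ts / td) * np.sin(np.pi * (t - ts) / td))

    def omega(self, r_mm, t_ms):
        """Angular velocity (rad/s) at radius r, linear transmural profile
        from omega_endo (wall inner border) to omega_epi (outer)."""
        r_endo, r_epi = self.radii(t_ms)
        u = np.clip((np.asarray(r_mm, float) - r_endo) / (r_epi - r_endo),
                    0.0, 1.0)
        g = self.omega_timecourse(t_ms)
        return g * (self.omega_endo_peak_rad_s * (1 - u)
                    + self.omega_epi_peak_rad_s * u)

    def vz(self, t_ms):
        """Longitudinal velocity (cm/s), positive base-to-apex."""
        return self.vz_peak_cm_s * self.omega_timecourse(t_ms)

    def median_radius_mm(self, t_ms, compartment: str = "full"):
        """Analytic median voxel radius of the (axisymmetric) wall.

        For voxels uniform over an annulus [R1, R2], the median radius is
        sqrt((R1^2 + R2^2) / 2); compartments are the halves of the wall
        either side of the full-wall median.
        """
        r_endo, r_epi = self.radii(t_ms)
        r_med = np.sqrt((r_endo ** 2 + r_epi ** 2) / 2.0)
        if compartment == "full":
            return r_med
        if compartment == "endo":
            return np.sqrt((r_endo ** 2 + r_med ** 2) / 2.0)
        if compartment == "epi":
            return np.sqrt((r_med ** 2 + r_epi ** 2) / 2.0)
        raise ValueError("compartment must be full|epi|endo")


# ---------------------------------------------------------------------------
# analytic velocity field
# ---------------------------------------------------------------------------

def _velocity_components(spec: PhantomSpec, dx, dy, t_ms):
    """(vx, vy, vz) cm/s at offsets (dx, dy) mm from the centre; no
    annulus bounds checking."""
    r = np.hypot(dx, dy)
    r_endo, r_epi = spec.radii(t_ms)
    v_endo, v_epi = spec.wall_rates_cm_s(t_ms)
    u = np.clip((r - r_endo) / (r_epi - r_endo), 0.0, 1.0)
    v_out = v_endo * (1 - u) + v_epi * u          # radial, outward positive
    om = spec.omega(r, t_ms)                      # rad/s, clockwise positive
    r_cm = r / 10.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy = np.where(r > 0, dx / r, 0.0), np.where(r > 0, dy / r, 0.0)
    # clockwise tangential unit vector in the y-down image frame: (-uy, ux)
    vx = v_out * ux + om * r_cm * (-uy)
    vy = v_out * uy + om * r_cm * ux
    vz = np.broadcast_to(spec.vz(t_ms), np.shape(vx))
    return vx, vy, np.array(vz, dtype=float)


def analytic_velocity(spec: PhantomSpec, x_mm, y_mm, t_ms):
    """Exact (vx, vy, vz) in cm/s at points inside the annulus.

    Raises ``ValueError`` for points outside the wall at time t.
    """
    dx = np.asarray(x_mm, float) - spec.center[0]
    dy = np.asarray(y_mm, float) - spec.center[1]
    r = np.hypot(dx, dy)
    r_endo, r_epi = spec.radii(t_ms)
    if np.any(r < r_endo) or np.any(r > r_epi):
        raise ValueError("point outside the myocardial annulus")
    return _velocity_components(spec, dx, dy, t_ms)


def velocity_maps(spec: PhantomSpec, matrix: int, frame: int):
    """(vx, vy, vz, annulus_mask) on a square grid of the given matrix
    (same FOV).

    The velocity maps are the continuous wall kinematics with the
    transmural profile clamped at the borders, so they remain valid for
    border voxels of a rasterized myocardial mask whose centres fall
    marginally outside the exact annulus.
    """
    voxel = spec.meta.fov_mm / matrix
    c = np.arange(matrix) * voxel
    X, Y = np.meshgrid(c, c, indexing="xy")
    dx, dy = X - spec.center[0], Y - spec.center[1]
    t = frame * spec.meta.frame_interval_ms
    r = np.hypot(dx, dy)
    r_endo, r_epi = spec.radii(t)
    mask = (r >= r_endo) & (r <= r_epi)
    vx, vy, vz = _velocity_components(spec, dx, dy, t)
    return vx, vy, vz, mask


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic reference values for a generated dataset."""

    spec: PhantomSpec | None = None
    flow_ml_min: float | None = None
    tube_radius_mm: float | None = None
    profile: str | None = None
    v_max_cm_s: float | None = None
    tube_meta: AcquisitionMeta | None = None

    def velocity_maps(self, matrix: int, frame: int):
        return velocity_maps(self.spec, matrix, frame)

    def twist_deg(self, compartment: str = "full") -> float:
        return analytic_twist(self.spec, compartment=compartment)

    # -- flow tube ----------------------------------------------------------

    def tube_center(self) -> np.ndarray:
        m = self.tube_meta
        c = (m.matrix - 1) / 2.0 * m.voxel_mm
        return np.array([c, c])

    def tube_mask(self, matrix: int) -> np.ndarray:
        m = self.tube_meta
        voxel = m.fov_mm / matrix
        c = np.arange(matrix) * voxel
        X, Y = np.meshgrid(c, c, indexing="xy")
        cx, cy = self.tube_center()
        return np.hypot(X - cx, Y - cy) <= self.tube_radius_mm

    def tube_velocity_map(self, matrix: int) -> np.ndarray:
        m = self.tube_meta
        voxel = m.fov_mm / matrix
        c = np.arange(matrix) * voxel
        X, Y = np.meshgrid(c, c, indexing="xy")
        cx, cy = self.tube_center()
        r = np.hypot(X - cx, Y - cy)
        inside = r <= self.tube_radius_mm
        if self.profile == "plug":
            v = np.full_like(r, self.v_max_cm_s)
        else:
            v = self.v_max_cm_s * (1.0 - (r / self.tube_radius_mm) ** 2)
        return np.where(inside, v, 0.0)


def analytic_twist(spec: PhantomSpec, segment=None,
                   compartment: str = "full") -> float:
    """Closed-form twist (degrees): integral of the angular velocity at
    the analytic median radius over end-diastole -> end-systole.

    The phantom is axisymmetric, so the result is independent of the
    segment; ``segment`` is accepted for interface symmetry.
    """
    def integrand(t_ms):
        r = spec.median_radius_mm(t_ms, compartment)
        return float(spec.omega(r, t_ms)) / 1000.0   # rad/ms
    val, _ = quad(integrand, 0.0, spec.t_sys_ms, limit=200)
    return float(np.degrees(val))


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _area_fraction_annulus(spec: PhantomSpec, t_ms) -> np.ndarray:
    """Tissue magnitude on the acquired grid: fraction of each voxel
    covered by the annulus or the static reference block, computed on a
    sub-voxel grid (keeps the object edges band-limited-ish rather than
    binary)."""
    n = spec.meta.matrix
    h = spec.meta.voxel_mm
    f = _SUPERSAMPLE
    coord = (np.arange(n * f) - (f - 1) / 2.0) * (h / f)
    X, Y = np.meshgrid(coord, coord, indexing="xy")
    r = np.hypot(X - spec.center[0], Y - spec.center[1])
    r_endo, r_epi = spec.radii(t_ms)
    fine = ((r >= r_endo) & (r <= r_epi)).astype(float)
    x0, y0, w, hgt = spec.reference_block_mm
    fine += ((X >= x0) & (X <= x0 + w) & (Y >= y0) & (Y <= y0 + hgt))
    fine = np.clip(fine, 0.0, 1.0)
    return fine.reshape(n, f, n, f).mean(axis=(1, 3))


def _circle(center, radius, n_pts: int = 180) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def generate_cine(spec: PhantomSpec, domain: str = "kspace"
                  ) -> tuple:
    """Synthesize one slice's four-scan cine dataset.

    Returns ``(CineEncodingSet, LVSegmentation, GroundTruth)``.  The
    segmentation (contours, masks, reference block) is given on the
    acquired grid; contours are in mm and can be re-rasterized onto the
    reconstruction grid.
    """
    meta = spec.meta
    n = meta.matrix
    voxel = meta.voxel_mm
    rng = np.random.default_rng(spec.seed)
    vencs = [meta.venc_inplane_cm_s, meta.venc_inplane_cm_s,
             meta.venc_through_cm_s]
    a, b, c = spec.background_plane
    cgrid = np.arange(n) * voxel
    X, Y = np.meshgrid(cgrid, cgrid, indexing="xy")
    plane = a + b * X + c * Y
    dx, dy = X - spec.center[0], Y - spec.center[1]
    ang = ccw_angle_deg(dx, dy)
    r = np.hypot(dx, dy)
    bx, by, bw, bh = spec.reference_block_mm
    in_block = (X >= bx) & (X <= bx + bw) & (Y >= by) & (Y <= by + bh)

    scans = np.zeros((4, meta.n_frames, n, n), dtype=complex)
    epi_contours, endo_contours = [], []
    for t_idx in range(meta.n_frames):
        t = t_idx * meta.frame_interval_ms
        r_endo, r_epi = spec.radii(t)
        annulus = (r >= r_endo) & (r <= r_epi)
        mag = _area_fraction_annulus(spec, t)
        # The transmural velocity profile is continued past the wall
        # borders by clamping: a border voxel's tissue fraction moves
        # with the adjacent wall edge, and where the magnitude is zero
        # the encoded phase is unobservable anyway.  This keeps the
        # complex object free of an artificial phase step at the border.
        vx, vy, vz = _velocity_components(spec, dx, dy, t)
        comps = [vx, vy, vz]
        scans[0, t_idx] = mag
        for i, (v, venc) in enumerate(zip(comps, vencs), start=1):
            if np.max(np.abs(v[annulus])) > 2 * venc:
                raise ValueError("prescribed velocity exceeds 2*venc: "
                                 "ground truth would double-wrap")
            v = np.where(in_block, 0.0, v)   # the reference block is static
            phase = plane - np.pi * v / venc
            if spec.artifact_sector is not None:
                start, end, sd = spec.artifact_sector
                wedge = annulus & (((ang - start) % 360.0)
                                   < ((end - start) % 360.0))
                # one coherent phase offset per frame and encoding, as a
                # flow-ghost overlay would produce
                phase = phase + np.where(wedge, rng.normal(0.0, sd), 0.0)
            scans[i, t_idx] = mag * np.exp(1j * phase)
        epi_contours.append(_circle(spec.center, r_epi))
        endo_contours.append(_circle(spec.center, r_endo))

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, scans.shape) \
            + 1j * rng.normal(0.0, spec.noise_sd, scans.shape)
        scans = scans + noise

    if domain == "kspace":
        scans = fft2c(scans)
    elif domain != "image":
        raise ValueError("domain must be 'kspace' or 'image'")

    x0, y0, w, hgt = spec.reference_block_mm
    ref_poly = np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + hgt],
                         [x0, y0 + hgt]])
    seg = LVSegmentation.from_contours(epi_contours, endo_contours, n, voxel,
                                       reference_polygon=ref_poly)
    cine = CineEncodingSet(scans=scans, meta=meta, domain=domain)
    return cine, seg, GroundTruth(spec=spec)


def generate_flow_tube(flow_ml_min: float, tube_radius_mm: float = 1.5,
                       venc_cm_s: float = 40.0, profile: str = "parabolic",
                       matrix: int = 128, fov_mm: float = 12.8,
                       n_frames: int = 1, noise_sd: float = 0.0,
                       seed: int = 0) -> tuple:
    """Synthesize a steady flow-tube dataset with known volume flow.

    Parabolic: v(r) = v_max (1 - r^2/R^2), Q = v_max pi R^2 / 2;
    plug: v(r) = v, Q = v pi R^2.  Returns ``(CineEncodingSet,
    GroundTruth)`` in the image domain.
    """
    if profile not in ("plug", "parabolic"):
        raise ValueError("profile must be 'plug' or 'parabolic'")
    r_cm = tube_radius_mm / 10.0
    q_cm3_s = flow_ml_min / 60.0
    area = np.pi * r_cm ** 2
    v_max = q_cm3_s / area if profile == "plug" else 2.0 * q_cm3_s / area
    if v_max >= venc_cm_s and flow_ml_min != 0:
        raise ValueError("peak velocity reaches venc: flow would alias")
    meta = AcquisitionMeta(fov_mm=fov_mm, matrix=matrix,
                           frame_interval_ms=4.6, n_frames=n_frames,
                           venc_inplane_cm_s=venc_cm_s,
                           venc_through_cm_s=venc_cm_s, slice_level="mid")
    truth = GroundTruth(flow_ml_min=flow_ml_min,
                        tube_radius_mm=tube_radius_mm, profile=profile,
                        v_max_cm_s=v_max, tube_meta=meta)
    # anti-aliased tube magnitude
    f = _SUPERSAMPLE
    voxel = meta.voxel_mm
    coord = (np.arange(matrix * f) - (f - 1) / 2.0) * (voxel / f)
    Xf, Yf = np.meshgrid(coord, coord, indexing="xy")
    cx, cy = truth.tube_center()
    fine = (np.hypot(Xf - cx, Yf - cy) <= tube_radius_mm).astype(float)
    mag = fine.reshape(matrix, f, matrix, f).mean(axis=(1, 3))
    vz = truth.tube_velocity_map(matrix)

    rng = np.random.default_rng(seed)
    scans = np.zeros((4, n_frames, matrix, matrix), dtype=complex)
    for t_idx in range(n_frames):
        scans[0, t_idx] = mag
        scans[1, t_idx] = mag          # x and y encodings: no in-plane flow
        scans[2, t_idx] = mag
        scans[3, t_idx] = mag * np.exp(-1j * np.pi * vz / venc_cm_s)
    if noise_sd > 0:
        scans = scans + rng.normal(0.0, noise_sd, scans.shape) \
            + 1j * rng.normal(0.0, noise_sd, scans.shape)
    cine = CineEncodingSet(scans=scans, meta=meta, domain="image")
    return cine, truth
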