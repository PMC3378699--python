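"""Velocity-field reconstruction from multi-encoded cine data.

The chain mirrors standard phase-contrast practice: the acquired k-space
of each of the four scans is apodized with a radial Butterworth window,
isotropically zero-filled (default factor two), and inverse Fourier
transformed with centred conventions.  Velocity maps are obtained by
phase subtraction of each motion-encoded scan from the motion-compensated
reference, scaled so a phase difference of pi maps to +venc, and the
combined magnitude image is the voxelwise sum of the magnitudes of all
four scans.  Residual background phase (eddy-current) offsets are removed
per frame by fitting a constant or linear plane over a static reference
region and subtracting it from the whole map.

No phase unwrapping is performed: velocities beyond venc alias, as in the
acquisition itself; a warning is logged when a non-negligible fraction of
in-mask voxels sits close to +-venc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import CineEncodingSet, VelocityField

log = logging.getLogger(__name__)

WRAP_GUARD_FRACTION = 0.005   # warn when >0.5% of voxels are near +-venc
WRAP_GUARD_BAND = 0.05        # "near" = within 5% of venc


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction parameters.

    ``filter_cutoff_frac`` is the Butterworth half-amplitude radius as a
    fraction of the acquired Nyquist frequency.
    """

    zerofill_factor: int = 2
    filter_order: int = 3
    filter_cutoff_frac: float = 1.0
    background_correction: str = "linear"   # off | constant | linear

    def __post_init__(self):
        if self.zerofill_factor < 1:
            raise ValueError("zerofill_factor must be >= 1")
        if not (0 < self.filter_cutoff_frac <= 1):
            raise ValueError("filter_cutoff_frac must be in (0, 1]")
        if self.background_correction not in ("off", "constant", "linear"):
            raise ValueError("background_correction must be "
                             "off|constant|linear")


# ---------------------------------------------------------------------------
# k-space operations
# ---------------------------------------------------------------------------

def fft2c(image: np.ndarray) -> np.ndarray:
    """Centred 2-D FFT (image -> k-space), orthonormal."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image,
                                                        axes=(-2, -1)),
                                       axes=(-2, -1), norm="ortho"),
                           axes=(-2, -1))


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Centred 2-D inverse FFT (k-space -> image), orthonormal."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace,
                                                         axes=(-2, -1)),
                                        axes=(-2, -1), norm="ortho"),
                           axes=(-2, -1))


def zerofill(kspace_frame: np.ndarray, factor: int) -> np.ndarray:
    """Embed a square k-space frame centred in a ``factor``-times larger
    zero matrix (sinc interpolation in image space)."""
    if factor < 1:
        raise ValueError("zerofill factor must be >= 1")
    if kspace_frame.shape[-2] != kspace_frame.shape[-1]:
        raise ValueError("k-space frame must be square")
    if factor == 1:
        return kspace_frame
    n = kspace_frame.shape[-1]
    m = factor * n
    out = np.zeros(kspace_frame.shape[:-2] + (m, m),
                   dtype=kspace_frame.dtype)
    start = (m - n) // 2
    out[..., start:start + n, start:start + n] = kspace_frame
    return out


def butterworth_window(matrix: int, order: int, cutoff_frac: float,
                       data_matrix: int | None = None) -> np.ndarray:
    """Radial low-pass window H(k) = 1 / (1 + (|k|/k_c)^(2*order)).

    H(0) = 1, H(k_c) = 1/2, monotonically non-increasing in |k|.  The
    cutoff is expressed as a fraction of the Nyquist radius of
    ``data_matrix`` (defaults to ``matrix``), so the window over an
    already zero-filled frame can be made identical to the window applied
    before zero-filling.
    """
    if cutoff_frac <= 0:
        raise ValueError("cutoff_frac must be > 0")
    if data_matrix is None:
        data_matrix = matrix
    idx = np.arange(matrix) - matrix // 2
    nyquist = data_matrix / 2.0
    kx, ky = np.meshgrid(idx / nyquist, idx / nyquist)
    kr = np.hypot(kx, ky)
    return 1.0 / (1.0 + (kr / cutoff_frac) ** (2 * order))


def apodize(kspace_frame: np.ndarray, order: int = 3,
            cutoff_frac: float = 1.0,
            data_matrix: int | None = None) -> np.ndarray:
    """Multiply k-space by the radial Butterworth window."""
    if kspace_frame.shape[-2] != kspace_frame.shape[-1]:
        raise ValueError("k-space frame must be square")
    h = butterworth_window(kspace_frame.shape[-1], order, cutoff_frac,
                           data_matrix)
    return kspace_frame * h


def reconstruct(cine: CineEncodingSet, cfg: ReconConfig | None = None
                ) -> np.ndarray:
    """Apodize, zero-fill and inverse-FFT all encodings of a cine set.

    Input in the image domain passes through unchanged.  Returns complex
    image stacks of shape ``(n_enc, n_frames, N, N)`` where N is the
    zero-filled matrix.
    """
    cfg = cfg or ReconConfig()
    if cine.domain == "image":
        return cine.scans
    k = apodize(cine.scans, cfg.filter_order, cfg.filter_cutoff_frac)
    k = zerofill(k, cfg.zerofill_factor)
    return ifft2c(k)


# ---------------------------------------------------------------------------
# velocity computation
# ---------------------------------------------------------------------------

def combine_magnitude(scans: np.ndarray) -> np.ndarray:
    """Voxelwise sum of the magnitudes of all scans (axis 0)."""
    scans = np.asarray(scans)
    shapes = {s.shape for s in scans}
    if len(shapes) != 1:
        raise ValueError("encoding shape mismatch")
    return np.abs(scans).sum(axis=0)


def phase_velocity(encoded: np.ndarray, reference: np.ndarray,
                   venc_cm_s: float) -> np.ndarray:
    """Velocity (cm/s) from the phase difference reference - encoded.

    delta_phi = arg(reference * conj(encoded)) in [-pi, pi);
    v = venc * delta_phi / pi, so delta_phi = pi maps to +venc.
    """
    if venc_cm_s is None or venc_cm_s <= 0:
        raise ValueError("venc must be > 0")
    if np.iscomplexobj(encoded) or np.iscomplexobj(reference):
        dphi = np.angle(np.asarray(reference) * np.conj(encoded))
    else:   # pre-computed phase maps (radians)
        dphi = np.angle(np.exp(1j * (np.asarray(reference)
                                     - np.asarray(encoded))))
    return venc_cm_s * dphi / np.pi


def background_correct(velocity: np.ndarray, static_reference_mask: np.ndarray,
                       mode: str = "linear", voxel_mm: float = 1.0
                       ) -> np.ndarray:
    """Remove a constant or linear background offset per frame.

    Fits v ~ a + b*x + c*y (mode='linear'; 'constant': a only) by least
    squares over the static reference voxels of each frame and subtracts
    the fitted plane from the whole map.  The post-correction mean over
    the reference mask is zero by construction.
    """
    if mode == "off":
        return np.array(velocity, copy=True)
    if mode not in ("constant", "linear"):
        raise ValueError("mode must be off|constant|linear")
    vel = np.asarray(velocity, dtype=float)
    single = vel.ndim == 2
    frames = vel[None] if single else vel
    mask = np.asarray(static_reference_mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    n_ref = rows.size
    if n_ref == 0:
        raise ValueError("static reference mask is empty")
    if mode == "linear" and n_ref < 3:
        raise ValueError("linear background correction needs >= 3 "
                         "reference voxels")
    x = cols * voxel_mm
    y = rows * voxel_mm
    if mode == "constant":
        design = np.ones((n_ref, 1))
    else:
        design = np.column_stack([np.ones(n_ref), x, y])
    n = frames.shape[-1]
    Xg, Yg = np.meshgrid(np.arange(n) * voxel_mm, np.arange(n) * voxel_mm,
                         indexing="xy")
    out = np.empty_like(frames)
    for t, fr in enumerate(frames):
        coef, *_ = np.linalg.lstsq(design, fr[rows, cols], rcond=None)
        plane = coef[0]
        if mode == "linear":
            plane = coef[0] + coef[1] * Xg + coef[2] * Yg
        out[t] = fr - plane
    return out[0] if single else out


def wrap_fraction(velocity: np.ndarray, venc_cm_s: float,
                  mask: np.ndarray | None = None) -> float:
    """Fraction of (masked) voxels within ``WRAP_GUARD_BAND`` of +-venc."""
    v = np.abs(np.asarray(velocity, dtype=float))
    if mask is not None:
        v = v[np.broadcast_to(mask, v.shape)]
    if v.size == 0:
        return 0.0
    return float(np.mean(v >= (1.0 - WRAP_GUARD_BAND) * venc_cm_s))


def reconstruct_velocities(cine: CineEncodingSet,
                           cfg: ReconConfig | None = None,
                           static_reference_mask: np.ndarray | None = None,
                           myocardial_mask: np.ndarray | None = None
                           ) -> VelocityField:
    """Full reconstruction: images, combined magnitude, velocity maps and
    background correction.

    ``static_reference_mask`` must be rasterized on the reconstructed
    (zero-filled) grid; it is required unless background correction is
    off.  ``myocardial_mask`` (optional, same grid) only scopes the
    aliasing warning.
    """
    cfg = cfg or ReconConfig()
    images = reconstruct(cine, cfg)
    magnitude = combine_magnitude(images)
    ref_img = images[0]
    meta = cine.meta
    vencs = {"x": meta.venc_inplane_cm_s, "y": meta.venc_inplane_cm_s,
             "z": meta.venc_through_cm_s}
    voxel = meta.fov_mm / images.shape[-1]
    comps = {}
    for i, axis in enumerate(cine.encodings[1:], start=1):
        v = phase_velocity(images[i], ref_img, vencs[axis])
        if cfg.background_correction != "off":
            if static_reference_mask is None:
                raise ValueError("background correction requires a static "
                                 "reference mask")
            v = background_correct(v, static_reference_mask,
                                   cfg.background_correction, voxel)
        check_mask = myocardial_mask
        if check_mask is None and magnitude.size:
            # without a segmentation, only voxels carrying signal are
            # meaningful for the aliasing check
            check_mask = magnitude > 0.2 * magnitude.max()
        frac = wrap_fraction(v, vencs[axis], check_mask)
        if frac > WRAP_GUARD_FRACTION:
            log.warning("%.1f%% of voxels within %d%% of +-venc on axis %s: "
                        "velocities may be aliased", 100 * frac,
                        int(100 * WRAP_GUARD_BAND), axis)
        comps[axis] = v
    return VelocityField(vx=comps["x"], vy=comps["y"], vz=comps.get("z"),
                         magnitude=magnitude, meta=meta)


def measure_flow(vz_map: np.ndarray, mask: np.ndarray, voxel_mm: float
                 ) -> float:
    """Volume flow (mL/min) through a through-plane ROI.

    Sum of through-plane velocity (cm/s) times voxel area over the ROI.
    """
    area_cm2 = (voxel_mm / 10.0) ** 2
    q_cm3_s = float(np.sum(np.asarray(vz_map)[np.asarray(mask, bool)])
                    * area_cm2)
    return q_cm3_s * 60.0
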