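"""Shared fixtures: phantoms and reconstructions reused across tests."""

import numpy as np
import pytest

from mtpm import PhantomSpec, ReconConfig, generate_cine, \
    reconstruct_velocities
from mtpm.dataio import AcquisitionMeta, LVSegmentation
from mtpm.cli import analyze_slice


def recon_at_zerofill(cine, seg, zerofill_factor=2):
    """Reconstruct and re-rasterize the segmentation on the recon grid."""
    matrix = cine.meta.matrix * (zerofill_factor
                                 if cine.domain == "kspace" else 1)
    seg_hi = LVSegmentation.from_contours(
        seg.epi_contours, seg.endo_contours, matrix,
        cine.meta.fov_mm / matrix, reference_polygon=seg.reference_polygon)
    vel = reconstruct_velocities(
        cine, ReconConfig(zerofill_factor=zerofill_factor),
        static_reference_mask=seg_hi.static_reference_mask)
    return vel, seg_hi


@pytest.fixture(scope="session")
def mid_noiseless():
    """Noiseless default mid-ventricular phantom, k-space domain, plus its
    zero-filled reconstruction and analysis."""
    spec = PhantomSpec.default("mid", noise_sd=0.0)
    cine, seg, truth = generate_cine(spec, domain="kspace")
    vel, seg_hi = recon_at_zerofill(cine, seg)
    return dict(spec=spec, cine=cine, seg=seg, truth=truth, vel=vel,
                seg_hi=seg_hi)


@pytest.fixture(scope="session")
def basal_apical_noiseless():
    """Noiseless basal + apical phantoms analysed end to end (twist and
    torsion checks)."""
    out = {}
    for level in ("basal", "apical"):
        spec = PhantomSpec.default(level, noise_sd=0.0)
        cine, seg, truth = generate_cine(spec, domain="kspace")
        vel, seg_hi = recon_at_zerofill(cine, seg)
        res = analyze_slice(vel, seg_hi)
        out[level] = dict(spec=spec, truth=truth, res=res)
    return out


@pytest.fixture(scope="session")
def rigid_rotation_analysis():
    """Rigid-body rotation at constant angular velocity 0.1745 rad/s over
    a 100 ms systolic window, analysed through the image-domain path."""
    meta = AcquisitionMeta(fov_mm=25.6, matrix=128, frame_interval_ms=5.0,
                           n_frames=25, venc_inplane_cm_s=6.0,
                           venc_through_cm_s=8.0, slice_level="basal")
    spec = PhantomSpec(meta=meta, dr_endo_mm=0.0, dr_epi_mm=0.0,
                       systolic_fraction=0.8,
                       omega_endo_peak_rad_s=0.1745,
                       omega_epi_peak_rad_s=0.1745,
                       omega_waveform="constant", vz_peak_cm_s=0.0,
                       noise_sd=0.0)
    cine, seg, truth = generate_cine(spec, domain="image")
    vel, seg_same = recon_at_zerofill(cine, seg, zerofill_factor=1)
    res = analyze_slice(vel, seg_same, es_frame=20)
    return dict(spec=spec, res=res)


@pytest.fixture()
def annulus_mask():
    """A simple rasterized annulus mask with its centre, for geometry
    tests."""
    n, voxel = 64, 0.4
    c = (n - 1) / 2 * voxel
    x = np.arange(n) * voxel
    X, Y = np.meshgrid(x, x)
    r = np.hypot(X - c, Y - c)
    return (r >= 4.0) & (r <= 8.0), np.array([c, c]), voxel
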