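"""Polar velocity components, bulk-motion correction and global courses.

Sign conventions (foot-to-head view, y down as displayed):

* radial velocity ``v_r``: positive when the myocardium moves toward the
  centre of mass (contraction);
* tangential velocity ``v_phi``: positive for visually clockwise
  rotation;
* longitudinal velocity ``v_z``: positive for base-to-apex motion.

Bulk motion is removed by subtracting the mask mean of each Cartesian
component.  Because that also zeroes the global longitudinal mean, global
``v_z`` time courses are taken before bulk correction while polar and
regional maps are computed after it.
"""

from __future__ import annotations

import logging

import numpy as np

from .dataio import mask_centroid

log = logging.getLogger(__name__)


def center_of_mass(mask_frame: np.ndarray, voxel_mm: float = 1.0
                   ) -> np.ndarray:
    """Unweighted centroid (x, y) in mm of the myocardial mask."""
    return mask_centroid(mask_frame, voxel_mm)


def bulk_correct(vx: np.ndarray, vy: np.ndarray, vz: np.ndarray | None,
                 mask_frame: np.ndarray):
    """Subtract the mask mean of each component from every voxel.

    Operates on single frames; the post-correction mask mean of every
    component is zero to machine precision.
    """
    mask = np.asarray(mask_frame, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    out = []
    for v in (vx, vy, vz):
        if v is None:
            out.append(None)
            continue
        v = np.asarray(v, dtype=float)
        out.append(v - v[mask].mean())
    return tuple(out)


def to_polar(vx: np.ndarray, vy: np.ndarray, mask_frame: np.ndarray,
             center_mm, voxel_mm: float = 1.0):
    """Project in-plane velocities onto radial/tangential directions.

    Returns ``(v_r, v_phi)`` maps that are NaN outside the mask.  With
    the outward unit vector r_hat and the visually clockwise tangential
    unit vector t_hat: ``v_r = -(v . r_hat)`` (positive = contraction)
    and ``v_phi = +(v . t_hat)`` (positive = clockwise, foot-to-head).
    A voxel coinciding with the centre has no defined direction and is
    excluded with a warning.
    """
    mask = np.asarray(mask_frame, dtype=bool)
    n_rows, n_cols = mask.shape
    X, Y = np.meshgrid(np.arange(n_cols) * voxel_mm,
                       np.arange(n_rows) * voxel_mm, indexing="xy")
    dx = X - center_mm[0]
    dy = Y - center_mm[1]
    r = np.hypot(dx, dy)
    degenerate = mask & (r == 0)
    if degenerate.any():
        log.warning("excluding %d voxel(s) coinciding with the centre of "
                    "mass (undefined radial direction)", degenerate.sum())
        mask = mask & ~degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy = dx / r, dy / r
    v_r = -(vx * ux + vy * uy)
    # clockwise tangential unit vector in the y-down frame: (-uy, ux)
    v_phi = vx * (-uy) + vy * ux
    v_r = np.where(mask, v_r, np.nan)
    v_phi = np.where(mask, v_phi, np.nan)
    return v_r, v_phi


def global_time_course(component_stack: np.ndarray, masks: np.ndarray,
                       frame_interval_ms: float):
    """Mask-mean series of one velocity component.

    Returns ``(times_ms, values)``; raises on an empty mask frame.
    """
    stack = np.asarray(component_stack, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    values = np.empty(stack.shape[0])
    for t in range(stack.shape[0]):
        m = masks[t]
        if not m.any():
            raise ValueError(f"empty mask at frame {t}")
        frame = stack[t][m]
        values[t] = np.nanmean(frame)
    times = np.arange(stack.shape[0]) * frame_interval_ms
    return times, values


def normalize_and_average(series_list, es_indices, n_out: int | None = None):
    """Cohort averaging of time courses normalized to end-systole.

    Each subject's time axis is linearly rescaled so that end-systole
    maps to normalized time 1.0 (the cycle end maps to its own rescaled
    position); the series are resampled by linear interpolation onto a
    common normalized grid spanning the interval covered by every
    subject, then averaged pointwise.

    Returns ``(grid, mean, sd)`` with the sample SD across subjects
    (zero for a single subject).
    """
    if len(series_list) == 0:
        raise ValueError("need at least one subject")
    if len(series_list) != len(es_indices):
        raise ValueError("one end-systolic index per subject is required")
    taus, values = [], []
    for series, es in zip(series_list, es_indices):
        series = np.asarray(series, dtype=float)
        if not (0 < es < len(series)):
            raise ValueError("end-systolic index must be inside the series "
                             "and nonzero")
        taus.append(np.arange(len(series)) / float(es))
        values.append(series)
    if n_out is None:
        n_out = max(len(s) for s in values)
    tau_end = min(t[-1] for t in taus)
    grid = np.linspace(0.0, tau_end, n_out)
    resampled = np.array([np.interp(grid, t, v)
                          for t, v in zip(taus, values)])
    mean = resampled.mean(axis=0)
    sd = (resampled.std(axis=0, ddof=1) if len(values) > 1
          else np.zeros(n_out))
    return grid, mean, sd
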