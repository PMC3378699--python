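"""AHA segment partitioning, epi/endo compartments and regional courses.

Basal and mid-ventricular slices are divided into six equiangular
segments, the apical slice into four; the apex-only 17th segment carries
no myocardium in a short-axis slice and is excluded.  Segment 1
(anterior) is by default centred at the top of the image (12 o'clock)
and ids advance counterclockwise in the foot-to-head view; the anchoring
angle is a configuration parameter, since no anatomical landmark rule is
imposed.  Each segment is further split at its median voxel radius into
an endocardial (r < median) and an epicardial (r >= median) compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import AHA_IDS, AHA_NAMES, ccw_angle_deg

COMPARTMENTS = ("full", "epi", "endo")
COMPONENTS = ("radial", "tangential", "longitudinal")


@dataclass(frozen=True)
class SegmentModel:
    """Equiangular segment model of one slice level."""

    slice_level: str
    reference_angle_deg: float | None = None

    @property
    def n_segments(self) -> int:
        return len(AHA_IDS[self.slice_level])

    @property
    def segment_ids(self) -> tuple:
        return AHA_IDS[self.slice_level]

    @property
    def names(self) -> dict:
        return dict(zip(self.segment_ids, AHA_NAMES[self.slice_level]))

    @property
    def width_deg(self) -> float:
        return 360.0 / self.n_segments

    @property
    def start_angle_deg(self) -> float:
        """Counterclockwise angle where segment 1 starts; the default
        centres the anterior segment at the top of the image."""
        if self.reference_angle_deg is not None:
            return self.reference_angle_deg
        return 90.0 - self.width_deg / 2.0


def angular_partition(mask_frame: np.ndarray, center_mm, n_segments: int,
                      reference_angle_deg: float, voxel_mm: float = 1.0,
                      first_label: int = 1) -> np.ndarray:
    """Label every mask voxel by its equiangular sector.

    Sectors are half-open ``[start, start + width)`` in the visually
    counterclockwise angle and labelled ``first_label ..
    first_label + n_segments - 1``; background voxels are 0.
    """
    mask = np.asarray(mask_frame, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_rows, n_cols = mask.shape
    X, Y = np.meshgrid(np.arange(n_cols) * voxel_mm,
                       np.arange(n_rows) * voxel_mm, indexing="xy")
    ang = ccw_angle_deg(X - center_mm[0], Y - center_mm[1])
    width = 360.0 / n_segments
    idx = np.floor(((ang - reference_angle_deg) % 360.0) / width).astype(int)
    idx = np.clip(idx, 0, n_segments - 1)   # guard the 360-degree edge
    labels = np.where(mask, first_label + idx, 0)
    return labels


def partition(mask_frame: np.ndarray, center_mm, model: SegmentModel,
              voxel_mm: float = 1.0) -> np.ndarray:
    """AHA label map for one frame (0 outside the mask)."""
    return angular_partition(mask_frame, center_mm, model.n_segments,
                             model.start_angle_deg, voxel_mm,
                             first_label=model.segment_ids[0])


def split_epi_endo(labels_frame: np.ndarray, center_mm,
                   voxel_mm: float = 1.0) -> np.ndarray:
    """Compartment map: 1 = endocardial, 2 = epicardial, 0 = background.

    Per segment, voxels with radius below the segment's median radius are
    endocardial; radius at or above the median is epicardial (so with all
    radii equal, every voxel is epicardial).
    """
    labels = np.asarray(labels_frame)
    n_rows, n_cols = labels.shape
    X, Y = np.meshgrid(np.arange(n_cols) * voxel_mm,
                       np.arange(n_rows) * voxel_mm, indexing="xy")
    r = np.hypot(X - center_mm[0], Y - center_mm[1])
    comp = np.zeros_like(labels, dtype=int)
    for sid in np.unique(labels[labels > 0]):
        sel = labels == sid
        if sel.sum() < 2:
            raise ValueError(f"segment {sid} has fewer than 2 voxels")
        med = np.median(r[sel])
        comp[sel & (r < med)] = 1
        comp[sel & (r >= med)] = 2
    return comp


@dataclass
class RegionalCourses:
    """Per-segment, per-compartment velocity and radius series.

    ``velocity[(segment, compartment, component)]`` are mask-mean series
    in cm/s (NaN where the region is empty); ``median_radius`` is in mm;
    ``v_rot`` is the region mean of the voxelwise angular velocity
    v_phi / r in rad/s, the integrand of the twist computation.
    """

    slice_level: str
    times_ms: np.ndarray
    velocity: dict
    median_radius: dict
    v_rot: dict
    segment_names: dict

    @property
    def segment_ids(self) -> tuple:
        return AHA_IDS[self.slice_level]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sid, comp, component), series in sorted(self.velocity.items()):
            med = self.median_radius[(sid, comp)]
            rot = self.v_rot[(sid, comp)]
            for t, val in enumerate(series):
                rows.append(dict(segment=sid,
                                 name=self.segment_names[sid],
                                 compartment=comp, component=component,
                                 frame=t, time_ms=self.times_ms[t],
                                 velocity_cm_s=val,
                                 median_radius_mm=med[t],
                                 v_rot_rad_s=rot[t]))
        return pd.DataFrame(rows)


def regional_time_courses(v_r: np.ndarray, v_phi: np.ndarray,
                          v_z: np.ndarray | None,
                          labels: np.ndarray, compartments: np.ndarray,
                          centers_mm: np.ndarray, model: SegmentModel,
                          voxel_mm: float, frame_interval_ms: float
                          ) -> RegionalCourses:
    """Average polar velocities per segment x compartment x frame.

    ``labels`` and ``compartments`` are per-frame maps from
    :func:`partition` and :func:`split_epi_endo`.  Empty regions yield
    NaN (missing), never zero.
    """
    n_frames = labels.shape[0]
    times = np.arange(n_frames) * frame_interval_ms
    comps_stacks = {"radial": v_r, "tangential": v_phi}
    if v_z is not None:
        comps_stacks["longitudinal"] = v_z
    velocity = {}
    median_radius = {}
    v_rot = {}
    n_rows, n_cols = labels.shape[1:]
    X, Y = np.meshgrid(np.arange(n_cols) * voxel_mm,
                       np.arange(n_rows) * voxel_mm, indexing="xy")
    for sid in model.segment_ids:
        for comp in COMPARTMENTS:
            key = (sid, comp)
            median_radius[key] = np.full(n_frames, np.nan)
            v_rot[key] = np.full(n_frames, np.nan)
            for component in comps_stacks:
                velocity[(sid, comp, component)] = np.full(n_frames, np.nan)
    for t in range(n_frames):
        r_map = np.hypot(X - centers_mm[t][0], Y - centers_mm[t][1])
        for sid in model.segment_ids:
            seg_sel = labels[t] == sid
            for comp in COMPARTMENTS:
                sel = seg_sel if comp == "full" else \
                    seg_sel & (compartments[t] == (1 if comp == "endo"
                                                   else 2))
                if not sel.any():
                    continue
                r_vox = r_map[sel]
                median_radius[(sid, comp)][t] = np.median(r_vox)
                with np.errstate(invalid="ignore", divide="ignore"):
                    v_rot[(sid, comp)][t] = np.nanmean(
                        v_phi[t][sel] / (r_vox / 10.0))
                for component, stack in comps_stacks.items():
                    velocity[(sid, comp, component)][t] = \
                        np.nanmean(stack[t][sel])
    return RegionalCourses(slice_level=model.slice_level, times_ms=times,
                           velocity=velocity, median_radius=median_radius,
                           v_rot=v_rot, segment_names=model.names)


def default_windows(n_frames: int, es_frame: int):
    """Default phase windows: systole = frames [0, es], diastole =
    (es, end]."""
    if not (0 < es_frame < n_frames):
        raise ValueError("es_frame must lie inside the cine")
    return np.arange(0, es_frame + 1), np.arange(es_frame + 1, n_frames)


def peak_velocities(series: np.ndarray, systole_window, diastole_window):
    """(peak systolic, peak diastolic) velocity of one series.

    Peak systole is the maximum over the systolic window, peak diastole
    the minimum over the diastolic window.  NaN frames (missing regions)
    propagate into the peaks rather than being zero-filled.
    """
    series = np.asarray(series, dtype=float)
    sw = np.asarray(systole_window, dtype=int)
    dw = np.asarray(diastole_window, dtype=int)
    if sw.size == 0 or dw.size == 0:
        raise ValueError("empty phase window")
    return float(np.max(series[sw])), float(np.min(series[dw]))


def bullseye(per_subject_values: list) -> pd.DataFrame:
    """Across-subject mean +- sample SD per AHA segment.

    ``per_subject_values`` is a list of ``{segment_id: value}`` dicts,
    one per subject; all subjects must provide the same segment set
    (segment 17 never appears).
    """
    if not per_subject_values:
        raise ValueError("no subjects")
    segs = sorted(per_subject_values[0])
    for d in per_subject_values[1:]:
        if sorted(d) != segs:
            raise ValueError("inconsistent segment sets across subjects")
    if any(s == 17 for s in segs):
        raise ValueError("segment 17 (apex cap) is excluded from analysis")
    rows = []
    for sid in segs:
        vals = np.array([d[sid] for d in per_subject_values], dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(dict(segment=sid, mean=vals.mean(), sd=sd, n=len(vals)))
    return pd.DataFrame(rows)
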