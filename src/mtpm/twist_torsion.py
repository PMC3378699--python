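"""Twist and torsion from segmental angular velocities.

The twist angle of a segment is the time integral (trapezoidal rule at
the native frame interval) of its angular velocity from end-diastole to
end-systole, in degrees; positive twist is clockwise in the
foot-to-head view.  Torsion of a wall is the apical twist minus the
basal twist.  The six basal/mid segments are collapsed onto the four
apical walls by averaging the two septal and the two lateral segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segments import RegionalCourses, COMPARTMENTS

#: mapping of the four apical walls onto basal/mid segment names
WALL_GROUPS = {
    "anterior": ("anterior",),
    "septum": ("anteroseptal", "inferoseptal"),
    "inferior": ("inferior",),
    "lateral": ("inferolateral", "anterolateral"),
}
#: apical segment names as walls
APICAL_WALLS = {"anterior": "anterior", "septal": "septum",
                "inferior": "inferior", "lateral": "lateral"}


@dataclass(frozen=True)
class TwistResult:
    segment: int
    compartment: str
    twist_deg: float
    ed_frame: int
    es_frame: int

    def __post_init__(self):
        if not np.isfinite(self.twist_deg):
            raise ValueError("twist must be finite")
        if not self.ed_frame < self.es_frame:
            raise ValueError("integration window must be ordered ED < ES")


@dataclass(frozen=True)
class TorsionResult:
    wall: str
    compartment: str   # overall | epi | endo
    torsion_deg: float


def angular_velocity(v_phi_cm_s, r_mm):
    """Angular velocity v_phi / r in rad/s (cm/s divided by cm).

    Accepts scalars or arrays; the sign is inherited from v_phi
    (positive = clockwise, foot-to-head view).
    """
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be > 0")
    return np.asarray(v_phi_cm_s, dtype=float) / (r / 10.0)


def twist(v_rot_series, frame_interval_ms: float, ed_frame: int = 0,
          es_frame: int | None = None) -> float:
    """Twist angle (degrees): trapezoidal integral of the angular
    velocity series over [ED, ES]."""
    v = np.asarray(v_rot_series, dtype=float)
    if es_frame is None:
        es_frame = len(v) - 1
    if not (0 <= ed_frame < es_frame <= len(v) - 1):
        raise ValueError("integration window outside the series")
    window = v[ed_frame:es_frame + 1]
    rad = np.trapezoid(window, dx=frame_interval_ms / 1000.0)
    return float(np.degrees(rad))


def torsion(twist_apical_deg: float, twist_basal_deg: float) -> float:
    """Ventricular torsion: apical twist minus basal twist (degrees)."""
    return twist_apical_deg - twist_basal_deg


def wall_map_6_to_4(six_segment_values: dict) -> dict:
    """Collapse six basal/mid segment values onto the four apical walls.

    The two septal segments average into 'septum', the two lateral
    segments into 'lateral'; anterior and inferior map one to one.
    """
    known = {n for group in WALL_GROUPS.values() for n in group}
    unknown = set(six_segment_values) - known
    if unknown:
        raise ValueError(f"unknown segment name(s): {sorted(unknown)}")
    out = {}
    for wall, group in WALL_GROUPS.items():
        vals = [six_segment_values[name] for name in group
                if name in six_segment_values]
        if vals:
            out[wall] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def twist_table(courses: RegionalCourses, frame_interval_ms: float,
                ed_frame: int = 0, es_frame: int | None = None
                ) -> pd.DataFrame:
    """Twist per segment and compartment of one slice."""
    rows = []
    for sid in courses.segment_ids:
        for comp in COMPARTMENTS:
            v_rot = courses.v_rot[(sid, comp)]
            es = es_frame if es_frame is not None else len(v_rot) - 1
            tw = twist(v_rot, frame_interval_ms, ed_frame, es)
            rows.append(dict(segment=sid, name=courses.segment_names[sid],
                             compartment=comp, twist_deg=tw,
                             ed_frame=ed_frame, es_frame=es))
    return pd.DataFrame(rows)


def torsion_table(twist_apical: pd.DataFrame, twist_basal: pd.DataFrame
                  ) -> pd.DataFrame:
    """Torsion per wall and compartment from apical and basal twists.

    The identity torsion = apical twist - basal twist holds exactly for
    every wall and compartment.
    """
    comp_label = {"full": "overall", "epi": "epi", "endo": "endo"}
    rows = []
    for comp in COMPARTMENTS:
        ap = twist_apical[twist_apical.compartment == comp]
        ba = twist_basal[twist_basal.compartment == comp]
        apical_walls = {APICAL_WALLS[n]: t
                        for n, t in zip(ap["name"], ap["twist_deg"])}
        basal_walls = wall_map_6_to_4(
            dict(zip(ba["name"], ba["twist_deg"])))
        for wall in ("septum", "inferior", "lateral", "anterior"):
            rows.append(dict(
                wall=wall, compartment=comp_label[comp],
                twist_apical_deg=apical_walls[wall],
                twist_basal_deg=basal_walls[wall],
                torsion_deg=torsion(apical_walls[wall], basal_walls[wall])))
    return pd.DataFrame(rows)
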