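"""Domain types, geometry conventions and on-disk I/O.

Shared conventions used throughout the package
----------------------------------------------
* Image arrays are indexed ``[frame, row, col]``; x increases with the
  column index (rightward as displayed), y increases with the row index
  (downward as displayed).  The short-axis slice is viewed from foot to
  head, so a visually clockwise rotation in this frame is the positive
  rotation direction of the analysis.
* All geometry is in millimetres.  The origin sits at the centre of the
  first voxel; voxel size is ``fov_mm / matrix`` of the grid the array
  lives on (acquired or reconstructed).
* Velocities are in cm/s, times in ms.
* Encoding order of a four-scan cine set is fixed: motion-compensated
  reference, then x-, y-, z-encoded.

On-disk formats: NIfTI for image stacks (complex data kept at full
precision), JSON for contours / config / manifests, CSV for all numeric
result tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

SLICE_LEVELS = ("basal", "mid", "apical")
ENCODING_ORDER = ("ref", "x", "y", "z")

#: AHA segment ids per slice level (segment 17, the apex cap, is excluded).
AHA_IDS = {"basal": tuple(range(1, 7)), "mid": tuple(range(7, 13)),
           "apical": tuple(range(13, 17))}
AHA_NAMES = {
    "basal": ("anterior", "anteroseptal", "inferoseptal",
              "inferior", "inferolateral", "anterolateral"),
    "mid": ("anterior", "anteroseptal", "inferoseptal",
            "inferior", "inferolateral", "anterolateral"),
    "apical": ("anterior", "septal", "inferior", "lateral"),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of one short-axis cine slice.

    ``venc_through_cm_s`` may be ``None`` for two-encoding (in-plane only)
    datasets; longitudinal outputs are then reported absent rather than
    zero.
    """

    fov_mm: float
    matrix: int
    frame_interval_ms: float
    n_frames: int
    venc_inplane_cm_s: float
    venc_through_cm_s: float | None = 8.0
    slice_level: str = "mid"
    slice_thickness_mm: float = 1.0

    def __post_init__(self):
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be > 0")
        if self.matrix <= 0:
            raise ValueError("matrix must be > 0")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be > 0")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be > 0")
        if self.venc_inplane_cm_s is None or self.venc_inplane_cm_s <= 0:
            raise ValueError("venc_inplane_cm_s must be > 0")
        if self.venc_through_cm_s is not None and self.venc_through_cm_s <= 0:
            raise ValueError("venc_through_cm_s must be > 0 (or None)")
        if self.slice_level not in SLICE_LEVELS:
            raise ValueError(f"slice_level must be one of {SLICE_LEVELS}")

    @property
    def voxel_mm(self) -> float:
        """In-plane voxel size of the acquired matrix."""
        return self.fov_mm / self.matrix

    @property
    def cycle_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ms

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class CineEncodingSet:
    """Four co-registered complex cine stacks of one slice.

    ``scans`` has shape ``(n_enc, n_frames, ny, nx)`` with encodings in
    the fixed order (ref, x, y, z); ``n_enc`` is 3 when the z encoding is
    absent.  ``domain`` states whether the stacks are k-space or image
    data.
    """

    scans: np.ndarray
    meta: AcquisitionMeta
    domain: str = "image"

    def __post_init__(self):
        self.scans = np.asarray(self.scans)
        if self.scans.ndim != 4 or self.scans.shape[0] not in (3, 4):
            raise ValueError("encoding shape mismatch: scans must be "
                             "(3|4, n_frames, ny, nx)")
        if self.scans.shape[1] != self.meta.n_frames:
            raise ValueError("encoding shape mismatch: frame count differs "
                             "from meta.n_frames")
        if self.scans.shape[2] != self.scans.shape[3]:
            raise ValueError("encoding shape mismatch: frames must be square")
        if self.domain not in ("kspace", "image"):
            raise ValueError("domain must be 'kspace' or 'image'")
        if self.has_z and self.meta.venc_through_cm_s is None:
            raise ValueError("missing venc: venc_through_cm_s is required "
                             "for a z-encoded dataset")

    @property
    def has_z(self) -> bool:
        return self.scans.shape[0] == 4

    @property
    def encodings(self) -> tuple:
        return ENCODING_ORDER[: self.scans.shape[0]]


@dataclass
class VelocityField:
    """Per-frame velocity maps (cm/s) plus combined magnitude.

    ``vz`` is ``None`` for two-encoding datasets.  Shapes equal the
    reconstructed (zero-filled) matrix.
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray | None
    magnitude: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self):
        for name, arr in (("vx", self.vx), ("vy", self.vy),
                          ("vz", self.vz), ("magnitude", self.magnitude)):
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if arr.shape != np.shape(self.vx):
                raise ValueError("velocity component shapes differ")

    @property
    def matrix(self) -> int:
        return self.vx.shape[-1]

    @property
    def voxel_mm(self) -> float:
        """Voxel size of the reconstructed grid."""
        return self.meta.fov_mm / self.matrix

    @property
    def has_longitudinal(self) -> bool:
        return self.vz is not None


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def _as_polygon(poly) -> np.ndarray:
    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("open polygon: need at least 3 (x, y) vertices")
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    if p.shape[0] < 3:
        raise ValueError("open polygon: need at least 3 distinct vertices")
    return p


def points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test, vectorised.

    ``points``: (N, 2) array of (x, y); ``poly``: (M, 2) closed polygon
    (last vertex implicitly joined to the first).
    """
    poly = _as_polygon(poly)
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        crosses = (y0 <= y) != (y1 <= y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (x < xi)
        x0, y0 = x1, y1
    return inside


def polygon_area(poly) -> float:
    """Shoelace area (mm^2), always positive."""
    p = _as_polygon(poly)
    x, y = p[:, 0], p[:, 1]
    return abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0


def voxel_grid(matrix: int, voxel_mm: float):
    """(X, Y) mm coordinates of voxel centres on a square grid."""
    c = np.arange(matrix) * voxel_mm
    return np.meshgrid(c, c, indexing="xy")


def rasterize_polygon(poly, matrix: int, voxel_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centre lies inside ``poly``."""
    X, Y = voxel_grid(matrix, voxel_mm)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    return points_in_polygon(pts, poly).reshape(matrix, matrix)


def ccw_angle_deg(dx, dy):
    """Visually counterclockwise polar angle in degrees, [0, 360).

    With y increasing downward (row index), the visually counterclockwise
    angle in the foot-to-head view is ``atan2(-dy, dx)``: 0 deg points
    right (east), 90 deg points to the top of the image.
    """
    return np.degrees(np.arctan2(-np.asarray(dy), np.asarray(dx))) % 360.0


def mask_centroid(mask: np.ndarray, voxel_mm: float) -> np.ndarray:
    """Unweighted centroid (x, y) in mm of a boolean mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    return np.array([cols.mean() * voxel_mm, rows.mean() * voxel_mm])


@dataclass
class LVSegmentation:
    """Frame-by-frame LV delineation.

    Contours are closed planar polygons in mm; the myocardial mask is the
    set of voxels whose centre lies between the contours (even-odd rule);
    the centre of mass is the unweighted centroid of the mask.
    """

    epi_contours: list
    endo_contours: list
    masks: np.ndarray
    centers_mm: np.ndarray
    voxel_mm: float
    static_reference_mask: np.ndarray | None = None
    reference_polygon: np.ndarray | None = None

    @classmethod
    def from_contours(cls, epi_contours, endo_contours, matrix: int,
                      voxel_mm: float, reference_polygon=None
                      ) -> "LVSegmentation":
        if len(epi_contours) != len(endo_contours):
            raise ValueError("need one epi and one endo contour per frame")
        epi = [_as_polygon(p) for p in epi_contours]
        endo = [_as_polygon(p) for p in endo_contours]
        masks, centers = [], []
        for e, n in zip(epi, endo):
            if not points_in_polygon(n, e).all():
                raise ValueError("endocardial contour must lie strictly "
                                 "inside the epicardial contour")
            m = rasterize_polygon(e, matrix, voxel_mm) \
                & ~rasterize_polygon(n, matrix, voxel_mm)
            masks.append(m)
            centers.append(mask_centroid(m, voxel_mm))
        ref_mask = None
        if reference_polygon is not None:
            reference_polygon = _as_polygon(reference_polygon)
            ref_mask = rasterize_polygon(reference_polygon, matrix, voxel_mm)
        return cls(epi, endo, np.array(masks), np.array(centers), voxel_mm,
                   ref_mask, reference_polygon)

    @property
    def n_frames(self) -> int:
        return len(self.epi_contours)

    def cavity_area_mm2(self, frame: int) -> float:
        return polygon_area(self.endo_contours[frame])

    def es_frame(self) -> int:
        """Default end-systole: frame of minimum cavity (endo) area."""
        areas = [self.cavity_area_mm2(t) for t in range(self.n_frames)]
        return int(np.argmin(areas))


@dataclass
class RegionalTimeCourse:
    """One segment x compartment x component velocity series."""

    segment: int
    compartment: str   # full | epi | endo
    component: str     # radial | tangential | longitudinal
    values: np.ndarray          # cm/s, NaN where the segment is missing
    times_ms: np.ndarray
    median_radius_mm: np.ndarray

    def __post_init__(self):
        if not (1 <= self.segment <= 16):
            raise ValueError("segment id must be in 1..16")
        if self.compartment not in ("full", "epi", "endo"):
            raise ValueError("compartment must be full|epi|endo")
        if self.component not in ("radial", "tangential", "longitudinal"):
            raise ValueError("unknown velocity component")
        if len(self.values) != len(self.times_ms):
            raise ValueError("series length must equal number of frames")


# ---------------------------------------------------------------------------
# NIfTI image I/O
# ---------------------------------------------------------------------------

def _affine(voxel_mm: float, slice_thickness_mm: float = 1.0) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, slice_thickness_mm, 1.0])


def _save_stack(stack: np.ndarray, path: Path, voxel_mm: float,
                slice_thickness_mm: float = 1.0) -> None:
    # (frames, ny, nx) -> NIfTI (nx, ny, frames); complex kept as-is.
    data = np.ascontiguousarray(np.transpose(stack, (2, 1, 0)))
    img = nib.Nifti1Image(data, _affine(voxel_mm, slice_thickness_mm))
    nib.save(img, str(path))


def _load_stack(path: Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)   # keep complex dtypes intact
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0)))


def write_cine_dataset(cs: CineEncodingSet, outdir, layout: str = "per_encoding"
                       ) -> None:
    """Write a cine encoding set as NIfTI stacks plus a meta.json.

    ``layout='per_encoding'`` writes one file per encoding
    (enc_ref.nii, enc_x.nii, ...); ``layout='stacked'`` writes a single
    4-D file with a trailing encoding dimension.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vx = cs.meta.voxel_mm
    if layout == "per_encoding":
        for name, stack in zip(cs.encodings, cs.scans):
            _save_stack(stack, outdir / f"enc_{name}.nii", vx,
                        cs.meta.slice_thickness_mm)
    elif layout == "stacked":
        data = np.ascontiguousarray(np.transpose(cs.scans, (3, 2, 1, 0)))
        nib.save(nib.Nifti1Image(data, _affine(vx, cs.meta.slice_thickness_mm)),
                 str(outdir / "encodings.nii"))
    else:
        raise ValueError("layout must be 'per_encoding' or 'stacked'")
    meta = cs.meta.to_dict()
    meta.update(domain=cs.domain, layout=layout,
                encodings=list(cs.encodings))
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))


def read_cine_dataset(path, config: dict | None = None) -> CineEncodingSet:
    """Read a cine encoding set written by :func:`write_cine_dataset`.

    ``config`` entries override / complete the stored metadata (keys
    ``venc_inplane``, ``venc_through``, ``frame_interval_ms``, ``fov_mm``,
    ``slice_level``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta_d = json.loads((path / "meta.json").read_text())
    if config:
        remap = {"venc_inplane": "venc_inplane_cm_s",
                 "venc_through": "venc_through_cm_s"}
        for k, v in config.items():
            meta_d[remap.get(k, k)] = v
    for required in ("venc_inplane_cm_s",):
        if meta_d.get(required) is None:
            raise ValueError(f"missing venc: {required} is required")
    layout = meta_d.get("layout", "per_encoding")
    encodings = meta_d.get("encodings", list(ENCODING_ORDER))
    if layout == "per_encoding":
        stacks = [_load_stack(path / f"enc_{name}.nii") for name in encodings]
        shapes = {s.shape for s in stacks}
        if len(shapes) != 1:
            raise ValueError("encoding shape mismatch between scan files")
        scans = np.stack(stacks)
    else:
        data = np.asanyarray(nib.load(str(path / "encodings.nii")).dataobj)
        scans = np.ascontiguousarray(np.transpose(data, (3, 2, 1, 0)))
    meta = AcquisitionMeta.from_dict(meta_d)
    return CineEncodingSet(scans=scans, meta=meta,
                           domain=meta_d.get("domain", "image"))


def write_velocity_field(vel: VelocityField, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vx_mm = vel.voxel_mm
    comps = {"vx": vel.vx, "vy": vel.vy, "magnitude": vel.magnitude}
    if vel.has_longitudinal:
        comps["vz"] = vel.vz
    for name, stack in comps.items():
        _save_stack(np.asarray(stack, dtype=np.float64),
                    outdir / f"{name}.nii", vx_mm,
                    vel.meta.slice_thickness_mm)
    meta = vel.meta.to_dict()
    meta["components"] = sorted(comps)
    meta["matrix_reconstructed"] = vel.matrix
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))


def read_velocity_field(path) -> VelocityField:
    path = Path(path)
    meta_d = json.loads((path / "meta.json").read_text())
    meta = AcquisitionMeta.from_dict(meta_d)
    vz = None
    if "vz" in meta_d.get("components", []):
        vz = _load_stack(path / "vz.nii")
    return VelocityField(vx=_load_stack(path / "vx.nii"),
                         vy=_load_stack(path / "vy.nii"),
                         vz=vz,
                         magnitude=_load_stack(path / "magnitude.nii"),
                         meta=meta)


# ---------------------------------------------------------------------------
# contour / mask JSON I/O
# ---------------------------------------------------------------------------

def write_contours(seg: LVSegmentation, path, matrix: int | None = None
                   ) -> None:
    matrix = matrix if matrix is not None else seg.masks.shape[-1]
    doc = {
        "matrix": int(matrix),
        "voxel_mm": float(seg.voxel_mm),
        "frames": [
            {"epi": np.asarray(e).tolist(), "endo": np.asarray(n).tolist()}
            for e, n in zip(seg.epi_contours, seg.endo_contours)
        ],
        "reference": (None if seg.reference_polygon is None
                      else np.asarray(seg.reference_polygon).tolist()),
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path, matrix: int | None = None,
                  voxel_mm: float | None = None) -> LVSegmentation:
    """Load contours and rasterize them.

    By default the grid stored in the file is used; passing ``matrix``
    (and optionally ``voxel_mm``) re-rasterizes onto another grid, e.g.
    the zero-filled reconstruction matrix.
    """
    doc = json.loads(Path(path).read_text())
    stored_matrix = doc["matrix"]
    stored_fov = doc["voxel_mm"] * stored_matrix
    if matrix is None:
        matrix = stored_matrix
    if voxel_mm is None:
        voxel_mm = stored_fov / matrix
    epi = [f["epi"] for f in doc["frames"]]
    endo = [f["endo"] for f in doc["frames"]]
    return LVSegmentation.from_contours(epi, endo, matrix, voxel_mm,
                                        reference_polygon=doc.get("reference"))


# ---------------------------------------------------------------------------
# result tables and manifests
# ---------------------------------------------------------------------------

def write_results(tables: dict, outdir, manifest: dict | None = None) -> list:
    """Write result DataFrames as CSV plus an optional JSON run manifest.

    Returns the list of files written.  An empty DataFrame yields a CSV
    with the header row only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        pd.DataFrame(df).to_csv(p, index=False)
        written.append(p)
    if manifest is not None:
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(p)
    return written


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
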