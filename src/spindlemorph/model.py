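"""Geometric data model and interchange I/O for reconstructed spindles.

A reconstructed spindle is a collection of microtubule polylines, closed
chromosome surface meshes and centriole axis segments, with all coordinates
in **nanometers**. Downstream statistics are reported in micrometers
(conversion factor exactly 1000). Coordinates are 0-based and right-handed;
no implicit axis flipping is performed anywhere.

Two plain-text interchange formats are supported:

``JSON`` (one object per file)::

    {
      "name": "...",
      "units": "nm",                      # mandatory
      "kinetochore_thickness_nm": 150.0,
      "microtubules":  [{"id": 1, "points": [[x,y,z], ...]}, ...],
      "chromosomes":   [{"id": 1, "cls": "autosome"|"x_chromosome",
                         "pair_id": 0 | null,
                         "vertices": [[x,y,z], ...],
                         "faces": [[i,j,k], ...]}, ...],
      "centrioles":    [{"id": 1, "pole_id": 1|2,
                         "role": "mother"|"daughter"|"unknown",
                         "centerline": [[x,y,z], [x,y,z]]}, ...]
    }

``CSV`` point table: one row per point with columns
``object_type, object_id, contour_id, x_nm, y_nm, z_nm`` plus the optional
attribute columns ``cls, pair_id, pole_id, role``. Microtubule rows use
``contour_id`` as the point index; chromosome surfaces are stored as
``chromosome_vertex`` rows (``contour_id`` = vertex index) and
``chromosome_face`` rows whose coordinate columns hold the three vertex
indices; centrioles as ``centriole`` rows. A single ``meta`` row carries the
model name and kinetochore thickness.

Chromosome surfaces may alternatively be supplied as voxel masks; they are
converted to triangle meshes by isosurface extraction at load time so that
downstream code sees a single surface representation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
import yaml

NM_PER_UM = 1000.0

__all__ = [
    "NM_PER_UM",
    "MicrotubulePath",
    "ChromosomeBody",
    "Centriole",
    "SpindleModel",
    "TimelapseSeries",
    "GeometryValidationError",
    "load_geometry",
    "save_geometry",
    "load_timelapse",
]


class GeometryValidationError(ValueError):
    """Raised when an interchange file or in-memory model violates the schema."""


@dataclass
class MicrotubulePath:
    """One microtubule as an ordered 3D polyline (coordinates in nm)."""

    id: int
    points: np.ndarray  # (n, 2+) float, nm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise GeometryValidationError(
                f"microtubule {self.id}: need an (n>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise GeometryValidationError(f"microtubule {self.id}: non-finite point")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
            raise GeometryValidationError(
                f"microtubule {self.id}: consecutive points coincide")
        self.points = pts

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, MicrotubulePath) and self.id == other.id
                and np.array_equal(self.points, other.points))


@dataclass
class ChromosomeBody:
    """A chromosome as a closed (watertight) triangle mesh, nm coordinates."""

    id: int
    cls: str  # 'autosome' | 'x_chromosome'
    mesh: trimesh.Trimesh
    pair_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cls not in ("autosome", "x_chromosome"):
            raise GeometryValidationError(
                f"chromosome {self.id}: cls must be autosome or x_chromosome")
        if not isinstance(self.mesh, trimesh.Trimesh):
            raise GeometryValidationError(f"chromosome {self.id}: mesh required")
        if len(self.mesh.faces) == 0 or not self.mesh.is_watertight:
            raise GeometryValidationError(
                f"chromosome {self.id}: surface mesh is not closed (watertight)")

    @classmethod
    def from_voxel_mask(cls, id: int, mask: np.ndarray, voxel_size_nm: Sequence[float],
                        chromosome_cls: str = "autosome",
                        pair_id: Optional[int] = None) -> "ChromosomeBody":
        """Build a surface mesh from a binary voxel mask by isosurface
        extraction (marching cubes at level 0.5)."""
        from skimage.measure import marching_cubes

        padded = np.pad(np.asarray(mask, dtype=float), 1)
        verts, faces, _, _ = marching_cubes(padded, level=0.5,
                                            spacing=tuple(float(v) for v in voxel_size_nm))
        verts -= np.asarray(voxel_size_nm, dtype=float)  # undo padding shift
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        trimesh.repair.fix_normals(mesh)
        return cls(id=id, cls=chromosome_cls, mesh=mesh, pair_id=pair_id)

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid (nm)."""
        return np.asarray(self.mesh.centroid, dtype=float)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ChromosomeBody) and self.id == other.id
                and self.cls == other.cls and self.pair_id == other.pair_id
                and np.array_equal(self.mesh.vertices, other.mesh.vertices)
                and np.array_equal(self.mesh.faces, other.mesh.faces))


@dataclass
class Centriole:
    """A centriole, stored as a short axis segment or a single centroid (nm)."""

    id: int
    pole_id: int  # 1 or 2
    centerline: np.ndarray  # (1 or 2, 3) nm
    role: str = "unknown"  # 'mother' | 'daughter' | 'unknown'

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if pts.shape[0] not in (1, 2) or pts.shape[1] != 3:
            raise GeometryValidationError(
                f"centriole {self.id}: centerline must be 1 or 2 points")
        if self.pole_id not in (1, 2):
            raise GeometryValidationError(f"centriole {self.id}: pole_id must be 1 or 2")
        if self.role not in ("mother", "daughter", "unknown"):
            raise GeometryValidationError(f"centriole {self.id}: bad role {self.role!r}")
        self.centerline = pts

    @property
    def centroid(self) -> np.ndarray:
        return self.centerline.mean(axis=0)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Centriole) and self.id == other.id
                and self.pole_id == other.pole_id and self.role == other.role
                and np.array_equal(self.centerline, other.centerline))


@dataclass
class SpindleModel:
    """One reconstructed spindle (all geometry in nm)."""

    name: str
    microtubules: list = field(default_factory=list)
    chromosomes: list = field(default_factory=list)
    centrioles: list = field(default_factory=list)
    kinetochore_thickness: float = 150.0  # nm
    units: str = "nm"

    def __post_init__(self) -> None:
        if self.kinetochore_thickness <= 0:
            raise GeometryValidationError("kinetochore_thickness must be > 0")
        if len(self.chromosomes) < 1:
            raise GeometryValidationError("model needs at least one chromosome")
        n_x = sum(1 for c in self.chromosomes if c.cls == "x_chromosome")
        if n_x > 1:
            raise GeometryValidationError("at most one X chromosome per model")
        for pid in (1, 2):
            n = len(self.centrioles_of_pole(pid))
            if n > 2:
                raise GeometryValidationError(f"pole {pid}: more than 2 centrioles")

    # -- convenience accessors -------------------------------------------
    @property
    def x_chromosome(self) -> Optional[ChromosomeBody]:
        for c in self.chromosomes:
            if c.cls == "x_chromosome":
                return c
        return None

    @property
    def autosomes(self) -> list:
        return [c for c in self.chromosomes if c.cls == "autosome"]

    def centrioles_of_pole(self, pole_id: int) -> list:
        return [c for c in self.centrioles if c.pole_id == pole_id]

    def pole_centroid(self, pole_id: int) -> np.ndarray:
        """Centrosome center: mean of the pole's centriole centroids (nm)."""
        cents = self.centrioles_of_pole(pole_id)
        if not cents:
            raise GeometryValidationError(f"pole {pole_id}: no centrioles")
        return np.mean([c.centroid for c in cents], axis=0)

    def spindle_axis(self) -> np.ndarray:
        """Unit vector pole 1 -> pole 2."""
        v = self.pole_centroid(2) - self.pole_centroid(1)
        n = np.linalg.norm(v)
        if n == 0:
            raise GeometryValidationError("coincident poles: spindle axis undefined")
        return v / n

    def mt_by_id(self, mt_id: int) -> MicrotubulePath:
        for mt in self.microtubules:
            if mt.id == mt_id:
                return mt
        raise KeyError(mt_id)

    def chromosome_by_id(self, chrom_id: int) -> ChromosomeBody:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SpindleModel) and self.name == other.name
                and self.units == other.units
                and self.kinetochore_thickness == other.kinetochore_thickness
                and self.microtubules == other.microtubules
                and self.chromosomes == other.chromosomes
                and self.centrioles == other.centrioles)


# ---------------------------------------------------------------------------
# geometry I/O
# ---------------------------------------------------------------------------

def save_geometry(model: SpindleModel, path, format: str = "json") -> None:
    """Write a model to JSON or the flat CSV point table.

    ``load_geometry(save_geometry(m)) == m`` holds bitwise on coordinates for
    both formats.
    """
    path = Path(path)
    if format == "json":
        obj = {
            "name": model.name,
            "units": model.units,
            "kinetochore_thickness_nm": model.kinetochore_thickness,
            "microtubules": [
                {"id": int(mt.id), "points": mt.points.tolist()}
                for mt in model.microtubules
            ],
            "chromosomes": [
                {"id": int(c.id), "cls": c.cls,
                 "pair_id": None if c.pair_id is None else int(c.pair_id),
                 "vertices": np.asarray(c.mesh.vertices, dtype=float).tolist(),
                 "faces": np.asarray(c.mesh.faces, dtype=int).tolist()}
                for c in model.chromosomes
            ],
            "centrioles": [
                {"id": int(c.id), "pole_id": int(c.pole_id), "role": c.role,
                 "centerline": c.centerline.tolist()}
                for c in model.centrioles
            ],
        }
        path.write_text(json.dumps(obj))
    elif format == "csv_points":
        rows = []

        def row(object_type, object_id, contour_id, x, y, z, **attrs):
            r = {"object_type": object_type, "object_id": object_id,
                 "contour_id": contour_id, "x_nm": x, "y_nm": y, "z_nm": z,
                 "cls": "", "pair_id": "", "pole_id": "", "role": ""}
            r.update(attrs)
            rows.append(r)

        row("meta", 0, 0, model.kinetochore_thickness, 0.0, 0.0, role=model.name)
        for mt in model.microtubules:
            for i, p in enumerate(mt.points):
                row("microtubule", int(mt.id), i, p[0], p[1], p[2])
        for c in model.chromosomes:
            pair = "" if c.pair_id is None else int(c.pair_id)
            for i, v in enumerate(np.asarray(c.mesh.vertices, dtype=float)):
                row("chromosome_vertex", int(c.id), i, v[0], v[1], v[2],
                    cls=c.cls, pair_id=pair)
            for i, f in enumerate(np.asarray(c.mesh.faces, dtype=int)):
                row("chromosome_face", int(c.id), i,
                    float(f[0]), float(f[1]), float(f[2]), cls=c.cls, pair_id=pair)
        for c in model.centrioles:
            for i, p in enumerate(c.centerline):
                row("centriole", int(c.id), i, p[0], p[1], p[2],
                    pole_id=int(c.pole_id), role=c.role)
        # %.17g round-trips IEEE doubles exactly
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown geometry format {format!r}")


def _mesh_from_arrays(chrom_id, vertices, faces) -> trimesh.Trimesh:
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if faces.size and faces.max() >= len(vertices):
        raise GeometryValidationError(
            f"chromosome {chrom_id}: face references missing vertex "
            f"{int(faces.max())} (only {len(vertices)} vertices)")
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def load_geometry(path, format: Optional[str] = None) -> SpindleModel:
    """Read a model from JSON or the flat CSV point table (unit tag: nm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv_points" if path.suffix.lower() == ".csv" else "json"

    if format == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise GeometryValidationError(f"malformed JSON in {path}: {e}") from e
        if obj.get("units") != "nm":
            raise GeometryValidationError(
                f"{path}: geometry files must declare units: nm "
                f"(found {obj.get('units')!r})")
        mts, chroms, cents = [], [], []
        for rec in obj.get("microtubules", []):
            try:
                mts.append(MicrotubulePath(id=int(rec["id"]),
                                           points=np.asarray(rec["points"], float)))
            except (KeyError, TypeError) as e:
                raise GeometryValidationError(
                    f"malformed microtubule record {rec.get('id')!r}: {e}") from e
        for rec in obj.get("chromosomes", []):
            if "mask" in rec:
                chroms.append(ChromosomeBody.from_voxel_mask(
                    id=int(rec["id"]), mask=np.asarray(rec["mask"]),
                    voxel_size_nm=rec["voxel_size_nm"],
                    chromosome_cls=rec.get("cls", "autosome"),
                    pair_id=rec.get("pair_id")))
            else:
                mesh = _mesh_from_arrays(rec.get("id"), rec["vertices"], rec["faces"])
                chroms.append(ChromosomeBody(
                    id=int(rec["id"]), cls=rec["cls"], mesh=mesh,
                    pair_id=rec.get("pair_id")))
        for rec in obj.get("centrioles", []):
            cents.append(Centriole(id=int(rec["id"]), pole_id=int(rec["pole_id"]),
                                   centerline=np.asarray(rec["centerline"], float),
                                   role=rec.get("role", "unknown")))
        return SpindleModel(
            name=obj.get("name", path.stem), microtubules=mts, chromosomes=chroms,
            centrioles=cents,
            kinetochore_thickness=float(obj.get("kinetochore_thickness_nm", 150.0)))

    if format == "csv_points":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"object_type", "object_id", "contour_id", "x_nm", "y_nm", "z_nm"}
        missing = required - set(df.columns)
        if missing:
            raise GeometryValidationError(f"{path}: missing CSV columns {sorted(missing)}")
        name, thickness = path.stem, 150.0
        meta = df[df.object_type == "meta"]
        if len(meta):
            name = str(meta.iloc[0]["role"])
            thickness = float(meta.iloc[0]["x_nm"])
        mts = []
        for mt_id, g in df[df.object_type == "microtubule"].groupby("object_id"):
            g = g.sort_values("contour_id")
            mts.append(MicrotubulePath(id=int(mt_id),
                                       points=g[["x_nm", "y_nm", "z_nm"]].to_numpy()))
        chroms = []
        verts_df = df[df.object_type == "chromosome_vertex"]
        faces_df = df[df.object_type == "chromosome_face"]
        for cid, g in verts_df.groupby("object_id"):
            g = g.sort_values("contour_id")
            fg = faces_df[faces_df.object_id == cid].sort_values("contour_id")
            faces = fg[["x_nm", "y_nm", "z_nm"]].to_numpy().astype(int)
            mesh = _mesh_from_arrays(cid, g[["x_nm", "y_nm", "z_nm"]].to_numpy(), faces)
            pair = g.iloc[0]["pair_id"]
            pair_id = None if (pd.isna(pair) or pair == "") else int(pair)
            chroms.append(ChromosomeBody(id=int(cid), cls=str(g.iloc[0]["cls"]),
                                         mesh=mesh, pair_id=pair_id))
        cents = []
        for cid, g in df[df.object_type == "centriole"].groupby("object_id"):
            g = g.sort_values("contour_id")
            cents.append(Centriole(id=int(cid), pole_id=int(g.iloc[0]["pole_id"]),
                                   centerline=g[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                                   role=str(g.iloc[0]["role"])))
        mts.sort(key=lambda m: m.id)
        chroms.sort(key=lambda c: c.id)
        cents.sort(key=lambda c: c.id)
        return SpindleModel(name=name, microtubules=mts, chromosomes=chroms,
                            centrioles=cents, kinetochore_thickness=thickness)

    raise ValueError(f"unknown geometry format {format!r}")


# ---------------------------------------------------------------------------
# time-lapse I/O
# ---------------------------------------------------------------------------

@dataclass
class TimelapseSeries:
    """Two-channel 4D fluorescence time series, normalized to T,C,Z,Y,X.

    voxel_size is (z, y, x) in micrometers, frame_interval in seconds.
    channel_roles maps 'poles' (gamma/beta-tubulin) and 'chromatin'
    (histone) to channel indices.
    """

    frames: np.ndarray  # (T, C, Z, Y, X)
    voxel_size: tuple  # (z, y, x) um
    frame_interval: float  # s
    channel_roles: dict

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 5:
            raise GeometryValidationError(
                f"time-lapse must be 5D (T,C,Z,Y,X); got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise GeometryValidationError("need at least 2 time points")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryValidationError("voxel sizes must be > 0")
        self.frames = frames
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """(T, Z, Y, X) stack for a channel role ('poles' or 'chromatin')."""
        return self.frames[:, self.channel_roles[role]]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def load_timelapse(tiff_path, sidecar_config) -> TimelapseSeries:
    """Read a multi-page TIFF plus YAML sidecar into a normalized series.

    The sidecar must provide ``axes`` (on-disk order, e.g. "TZCYX"),
    ``voxel_size_um`` ([z, y, x] or mapping), ``frame_interval_s`` and
    ``channel_roles`` ({"poles": idx, "chromatin": idx}).
    """
    import tifffile

    if isinstance(sidecar_config, (str, Path)):
        cfg = yaml.safe_load(Path(sidecar_config).read_text())
    else:
        cfg = dict(sidecar_config)
    for key in ("axes", "voxel_size_um", "frame_interval_s", "channel_roles"):
        if key not in cfg:
            raise GeometryValidationError(f"sidecar config missing key {key!r}")

    data = tifffile.imread(str(tiff_path))
    axes = str(cfg["axes"]).upper()
    if sorted(axes) != sorted("TCZYX"):
        raise GeometryValidationError(
            f"axes must be a permutation of TCZYX, got {axes!r}")
    if data.ndim != 5:
        raise GeometryValidationError(
            f"expected a 5D stack for axes {axes!r}, found shape {data.shape}")
    order = [axes.index(a) for a in "TCZYX"]
    data = np.transpose(data, order)

    vs = cfg["voxel_size_um"]
    if isinstance(vs, dict):
        voxel = (float(vs["z"]), float(vs["y"]), float(vs["x"]))
    else:
        voxel = tuple(float(v) for v in vs)
    return TimelapseSeries(frames=data.astype(float), voxel_size=voxel,
                           frame_interval=float(cfg["frame_interval_s"]),
                           channel_roles={k: int(v)
                                          for k, v in cfg["channel_roles"].items()})
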