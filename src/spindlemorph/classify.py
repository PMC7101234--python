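"""Kinetochore-microtubule classification.

A microtubule is a kinetochore microtubule (KMT) when any of its polyline
points lies within the kinetochore zone of a chromosome — a shell of
configurable thickness (default 150 nm, the measured extent of the
ribosome-free holocentric kinetochore) around the chromosome surface.
Because anaphase microtubules can pass between the autosomes before reaching
the univalent X, candidates are tested against the X chromosome first and
only unassociated ones against the autosomes (nearest autosome wins; ties on
distance break toward the lower chromosome id).

The association is *end-on* when a 150 nm extrapolation beyond the putative
plus end (direction: chord over the final 100 nm of the path) intersects the
chromosome surface, otherwise *lateral*. The putative plus end of a KMT is
the endpoint closer to the associated chromosome's surface; for non-KMTs it
is the endpoint farther from the nearest centriole (spindle polarity).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._geom import point_triangle_distance, ray_triangle_hits
from .model import MicrotubulePath, ChromosomeBody, SpindleModel

logger = logging.getLogger(__name__)

__all__ = [
    "MicrotubuleAnnotation",
    "min_distance_to_surface",
    "classify_kmt",
    "association_type",
    "classify_all",
    "count_table",
]

#: arc length of the terminal chord used to estimate the plus-end direction (nm)
PLUS_END_CHORD_NM = 100.0


@dataclass
class MicrotubuleAnnotation:
    mt_id: int
    is_kmt: bool
    chromosome_id: Optional[int]
    association: str  # 'end_on' | 'lateral' | 'none'
    min_surface_distance: float  # nm, to the associated chromosome (nan if none)
    plus_end_index: str  # 'first' | 'last'
    pole_id: Optional[int]  # pole of the centriole nearest the minus end

    def __post_init__(self) -> None:
        if self.is_kmt != (self.association != "none"):
            raise ValueError("association must be 'none' iff not a KMT")


def _triangles(chrom: ChromosomeBody) -> np.ndarray:
    tri = np.asarray(chrom.mesh.triangles, dtype=float)
    if len(tri) == 0:
        raise ValueError(f"chromosome {chrom.id}: degenerate mesh (no faces)")
    return tri


def min_distance_to_surface(mt: MicrotubulePath, chrom: ChromosomeBody) -> float:
    """Minimum distance (nm) over the polyline *points* to the surface mesh.

    Matches the per-point classification distance (intermediate positions on
    segments are not interpolated).
    """
    return float(point_triangle_distance(mt.points, _triangles(chrom)).min())


def _plus_end_direction(points: np.ndarray, plus_first: bool,
                        chord_nm: float = PLUS_END_CHORD_NM,
                        mode: str = "chord") -> tuple[np.ndarray, np.ndarray]:
    """Plus-end position and outgoing unit direction.

    mode='chord': direction of the chord spanning the final `chord_nm` of arc
    length before the plus end (robust to digitization noise).
    mode='segment': direction of the literal last segment.
    """
    pts = points[::-1] if plus_first else points
    tip = pts[-1]
    if mode == "segment":
        base = pts[-2]
    else:
        # walk back along the path until chord_nm of arc length is covered
        acc = 0.0
        base = pts[-2]
        for i in range(len(pts) - 1, 0, -1):
            acc += float(np.linalg.norm(pts[i] - pts[i - 1]))
            base = pts[i - 1]
            if acc >= chord_nm:
                break
    d = tip - base
    n = np.linalg.norm(d)
    if n == 0:  # fall back to full end-to-end chord
        d = tip - pts[0]
        n = np.linalg.norm(d)
    return tip, d / n


def association_type(mt: MicrotubulePath, chrom: ChromosomeBody,
                     extrapolation_nm: float = 150.0,
                     direction_mode: str = "chord") -> str:
    """'end_on' if the extrapolated plus end points into the chromosome,
    else 'lateral'. The microtubule must already be assigned to `chrom`."""
    tri = _triangles(chrom)
    d_first = point_triangle_distance(mt.points[0], tri)[0]
    d_last = point_triangle_distance(mt.points[-1], tri)[0]
    plus_first = d_first < d_last
    tip, direction = _plus_end_direction(mt.points, plus_first, mode=direction_mode)
    hits = ray_triangle_hits(tip, direction, tri)
    return "end_on" if (len(hits) and hits[0] <= extrapolation_nm) else "lateral"


def _nearest_pole(model: SpindleModel, point: np.ndarray) -> Optional[int]:
    if not model.centrioles:
        return None
    dists = [(np.linalg.norm(c.centroid - point), c.pole_id) for c in model.centrioles]
    return min(dists)[1]


def classify_kmt(mt: MicrotubulePath, model: SpindleModel,
                 threshold_nm: Optional[float] = None,
                 direction_mode: str = "chord") -> MicrotubuleAnnotation:
    """Classify a single microtubule against all chromosomes of the model."""
    threshold = model.kinetochore_thickness if threshold_nm is None else threshold_nm

    chrom: Optional[ChromosomeBody] = None
    dist = np.nan
    x = model.x_chromosome
    if x is not None:
        d = min_distance_to_surface(mt, x)
        if d <= threshold:
            chrom, dist = x, d
    if chrom is None:
        best = None
        for c in sorted(model.autosomes, key=lambda c: c.id):
            d = min_distance_to_surface(mt, c)
            if d <= threshold and (best is None or d < best[0]):
                best = (d, c)
            elif best is not None and d == best[0]:
                logger.debug("mt %s equidistant to autosomes %s and %s; keeping %s",
                             mt.id, best[1].id, c.id, best[1].id)
        if best is not None:
            dist, chrom = best

    if chrom is None:
        # non-KMT: plus end = endpoint farther from the nearest centriole
        if model.centrioles:
            cents = np.array([c.centroid for c in model.centrioles])
            d0 = np.linalg.norm(cents - mt.points[0], axis=1).min()
            d1 = np.linalg.norm(cents - mt.points[-1], axis=1).min()
            plus_first = d0 > d1
        else:
            plus_first = False
        minus_end = mt.points[-1] if plus_first else mt.points[0]
        return MicrotubuleAnnotation(
            mt_id=mt.id, is_kmt=False, chromosome_id=None, association="none",
            min_surface_distance=np.nan,
            plus_end_index="first" if plus_first else "last",
            pole_id=_nearest_pole(model, minus_end))

    tri = _triangles(chrom)
    d_first = point_triangle_distance(mt.points[0], tri)[0]
    d_last = point_triangle_distance(mt.points[-1], tri)[0]
    plus_first = d_first < d_last
    assoc = association_type(mt, chrom, extrapolation_nm=model.kinetochore_thickness,
                             direction_mode=direction_mode)
    minus_end = mt.points[-1] if plus_first else mt.points[0]
    return MicrotubuleAnnotation(
        mt_id=mt.id, is_kmt=True, chromosome_id=chrom.id, association=assoc,
        min_surface_distance=float(dist),
        plus_end_index="first" if plus_first else "last",
        pole_id=_nearest_pole(model, minus_end))


def classify_all(model: SpindleModel, threshold_nm: Optional[float] = None,
                 direction_mode: str = "chord") -> pd.DataFrame:
    """Annotate every microtubule. Returns one row per microtubule with
    columns mt_id, is_kmt, chromosome_id, association, min_surface_distance,
    plus_end_index, pole_id.

    Semantics are identical to calling `classify_kmt` per microtubule; the
    point-to-surface distances are computed in one batch per chromosome.
    """
    threshold = model.kinetochore_thickness if threshold_nm is None else threshold_nm
    mts = model.microtubules
    if not mts:
        return pd.DataFrame(columns=["mt_id", "is_kmt", "chromosome_id",
                                     "association", "min_surface_distance",
                                     "plus_end_index", "pole_id"])
    all_pts = np.vstack([mt.points for mt in mts])
    bounds = np.cumsum([0] + [len(mt.points) for mt in mts])
    x = model.x_chromosome
    chroms = ([] if x is None else [x]) + sorted(model.autosomes, key=lambda c: c.id)
    dist = np.empty((len(mts), len(chroms)))
    for j, c in enumerate(chroms):
        d = point_triangle_distance(all_pts, _triangles(c), chunk=128)
        dist[:, j] = np.minimum.reduceat(d, bounds[:-1])

    cents = (np.array([c.centroid for c in model.centrioles])
             if model.centrioles else None)
    pole_ids = [c.pole_id for c in model.centrioles]
    rows = []
    for i, mt in enumerate(mts):
        chrom = None
        if x is not None and dist[i, 0] <= threshold:
            chrom, dmin = x, dist[i, 0]
        else:
            j0 = 0 if x is None else 1
            auto = dist[i, j0:]
            if len(auto) and auto.min() <= threshold:
                j = int(np.argmin(auto))  # ties -> lower id (sorted order)
                chrom, dmin = chroms[j0 + j], auto[j]
        if chrom is None:
            if cents is not None:
                d0 = np.linalg.norm(cents - mt.points[0], axis=1).min()
                d1 = np.linalg.norm(cents - mt.points[-1], axis=1).min()
                plus_first = d0 > d1
            else:
                plus_first = False
            minus_end = mt.points[-1] if plus_first else mt.points[0]
            pole = (pole_ids[int(np.argmin(np.linalg.norm(cents - minus_end, axis=1)))]
                    if cents is not None else None)
            rows.append(dict(mt_id=mt.id, is_kmt=False, chromosome_id=None,
                             association="none", min_surface_distance=np.nan,
                             plus_end_index="first" if plus_first else "last",
                             pole_id=pole))
            continue
        tri = _triangles(chrom)
        d_first = point_triangle_distance(mt.points[0], tri)[0]
        d_last = point_triangle_distance(mt.points[-1], tri)[0]
        plus_first = d_first < d_last
        assoc = association_type(mt, chrom,
                                 extrapolation_nm=model.kinetochore_thickness,
                                 direction_mode=direction_mode)
        minus_end = mt.points[-1] if plus_first else mt.points[0]
        pole = (pole_ids[int(np.argmin(np.linalg.norm(cents - minus_end, axis=1)))]
                if cents is not None else None)
        rows.append(dict(mt_id=mt.id, is_kmt=True, chromosome_id=chrom.id,
                         association=assoc, min_surface_distance=float(dmin),
                         plus_end_index="first" if plus_first else "last",
                         pole_id=pole))
    return pd.DataFrame(rows)


def count_table(model: SpindleModel, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-spindle count summary mirroring the tomography report layout."""
    ann = annotations
    x = model.x_chromosome
    x_id = None if x is None else x.id
    on_x = ann.chromosome_id == x_id if x_id is not None else pd.Series(False, index=ann.index)
    kmt = ann.is_kmt
    rows = {
        "mts_total": len(ann),
        "kmts_total": int(kmt.sum()),
        "end_on_x": int((on_x & (ann.association == "end_on")).sum()),
        "lateral_x": int((on_x & (ann.association == "lateral")).sum()),
        "end_on_autosomes": int((kmt & ~on_x & (ann.association == "end_on")).sum()),
        "lateral_autosomes": int((kmt & ~on_x & (ann.association == "lateral")).sum()),
    }
    return pd.DataFrame([rows], index=[model.name])
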