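"""Per-spindle geometric statistics of reconstructed spindles.

All inputs are nanometer geometry; every reported scalar is in micrometers
(or degrees for angles). The spindle axis is the unit vector between the two
pole centroids, where a pole centroid is the mean of that pole's centriole
centroids. Chromosome centers are area-weighted surface-mesh centroids.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._geom import point_triangle_distance, segment_box_clip_length
from .model import NM_PER_UM, ChromosomeBody, MicrotubulePath, SpindleModel

__all__ = [
    "arc_length",
    "tortuosity",
    "plus_end_to_centriole",
    "attachment_angle",
    "AngleMeasurement",
    "stretch_fwhm",
    "StretchMeasurement",
    "polymer_box_ratio",
    "BoxRatio",
    "stage_metrics",
    "StageMetrics",
    "summarize_spindle",
]


# ---------------------------------------------------------------------------
# polyline statistics
# ---------------------------------------------------------------------------

def arc_length(mt: MicrotubulePath) -> float:
    """Polyline chord-sum length in micrometers."""
    return float(np.linalg.norm(np.diff(mt.points, axis=0), axis=1).sum()) / NM_PER_UM


def tortuosity(mt: MicrotubulePath) -> float:
    """Path length divided by end-to-end distance (>= 1; 1 for straight)."""
    ee = float(np.linalg.norm(mt.points[-1] - mt.points[0]))
    if ee == 0:
        raise ValueError(f"microtubule {mt.id}: coincident endpoints, "
                         "tortuosity undefined for a closed path")
    return arc_length(mt) * NM_PER_UM / ee


# ---------------------------------------------------------------------------
# plus-end geometry (end-on autosomal KMTs)
# ---------------------------------------------------------------------------

def _plus_minus_ends(mt: MicrotubulePath, plus_end_index: str):
    if plus_end_index == "first":
        return mt.points[0], mt.points[-1]
    return mt.points[-1], mt.points[0]


def plus_end_to_centriole(annotation, model: SpindleModel) -> float:
    """Distance (um) from a KMT's plus end to the centroid of the centriole
    closest to its minus end."""
    if not model.centrioles:
        raise ValueError("model has no centrioles")
    mt = model.mt_by_id(annotation.mt_id)
    plus, minus = _plus_minus_ends(mt, annotation.plus_end_index)
    cents = [c.centroid for c in model.centrioles]
    nearest = min(cents, key=lambda c: np.linalg.norm(c - minus))
    return float(np.linalg.norm(plus - nearest)) / NM_PER_UM


@dataclass
class AngleMeasurement:
    mt_id: int
    alpha: float  # degrees in [0, 180]


def attachment_angle(annotation, model: SpindleModel) -> AngleMeasurement:
    """Angle alpha between the chromosome-center -> centrosome-center axis
    and the chromosome-center -> plus-end vector, in degrees."""
    if annotation.chromosome_id is None:
        raise ValueError("attachment angle needs a chromosome-associated KMT")
    mt = model.mt_by_id(annotation.mt_id)
    chrom = model.chromosome_by_id(annotation.chromosome_id)
    plus, minus = _plus_minus_ends(mt, annotation.plus_end_index)
    center = chrom.centroid
    # centrosome of the pole nearest the minus end
    pole_id = annotation.pole_id
    if pole_id is None:
        raise ValueError("annotation carries no pole assignment")
    centrosome = model.pole_centroid(pole_id)
    v_axis = centrosome - center
    v_plus = plus - center
    na, npl = np.linalg.norm(v_axis), np.linalg.norm(v_plus)
    if na == 0 or npl == 0:
        raise ValueError("zero-length vector in attachment angle")
    cosa = np.clip(v_axis @ v_plus / (na * npl), -1.0, 1.0)
    return AngleMeasurement(mt_id=annotation.mt_id,
                            alpha=float(np.degrees(np.arccos(cosa))))


# ---------------------------------------------------------------------------
# chromosome stretch (FWHM of the cross-sectional area profile)
# ---------------------------------------------------------------------------

@dataclass
class StretchMeasurement:
    chromosome_id: int
    positions_nm: np.ndarray        # axial station of each plane
    areas_nm2: np.ndarray           # mesh cross-sectional area at each station
    fit_params: Optional[np.ndarray]  # 5x(amplitude, center, width), nm units
    fwhm: float                     # um
    fit_ok: bool = True


def _gaussian_sum(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    p = params.reshape(-1, 3)
    y = np.zeros_like(x, dtype=float)
    for amp, mu, sig in p:
        y += amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def _fwhm_of_curve(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum: outermost crossings of half the maximum."""
    half = y.max() / 2.0
    above = y >= half
    if not above.any():
        return 0.0
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    # linear interpolation to the crossing on each side
    x_lo = x[i0]
    if i0 > 0 and y[i0] != y[i0 - 1]:
        t = (half - y[i0 - 1]) / (y[i0] - y[i0 - 1])
        x_lo = x[i0 - 1] + t * (x[i0] - x[i0 - 1])
    x_hi = x[i1]
    if i1 < len(x) - 1 and y[i1] != y[i1 + 1]:
        t = (half - y[i1 + 1]) / (y[i1] - y[i1 + 1])
        x_hi = x[i1 + 1] - t * (x[i1 + 1] - x[i1])
    return float(x_hi - x_lo)


def fit_gaussian_sum(x: np.ndarray, y: np.ndarray, n_components: int = 5,
                     n_restarts: int = 3) -> Optional[np.ndarray]:
    """Least-squares fit of a sum of Gaussian components with multi-start
    initialization (centers spread over the profile support). Returns the
    best parameter vector or None if no start converges."""
    span = x.max() - x.min()
    if span == 0 or y.max() <= 0:
        return None
    scale = y.max() / n_components
    best, best_cost = None, np.inf
    lb = np.tile([0.0, x.min() - 0.5 * span, span / (20 * n_components)], n_components)
    ub = np.tile([10 * y.max(), x.max() + 0.5 * span, 2 * span], n_components)
    for r in range(n_restarts):
        frac = (np.arange(n_components) + 0.5 + 0.15 * r) / (n_components + 0.3 * r)
        centers = x.min() + span * np.clip(frac, 0, 1)
        widths = np.full(n_components, span / (2.5 + r) / n_components * 2.5)
        p0 = np.column_stack([np.full(n_components, scale), centers, widths]).ravel()
        try:
            res = least_squares(lambda p: _gaussian_sum(p, x) - y, p0,
                                bounds=(lb, ub), max_nfev=4000)
        except Exception:
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)):
            best, best_cost = res.x, res.cost
    if best is None:
        return None
    # reject fits that do not actually describe the profile
    resid = np.sqrt(2 * best_cost / len(x))
    if resid > 0.2 * y.max():
        return None
    return best


def stretch_fwhm(chrom: ChromosomeBody, axis: np.ndarray,
                 spacing_nm: float = 10.0, n_components: int = 5) -> StretchMeasurement:
    """Chromosome stretch along the spindle axis.

    Orthogonal planes are placed along `axis` at `spacing_nm` intervals; the
    cross-sectional area of the mesh is computed in every plane, a sum of
    `n_components` Gaussian components is fit to the area profile and the
    FWHM is read off the fitted curve on a dense 1 nm grid (half of the
    fitted maximum, outermost crossings). If the fit fails the FWHM of the
    raw profile is reported and flagged.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = np.asarray(chrom.mesh.vertices, float) @ axis
    t0, t1 = proj.min(), proj.max()
    heights = np.arange(t0 + spacing_nm / 2, t1, spacing_nm)
    origin = axis * t0  # any point with zero offset along the axis works
    sections = chrom.mesh.section_multiplane(
        plane_origin=origin, plane_normal=axis, heights=heights - t0)
    areas = np.array([0.0 if s is None else float(s.area) for s in sections])
    if not areas.any():
        raise ValueError(f"chromosome {chrom.id}: empty cross-section profile")

    params = fit_gaussian_sum(heights, areas, n_components=n_components)
    if params is not None:
        grid = np.arange(t0 - 0.25 * (t1 - t0), t1 + 0.25 * (t1 - t0), 1.0)
        fwhm_nm = _fwhm_of_curve(grid, _gaussian_sum(params, grid))
        ok = True
    else:
        warnings.warn(f"chromosome {chrom.id}: Gaussian-sum fit did not "
                      "converge; reporting raw-profile FWHM", RuntimeWarning)
        fwhm_nm = _fwhm_of_curve(heights, areas)
        ok = False
    return StretchMeasurement(chromosome_id=chrom.id, positions_nm=heights,
                              areas_nm2=areas, fit_params=params,
                              fwhm=fwhm_nm / NM_PER_UM, fit_ok=ok)


# ---------------------------------------------------------------------------
# polymer content on either side of the X chromosome
# ---------------------------------------------------------------------------

@dataclass
class BoxRatio:
    box_side: float            # um
    sum_length_side1: float    # um of polymer in the box toward pole 1
    sum_length_side2: float    # um
    ratio: float               # side1 / side2


def _axis_frame(model: SpindleModel):
    """Orthonormal frame with ez along the spindle axis. The lateral
    orientation is seeded from the model's own geometry (the lowest-id
    autosome centroid) so the frame co-rotates with the spindle and every
    frame-dependent statistic is rigid-motion invariant."""
    ez = model.spindle_axis()
    seed = None
    autos = sorted(model.autosomes, key=lambda c: c.id)
    if autos:
        v = autos[0].centroid - model.pole_centroid(1)
        v = v - (v @ ez) * ez
        if np.linalg.norm(v) > 1e-9:
            seed = v
    if seed is None:
        seed = np.array([1.0, 0, 0]) if abs(ez[0]) < 0.9 else np.array([0, 1.0, 0])
        seed = seed - (seed @ ez) * ez
    ex = seed / np.linalg.norm(seed)
    ey = np.cross(ez, ex)
    return ex, ey, ez


def polymer_box_ratio(model: SpindleModel, side_um: float = 1.0,
                      offset_um: float = 0.0) -> BoxRatio:
    """Total microtubule polymer length inside two cubes of side `side_um`
    abutting the X chromosome's axial extremes, one toward each pole.

    The cubes are aligned to the spindle axis (faces perpendicular to it),
    laterally centered on the X centroid, separated from the X bounding
    planes by `offset_um`. Polymer length is the sum of all polyline segment
    pieces clipped to each cube. Side 1 faces pole 1.
    """
    x = model.x_chromosome
    if x is None:
        raise ValueError("model contains no X chromosome")
    side = side_um * NM_PER_UM
    offset = offset_um * NM_PER_UM
    ex, ey, ez = _axis_frame(model)
    R = np.column_stack([ex, ey, ez])  # world -> frame via p @ R

    xv = np.asarray(x.mesh.vertices, float) @ R
    cx, cy, _ = x.centroid @ R
    z_lo, z_hi = xv[:, 2].min(), xv[:, 2].max()
    z_pole1 = float(model.pole_centroid(1) @ ez)
    z_x = 0.5 * (z_lo + z_hi)
    sign1 = 1.0 if z_pole1 > z_x else -1.0  # axial direction toward pole 1

    def box(sign):
        z_edge = z_hi if sign > 0 else z_lo
        z0, z1 = sorted((z_edge + sign * offset, z_edge + sign * (offset + side)))
        lo = np.array([cx - side / 2, cy - side / 2, z0])
        hi = np.array([cx + side / 2, cy + side / 2, z1])
        return lo, hi

    lo1, hi1 = box(sign1)
    lo2, hi2 = box(-sign1)
    len1 = len2 = 0.0
    for mt in model.microtubules:
        pts = mt.points @ R
        p0, p1 = pts[:-1], pts[1:]
        len1 += segment_box_clip_length(p0, p1, lo1, hi1).sum()
        len2 += segment_box_clip_length(p0, p1, lo2, hi2).sum()
    len1 /= NM_PER_UM
    len2 /= NM_PER_UM
    ratio = len1 / len2 if len2 > 0 else np.inf
    return BoxRatio(box_side=side_um, sum_length_side1=len1,
                    sum_length_side2=len2, ratio=ratio)


# ---------------------------------------------------------------------------
# staging distances
# ---------------------------------------------------------------------------

@dataclass
class StageMetrics:
    aa_distance: float                  # um; nan when pairing unavailable
    ax_distances: tuple                 # (group1->X, group2->X) um; nan if no X
    pp_distance: float                  # um
    px_distances: tuple                 # (pole1->X, pole2->X) um
    autosome_centrosome_distance: float  # um, mean over the two groups
    centriole_split: float              # um, mother-daughter mean over poles
    group_centroids: tuple = field(default=(None, None), repr=False)


def _autosome_groups(model: SpindleModel):
    """Split autosomes into the two segregating sets by the sign of their
    axial coordinate relative to the spindle midpoint (group 1 = pole 1
    side). Used for A-X / autosome-centrosome distances and as the pairing
    fallback."""
    ez = model.spindle_axis()
    mid = 0.5 * (model.pole_centroid(1) + model.pole_centroid(2))
    s_pole1 = (model.pole_centroid(1) - mid) @ ez
    g1, g2 = [], []
    for c in model.autosomes:
        s = (c.centroid - mid) @ ez
        (g1 if np.sign(s) == np.sign(s_pole1) else g2).append(c)
    return g1, g2


def stage_metrics(model: SpindleModel, pairing: str = "homolog") -> StageMetrics:
    """Distances used for staging a reconstruction.

    aa_distance: with `pairing='homolog'` (preferred), the mean over homolog
    pairs of the centroid distance between the two members sharing a
    pair_id; with `pairing='groups'` or when no pair_ids are present, the
    distance between the two axial group centroids. NaN if neither applies.
    """
    p1, p2 = model.pole_centroid(1), model.pole_centroid(2)
    pp = np.linalg.norm(p2 - p1) / NM_PER_UM

    autosomes = model.autosomes
    pairs = {}
    for c in autosomes:
        if c.pair_id is not None:
            pairs.setdefault(c.pair_id, []).append(c)
    aa = np.nan
    if pairing == "homolog" and pairs and all(len(v) == 2 for v in pairs.values()):
        aa = float(np.mean([np.linalg.norm(v[0].centroid - v[1].centroid)
                            for v in pairs.values()])) / NM_PER_UM
    else:
        g1, g2 = _autosome_groups(model)
        if g1 and g2:
            c1 = np.mean([c.centroid for c in g1], axis=0)
            c2 = np.mean([c.centroid for c in g2], axis=0)
            aa = float(np.linalg.norm(c1 - c2)) / NM_PER_UM

    g1, g2 = _autosome_groups(model)
    gc1 = np.mean([c.centroid for c in g1], axis=0) if g1 else None
    gc2 = np.mean([c.centroid for c in g2], axis=0) if g2 else None

    x = model.x_chromosome
    if x is not None:
        xc = x.centroid
        ax = (np.nan if gc1 is None else float(np.linalg.norm(gc1 - xc)) / NM_PER_UM,
              np.nan if gc2 is None else float(np.linalg.norm(gc2 - xc)) / NM_PER_UM)
        px = (float(np.linalg.norm(p1 - xc)) / NM_PER_UM,
              float(np.linalg.norm(p2 - xc)) / NM_PER_UM)
    else:
        ax = (np.nan, np.nan)
        px = (np.nan, np.nan)

    ac = []
    if gc1 is not None:
        ac.append(min(np.linalg.norm(gc1 - p1), np.linalg.norm(gc1 - p2)))
    if gc2 is not None:
        ac.append(min(np.linalg.norm(gc2 - p1), np.linalg.norm(gc2 - p2)))
    ac_mean = float(np.mean(ac)) / NM_PER_UM if ac else np.nan

    splits = []
    for pid in (1, 2):
        cents = model.centrioles_of_pole(pid)
        if len(cents) == 2:
            splits.append(np.linalg.norm(cents[0].centroid - cents[1].centroid))
    split = float(np.mean(splits)) / NM_PER_UM if splits else np.nan

    return StageMetrics(aa_distance=aa, ax_distances=ax, pp_distance=float(pp),
                        px_distances=px, autosome_centrosome_distance=ac_mean,
                        centriole_split=split, group_centroids=(gc1, gc2))


# ---------------------------------------------------------------------------
# per-spindle report
# ---------------------------------------------------------------------------

def _length_stats(model: SpindleModel, ann: pd.DataFrame, mask) -> tuple:
    ids = ann.loc[mask, "mt_id"]
    if len(ids) == 0:
        return (np.nan, np.nan)
    lens = [arc_length(model.mt_by_id(i)) for i in ids]
    return (float(np.mean(lens)), float(np.std(lens, ddof=1)) if len(lens) > 1 else 0.0)


def summarize_spindle(model: SpindleModel, annotations: pd.DataFrame) -> pd.DataFrame:
    """One row per spindle: classification counts, staging distances and
    per-class length / tortuosity statistics."""
    from .classify import count_table

    counts = count_table(model, annotations).iloc[0].to_dict()
    try:
        sm = stage_metrics(model)
        stage = {
            "aa_distance_um": sm.aa_distance,
            "a1x_distance_um": sm.ax_distances[0],
            "a2x_distance_um": sm.ax_distances[1],
            "pp_distance_um": sm.pp_distance,
            "p1x_distance_um": sm.px_distances[0],
            "p2x_distance_um": sm.px_distances[1],
            "autosome_centrosome_um": sm.autosome_centrosome_distance,
            "centriole_split_um": sm.centriole_split,
        }
    except Exception:
        stage = {}

    ann = annotations
    x = model.x_chromosome
    on_x = (ann.chromosome_id == x.id) if x is not None else pd.Series(False, index=ann.index)
    classes = {
        "end_on_x": on_x & (ann.association == "end_on"),
        "lateral_x": on_x & (ann.association == "lateral"),
        "end_on_autosome": ann.is_kmt & ~on_x & (ann.association == "end_on"),
        "lateral_autosome": ann.is_kmt & ~on_x & (ann.association == "lateral"),
    }
    stats = {}
    for name, mask in classes.items():
        mean, sd = _length_stats(model, ann, mask)
        stats[f"len_{name}_mean_um"] = mean
        stats[f"len_{name}_sd_um"] = sd
    torts = []
    for mt in model.microtubules:
        try:
            torts.append(tortuosity(mt))
        except ValueError:
            pass
    stats["tortuosity_mean"] = float(np.mean(torts)) if torts else np.nan
    stats["tortuosity_sd"] = (float(np.std(torts, ddof=1))
                              if len(torts) > 1 else np.nan)
    return pd.DataFrame([{**counts, **stage, **stats}], index=[model.name])
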