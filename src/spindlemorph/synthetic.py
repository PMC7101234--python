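"""Ground-truth-labeled synthetic spindles and movies.

Two generators make every analysis stage testable without the deposited
tomograms:

* `simulate_geometry` builds a spermatocyte-like spindle reconstruction —
  five paired autosome ellipsoids in a rosette around the central univalent
  X (metaphase) or two separating autosome groups with the X between them
  (anaphase), centriole pairs at both poles, and microtubule polylines grown
  with designed kinetochore associations: end-on KMTs terminate inside the
  kinetochore zone aimed at the surface, lateral KMTs pass through the zone
  tangentially, non-KMTs avoid every zone. Every microtubule carries its
  true label, and the construction is validated against the classification
  margins so the labels are exact by design.

* `simulate_kinetics` / `render_movie` produce pole/chromosome trajectories
  following measured meiosis-I kinetics (saturating-exponential distance
  curves; the lagging X starts moving at a random onset and side with a
  random speed) and render them into two-channel z-stacks with Poisson shot
  noise and Gaussian read noise.

Distance curves follow D(t) = D0 + (Df - D0)(1 - exp(-t / tau)) for t >= 0.
The quoted "initial rate (first minute)" is, by the measurement protocol, a
linear fit over the first minute of a decelerating curve; the default
calibration therefore chooses tau so the noiseless first-minute secant of
the curve equals the quoted rate (`rate_convention='first_minute'`).
`rate_convention='instantaneous'` instead sets tau = (Df - D0)/r0 so the
t->0+ slope is the quoted rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

from ._geom import point_triangle_distance, ray_triangle_hits
from .model import (NM_PER_UM, Centriole, ChromosomeBody, MicrotubulePath,
                    SpindleModel, TimelapseSeries)
from .dynamics import DistanceSeries

__all__ = [
    "GeometryRecipe",
    "KineticsParams",
    "Trajectories",
    "simulate_geometry",
    "distance_curve",
    "simulate_kinetics",
    "simulate_distance_series",
    "draw_x_speeds",
    "render_movie",
    "voxelized_ellipsoid",
]

X_ID = 99

#: stage-dependent defaults: pole-pole / autosome-autosome separation,
#: mother-daughter centriole split, axial offset of the X (um) — the scale
#: of staged tomographic reconstructions.
STAGE_DEFAULTS = {
    "metaphase": dict(pp_um=3.41, aa_um=0.94, centriole_split_um=0.21, x_offset_um=0.0),
    "anaphase_onset": dict(pp_um=3.51, aa_um=1.00, centriole_split_um=0.35, x_offset_um=0.0),
    "mid_anaphase": dict(pp_um=5.22, aa_um=3.35, centriole_split_um=0.73, x_offset_um=0.0),
    "late_anaphase": dict(pp_um=7.04, aa_um=5.44, centriole_split_um=1.11, x_offset_um=-0.78),
}


@dataclass
class GeometryRecipe:
    """Recipe for one synthetic reconstruction (distances in um unless
    suffixed _nm). Per-class KMT counts default to a full metaphase
    reconstruction's scale; tests typically pass much smaller counts."""

    seed: int
    stage: str = "metaphase"
    n_mts: int = 2406
    x_end_on: int = 38
    x_lateral: int = 34
    autosome_end_on: int = 355
    autosome_lateral: int = 485
    fraction_kmt: Optional[float] = None  # overrides the counts when set
    n_pairs: int = 5
    pp_um: Optional[float] = None
    aa_um: Optional[float] = None
    centriole_split_um: Optional[float] = None
    x_offset_um: Optional[float] = None
    ring_radius_um: float = 1.0
    autosome_axes_nm: tuple = (250.0, 250.0, 280.0)   # (x, y, z=axial) semi-axes
    stretch: float = 1.0                              # multiplies the axial semi-axis
    x_axes_nm: tuple = (300.0, 300.0, 350.0)
    endon_len_um: tuple = (0.65, 0.10)                # mean, sd
    lateral_len_um: tuple = (1.30, 0.20)
    other_len_um: tuple = (1.60, 0.50)
    tortuosity: float = 1.02
    x_side_bias: float = 0.5   # fraction of X end-on KMTs anchored at pole 1
    kinetochore_thickness_nm: float = 150.0
    mesh_subdivisions: int = 3

    def resolved(self) -> "GeometryRecipe":
        if self.stage not in STAGE_DEFAULTS:
            raise ValueError(f"unknown stage {self.stage!r}")
        out = replace(self)
        for key, val in STAGE_DEFAULTS[self.stage].items():
            if getattr(out, key) is None:
                setattr(out, key, val)
        if out.fraction_kmt is not None:
            n_kmt = int(round(out.fraction_kmt * out.n_mts))
            weights = np.array([self.x_end_on, self.x_lateral,
                                self.autosome_end_on, self.autosome_lateral], float)
            weights = weights / weights.sum()
            counts = np.floor(weights * n_kmt).astype(int)
            counts[3] += n_kmt - counts.sum()
            out.x_end_on, out.x_lateral, out.autosome_end_on, \
                out.autosome_lateral = (int(c) for c in counts)
        total_kmt = out.x_end_on + out.x_lateral + out.autosome_end_on + out.autosome_lateral
        if total_kmt > out.n_mts:
            raise ValueError("KMT counts exceed n_mts")
        return out


def _ellipsoid(center_nm, axes_nm, subdivisions=3) -> trimesh.Trimesh:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale(axes_nm)
    mesh.apply_translation(center_nm)
    return mesh


def _sample_surface(mesh: trimesh.Trimesh, rng: np.random.Generator, n: int):
    """Deterministic area-weighted surface sampling: points and outward
    face normals."""
    areas = mesh.area_faces
    fids = rng.choice(len(areas), size=n, p=areas / areas.sum())
    tri = mesh.triangles[fids]
    r1, r2 = rng.random(n), rng.random(n)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) \
        + r2[:, None] * (tri[:, 2] - tri[:, 0])
    return pts, mesh.face_normals[fids]


def _bend(points: np.ndarray, target_tortuosity: float, normal: np.ndarray) -> np.ndarray:
    """Add a smooth perpendicular bow (zero at the ends and over the final
    two points, so the terminal chord keeps its direction) reaching the
    requested tortuosity."""
    if target_tortuosity <= 1.0 or len(points) < 5:
        return points
    chord = np.linalg.norm(points[-1] - points[0])
    t = np.linspace(0, 1, len(points))
    env = np.sin(np.pi * t) ** 2
    env[-2:] = 0.0
    lo, hi = 0.0, chord

    def tort(a):
        p = points + (a * env)[:, None] * normal
        return np.linalg.norm(np.diff(p, axis=0), axis=1).sum() / \
            np.linalg.norm(p[-1] - p[0])

    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if tort(mid) < target_tortuosity:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    return points + (a * env)[:, None] * normal


def _min_dist_to_chromosomes(points, chromosomes, skip_id=None) -> float:
    d = np.inf
    for c in chromosomes:
        if c.id == skip_id:
            continue
        d = min(d, float(point_triangle_distance(points, np.asarray(c.mesh.triangles)).min()))
    return d


def simulate_geometry(recipe: GeometryRecipe):
    """Build a labeled spindle model. Returns (SpindleModel, truth), where
    truth is a DataFrame with mt_id, is_kmt, chromosome_id, association and
    pole_id — the designed ground truth of every microtubule."""
    r = recipe.resolved()
    rng = np.random.default_rng(r.seed)
    thr = r.kinetochore_thickness_nm
    margin = 30.0  # clearance (nm) between designed classes and the threshold

    pp = r.pp_um * NM_PER_UM
    aa = r.aa_um * NM_PER_UM
    split = r.centriole_split_um * NM_PER_UM
    ring = r.ring_radius_um * NM_PER_UM

    centrioles = []
    pole_centers = {1: np.array([0, 0, -pp / 2]), 2: np.array([0, 0, pp / 2])}
    cid = 1
    for pid, center in pole_centers.items():
        for k, role in enumerate(("mother", "daughter")):
            z = center[2] + (k - 0.5) * split
            centrioles.append(Centriole(id=cid, pole_id=pid,
                                        centerline=np.array([[0, 0, z - 100.0],
                                                             [0, 0, z + 100.0]]),
                                        role=role))
            cid += 1

    auto_axes = np.array(r.autosome_axes_nm, float)
    auto_axes[2] *= r.stretch
    chromosomes = []
    for k in range(r.n_pairs):
        theta = 2 * np.pi * k / r.n_pairs
        lateral = np.array([ring * np.cos(theta), ring * np.sin(theta), 0.0])
        for side, sgn in ((0, -1.0), (1, 1.0)):
            center = lateral + np.array([0, 0, sgn * aa / 2])
            chromosomes.append(ChromosomeBody(
                id=2 * k + side + 1, cls="autosome",
                mesh=_ellipsoid(center, auto_axes, r.mesh_subdivisions),
                pair_id=k))
    x_center = np.array([0, 0, r.x_offset_um * NM_PER_UM])
    chromosomes.append(ChromosomeBody(
        id=X_ID, cls="x_chromosome",
        mesh=_ellipsoid(x_center, np.array(r.x_axes_nm, float), r.mesh_subdivisions)))
    by_id = {c.id: c for c in chromosomes}

    mts, truth = [], []
    mt_id = 1

    def pole_for(z):
        return 1 if z < 0 else 2

    def add(points, is_kmt, chrom_id, assoc):
        nonlocal mt_id
        minus_z = points[0][2]
        mts.append(MicrotubulePath(id=mt_id, points=np.asarray(points, float)))
        truth.append(dict(mt_id=mt_id, is_kmt=is_kmt, chromosome_id=chrom_id,
                          association=assoc, pole_id=pole_for(minus_z)))
        mt_id += 1

    def grow_end_on(chrom, pole_sign, length_um, anchor_pole=False):
        """End-on KMT: plus end inside the kinetochore zone, final chord
        aimed at the surface, minus end toward pole `pole_sign`. With
        `anchor_pole` the length spans most of the way to the pole
        (continuous pole-chromosome tethers, as for the lagging X)."""
        tri = np.asarray(chrom.mesh.triangles)
        for _ in range(200):
            pts_s, normals = _sample_surface(chrom.mesh, rng, 8)
            facing = normals[:, 2] * pole_sign > 0.35
            if not facing.any():
                continue
            i = int(np.argmax(normals[:, 2] * pole_sign))
            s, n = pts_s[i], normals[i]
            d = rng.uniform(40.0, thr - margin)
            q = s + d * n
            # approach direction: surface normal with a small random tilt
            tilt = rng.normal(scale=0.06, size=3)
            w = n + tilt - (tilt @ n) * n * 0.0
            w = w / np.linalg.norm(w)
            if w @ n < 0.95:
                continue
            if anchor_pole:
                pole = pole_centers[1 if pole_sign < 0 else 2]
                L = float(np.linalg.norm(pole - q)) * rng.uniform(0.78, 0.92)
            else:
                L = max(0.2, length_um
                        + rng.normal(scale=recipe.endon_len_um[1])) * NM_PER_UM
            m = q + L * w
            n_pts = 8
            pts = np.linspace(m, q, n_pts)
            perp = np.cross(w, rng.normal(size=3))
            if np.linalg.norm(perp) < 1e-9:
                continue
            perp /= np.linalg.norm(perp)
            if perp @ (s - np.asarray(chrom.centroid)) < 0:
                perp = -perp
            pts = _bend(pts, r.tortuosity, perp)
            # verify the designed label against the classification rules
            hits = ray_triangle_hits(pts[-1], pts[-1] - pts[-2], tri)
            own = point_triangle_distance(pts, tri).min()
            if not (len(hits) and hits[0] <= thr and own <= thr - margin / 2):
                continue
            if _min_dist_to_chromosomes(pts, chromosomes, skip_id=chrom.id) < thr + margin:
                continue
            add(pts, True, chrom.id, "end_on")
            return
        raise RuntimeError("could not place an end-on KMT (infeasible recipe)")

    def grow_lateral(chrom, length_um):
        """Lateral KMT: passes tangentially through the kinetochore zone;
        the closest polyline point sits at the approach distance."""
        tri = np.asarray(chrom.mesh.triangles)
        for _ in range(200):
            pts_s, normals = _sample_surface(chrom.mesh, rng, 4)
            s, n = pts_s[0], normals[0]
            d = rng.uniform(40.0, thr - margin)
            p = s + d * n
            tangent = np.cross(n, rng.normal(size=3))
            if np.linalg.norm(tangent) < 1e-9:
                continue
            tangent /= np.linalg.norm(tangent)
            L = max(0.4, length_um + rng.normal(scale=recipe.lateral_len_um[1])) * NM_PER_UM
            frac = rng.uniform(0.35, 0.65)  # where along the path p sits
            a = p - frac * L * tangent
            b = p + (1 - frac) * L * tangent
            n_half = 4
            pts = np.vstack([np.linspace(a, p, n_half, endpoint=False),
                             np.linspace(p, b, n_half + 1)])
            dists = point_triangle_distance(pts, tri)
            ends_clear = min(dists[0], dists[-1]) > d + 10
            if not (dists.min() <= thr - margin / 2 and ends_clear):
                continue
            # both end extrapolations must miss the surface
            h1 = ray_triangle_hits(pts[-1], pts[-1] - pts[-2], tri)
            h2 = ray_triangle_hits(pts[0], pts[0] - pts[1], tri)
            if (len(h1) and h1[0] <= thr) or (len(h2) and h2[0] <= thr):
                continue
            if _min_dist_to_chromosomes(pts, chromosomes, skip_id=chrom.id) < thr + margin:
                continue
            add(pts, True, chrom.id, "lateral")
            return
        raise RuntimeError("could not place a lateral KMT (infeasible recipe)")

    def grow_other(length_um):
        """Non-KMT: a bundle microtubule at a lateral radius outside every
        kinetochore zone, roughly parallel to the spindle axis."""
        outer = ring + max(auto_axes.max(), max(r.x_axes_nm)) + thr + 200.0
        for _ in range(200):
            rho = rng.uniform(outer, outer + 800.0)
            phi = rng.uniform(0, 2 * np.pi)
            z0 = rng.uniform(-pp / 2, pp / 2)
            L = max(0.3, length_um + rng.normal(scale=recipe.other_len_um[1])) * NM_PER_UM
            direction = np.array([rng.normal(scale=0.15),
                                  rng.normal(scale=0.15),
                                  rng.choice([-1.0, 1.0])])
            direction /= np.linalg.norm(direction)
            a = np.array([rho * np.cos(phi), rho * np.sin(phi), z0])
            pts = np.linspace(a, a + L * direction, 6)
            if _min_dist_to_chromosomes(pts, chromosomes) < thr + 2 * margin:
                continue
            if pts[0][2] > pts[-1][2]:
                pts = pts[::-1].copy()  # minus end toward pole 1 by convention
            # orient: minus end = endpoint nearer its pole
            add(pts, False, None, "none")
            return
        raise RuntimeError("could not place a non-KMT (infeasible recipe)")

    x = by_id[X_ID]
    n_side1 = int(round(r.x_side_bias * r.x_end_on))
    for i in range(r.x_end_on):
        grow_end_on(x, pole_sign=-1.0 if i < n_side1 else 1.0,
                    length_um=r.endon_len_um[0], anchor_pole=True)
    for _ in range(r.x_lateral):
        grow_lateral(x, r.lateral_len_um[0])
    autos = [c for c in chromosomes if c.cls == "autosome"]
    for i in range(r.autosome_end_on):
        c = autos[i % len(autos)]
        sgn = -1.0 if c.centroid[2] < x_center[2] else 1.0
        grow_end_on(c, pole_sign=sgn, length_um=r.endon_len_um[0])
    for i in range(r.autosome_lateral):
        grow_lateral(autos[i % len(autos)], r.lateral_len_um[0])
    n_other = r.n_mts - len(mts)
    for _ in range(n_other):
        grow_other(r.other_len_um[0])

    model = SpindleModel(name=f"synthetic_{r.stage}_{r.seed}", microtubules=mts,
                         chromosomes=chromosomes, centrioles=centrioles,
                         kinetochore_thickness=thr)
    return model, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticsParams:
    """Generator ground truth for meiosis-I trajectories.

    Distance parameters are (initial um, final um, initial rate um/min) —
    defaults are the measured meiosis-I values. X onset is minutes after
    anaphase onset; the X speed distribution is a truncated normal.
    """

    pp: tuple = (4.1, 8.0, 1.29)
    aa: tuple = (0.9, 6.5, 2.07)
    pa: tuple = (1.6, 0.8, -0.39)
    x_onset_min: tuple = (4.9, 1.5)       # mean, sd (min)
    x_speed: tuple = (2.2, 0.9, 0.1)      # mean, sd, lower truncation (um/min)
    frame_interval_s: float = 20.0
    baseline_min: float = 2.0             # metaphase footage before onset
    duration_min: float = 8.0             # footage after onset
    rate_convention: str = "first_minute"  # or 'instantaneous'
    noise_sd_um: float = 0.05             # localization noise on distances
    psf_sigma_um: tuple = (0.35, 0.15, 0.15)   # (z, y, x)
    voxel_um: tuple = (0.3, 0.1, 0.1)
    photons_peak: float = 200.0
    read_noise_sd: float = 2.0
    tubulin_asymmetry: float = 1.0  # tubulin-line gain on the X's target side
    seed: int = 0


def _tau_min(d0: float, df: float, rate: float, convention: str) -> float:
    delta = df - d0
    if delta == 0 or rate == 0:
        return np.inf
    if convention == "instantaneous":
        return delta / rate
    if convention == "first_minute":
        ratio = rate / delta  # fraction of the total change covered in 1 min
        if not 0 < ratio < 1:
            raise ValueError("first-minute rate inconsistent with total change")
        return -1.0 / np.log1p(-ratio)
    raise ValueError(f"unknown rate convention {convention!r}")


def distance_curve(t_min: np.ndarray, d0: float, df: float, rate: float,
                   convention: str = "first_minute") -> np.ndarray:
    """Saturating-exponential distance curve: d0 before onset (t<0), then
    d0 + (df-d0)(1 - exp(-t/tau)). tau is calibrated so that either the
    first-minute secant (default) or the instantaneous t->0+ slope equals
    `rate`."""
    t = np.asarray(t_min, dtype=float)
    tau = _tau_min(d0, df, rate, convention)
    out = np.full_like(t, d0)
    pos = t > 0
    out[pos] = d0 + (df - d0) * (1 - np.exp(-t[pos] / tau))
    return out


@dataclass
class Trajectories:
    """Noiseless ground-truth trajectories on the frame grid. Times are
    minutes relative to anaphase onset; x_axial is the X centroid position
    along the axis relative to the spindle midpoint (um)."""

    t_min: np.ndarray
    pp: np.ndarray
    aa: np.ndarray
    pa1: np.ndarray
    pa2: np.ndarray
    x_axial: np.ndarray
    x_onset_min: float
    x_speed: float
    x_side: int
    params: KineticsParams = field(repr=False, default=None)


def draw_x_speeds(params: KineticsParams, n: int,
                  rng: np.random.Generator, antithetic: bool = False) -> np.ndarray:
    """Draw n per-cell X segregation speeds from the truncated-normal speed
    distribution. With `antithetic=True` the draws come in quantile pairs
    (u, 1-u): each draw keeps the exact marginal distribution while the
    sample mean has strongly reduced Monte-Carlo variance — useful when an
    ensemble mean is the quantity of interest."""
    from scipy.stats import truncnorm

    m, s, lo = params.x_speed
    a = (lo - m) / s
    if antithetic:
        u = rng.random((n + 1) // 2)
        u = np.concatenate([u, 1 - u])[:n]
    else:
        u = rng.random(n)
    return truncnorm.ppf(u, a, np.inf, loc=m, scale=s)


def simulate_kinetics(params: KineticsParams,
                      rng: Optional[np.random.Generator] = None,
                      x_speed: Optional[float] = None,
                      x_onset_min: Optional[float] = None) -> Trajectories:
    """Ground-truth trajectories for one cell.

    Pole and autosome-group positions follow the pole-pole and
    autosome-autosome curves (the pole-autosome curves are their implied
    difference, consistent by construction). The X stays at the midzone
    until its drawn onset, then moves toward the drawn side at its drawn
    speed (no arrival cap — see render_movie for the rendered position).
    """
    from scipy.stats import truncnorm

    rng = np.random.default_rng(params.seed) if rng is None else rng
    dt = params.frame_interval_s / 60.0
    t = np.arange(-params.baseline_min, params.duration_min + dt / 2, dt)
    conv = params.rate_convention
    pp = distance_curve(t, *params.pp, conv)
    aa = distance_curve(t, *params.aa, conv)
    pa = (pp - aa) / 2.0

    mu, sd = params.x_onset_min
    onset = float(rng.normal(mu, sd)) if x_onset_min is None else float(x_onset_min)
    onset = max(onset, dt)  # X never resolves before anaphase onset
    m, s, lo = params.x_speed
    speed = float(truncnorm.rvs((lo - m) / s, np.inf, loc=m, scale=s,
                                random_state=rng)) if x_speed is None else float(x_speed)
    side = int(rng.choice([-1, 1]))
    x_axial = np.where(t > onset, side * speed * (t - onset), 0.0)
    return Trajectories(t_min=t, pp=pp, aa=aa, pa1=pa.copy(), pa2=pa.copy(),
                        x_axial=x_axial, x_onset_min=onset, x_speed=speed,
                        x_side=side, params=params)


def simulate_distance_series(params: KineticsParams,
                             rng: Optional[np.random.Generator] = None,
                             noise_sd_um: Optional[float] = None) -> tuple:
    """A noisy DistanceSeries straight from the kinetic law (localization
    noise only, no imaging) plus its ground truth. The pa curves here use
    the direct pole-autosome parameterization."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    traj = simulate_kinetics(params, rng)
    sd = params.noise_sd_um if noise_sd_um is None else noise_sd_um
    t = traj.t_min
    conv = params.rate_convention
    pa = distance_curve(t, *params.pa, conv)
    n = len(t)

    def noisy(y):
        return np.clip(y + rng.normal(0, sd, n), 0.0, None)

    group = traj.aa / 2.0
    a1x = np.abs(traj.x_axial + group)
    a2x = np.abs(group - traj.x_axial)
    d = DistanceSeries(t=(t - t[0]) * 60.0, pp=noisy(traj.pp), aa=noisy(traj.aa),
                       pa1=noisy(pa), pa2=noisy(pa), a1x=noisy(a1x),
                       a2x=noisy(a2x))
    return d, traj


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def _add_gaussian_blob(vol: np.ndarray, voxel: np.ndarray, center_um: np.ndarray,
                       sigma_um: np.ndarray, amplitude: float) -> None:
    """Accumulate an anisotropic (axis-aligned) Gaussian into `vol`,
    evaluated on a +/-4 sigma window only."""
    lo = np.maximum(np.floor((center_um - 4 * sigma_um) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + 4 * sigma_um) / voxel).astype(int) + 1,
                    vol.shape)
    if np.any(lo >= hi):
        return
    coords = [np.arange(lo[a], hi[a]) * voxel[a] for a in range(3)]
    Z, Y, X = np.meshgrid(*coords, indexing="ij")
    e = ((Z - center_um[0]) ** 2 / sigma_um[0] ** 2
         + (Y - center_um[1]) ** 2 / sigma_um[1] ** 2
         + (X - center_um[2]) ** 2 / sigma_um[2] ** 2)
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * e)


def render_movie(traj: Trajectories, params: Optional[KineticsParams] = None,
                 rng: Optional[np.random.Generator] = None,
                 axis=(0.25, 0.9, 0.35), tubulin_line: bool = False,
                 noise: bool = True):
    """Render ground-truth trajectories into a two-channel 4D stack.

    Poles are 3D Gaussian spots, chromatin bodies Gaussian-blurred
    ellipsoids (rendered as Gaussian blobs whose half-max extents match the
    body axes, PSF added in quadrature); Poisson shot noise and Gaussian
    read noise are applied. Returns (TimelapseSeries, truth) where truth
    holds the per-frame world positions (um, z/y/x) of poles, groups and X.
    """
    params = traj.params if params is None else params
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    u = np.asarray(axis, float)
    u /= np.linalg.norm(u)
    voxel = np.asarray(params.voxel_um)
    psf = np.asarray(params.psf_sigma_um)

    half_span = traj.pp.max() / 2 + 1.5
    shape = tuple(int(np.ceil(2 * (abs(half_span * u[a]) + 2.0) / voxel[a]))
                  for a in range(3))
    center = 0.5 * (np.array(shape) - 1) * voxel

    T = len(traj.t_min)
    frames = np.zeros((T, 2) + shape)
    truth_pos = {"poles": np.zeros((T, 2, 3)), "groups": np.zeros((T, 2, 3)),
                 "x": np.zeros((T, 3))}
    # half-max extents of the rendered bodies (um, along/perpendicular to axis)
    group_sigma = np.sqrt((0.35 ** 2) + psf.mean() ** 2)
    x_sigma_ax = np.sqrt(0.30 ** 2 + psf.mean() ** 2)
    x_sigma_lat = np.sqrt(0.26 ** 2 + psf.mean() ** 2)

    for i in range(T):
        p1 = center - (traj.pp[i] / 2) * u
        p2 = center + (traj.pp[i] / 2) * u
        g1 = center - (traj.aa[i] / 2) * u
        g2 = center + (traj.aa[i] / 2) * u
        # the rendered X stops at its target group (visual realism)
        x_ax = np.clip(traj.x_axial[i], -(traj.aa[i] / 2), traj.aa[i] / 2)
        xp = center + x_ax * u
        truth_pos["poles"][i] = [p1, p2]
        truth_pos["groups"][i] = [g1, g2]
        truth_pos["x"][i] = xp

        pole_sig = np.sqrt(psf ** 2 + 0.12 ** 2)
        for p in (p1, p2):
            _add_gaussian_blob(frames[i, 0], voxel, p, pole_sig,
                               params.photons_peak)
        if tubulin_line:
            line_sig = np.sqrt(psf ** 2 + 0.25 ** 2)
            n_seg = max(int(traj.pp[i] / 0.2), 2)
            positions = np.linspace(0.1, 0.9, n_seg)
            spacing = (positions[1] - positions[0]) * traj.pp[i]
            # overlapping blobs sum into a ridge: normalize so the ridge
            # peak stays at the intended fraction of the pole brightness
            overlap = np.sqrt(2 * np.pi) * float(np.mean(line_sig)) / spacing
            for s in positions:
                amp = 0.25 * params.photons_peak / overlap
                if (s - 0.5) * traj.x_side > 0:
                    amp *= params.tubulin_asymmetry
                _add_gaussian_blob(frames[i, 0], voxel, p1 + s * (p2 - p1),
                                   line_sig, amp)
        for g in (g1, g2):
            _add_gaussian_blob(frames[i, 1], voxel, g,
                               np.full(3, group_sigma), 0.8 * params.photons_peak)
        x_sig = np.full(3, x_sigma_lat) + (x_sigma_ax - x_sigma_lat) * np.abs(u)
        _add_gaussian_blob(frames[i, 1], voxel, xp, x_sig,
                           0.55 * params.photons_peak)

    if noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
        frames += rng.normal(0, params.read_noise_sd, frames.shape)
    series = TimelapseSeries(frames=frames, voxel_size=tuple(voxel),
                             frame_interval=params.frame_interval_s,
                             channel_roles={"poles": 0, "chromatin": 1})
    return series, {"trajectories": traj, "positions_um": truth_pos, "axis": u}


def voxelized_ellipsoid(axes_um=(1.4, 1.1, 0.9), voxel_um: float = 0.1,
                        pad_um: float = 0.5) -> np.ndarray:
    """Binary voxelization of a triaxial ellipsoid with full axis lengths
    `axes_um` ordered (z, y, x); the first axis lies along z."""
    semi = np.asarray(axes_um, float) / 2.0
    shape = np.ceil((2 * (semi + pad_um)) / voxel_um).astype(int) | 1
    center = 0.5 * (shape - 1) * voxel_um
    grids = np.meshgrid(*[np.arange(s) * voxel_um for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return (q <= 1.0).astype(float)
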