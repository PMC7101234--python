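"""Spindle kinetics from two-channel time-lapse stacks.

The pipeline mirrors a standard spermatocyte live-imaging analysis: spindle
poles are segmented by relative thresholding in the tubulin channel and
tracked as intensity-weighted centroids; chromatin components are clustered
into the two segregating autosome groups (plus the lagging X between them);
distance curves are aligned on anaphase onset; the initial rate of each
distance is the slope of a linear fit over the first minute after onset
(segregation decelerates continuously afterwards, so the window matters and
is reported with the fit). Volumes are resampled onto the spindle axis for
kymographs, X-shape coefficients and the two-box fluorescence ratio.

All distances are in micrometers, times in seconds (rates in um/min).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .model import TimelapseSeries

__all__ = [
    "DistanceSeries",
    "ShapeCoefficientSeries",
    "KineticsFit",
    "FrameSegmentation",
    "segment_poles",
    "centrosome_volume_series",
    "track_distances",
    "detect_onset",
    "fit_initial_rate",
    "AxisVolume",
    "resample_to_axis",
    "Kymograph",
    "kymograph",
    "kymograph_peak_distances",
    "shape_coefficient_from_volume",
    "shape_coefficient",
    "box_intensity_ratio",
    "bleach_correct",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    """Per-frame distance curves (um). Missing measurements are NaN."""

    t: np.ndarray        # seconds (movie clock; aligned() is onset-relative)
    pp: np.ndarray
    aa: np.ndarray
    pa1: np.ndarray
    pa2: np.ndarray
    a1x: np.ndarray
    a2x: np.ndarray
    onset_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("pp", "aa", "pa1", "pa2", "a1x", "a2x"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name}: shape mismatch with t")
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError(f"{name}: distances must be >= 0")
            setattr(self, name, arr)

    def aligned(self) -> np.ndarray:
        """Times relative to anaphase onset (requires onset_frame)."""
        if self.onset_frame is None:
            raise ValueError("onset not detected yet")
        return self.t - self.t[self.onset_frame]


@dataclass
class ShapeCoefficientSeries:
    t: np.ndarray
    coeff: np.ndarray       # z / ((x + y)/2), unitless
    dims: np.ndarray        # (T, 3): z, x, y extents in um


@dataclass
class KineticsFit:
    initial_rate: float          # um/min
    rate_se: float               # um/min
    initial_length: float        # um (metaphase plateau mean)
    final_length: float          # um (post-elongation plateau mean)
    elongation_duration: float   # min
    fit_window_s: tuple          # (t_start, t_end) on the movie clock
    n_points: int


@dataclass
class FrameSegmentation:
    centroids: Optional[np.ndarray]   # (2, 3) um, (z, y, x)
    volumes: Optional[np.ndarray]     # (2,) um^3
    ok: bool
    n_components: int


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _threshold(vol: np.ndarray, method: str, fraction: float) -> float:
    if method == "otsu":
        from skimage.filters import threshold_otsu
        return float(threshold_otsu(vol))
    if method == "fraction":
        return fraction * float(vol.max())
    raise ValueError(f"unknown threshold method {method!r}")


def _components(vol: np.ndarray, thr: float, min_voxels: int = 3):
    mask = vol > thr
    labels, n = ndimage.label(mask)
    comps = []
    for lab in range(1, n + 1):
        sel = labels == lab
        size = int(sel.sum())
        if size < min_voxels:
            continue
        w = np.where(sel, vol, 0.0)
        mass = float(w.sum())
        centroid = np.array(ndimage.center_of_mass(w))
        comps.append({"centroid_idx": centroid, "voxels": size, "mass": mass})
    return comps


def segment_poles(series: TimelapseSeries, frame: int, threshold: float = 0.5,
                  method: str = "fraction") -> FrameSegmentation:
    """Two largest connected components in the pole channel after relative
    thresholding (default: half of the per-frame maximum over background).

    Centroids are intensity-weighted centers of mass (um, z/y/x); volumes
    are voxel counts times the voxel volume. Frames where fewer than two
    components are found (e.g. pre-split centrosomes) are flagged.
    """
    vol = series.channel("poles")[frame].astype(float)
    bg = float(np.median(vol))
    vol = np.clip(vol - bg, 0.0, None)
    comps = _components(vol, _threshold(vol, method, threshold))
    comps.sort(key=lambda c: -c["mass"])
    voxel = np.asarray(series.voxel_size)
    if len(comps) < 2:
        return FrameSegmentation(None, None, ok=False, n_components=len(comps))
    two = sorted(comps[:2], key=lambda c: tuple(c["centroid_idx"]))
    cents = np.array([c["centroid_idx"] * voxel for c in two])
    vols = np.array([c["voxels"] * voxel.prod() for c in two])
    return FrameSegmentation(cents, vols, ok=True, n_components=len(comps))


def centrosome_volume_series(series: TimelapseSeries, threshold: float = 0.5,
                             method: str = "fraction") -> np.ndarray:
    """Per-frame summed centrosome volume (um^3): thresholded pole-channel
    components (largest two, or the single one before splitting) summed."""
    voxel_vol = float(np.prod(series.voxel_size))
    out = np.empty(series.n_frames)
    for t in range(series.n_frames):
        vol = series.channel("poles")[t].astype(float)
        vol = np.clip(vol - float(np.median(vol)), 0.0, None)
        comps = _components(vol, _threshold(vol, method, threshold))
        comps.sort(key=lambda c: -c["voxels"])
        out[t] = sum(c["voxels"] for c in comps[:2]) * voxel_vol
    return out


# ---------------------------------------------------------------------------
# distance tracking
# ---------------------------------------------------------------------------

def _two_gaussian_axial_fit(s: np.ndarray, w: np.ndarray, init_sep: float):
    """Axial positions of the two autosome groups from a merged chromatin
    intensity profile: a three-Gaussian shared-width fit (outer two
    components = the groups, middle component = the X univalent sitting
    between them). Returns the sorted outer centers, or None."""
    bins = np.arange(s.min() - 0.2, s.max() + 0.3, 0.1)
    hist, edges = np.histogram(s, bins=bins, weights=w)
    xc = 0.5 * (edges[:-1] + edges[1:])
    if hist.max() <= 0:
        return None
    m = float(np.average(xc, weights=hist))

    def model(x, a1, mu1, a2, mu2, ax, mux, sig):
        return (a1 * np.exp(-0.5 * ((x - mu1) / sig) ** 2)
                + a2 * np.exp(-0.5 * ((x - mu2) / sig) ** 2)
                + ax * np.exp(-0.5 * ((x - mux) / sig) ** 2))

    amp = hist.max()
    p0 = [amp, m - init_sep / 2, amp, m + init_sep / 2, 0.5 * amp, m,
          max(0.25, init_sep / 4)]
    try:
        popt, _ = curve_fit(model, xc, hist, p0=p0,
                            bounds=([0, xc.min(), 0, xc.min(), 0, xc.min(), 0.05],
                                    [np.inf, xc.max(), np.inf, xc.max(),
                                     np.inf, xc.max(), 5.0]),
                            maxfev=8000)
    except Exception:
        return None
    return sorted([popt[1], popt[3]])


def track_distances(series: TimelapseSeries, pole_threshold: float = 0.5,
                    chrom_method: str = "otsu") -> DistanceSeries:
    """Distance curves for a whole movie.

    Pole positions come from `segment_poles` with identities matched frame
    to frame by minimal displacement. Chromatin components are assigned by
    their axial position: the two extreme components are the segregating
    autosome groups and the dimmest interior component (when present) is the
    lagging X. When autosome groups are unresolved (single merged component,
    typical at metaphase), the group separation falls back to a
    two-Gaussian fit of the axial chromatin intensity profile.
    """
    T = series.n_frames
    nan = np.full(T, np.nan)
    pp, aa = nan.copy(), nan.copy()
    pa1, pa2, a1x, a2x = nan.copy(), nan.copy(), nan.copy(), nan.copy()
    voxel = np.asarray(series.voxel_size)
    prev_poles = None
    prev_sep = None

    for t in range(T):
        seg = segment_poles(series, t, threshold=pole_threshold)
        if not seg.ok:
            continue
        poles = seg.centroids
        if prev_poles is not None:
            swap = np.linalg.norm(poles[::-1] - prev_poles, axis=1).sum() < \
                np.linalg.norm(poles - prev_poles, axis=1).sum()
            if swap:
                poles = poles[::-1]
        prev_poles = poles
        p1, p2 = poles
        pp[t] = np.linalg.norm(p2 - p1)
        axis = (p2 - p1) / np.linalg.norm(p2 - p1)
        mid = 0.5 * (p1 + p2)

        chrom = series.channel("chromatin")[t].astype(float)
        chrom = np.clip(chrom - float(np.median(chrom)), 0.0, None)
        try:
            thr = _threshold(chrom, chrom_method, 0.5)
        except Exception:
            continue
        comps = _components(chrom, thr, min_voxels=5)
        if not comps:
            continue
        for c in comps:
            c["pos"] = c["centroid_idx"] * voxel
            c["s"] = float((c["pos"] - mid) @ axis)
        comps.sort(key=lambda c: c["s"])

        g1 = g2 = xpos = None
        if len(comps) >= 3:
            lo, hi = comps[0], comps[-1]
            interior = comps[1:-1]
            xc = min(interior, key=lambda c: c["mass"])
            others = [c for c in comps if c is not xc]
            side1 = [c for c in others if c["s"] < xc["s"]] or [lo]
            side2 = [c for c in others if c["s"] >= xc["s"]] or [hi]
            g1 = np.average([c["pos"] for c in side1], axis=0,
                            weights=[c["mass"] for c in side1])
            g2 = np.average([c["pos"] for c in side2], axis=0,
                            weights=[c["mass"] for c in side2])
            xpos = xc["pos"]
        elif len(comps) == 2:
            g1, g2 = comps[0]["pos"], comps[-1]["pos"]
        else:
            # merged groups: two-Gaussian fit of the axial profile
            mask = chrom > 0.2 * thr
            idx = np.array(np.nonzero(mask)).T
            w = chrom[mask]
            s = (idx * voxel - mid) @ axis
            init = prev_sep if prev_sep else 2.0 * float(np.sqrt(
                max(np.average((s - np.average(s, weights=w)) ** 2, weights=w)
                    - 0.15, 0.01)))
            fit = _two_gaussian_axial_fit(s, w, init)
            if fit is not None:
                mu1, mu2 = fit
                g1 = mid + mu1 * axis
                g2 = mid + mu2 * axis

        if g1 is None or g2 is None:
            continue
        # group 1 is the group on the pole-1 side
        if (g1 - mid) @ axis > (g2 - mid) @ axis:
            g1, g2 = g2, g1
        if (p1 - mid) @ axis > 0:
            g1, g2 = g2, g1
        aa[t] = np.linalg.norm(g2 - g1)
        prev_sep = aa[t]
        pa1[t] = np.linalg.norm(g1 - p1)
        pa2[t] = np.linalg.norm(g2 - p2)
        if xpos is not None:
            a1x[t] = np.linalg.norm(xpos - g1)
            a2x[t] = np.linalg.norm(xpos - g2)

    return DistanceSeries(t=series.times(), pp=pp, aa=aa, pa1=pa1, pa2=pa2,
                          a1x=a1x, a2x=a2x)


# ---------------------------------------------------------------------------
# onset detection and initial-rate fits
# ---------------------------------------------------------------------------

def detect_onset(d: DistanceSeries, key: str = "aa",
                 min_baseline: int = 3) -> int:
    """Anaphase onset on a distance curve.

    Scans for the first frame whose value departs from the metaphase
    baseline by more than three baseline standard deviations and stays
    departed over the next two frames (either direction, so the same
    detector serves rising separation curves and shrinking pole-to-autosome
    curves). The returned onset frame is the last baseline frame — the
    breakpoint — and is stored on the series.
    """
    onset = detect_onset_curve(np.asarray(getattr(d, key), dtype=float),
                               min_baseline=min_baseline)
    d.onset_frame = onset
    return onset


def detect_onset_curve(y: np.ndarray, min_baseline: int = 3) -> int:
    """Movement-onset frame of a single measurement trace (see
    `detect_onset`); also serves X-position traces, which may be signed."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    # floor for the baseline SD: a robust noise scale from the whole series
    # (lower quartile of frame-to-frame changes), guarding against
    # pathologically small SD estimates from very short baselines
    diffs = np.abs(np.diff(y[np.isfinite(y)]))
    noise_floor = float(np.quantile(diffs, 0.25)) if len(diffs) else 0.0

    def stats(upto):
        # median/MAD: a few frames of missed early anaphase in the prefix
        # must not inflate the baseline spread and block later candidates
        base = y[:upto]
        base = base[np.isfinite(base)]
        if len(base) < min_baseline:
            return None
        mu = float(np.median(base))
        mad = 1.4826 * float(np.median(np.abs(base - mu)))
        return mu, max(mad, noise_floor, 1e-9)

    # scan candidate breakpoints: frames <= k are baseline, frames k+1..k+3
    # must all deviate beyond baseline + 3 SD with a common sign. Testing
    # each candidate against its own untouched prefix keeps the threshold
    # free of contamination by missed anaphase frames.
    for k in range(min_baseline - 1, n - 3):
        st = stats(k + 1)
        if st is None:
            continue
        mu, sd = st
        devs = y[k + 1:k + 4] - mu
        if not np.all(np.isfinite(devs)):
            continue
        sign = np.sign(devs[0])
        if sign == 0 or not np.all(np.sign(devs) == sign):
            continue
        if not np.all(np.abs(devs) > 3 * sd):
            continue
        # the last baseline frame may itself already deviate (the 3 SD test
        # can fire one frame after the true breakpoint): step back while the
        # frame deviates from its own prefix by more than 2 SD
        j = k
        while j >= max(min_baseline, k - 2):
            st = stats(j)
            if st is None:
                break
            mu_j, sd_j = st
            if (np.isfinite(y[j]) and np.sign(y[j] - mu_j) == sign
                    and abs(y[j] - mu_j) > 2 * sd_j):
                j -= 1
            else:
                break
        return j
    raise ValueError("no anaphase detected")


def fit_initial_rate(d: DistanceSeries, key: str = "pp",
                     window_s: float = 60.0) -> KineticsFit:
    """Linear fit over the first `window_s` seconds after anaphase onset.

    Returns the slope in um/min plus the metaphase plateau (mean of the
    baseline frames up to onset) and the post-elongation plateau (mean of
    the trailing 15% of frames) as initial/final lengths.
    """
    if d.onset_frame is None:
        detect_onset(d, key=key)
    y = np.asarray(getattr(d, key), dtype=float)
    t = d.t
    t0 = t[d.onset_frame]
    sel = (t >= t0) & (t <= t0 + window_s) & np.isfinite(y)
    if sel.sum() < 2:
        raise ValueError("insufficient samples in the fit window")
    ts, ys = t[sel], y[sel]
    A = np.vstack([ts - t0, np.ones_like(ts)]).T
    coef, res, *_ = np.linalg.lstsq(A, ys, rcond=None)
    slope = coef[0] * 60.0
    dof = len(ts) - 2
    if dof > 0 and len(res):
        s2 = res[0] / dof
        se = float(np.sqrt(s2 / np.sum((ts - ts.mean()) ** 2))) * 60.0
    else:
        se = np.nan

    base = y[:d.onset_frame + 1]
    initial = float(np.nanmean(base)) if np.isfinite(base).any() else np.nan
    n_tail = max(2, int(round(0.15 * len(y))))
    final = float(np.nanmean(y[-n_tail:]))

    # elongation duration: time from onset until the curve settles at the
    # final plateau (within 2 baseline SDs or 5% of the total change)
    noise = np.nanstd(base, ddof=1) if np.isfinite(base).sum() > 1 else 0.0
    tol = max(2 * noise, 0.05 * abs(final - initial))
    dur = np.nan
    for i in range(d.onset_frame + 1, len(y)):
        if np.isfinite(y[i]) and abs(y[i] - final) <= tol:
            dur = (t[i] - t0) / 60.0
            break
    return KineticsFit(initial_rate=float(slope), rate_se=se,
                       initial_length=initial, final_length=final,
                       elongation_duration=float(dur),
                       fit_window_s=(float(t0), float(t0 + window_s)),
                       n_points=int(sel.sum()))


# ---------------------------------------------------------------------------
# axis-aligned resampling, kymographs
# ---------------------------------------------------------------------------

@dataclass
class AxisVolume:
    data: np.ndarray        # (n_axial, n_lat, n_lat); axis along dim 0
    voxel_um: float
    axis: np.ndarray        # unit vector, world (z, y, x)
    origin: np.ndarray      # world position (um) of data[0, center, center]
    pole_axial: tuple       # axial coordinates (um) of the two poles in data


def _frame_poles(series: TimelapseSeries, frame: int, poles) -> np.ndarray:
    if poles is not None:
        return np.asarray(poles, dtype=float)
    seg = segment_poles(series, frame)
    if not seg.ok:
        raise ValueError(f"frame {frame}: poles not segmentable")
    return seg.centroids


def resample_to_axis(series: TimelapseSeries, frame: int, channel: str = "poles",
                     radius_um: float = 0.9, extrap_um: float = 1.0,
                     voxel_um: float = 0.1, poles=None) -> AxisVolume:
    """Trilinear resampling of one frame onto an isotropic grid aligned with
    the pole-to-pole axis (axis = first array dimension).

    The grid spans the pole separation extended by `extrap_um` on each side
    and a square cross-section of half-width `radius_um`. Defaults (0.9, 1.0)
    are the kymograph geometry; use (3.0, 2.0) for display projections.
    """
    p1, p2 = _frame_poles(series, frame, poles)
    sep = np.linalg.norm(p2 - p1)
    if sep == 0:
        raise ValueError("coincident poles: axis undefined")
    ez = (p2 - p1) / sep
    seed = np.array([1.0, 0, 0]) if abs(ez[0]) < 0.9 else np.array([0, 1.0, 0])
    ex = seed - (seed @ ez) * ez
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    n_ax = int(np.floor((sep + 2 * extrap_um) / voxel_um)) + 1
    n_lat = 2 * int(np.round(radius_um / voxel_um)) + 1
    zc = np.arange(n_ax) * voxel_um - extrap_um          # axial, 0 at pole 1
    lat = (np.arange(n_lat) - n_lat // 2) * voxel_um
    Z, Y, X = np.meshgrid(zc, lat, lat, indexing="ij")
    world = (p1[None, None, None, :] + Z[..., None] * ez
             + Y[..., None] * ex + X[..., None] * ey)
    idx = world / np.asarray(series.voxel_size)[None, None, None, :]
    vol = series.channel(channel)[frame].astype(float)
    data = ndimage.map_coordinates(vol, [idx[..., 0], idx[..., 1], idx[..., 2]],
                                   order=1, mode="constant", cval=0.0)
    return AxisVolume(data=data, voxel_um=voxel_um, axis=ez,
                      origin=p1 - extrap_um * ez,
                      pole_axial=(0.0, float(sep)))


@dataclass
class Kymograph:
    data: np.ndarray       # (n_axial, T); NaN where outside a frame's span
    axial_um: np.ndarray   # coordinate relative to the spindle midpoint
    interval_s: float


def _weighted_line(av: AxisVolume, sigma_um: float, radius_um: float) -> np.ndarray:
    n_lat = av.data.shape[1]
    lat = (np.arange(n_lat) - n_lat // 2) * av.voxel_um
    YY, XX = np.meshgrid(lat, lat, indexing="ij")
    r2 = YY ** 2 + XX ** 2
    w = np.exp(-r2 / (2 * sigma_um ** 2))
    w[np.sqrt(r2) > radius_um] = 0.0
    return np.tensordot(av.data, w, axes=([1, 2], [0, 1]))


def kymograph(series: TimelapseSeries, channel: str = "poles",
              sigma_um: float = 0.3, radius_um: float = 0.9,
              extrap_um: float = 1.0, voxel_um: float = 0.1,
              poles_per_frame=None) -> Kymograph:
    """Axis position x time map: per axial plane, the Gaussian-weighted sum
    of fluorescence (weight exp(-r^2 / 2 sigma^2) in radial distance from
    the axis), per frame, with all frames centered on the spindle midpoint.
    """
    lines, centers = [], []
    for t in range(series.n_frames):
        poles = None if poles_per_frame is None else poles_per_frame[t]
        av = resample_to_axis(series, t, channel=channel, radius_um=radius_um,
                              extrap_um=extrap_um, voxel_um=voxel_um, poles=poles)
        line = _weighted_line(av, sigma_um, radius_um)
        lines.append(line)
        centers.append(0.5 * (av.pole_axial[0] + av.pole_axial[1]) + extrap_um)

    half = max(len(l) * voxel_um / 2 for l in lines)
    n_half = int(np.ceil(half / voxel_um))
    axial = np.arange(-n_half, n_half + 1) * voxel_um
    data = np.full((len(axial), series.n_frames), np.nan)
    for t, (line, c) in enumerate(zip(lines, centers)):
        pos = np.arange(len(line)) * voxel_um - c
        i0 = int(np.round((pos[0] - axial[0]) / voxel_um))
        data[i0:i0 + len(line), t] = line
    return Kymograph(data=data, axial_um=axial, interval_s=series.frame_interval)


def kymograph_peak_distances(kym: Kymograph, prominence_frac: float = 0.2) -> np.ndarray:
    """Per-frame distance between the two most prominent fluorescence peaks
    along the axis (um), with parabolic sub-voxel refinement. NaN where
    fewer than two peaks are found."""
    T = kym.data.shape[1]
    out = np.full(T, np.nan)
    dz = kym.axial_um[1] - kym.axial_um[0]
    for t in range(T):
        line = kym.data[:, t]
        finite = np.isfinite(line)
        y = np.where(finite, line, 0.0)
        if y.max() <= 0:
            continue
        peaks, props = find_peaks(y, prominence=prominence_frac * y.max())
        if len(peaks) < 2:
            continue
        order = np.argsort(props["prominences"])[::-1][:2]
        pk = np.sort(peaks[order])
        refined = []
        for p in pk:
            if 0 < p < len(y) - 1 and (y[p - 1] - 2 * y[p] + y[p + 1]) != 0:
                delta = 0.5 * (y[p - 1] - y[p + 1]) / (y[p - 1] - 2 * y[p] + y[p + 1])
                refined.append(p + np.clip(delta, -0.5, 0.5))
            else:
                refined.append(float(p))
        out[t] = abs(refined[1] - refined[0]) * dz
    return out


# ---------------------------------------------------------------------------
# X-chromosome shape and the two-box fluorescence ratio
# ---------------------------------------------------------------------------

def shape_coefficient_from_volume(vol: np.ndarray, voxel_um: float,
                                  threshold: float = 0.5):
    """z / ((x + y)/2) of the largest connected component above
    `threshold` x max, with extents measured on the axis-aligned bounding
    box of the thresholded mask (axis 0 is z)."""
    mask = vol >= threshold * vol.max()
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.nan, (np.nan, np.nan, np.nan)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    ext = []
    for ax in range(3):
        idx = np.nonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))[0]
        ext.append((idx[-1] - idx[0] + 1) * voxel_um)
    z, y, x = ext
    return float(z / ((x + y) / 2)), (float(z), float(x), float(y))


def _locate_x(av_chrom: AxisVolume, min_voxels: int = 5):
    """The lagging X in an axis-aligned chromatin volume: the dimmest of
    three or more components, otherwise None. The detection threshold is
    deliberately below the half-max used for extents — the X is fainter
    than the autosome groups."""
    vol = np.clip(av_chrom.data - np.median(av_chrom.data), 0.0, None)
    comps = _components(vol, 0.3 * vol.max(), min_voxels=min_voxels)
    if len(comps) < 3:
        return None
    comps.sort(key=lambda c: c["centroid_idx"][0])
    xc = min(comps[1:-1], key=lambda c: c["mass"])
    return xc["centroid_idx"]


def shape_coefficient(series: TimelapseSeries, frame: int, poles=None,
                      voxel_um: float = 0.1, radius_um: float = 1.2,
                      threshold: float = 0.5):
    """Shape coefficient of the lagging X at one frame (NaN when the X is
    not resolvable). z is the spindle-axis extent by construction of the
    resampled volume."""
    av = resample_to_axis(series, frame, channel="chromatin",
                          radius_um=radius_um, extrap_um=1.0,
                          voxel_um=voxel_um, poles=poles)
    cx = _locate_x(av)
    if cx is None:
        return np.nan, (np.nan, np.nan, np.nan)
    half = int(np.round(1.2 / voxel_um))
    z0 = int(np.round(cx[0]))
    lo, hi = max(0, z0 - half), min(av.data.shape[0], z0 + half + 1)
    sub = av.data[lo:hi]
    return shape_coefficient_from_volume(sub, voxel_um, threshold=threshold)


def box_intensity_ratio(series: TimelapseSeries, frame: int,
                        side_um: float = 1.0, side1_direction: int = 1,
                        poles=None, voxel_um: float = 0.1):
    """V1/V2: summed tubulin fluorescence in two cubes of side `side_um`
    abutting the X chromosome along the spindle axis. Box 1 lies on
    `side1_direction` (+1: toward pole 2) — by convention the side the X
    resolves toward. NaN when the X is missing or a box leaves the volume.
    """
    p = _frame_poles(series, frame, poles)
    radius = max(0.9, side_um / np.sqrt(2.0))
    av_c = resample_to_axis(series, frame, channel="chromatin",
                            radius_um=radius, extrap_um=1.0,
                            voxel_um=voxel_um, poles=p)
    cx = _locate_x(av_c)
    if cx is None:
        return np.nan
    av_t = resample_to_axis(series, frame, channel="poles", radius_um=radius,
                            extrap_um=1.0, voxel_um=voxel_um, poles=p)
    # axial extent of the X around its centroid
    z0 = int(np.round(cx[0]))
    mask = av_c.data >= 0.5 * av_c.data.max()
    labels, _ = ndimage.label(mask)
    lab = labels[tuple(np.round(cx).astype(int))]
    zsel = np.nonzero((labels == lab).any(axis=(1, 2)))[0]
    z_lo, z_hi = zsel[0], zsel[-1]

    n_side = int(np.round(side_um / voxel_um))
    n_lat = av_t.data.shape[1]
    lat0 = n_lat // 2 - n_side // 2
    lat1 = lat0 + n_side

    def box_sum(z_start, z_end):
        if z_start < 0 or z_end > av_t.data.shape[0]:
            return np.nan
        return float(av_t.data[z_start:z_end, lat0:lat1, lat0:lat1].sum())

    v_plus = box_sum(z_hi + 1, z_hi + 1 + n_side)
    v_minus = box_sum(z_lo - n_side, z_lo)
    v1, v2 = (v_plus, v_minus) if side1_direction > 0 else (v_minus, v_plus)
    if not np.isfinite(v1) or not np.isfinite(v2) or v2 == 0:
        return np.nan
    return v1 / v2


# ---------------------------------------------------------------------------
# photobleaching correction
# ---------------------------------------------------------------------------

def bleach_correct(series: TimelapseSeries) -> TimelapseSeries:
    """Ratio normalization against the first frame: every frame is divided
    by (its foreground mean / the first frame's foreground mean), per
    channel. The foreground mask is fixed from the first frame (Otsu)."""
    from skimage.filters import threshold_otsu

    frames = series.frames.astype(float).copy()
    for c in range(frames.shape[1]):
        first = frames[0, c]
        try:
            mask = first > threshold_otsu(first)
        except Exception:
            mask = np.ones_like(first, dtype=bool)
        if not mask.any() or first[mask].mean() == 0:
            warnings.warn(f"channel {c}: empty first frame, left uncorrected",
                          RuntimeWarning)
            continue
        ref = first[mask].mean()
        for t in range(frames.shape[0]):
            m = frames[t, c][mask].mean()
            if m == 0:
                warnings.warn(f"channel {c} frame {t}: all-zero foreground, "
                              "left uncorrected", RuntimeWarning)
                continue
            frames[t, c] *= ref / m
    return replace(series, frames=frames)
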