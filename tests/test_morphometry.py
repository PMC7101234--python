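"""Geometric statistics: analytic examples, stochastic-integration oracles,
and rigid-motion invariance."""
import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from spindlemorph import classify as cls
from spindlemorph import morphometry as mo
from spindlemorph.model import (Centriole, ChromosomeBody, MicrotubulePath,
                                SpindleModel)
from spindlemorph._geom import segment_box_clip_length


def semicircle_mt(r_nm=1000.0, n=101):
    th = np.linspace(0, np.pi, n)
    pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)]) * r_nm
    return MicrotubulePath(id=1, points=pts)


# ---------------------------------------------------------------------------
# arc length and tortuosity
# ---------------------------------------------------------------------------

def test_arc_length_examples():
    straight = MicrotubulePath(id=1, points=[[0, 0, 0], [0, 0, 1000.0]])
    assert mo.arc_length(straight) == 1.0
    assert mo.arc_length(semicircle_mt()) == pytest.approx(np.pi, rel=1e-3)


def test_arc_length_additive_under_concatenation():
    a = MicrotubulePath(id=1, points=[[0, 0, 0], [500.0, 0, 0], [500.0, 700.0, 0]])
    b = MicrotubulePath(id=2, points=[[500.0, 700.0, 0], [0, 700.0, 900.0]])
    both = MicrotubulePath(id=3, points=np.vstack([a.points, b.points[1:]]))
    assert mo.arc_length(both) == pytest.approx(mo.arc_length(a) + mo.arc_length(b))


def test_tortuosity_straight_is_exactly_one():
    mt = MicrotubulePath(id=1, points=[[0, 0, 0], [0, 0, 500.0], [0, 0, 1500.0]])
    assert mo.tortuosity(mt) == 1.0


def test_tortuosity_semicircle():
    assert mo.tortuosity(semicircle_mt()) == pytest.approx(np.pi / 2, rel=1e-3)


def test_tortuosity_closed_path_rejected():
    mt = MicrotubulePath(id=1, points=[[0, 0, 0], [500.0, 0, 0], [0, 0, 0]])
    with pytest.raises(ValueError, match="closed"):
        mo.tortuosity(mt)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_tortuosity_at_least_one(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(scale=100.0, size=(8, 3)), axis=0)
    mt = MicrotubulePath(id=1, points=pts)
    if np.linalg.norm(pts[-1] - pts[0]) == 0:
        return
    assert mo.tortuosity(mt) >= 1.0 - 1e-12


# ---------------------------------------------------------------------------
# plus-end geometry
# ---------------------------------------------------------------------------

def _single_kmt_model(extra_centrioles=()):
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=400.0)
    mesh.apply_translation([0, 0, 1000.0])
    chrom = ChromosomeBody(id=1, cls="autosome", mesh=mesh)
    # straight 630 nm end-on KMT: minus end exactly at the pole-1 centriole
    mt = MicrotubulePath(id=1, points=np.linspace([0, 0, -30.0], [0, 0, 600.0], 5))
    cents = [Centriole(id=1, pole_id=1, centerline=[[0, 0, -30.0]]),
             Centriole(id=2, pole_id=2, centerline=[[0, 0, 2600.0]])]
    cents += list(extra_centrioles)
    model = SpindleModel(name="single", microtubules=[mt], chromosomes=[chrom],
                         centrioles=cents)
    ann = cls.classify_kmt(mt, model)
    return model, ann


def test_plus_end_to_centriole_straight_example():
    model, ann = _single_kmt_model()
    assert mo.plus_end_to_centriole(ann, model) == pytest.approx(0.63, abs=1e-9)


def test_plus_end_to_centriole_ignores_far_pole():
    model, ann = _single_kmt_model()
    moved, _ = _single_kmt_model(
        extra_centrioles=[])
    moved.centrioles[1] = Centriole(id=2, pole_id=2, centerline=[[500.0, 0, 9000.0]])
    assert mo.plus_end_to_centriole(ann, moved) == \
        mo.plus_end_to_centriole(ann, model)


def test_plus_end_to_centriole_matches_exhaustive_pairing(labeled_model,
                                                          annotations):
    model, _, _ = labeled_model
    rows = annotations[annotations.is_kmt & (annotations.association == "end_on")]
    cents = np.array([c.centroid for c in model.centrioles])
    for _, row in rows.head(10).iterrows():
        ann = cls.classify_kmt(model.mt_by_id(row.mt_id), model)
        got = mo.plus_end_to_centriole(ann, model)
        mt = model.mt_by_id(row.mt_id)
        plus, minus = ((mt.points[0], mt.points[-1])
                       if ann.plus_end_index == "first"
                       else (mt.points[-1], mt.points[0]))
        k = np.argmin(np.linalg.norm(cents - minus, axis=1))
        expect = np.linalg.norm(plus - cents[k]) / 1000.0
        assert got == pytest.approx(expect, abs=1e-12)


def test_attachment_angle_on_axis_is_zero():
    model, ann = _single_kmt_model()
    # plus end lies on the chromosome -> centrosome axis
    assert mo.attachment_angle(ann, model).alpha == pytest.approx(0.0, abs=1e-6)


def test_attachment_angle_45_degrees():
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=600.0)
    chrom = ChromosomeBody(id=1, cls="autosome", mesh=mesh)  # centered at origin
    mt = MicrotubulePath(id=1, points=np.linspace([2000.0, 2000.0, 0],
                                                  [500.0, 500.0, 0], 5))
    cents = [Centriole(id=1, pole_id=1, centerline=[[2000.0, 0, 0]]),
             Centriole(id=2, pole_id=2, centerline=[[-2000.0, 0, 0]])]
    model = SpindleModel(name="a", microtubules=[mt], chromosomes=[chrom],
                         centrioles=cents)
    ann = cls.classify_kmt(mt, model)
    assert ann.pole_id == 1
    assert mo.attachment_angle(ann, model).alpha == pytest.approx(45.0, abs=1e-9)


def test_attachment_angle_equals_independent_arccos(labeled_model, annotations):
    model, _, _ = labeled_model
    rows = annotations[annotations.is_kmt & (annotations.association == "end_on")]
    for _, row in rows.head(8).iterrows():
        ann = cls.classify_kmt(model.mt_by_id(row.mt_id), model)
        got = mo.attachment_angle(ann, model).alpha
        mt = model.mt_by_id(row.mt_id)
        plus = mt.points[0] if ann.plus_end_index == "first" else mt.points[-1]
        center = model.chromosome_by_id(ann.chromosome_id).centroid
        centrosome = model.pole_centroid(ann.pole_id)
        u = (centrosome - center) / np.linalg.norm(centrosome - center)
        v = (plus - center) / np.linalg.norm(plus - center)
        assert got == pytest.approx(np.degrees(np.arccos(np.clip(u @ v, -1, 1))),
                                    abs=1e-9)


# ---------------------------------------------------------------------------
# chromosome stretch FWHM
# ---------------------------------------------------------------------------

def test_fwhm_sphere_analytic():
    # area profile pi (r^2 - t^2): half max at t = r/sqrt(2) -> FWHM sqrt(2) r
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=500.0)
    chrom = ChromosomeBody(id=1, cls="autosome", mesh=mesh)
    sm = mo.stretch_fwhm(chrom, axis=[0, 0, 1])
    assert sm.fit_ok
    assert sm.fwhm == pytest.approx(np.sqrt(2) * 0.5, rel=0.02)


def test_fwhm_gaussian_profile_analytic():
    x = np.arange(-1000.0, 1001.0, 10.0)
    y = 5e4 * np.exp(-0.5 * (x / 250.0) ** 2)
    params = mo.fit_gaussian_sum(x, y)
    grid = np.arange(-1500.0, 1500.0, 1.0)
    fwhm = mo._fwhm_of_curve(grid, mo._gaussian_sum(params, grid)) / 1000.0
    assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.25, rel=0.01)


def test_fwhm_scales_with_axial_stretch():
    base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    m1 = base.copy(); m1.apply_scale([300.0, 300.0, 300.0])
    m2 = base.copy(); m2.apply_scale([300.0, 300.0, 600.0])
    f1 = mo.stretch_fwhm(ChromosomeBody(id=1, cls="autosome", mesh=m1), [0, 0, 1]).fwhm
    f2 = mo.stretch_fwhm(ChromosomeBody(id=2, cls="autosome", mesh=m2), [0, 0, 1]).fwhm
    assert f2 == pytest.approx(2 * f1, rel=0.02)


def test_fwhm_recovers_generator_ellipsoids(labeled_model):
    model, _, recipe = labeled_model
    axis = model.spindle_axis()
    for chrom in model.autosomes[:3]:
        sm = mo.stretch_fwhm(chrom, axis)
        c_nm = recipe.autosome_axes_nm[2] * recipe.stretch
        assert sm.fwhm == pytest.approx(np.sqrt(2) * c_nm / 1000.0, rel=0.05)


# ---------------------------------------------------------------------------
# polymer box ratio
# ---------------------------------------------------------------------------

def _two_sided_model(n1, n2):
    """n1 / n2 straight 1-um microtubules centered in the boxes on the pole-1
    (negative z) and pole-2 sides of a central X."""
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=300.0)
    x = ChromosomeBody(id=99, cls="x_chromosome", mesh=mesh)
    auto = trimesh.creation.icosphere(subdivisions=3, radius=200.0)
    auto.apply_translation([1500.0, 0, 0])
    mts = []
    k = 1
    for n, sign in ((n1, -1.0), (n2, 1.0)):
        for i in range(n):
            zc = sign * (300.0 + 500.0)
            off = 40.0 * (i - n / 2)
            mts.append(MicrotubulePath(
                id=k, points=[[off, 60.0, zc - 500.0], [off, 60.0, zc + 500.0]]))
            k += 1
    cents = [Centriole(id=1, pole_id=1, centerline=[[0, 0, -2500.0]]),
             Centriole(id=2, pole_id=2, centerline=[[0, 0, 2500.0]])]
    return SpindleModel(name="boxes", microtubules=mts,
                        chromosomes=[x, ChromosomeBody(id=1, cls="autosome",
                                                       mesh=auto)],
                        centrioles=cents)


def test_box_ratio_constructed_two_to_one():
    model = _two_sided_model(10, 5)
    br = mo.polymer_box_ratio(model)
    assert br.sum_length_side1 == pytest.approx(10.0, abs=1e-9)
    assert br.sum_length_side2 == pytest.approx(5.0, abs=1e-9)
    assert br.ratio == pytest.approx(2.0, abs=1e-9)


def test_box_ratio_symmetric_model_is_one():
    model = _two_sided_model(7, 7)
    assert mo.polymer_box_ratio(model).ratio == pytest.approx(1.0, abs=1e-6)


def test_box_ratio_requires_x():
    model = _two_sided_model(3, 3)
    model.chromosomes[0].cls = "autosome"
    with pytest.raises(ValueError, match="X chromosome"):
        mo.polymer_box_ratio(model)


def test_clip_sum_matches_monte_carlo(labeled_model):
    """Clipped-segment polymer length vs stochastic integration."""
    model, _, _ = labeled_model
    ez = model.spindle_axis()
    br = mo.polymer_box_ratio(model)
    # rebuild box 1 exactly as polymer_box_ratio does and integrate by MC
    from spindlemorph.morphometry import _axis_frame
    ex, ey, ez = _axis_frame(model)
    R = np.column_stack([ex, ey, ez])
    x = model.x_chromosome
    xv = np.asarray(x.mesh.vertices) @ R
    cx, cy, _ = x.centroid @ R
    z_hi, z_lo = xv[:, 2].max(), xv[:, 2].min()
    z_p1 = float(model.pole_centroid(1) @ ez)
    sign1 = 1.0 if z_p1 > 0.5 * (z_lo + z_hi) else -1.0
    z_edge = z_hi if sign1 > 0 else z_lo
    z0, z1 = sorted((z_edge, z_edge + sign1 * 1000.0))
    lo = np.array([cx - 500.0, cy - 500.0, z0])
    hi = np.array([cx + 500.0, cy + 500.0, z1])
    rng = np.random.default_rng(0)
    total = 0.0
    for mt in model.microtubules:
        pts = mt.points @ R
        seg = np.diff(pts, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        for p0, d, L in zip(pts[:-1], seg, lens):
            n = max(int(L), 50)
            samples = p0 + rng.random((n, 1)) * d
            frac = np.all((samples >= lo) & (samples <= hi), axis=1).mean()
            total += frac * L
    assert total / 1000.0 == pytest.approx(br.sum_length_side1, rel=0.005)


# ---------------------------------------------------------------------------
# staging distances
# ---------------------------------------------------------------------------

def test_stage_metrics_match_generator_design(labeled_model):
    model, _, recipe = labeled_model
    sm = mo.stage_metrics(model)
    r = recipe.resolved()
    assert sm.aa_distance == pytest.approx(r.aa_um, abs=0.01)
    assert sm.pp_distance == pytest.approx(r.pp_um, abs=0.01)
    assert sm.centriole_split == pytest.approx(r.centriole_split_um, abs=0.01)
    assert sm.px_distances[0] == pytest.approx(r.pp_um / 2, abs=0.02)


def test_stage_metrics_translation_invariant(labeled_model):
    model, _, _ = labeled_model
    shift = np.array([1234.5, -987.0, 456.7])
    moved = _rigid_copy(model, np.eye(3), shift)
    a, b = mo.stage_metrics(model), mo.stage_metrics(moved)
    assert a.aa_distance == pytest.approx(b.aa_distance, rel=1e-9)
    assert a.pp_distance == pytest.approx(b.pp_distance, rel=1e-9)
    assert a.px_distances == pytest.approx(b.px_distances, rel=1e-9)


def test_stage_metrics_pole_swap(labeled_model):
    model, _, _ = labeled_model
    swapped = SpindleModel(
        name="sw", microtubules=model.microtubules, chromosomes=model.chromosomes,
        centrioles=[Centriole(id=c.id, pole_id=3 - c.pole_id,
                              centerline=c.centerline.copy(), role=c.role)
                    for c in model.centrioles],
        kinetochore_thickness=model.kinetochore_thickness)
    a, b = mo.stage_metrics(model), mo.stage_metrics(swapped)
    assert a.pp_distance == pytest.approx(b.pp_distance, rel=1e-12)
    assert a.px_distances == pytest.approx(b.px_distances[::-1], rel=1e-9)


# ---------------------------------------------------------------------------
# rigid-motion invariance of every scalar statistic
# ---------------------------------------------------------------------------

def _rigid_copy(model, R, t_nm):
    def tf(pts):
        return np.asarray(pts) @ R.T + t_nm

    mts = [MicrotubulePath(id=mt.id, points=tf(mt.points))
           for mt in model.microtubules]
    chroms = [ChromosomeBody(id=c.id, cls=c.cls, pair_id=c.pair_id,
                             mesh=trimesh.Trimesh(vertices=tf(c.mesh.vertices),
                                                  faces=np.asarray(c.mesh.faces),
                                                  process=False))
              for c in model.chromosomes]
    cents = [Centriole(id=c.id, pole_id=c.pole_id, role=c.role,
                       centerline=tf(c.centerline)) for c in model.centrioles]
    return SpindleModel(name=model.name + "_moved", microtubules=mts,
                        chromosomes=chroms, centrioles=cents,
                        kinetochore_thickness=model.kinetochore_thickness)


def test_rigid_motion_invariance(labeled_model, annotations):
    model, _, _ = labeled_model
    rng = np.random.default_rng(42)
    q = rng.normal(size=4); q /= np.linalg.norm(q)
    R = trimesh.transformations.quaternion_matrix(q)[:3, :3]
    moved = _rigid_copy(model, R, rng.normal(scale=2000.0, size=3))

    mt0, mt1 = model.microtubules[0], moved.microtubules[0]
    assert mo.arc_length(mt1) == pytest.approx(mo.arc_length(mt0), rel=1e-9)
    assert mo.tortuosity(mt1) == pytest.approx(mo.tortuosity(mt0), rel=1e-9)

    a, b = mo.stage_metrics(model), mo.stage_metrics(moved)
    for name in ("aa_distance", "pp_distance", "autosome_centrosome_distance",
                 "centriole_split"):
        assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-6)

    r1 = mo.polymer_box_ratio(model).ratio
    r2 = mo.polymer_box_ratio(moved).ratio
    assert r2 == pytest.approx(r1, rel=1e-6)

    row = annotations[annotations.is_kmt & (annotations.association == "end_on")].iloc[0]
    ann0 = cls.classify_kmt(model.mt_by_id(row.mt_id), model)
    ann1 = cls.classify_kmt(moved.mt_by_id(row.mt_id), moved)
    assert mo.attachment_angle(ann1, moved).alpha == \
        pytest.approx(mo.attachment_angle(ann0, model).alpha, rel=1e-6)
    assert mo.plus_end_to_centriole(ann1, moved) == \
        pytest.approx(mo.plus_end_to_centriole(ann0, model), rel=1e-6)

    chrom0, chrom1 = model.autosomes[0], moved.autosomes[0]
    f0 = mo.stretch_fwhm(chrom0, model.spindle_axis()).fwhm
    f1 = mo.stretch_fwhm(chrom1, moved.spindle_axis()).fwhm
    assert f1 == pytest.approx(f0, rel=1e-4)


# ---------------------------------------------------------------------------
# per-spindle report
# ---------------------------------------------------------------------------

def test_summary_counts_match_truth(labeled_model, annotations):
    model, truth, recipe = labeled_model
    table = mo.summarize_spindle(model, annotations)
    row = table.iloc[0]
    assert row.mts_total == recipe.n_mts
    assert row.end_on_x == recipe.x_end_on
    assert row.kmts_total == truth.is_kmt.sum()
    assert row.aa_distance_um == pytest.approx(0.94, abs=0.01)


def test_summary_deterministic(labeled_model, annotations):
    model, _, _ = labeled_model
    t1 = mo.summarize_spindle(model, annotations)
    t2 = mo.summarize_spindle(model, annotations)
    assert t1.equals(t2)


def test_end_on_x_length_tracks_pole_distance():
    """Mean end-on X KMT length grows with imposed pole separation across
    anaphase stages (continuous pole-chromosome connections lengthen)."""
    means = []
    for stage in ("metaphase", "mid_anaphase", "late_anaphase"):
        from spindlemorph import synthetic as syn
        model, truth = syn.simulate_geometry(syn.GeometryRecipe(
            seed=2, stage=stage, n_mts=16, x_end_on=8, x_lateral=2,
            autosome_end_on=3, autosome_lateral=3, mesh_subdivisions=2))
        ids = truth[(truth.chromosome_id == 99) &
                    (truth.association == "end_on")].mt_id
        means.append(np.mean([mo.arc_length(model.mt_by_id(i)) for i in ids]))
    assert means[0] < means[1] < means[2]
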