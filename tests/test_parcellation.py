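import numpy as np
import pytest

from ccparc import (
    CortexLookup,
    LabeledMesh,
    LabelMap,
    Tractogram,
    ValidationError,
    Volume3D,
    VoteConfig,
    build_bundles,
    cortical_areas,
    density_maps,
    endpoint_parcel,
    fill_gaps,
    parcel_areas,
    qc_report,
    regularized_vote,
    select_cc_streamlines,
    witelson_baseline,
)
from ccparc.errors import PipelineError
from ccparc.formats_io import PARCEL_NAMES
from ccparc.parcellation import LabeledBundle, run_parcellation
from ccparc.section import PlaneSpec, extract_section
from ccparc.synthetic import PhantomSpec, generate_phantom

from conftest import make_strip_grid


# ---------------------------------------------------------------------------
# Streamline selection
# ---------------------------------------------------------------------------

def segment_box_crossings(pts, plane, grid):
    """Oracle: exhaustive per-segment plane crossing + point-in-box test."""
    hits = set()
    d = plane.signed_distance(pts)
    for k in range(len(pts) - 1):
        s0, s1 = d[k] >= 0, d[k + 1] >= 0
        if s0 == s1:
            continue
        t = d[k] / (d[k] - d[k + 1])
        p = pts[k] + t * (pts[k + 1] - pts[k])
        for v in range(len(grid)):
            c = grid.centers[v]
            half = np.sqrt(grid.voxel_area) / 2  # square in-plane voxels
            # half-open in-plane box, ignore the slab axis
            lo = c[1:] - half
            hi = c[1:] + half
            if np.all(p[1:] >= lo) and np.all(p[1:] < hi):
                hits.add(v)
    return hits


class TestSelect:
    def test_one_sided_streamline_excluded(self):
        grid = make_strip_grid()
        tract = Tractogram([np.array([[1.0, 0, 0], [5.0, 1, 1]])])
        sel = select_cc_streamlines(tract, grid)
        assert len(sel.indices) == 0

    def test_crossing_outside_grid_excluded(self):
        grid = make_strip_grid()  # footprint y,z in [0, 3) mm
        tract = Tractogram([np.array([[-5.0, 0, -20.0], [5.0, 0, -20.0]])])
        sel = select_cc_streamlines(tract, grid)
        assert len(sel.indices) == 0

    def test_three_streamline_toy_matches_oracle(self):
        grid = make_strip_grid(n_i=6, n_j=6, voxel=0.5)
        through = np.array([[-3.0, 1.1, 1.1], [3.0, 1.1, 1.1]])
        outside = np.array([[-3.0, 40.0, 40.0], [3.0, 40.0, 40.0]])
        non_crossing = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
        tract = Tractogram([through, outside, non_crossing])
        sel = select_cc_streamlines(tract, grid)
        assert list(sel.indices) == [0]
        oracle = segment_box_crossings(through, grid.plane, grid)
        assert set(sel.crossing_voxels[0]) == oracle

    def test_random_polylines_match_oracle(self):
        grid = make_strip_grid(n_i=8, n_j=8, voxel=0.5)
        rng = np.random.default_rng(11)
        for _ in range(30):
            pts = rng.normal(0, 2.0, size=(5, 3)) + [0, 2, 2]
            tract = Tractogram([pts])
            sel = select_cc_streamlines(tract, grid)
            oracle = segment_box_crossings(pts, grid.plane, grid)
            got = set(sel.crossing_voxels[0]) if len(sel.indices) else set()
            assert got == oracle

    def test_loop_records_voxel_once(self):
        grid = make_strip_grid()
        # crosses forward and back through the same voxel
        pts = np.array([[-2.0, 1.1, 1.1], [2.0, 1.1, 1.1],
                        [-2.0, 1.15, 1.1]])
        sel = select_cc_streamlines(Tractogram([pts]), grid)
        assert len(sel.crossing_voxels[0]) == 1


# ---------------------------------------------------------------------------
# Endpoint mapping
# ---------------------------------------------------------------------------

def _cortex_volume():
    data = np.zeros((9, 9, 9), dtype=np.int16)
    data[1, 4, 4] = 4   # lone labeled voxel, world (1,4,4)
    data[7, 2:5, 2:5] = 2
    return Volume3D(data, np.eye(4))


class TestEndpointParcel:
    plane = PlaneSpec(origin=[4.0, 0, 0], normal=[1, 0, 0])

    def test_inside_labeled_voxel(self):
        cortex = CortexLookup(_cortex_volume())
        label, hemi = endpoint_parcel([1.1, 4.2, 3.8], cortex, self.plane)
        assert label == 4
        assert hemi == -1

    def test_nearest_within_radius_matches_scan(self):
        vol = _cortex_volume()
        cortex = CortexLookup(vol)
        point = np.array([1.0, 4.0, 5.2])  # 1.2 mm from (1,4,4)
        label, hemi = endpoint_parcel(point, cortex, self.plane, radius=3.0)
        # exhaustive oracle over all labeled voxel centres
        labeled = np.argwhere(vol.data > 0)
        dists = np.linalg.norm(labeled - point, axis=1)
        expect = int(vol.data[tuple(labeled[np.argmin(dists)])])
        assert dists.min() == pytest.approx(1.2)
        assert label == expect == 4

    def test_out_of_reach(self):
        cortex = CortexLookup(_cortex_volume())
        label, _ = endpoint_parcel([1.0, 4.0, 8.9], cortex, self.plane,
                                   radius=3.0)
        assert label == 0

    def test_hemisphere_sign(self):
        cortex = CortexLookup(_cortex_volume())
        _, hemi = endpoint_parcel([7.0, 3.0, 3.0], cortex, self.plane)
        assert hemi == 1

    def test_on_plane_hemisphere_undefined(self):
        cortex = CortexLookup(_cortex_volume())
        _, hemi = endpoint_parcel([4.0, 3.0, 3.0], cortex, self.plane)
        assert hemi == 0

    def test_mesh_backend(self):
        mesh = LabeledMesh(
            vertices=np.array([[0.0, 0, 0], [10.0, 0, 0]]),
            triangles=np.zeros((0, 3), dtype=int),
            vertex_labels=np.array([3, 6]),
        )
        cortex = CortexLookup(mesh)
        assert cortex.lookup([0.5, 0, 0], radius=1.0) == 3
        assert cortex.lookup([5.0, 0, 0], radius=1.0) == 0

    def test_negative_radius_rejected(self):
        cortex = CortexLookup(_cortex_volume())
        with pytest.raises(ValidationError):
            cortex.lookup([0, 0, 0], radius=-1.0)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

class TestBuildBundles:
    def test_phantom_bundle_sizes_match_ground_truth(
            self, phantom, phantom_grid, phantom_cortex):
        sel = select_cc_streamlines(phantom.tractogram, phantom_grid)
        bundles, qc = build_bundles(phantom.tractogram, sel, phantom_cortex,
                                    phantom.plane)
        truth = phantom.ground_truth["bundle_counts"]
        for l, name in enumerate(PARCEL_NAMES, start=1):
            assert len(bundles[l]) == truth[name]
        assert qc["heterotopic"] == phantom.ground_truth["n_heterotopic"]
        assert qc["homotopic"] == phantom.ground_truth["n_homotopic"]

    def test_homotopic_and_heterotopic_routing(self, phantom_grid,
                                               phantom_cortex, phantom):
        # two handmade fibers: one homotopic precentral, one heterotopic
        y_pre = 0.5 * (phantom.ground_truth["band_start_y"][3]
                       + phantom.ground_truth["band_end_y"][3]) - 0.25
        y_post = 0.5 * (phantom.ground_truth["band_start_y"][4]
                        + phantom.ground_truth["band_end_y"][4]) - 0.25
        z = 10.25
        x0 = phantom.ground_truth["plane_x_mm"]
        homo = np.array([[x0 - 10, y_pre, z], [x0 + 10, y_pre, z]])
        hetero = np.array([[x0 - 10, y_pre, z], [x0 + 10, y_post, z]])
        tract = Tractogram([homo, hetero])
        sel = select_cc_streamlines(tract, phantom_grid)
        bundles, qc = build_bundles(tract, sel, phantom_cortex, phantom.plane)
        assert len(bundles[4]) == 1          # precentral
        assert qc["heterotopic"] == 1

    def test_same_hemisphere_discarded(self, phantom_grid, phantom_cortex,
                                       phantom):
        x0 = phantom.ground_truth["plane_x_mm"]
        y = phantom.ground_truth["band_start_y"][3] + 0.75
        pts = np.array([[x0 - 10, y, 10.25], [x0 + 3, y, 10.25],
                        [x0 - 10, y, 11.25]])
        sel = select_cc_streamlines(Tractogram([pts]), phantom_grid)
        _, qc = build_bundles(Tractogram([pts]), sel, phantom_cortex,
                              phantom.plane)
        assert qc["same_hemisphere"] == 1


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

def _bundle(label, weights, voxel_lists):
    return LabeledBundle(
        label=label,
        streamline_indices=np.arange(len(weights)),
        weights=np.asarray(weights, dtype=float),
        crossing_voxels=[np.asarray(v, dtype=int) for v in voxel_lists],
    )


def _empty_bundles():
    return {l: _bundle(l, [], []) for l in range(1, 8)}


class TestDensityMaps:
    def test_single_weighted_streamline(self):
        grid = make_strip_grid(3, 3)
        bundles = _empty_bundles()
        bundles[2] = _bundle(2, [2.0], [[4]])
        d = density_maps(bundles, grid)
        assert d[1, 4] == 2.0
        assert d.sum() == 2.0

    def test_loop_counts_once(self):
        # crossing_voxels is a distinct-voxel set by construction; a loop
        # contributes its weight once.
        grid = make_strip_grid(3, 3)
        bundles = _empty_bundles()
        bundles[3] = _bundle(3, [1.5], [[7]])
        d = density_maps(bundles, grid)
        assert d[2, 7] == 1.5

    def test_brute_force_sum(self):
        grid = make_strip_grid(2, 2)
        weights = [0.5, 2.0, 1.0]
        voxels = [[0, 1], [1], [0, 2]]
        bundles = _empty_bundles()
        bundles[5] = _bundle(5, weights, voxels)
        d = density_maps(bundles, grid)
        oracle = np.zeros(4)
        for w, vs in zip(weights, voxels):
            for v in set(vs):
                oracle[v] += w
        np.testing.assert_allclose(d[4], oracle)
        assert np.all(d[[0, 1, 2, 3, 5, 6]] == 0)


# ---------------------------------------------------------------------------
# Regularized vote
# ---------------------------------------------------------------------------

def vote_oracle(d, grid, self_w=0.5, nb_w=1.0 / 12.0):
    """Independent dense-raster kernel evaluation."""
    ij = grid.ij
    lo = ij.min(axis=0)
    shape = tuple(ij.max(axis=0) - lo + 3)  # pad border
    dense = np.zeros((7,) + shape)
    for v, (i, j) in enumerate(ij):
        dense[:, i - lo[0] + 1, j - lo[1] + 1] = d[:, v]
    mass = d.sum(axis=1)
    labels = np.zeros(len(ij), dtype=int)
    for v, (i, j) in enumerate(ij):
        a, b = i - lo[0] + 1, j - lo[1] + 1
        scores = np.zeros(7)
        for l in range(7):
            nb = dense[l, a - 1:a + 2, b - 1:b + 2].sum() - dense[l, a, b]
            scores[l] = self_w * dense[l, a, b] + nb_w * nb
        best = scores.max()
        if best <= 0:
            labels[v] = 0
            continue
        cands = [l for l in range(7) if scores[l] == best]
        cands.sort(key=lambda l: (-mass[l], l))
        labels[v] = cands[0] + 1
    return labels


class TestRegularizedVote:
    def test_lone_density_wins(self):
        grid = make_strip_grid(3, 3)
        d = np.zeros((7, 9))
        d[0, 4] = 1.0
        out = regularized_vote(d, grid)
        # the centre voxel and (via the kernel) all its neighbours get label 1
        assert np.all(out.labels == 1)
        assert not out.filled.any()

    def test_isolated_voxel_regularized_away(self):
        # centre has d_B = 1; its 8 neighbours have d_A = 1 each:
        # score_A(centre) = 8/12 > score_B(centre) = 1/2, so A wins.
        grid = make_strip_grid(3, 3)
        d = np.zeros((7, 9))
        center = grid.index_of((1, 1))
        for v in range(9):
            if v == center:
                d[1, v] = 1.0   # label B = 2
            else:
                d[0, v] = 1.0   # label A = 1
        out = regularized_vote(d, grid)
        assert out.labels[center] == 1
        # hand-computed scores
        assert 8 / 12 > 0.5

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        grid = make_strip_grid(5, 5)
        for _ in range(50):
            d = np.zeros((7, 25))
            active = rng.choice(7, size=2, replace=False)
            d[active] = rng.random((2, 25)) * (rng.random((2, 25)) < 0.6)
            if not np.any(d > 0):
                continue
            out = regularized_vote(d, grid)
            np.testing.assert_array_equal(out.labels, vote_oracle(d, grid))

    def test_all_zero_densities_error(self):
        grid = make_strip_grid(2, 2)
        with pytest.raises(PipelineError, match="no callosal fibers"):
            regularized_vote(np.zeros((7, 4)), grid)

    def test_tie_breaks_to_larger_bundle_mass(self):
        grid = make_strip_grid(1, 2)
        d = np.zeros((7, 2))
        d[0, 0] = 1.0           # label 1: mass 1
        d[6, 0] = 1.0           # label 7: mass 2 -> wins the tie at voxel 0
        d[6, 1] = 1.0
        out = regularized_vote(d, grid)
        assert out.labels[0] == 7

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(17)
        grid = make_strip_grid(6, 6)
        d = rng.random((7, 36)) * (rng.random((7, 36)) < 0.4)
        d[0, 0] = 0.3
        base = regularized_vote(d, grid).labels
        for c in (0.01, 3.7, 1e4):
            np.testing.assert_array_equal(
                regularized_vote(c * d, grid).labels, base)


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

class TestFillGaps:
    def test_fully_assigned_unchanged(self):
        grid = make_strip_grid(3, 3)
        labels = np.full(9, 4)
        out = fill_gaps(LabelMap(labels, np.zeros(9, bool)), grid)
        np.testing.assert_array_equal(out.labels, labels)
        assert not out.filled.any()

    def test_interior_zero_surrounded(self):
        grid = make_strip_grid(3, 3)
        labels = np.full(9, 5)
        center = grid.index_of((1, 1))
        labels[center] = 0
        out = fill_gaps(LabelMap(labels, np.zeros(9, bool)), grid)
        assert out.labels[center] == 5
        assert out.filled[center]

    def test_two_voxel_gap_matches_nearest_label(self):
        # a 1 x 8 strip: labels 4,4,4,0,0,6,6,6 -> the two gap voxels take
        # their nearest assigned label.
        grid = make_strip_grid(8, 1)
        labels = np.array([4, 4, 4, 0, 0, 6, 6, 6])
        out = fill_gaps(LabelMap(labels, np.zeros(8, bool)), grid)
        # oracle: exhaustive nearest assigned voxel (modal pass matches it
        # here because each gap voxel has exactly one adjacent label)
        expect = labels.copy()
        for v in (3, 4):
            dists = [(abs(v - u), labels[u]) for u in range(8) if labels[u]]
            dmin = min(d for d, _ in dists)
            expect[v] = min(l for d, l in dists if d == dmin)
        np.testing.assert_array_equal(out.labels, expect)

    def test_partition_total(self):
        rng = np.random.default_rng(23)
        grid = make_strip_grid(7, 7)
        labels = rng.integers(0, 8, size=49)
        if not (labels > 0).any():
            labels[0] = 1
        out = fill_gaps(LabelMap(labels, np.zeros(49, bool)), grid)
        assert np.all(out.labels >= 1) and np.all(out.labels <= 7)

    def test_needs_one_assigned_voxel(self):
        grid = make_strip_grid(2, 2)
        with pytest.raises(ValidationError):
            fill_gaps(LabelMap(np.zeros(4, int), np.zeros(4, bool)), grid)


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

class TestParcelAreas:
    def test_ten_voxels_at_quarter_mm2(self):
        grid = make_strip_grid(5, 2, voxel=0.5)
        labels = np.full(10, 3)
        m = parcel_areas(LabelMap(labels, np.zeros(10, bool)), grid)
        assert m.ccps_mm2["posterior_prefrontal"] == pytest.approx(2.5)
        assert m.cc_total_mm2 == pytest.approx(2.5)

    def test_conservation_exact(self):
        rng = np.random.default_rng(2)
        grid = make_strip_grid(20, 10, voxel=0.5)
        labels = rng.integers(1, 8, size=200)
        m = parcel_areas(LabelMap(labels, np.zeros(200, bool)), grid)
        assert sum(m.ccps_mm2.values()) == m.cc_total_mm2
        assert m.cc_total_mm2 == pytest.approx(200 * 0.25)

    def test_absent_label_reports_zero(self):
        grid = make_strip_grid(2, 2)
        m = parcel_areas(LabelMap(np.full(4, 7), np.zeros(4, bool)), grid)
        assert m.ccps_mm2["frontopolar"] == 0.0

    def test_phantom_fractions_near_targets(self, phantom, phantom_grid,
                                            phantom_cortex):
        res = run_parcellation(phantom.tractogram, phantom_grid,
                               phantom_cortex)
        total = res.morphometry.cc_total_mm2
        for name, target in zip(PARCEL_NAMES,
                                phantom.spec.band_fractions):
            frac = res.morphometry.ccps_mm2[name] / total
            assert abs(frac - target) <= 0.05


class TestCorticalAreas:
    def test_unit_right_triangle(self):
        mesh = LabeledMesh(
            vertices=np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            triangles=np.array([[0, 1, 2]]),
            vertex_labels=np.array([3, 3, 3]),
        )
        cxps, tcxs, _ = cortical_areas(mesh)
        assert cxps["posterior_prefrontal"] == pytest.approx(0.005)
        assert tcxs == pytest.approx(0.005)

    def test_two_triangle_square_split(self):
        # unit square, triangle 1 all label 1, triangle 2 all label 2:
        # each triangle has area 1/2, all three corners one label -> 50/50
        mesh = LabeledMesh(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                               [0.0, 0, 0], [1, 1, 0]]),
            triangles=np.array([[0, 1, 2], [4, 5, 3]]),
            vertex_labels=np.array([1, 1, 1, 2, 2, 2]),
        )
        cxps, tcxs, _ = cortical_areas(mesh)
        assert cxps["frontopolar"] == pytest.approx(0.005)
        assert cxps["anterior_prefrontal"] == pytest.approx(0.005)
        assert tcxs == pytest.approx(0.01)

    def test_mixed_labels_third_share(self):
        # one unit right triangle, corners labeled 1, 1, 2:
        # label 1 gets 2/3 of the area, label 2 gets 1/3
        mesh = LabeledMesh(
            vertices=np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]]),
            triangles=np.array([[0, 1, 2]]),
            vertex_labels=np.array([1, 1, 2]),
        )
        cxps, _, _ = cortical_areas(mesh)
        assert cxps["frontopolar"] == pytest.approx(0.5 * 2 / 3 / 100)
        assert cxps["anterior_prefrontal"] == pytest.approx(0.5 / 3 / 100)

    def test_conservation(self, phantom):
        cxps, tcxs, _ = cortical_areas(phantom.mesh)
        assert sum(cxps.values()) == pytest.approx(tcxs)

    def test_degenerate_triangles_counted(self):
        mesh = LabeledMesh(
            vertices=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),
            triangles=np.array([[0, 1, 2]]),
            vertex_labels=np.array([1, 1, 1]),
        )
        cxps, tcxs, degenerate = cortical_areas(mesh)
        assert degenerate == 1
        assert tcxs == 0.0


# ---------------------------------------------------------------------------
# Geometric baseline, QC
# ---------------------------------------------------------------------------

class TestWitelsonBaseline:
    def test_fraction_arithmetic(self):
        # 30-column strip, cuts (1/3, 1/2, 2/3, 4/5): bins of 10,5,5,4,6
        grid = make_strip_grid(30, 1, voxel=1.0)
        out = witelson_baseline(grid, (1 / 3, 1 / 2, 2 / 3, 4 / 5))
        # anterior = larger world y = larger i
        widths = {l: int((out.labels == l).sum()) for l in range(1, 6)}
        assert widths == {1: 10, 2: 5, 3: 5, 4: 4, 5: 6}

    def test_half_split(self):
        grid = make_strip_grid(10, 1, voxel=1.0)
        out = witelson_baseline(grid, (0.5,))
        assert (out.labels == 1).sum() == 5
        assert (out.labels == 2).sum() == 5

    def test_empty_fractions_single_parcel(self):
        grid = make_strip_grid(4, 4)
        out = witelson_baseline(grid, ())
        assert np.all(out.labels == 1)

    def test_non_increasing_rejected(self):
        grid = make_strip_grid(4, 4)
        with pytest.raises(ValidationError):
            witelson_baseline(grid, (0.5, 0.5))
        with pytest.raises(ValidationError):
            witelson_baseline(grid, (0.0, 0.5))

    def test_anterior_is_label_one(self):
        grid = make_strip_grid(10, 1, voxel=1.0)
        out = witelson_baseline(grid, (0.5,))
        ap = grid.ap
        assert ap[out.labels == 1].min() > ap[out.labels == 2].max()


class TestQcReport:
    def test_contiguous_bands_clean(self, phantom, phantom_grid,
                                    phantom_cortex):
        res = run_parcellation(phantom.tractogram, phantom_grid,
                               phantom_cortex)
        rep = res.qc
        for name in PARCEL_NAMES:
            assert rep["labels"][name]["components"] == 1
        assert rep["warnings"] == []

    def test_split_parcel_warning(self):
        grid = make_strip_grid(9, 1, voxel=1.0)
        labels = np.array([2, 2, 5, 5, 2, 5, 5, 2, 2])
        rep = qc_report(LabelMap(labels, np.zeros(9, bool)), grid,
                        fraction_band=(0.0, 1.0))
        assert rep["labels"]["anterior_prefrontal"]["components"] == 3
        assert any("anterior_prefrontal" in w for w in rep["warnings"])

    def test_agenesis_reports_zero(self, phantom_cortex):
        spec = PhantomSpec(seed=3, agenesis=frozenset({6, 7}))
        ph = generate_phantom(spec)
        grid = extract_section(ph.wm_mask, ph.plane, 2)
        res = run_parcellation(ph.tractogram, grid,
                               CortexLookup(ph.cortex_labels))
        for name in ("parietal", "occipital"):
            assert res.qc["labels"][name]["components"] == 0
            assert res.qc["labels"][name]["area_mm2"] == 0.0


# ---------------------------------------------------------------------------
# End-to-end invariants
# ---------------------------------------------------------------------------

class TestPipelineInvariants:
    def test_recovery_99_percent(self, phantom, phantom_grid, phantom_cortex):
        res = run_parcellation(phantom.tractogram, phantom_grid,
                               phantom_cortex)
        truth = phantom.truth_labels(phantom_grid)
        assert (res.label_map.labels == truth).mean() >= 0.99

    def test_partition_and_conservation(self, phantom, phantom_grid,
                                        phantom_cortex):
        res = run_parcellation(phantom.tractogram, phantom_grid,
                               phantom_cortex)
        assert np.all(res.label_map.labels >= 1)
        assert sum(res.morphometry.ccps_mm2.values()) == \
            res.morphometry.cc_total_mm2
        assert res.morphometry.cc_total_mm2 == pytest.approx(phantom_grid.area)

    def test_weight_scaling_leaves_labels_unchanged(
            self, phantom, phantom_grid, phantom_cortex):
        res1 = run_parcellation(phantom.tractogram, phantom_grid,
                                phantom_cortex)
        scaled = Tractogram(phantom.tractogram.streamlines,
                            phantom.tractogram.weights * 137.5)
        res2 = run_parcellation(scaled, phantom_grid, phantom_cortex)
        np.testing.assert_array_equal(res1.label_map.labels,
                                      res2.label_map.labels)

    def test_heterotopic_fibers_do_not_matter(self, phantom_grid):
        base = generate_phantom(PhantomSpec(seed=4, heterotopic_fraction=0.0,
                                            stray_fraction=0.0))
        noisy = generate_phantom(PhantomSpec(seed=4, heterotopic_fraction=0.2,
                                             stray_fraction=0.0))
        grid = extract_section(base.wm_mask, base.plane, 2)
        res_base = run_parcellation(base.tractogram, grid,
                                    CortexLookup(base.cortex_labels))
        res_noisy = run_parcellation(noisy.tractogram, grid,
                                     CortexLookup(noisy.cortex_labels))
        np.testing.assert_array_equal(res_base.label_map.labels,
                                      res_noisy.label_map.labels)
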