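"""Spatial statistics: alignment recovery, pair-correlation against an
O(n^2) oracle and CSR theory, focus segmentation against a brute-force
density-connectivity reference, rendering and percent-change."""

import numpy as np
import pytest

import forkstat as fs


@pytest.fixture
def square_roi():
    return fs.RectROI(0, 0, 5000, 5000)


def brute_force_pair_counts(A, B, edges, exclude_self=False):
    """Direct O(n^2) distance histogram with half-open (lo, hi] bins."""
    counts = np.zeros(len(edges) - 1)
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            if exclude_self and i == j:
                continue
            d = np.hypot(a[0] - b[0], a[1] - b[1])
            for k in range(len(edges) - 1):
                if edges[k] < d <= edges[k + 1]:
                    counts[k] += 1
    return counts


def brute_force_dbscan(points, eps, min_pts):
    """Reference density-connectivity clustering (BFS over core points)."""
    n = len(points)
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    neighbours = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbours]
    labels = np.full(n, -1)
    current = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbours[j]:
                if labels[k] == -1:
                    labels[k] = current
                    stack.append(k)
        current += 1
    return labels


class TestAlignChannels:
    def test_identity(self, rng):
        pts = rng.uniform(0, 1000, (10, 2))
        t = fs.align_channels(pts, pts)
        np.testing.assert_allclose(t.matrix, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-6)
        assert t.rms_nm < 1e-6

    def test_pure_translation_recovered(self, rng):
        pts = rng.uniform(0, 1000, (8, 2))
        t = fs.align_channels(pts, pts - [10.0, 5.0])
        np.testing.assert_allclose(t.matrix, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(t.translation, [10.0, 5.0], atol=1e-6)

    def test_random_affine_with_noise_recovered(self, rng):
        mov = rng.uniform(0, 5000, (20, 2))
        true_m = np.array([[1.01, 0.02], [-0.015, 0.99]])
        true_t = np.array([30.0, -12.0])
        ref = mov @ true_m.T + true_t + rng.normal(0, 1.0, (20, 2))
        t = fs.align_channels(ref, mov)
        assert t.rms_nm <= 2.0
        resid = ref - t.apply(mov)
        assert np.sqrt((resid ** 2).sum(1).mean()) <= 2.0

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="collinear"):
            fs.align_channels(pts, pts)


class TestPairCorrelation:
    def test_single_pair_occupies_one_bin(self, square_roi):
        A = np.array([[1000.0, 1000.0]])
        B = np.array([[1000.0, 1070.0]])  # d = 70 nm
        res = fs.cross_pair_correlation(A, B, 200, 25, square_roi)
        occupied = np.flatnonzero(res.counts)
        assert list(occupied) == [2]  # bin (50, 75]

    def test_counts_match_brute_force_oracle(self, rng, square_roi):
        A = rng.uniform(0, 5000, (200, 2))
        B = rng.uniform(0, 5000, (150, 2))
        res = fs.cross_pair_correlation(A, B, 400, 40, square_roi)
        expected = brute_force_pair_counts(A, B, res.r_bin_edges)
        np.testing.assert_array_equal(res.counts, expected)

    def test_auto_counts_match_brute_force_oracle(self, rng, square_roi):
        X = rng.uniform(0, 5000, (180, 2))
        res = fs.auto_pair_correlation(X, 300, 30, square_roi)
        expected = brute_force_pair_counts(X, X, res.r_bin_edges, exclude_self=True)
        np.testing.assert_array_equal(res.counts, expected)

    def test_auto_equals_cross_with_self(self, rng, square_roi):
        X = rng.uniform(0, 5000, (100, 2))
        ra = fs.auto_pair_correlation(X, 300, 30, square_roi)
        rc = fs.cross_pair_correlation(X, X, 300, 30, square_roi)
        np.testing.assert_array_equal(ra.counts, rc.counts)  # d=0 outside (0,h]

    def test_pdf_integrates_to_one(self, rng, square_roi):
        A = rng.uniform(0, 5000, (300, 2))
        B = rng.uniform(0, 5000, (300, 2))
        res = fs.cross_pair_correlation(A, B, 500, 25, square_roi)
        widths = np.diff(res.r_bin_edges)
        assert np.sum(res.pdf * widths) == pytest.approx(1.0)

    def test_csr_density_at_b_matches_generating_density(self):
        dens = 50.0
        spec = fs.CoClusterSpec(density_a=dens, density_b=dens,
                                coloc_fraction=0.0, region_nm=(0, 0, 5000, 5000))
        roi = fs.RectROI(0, 0, 5000, 5000)
        vals = []
        for seed in range(20):
            A, B, _ = fs.simulate_point_pattern(spec, seed)
            res = fs.cross_pair_correlation(A, B, 300, 25, roi)
            vals.append(res.density_at_b_per_um2)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - dens) < 3 * se

    def test_csr_auto_pdf_flat_chisquare(self):
        spec = fs.CoClusterSpec(density_a=10.0, coloc_fraction=0.0,
                                region_nm=(0, 0, 8000, 8000))
        roi = fs.RectROI(0, 0, 8000, 8000)
        for seed in range(10):
            A, _, _ = fs.simulate_point_pattern(spec, seed)
            assert fs.spatial.csr_flatness_pvalue(A, 300, 30, roi) > 0.01

    def test_enrichment_monotone_in_coloc_fraction(self, square_roi):
        values = []
        for frac in (0.0, 0.25, 0.5, 1.0):
            spec = fs.CoClusterSpec(density_a=50.0, density_b=50.0,
                                    coloc_fraction=frac, coloc_sigma_nm=20.0)
            A, B, _ = fs.simulate_point_pattern(spec, 42)
            res = fs.cross_pair_correlation(A, B, 300, 25, square_roi)
            values.append(res.density_at_b_per_um2)
        assert values == sorted(values)

    def test_rigid_motion_invariance(self, rng):
        A = rng.uniform(1000, 4000, (150, 2))
        B = rng.uniform(1000, 4000, (120, 2))
        roi = fs.RectROI(0, 0, 5000, 5000)
        res1 = fs.cross_pair_correlation(A, B, 300, 30, roi)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        center = np.array([2500.0, 2500.0])
        shift = np.array([100.0, -50.0])
        A2 = (A - center) @ R.T + center + shift
        B2 = (B - center) @ R.T + center + shift
        roi2 = fs.PolygonROI((np.array([[0, 0], [5000, 0], [5000, 5000],
                                        [0, 5000]]) - center) @ R.T + center + shift)
        res2 = fs.cross_pair_correlation(A2, B2, 300, 30, roi2)
        np.testing.assert_array_equal(res1.counts, res2.counts)
        assert res2.density_at_b_per_um2 == pytest.approx(
            res1.density_at_b_per_um2, rel=1e-3)

    def test_empty_sets_distinguished(self, square_roi):
        pts = np.array([[1.0, 1.0]])
        with pytest.raises(ValueError, match="A"):
            fs.cross_pair_correlation(np.empty((0, 2)), pts, 100, 10, square_roi)
        with pytest.raises(ValueError, match="B"):
            fs.cross_pair_correlation(pts, np.empty((0, 2)), 100, 10, square_roi)


class TestROIGeometry:
    def test_rect_disc_area_matches_shapely(self, rng):
        roi = fs.RectROI(0, 0, 1000, 800)
        poly = roi.as_polygon()
        centers = np.column_stack([rng.uniform(-100, 1100, 40),
                                   rng.uniform(-100, 900, 40)])
        import shapely
        for r in (30.0, 150.0, 400.0):
            exact = roi.disc_areas(centers, r)
            approx = np.array([shapely.Point(c).buffer(r, quad_segs=256)
                               .intersection(poly).area for c in centers])
            np.testing.assert_allclose(exact, approx, rtol=1e-4, atol=1.0)

    def test_interior_disc_is_full_circle(self):
        roi = fs.RectROI(0, 0, 1000, 1000)
        area = roi.disc_areas(np.array([[500.0, 500.0]]), 100.0)[0]
        assert area == pytest.approx(np.pi * 100.0 ** 2)


class TestFoci:
    def test_two_separated_blobs(self, rng):
        blob1 = rng.normal([1000, 1000], 40, (50, 2))
        blob2 = rng.normal([4000, 4000], 40, (50, 2))
        foci, qc = fs.segment_foci(np.vstack([blob1, blob2]), eps_nm=150,
                                   min_pts=10)
        assert len(foci) == 2
        assert {f.n for f in foci} == {50}

    def test_sparse_background_no_foci(self, rng):
        pts = rng.uniform(0, 10_000, (40, 2))  # far below min_pts density
        foci, _ = fs.segment_foci(pts, eps_nm=100, min_pts=10)
        assert foci == []

    def test_matches_brute_force_density_connectivity(self, rng):
        pts = np.vstack([rng.normal([500, 500], 60, (60, 2)),
                         rng.normal([1500, 600], 60, (60, 2)),
                         rng.uniform(0, 2000, (60, 2))])
        eps, min_pts = 120.0, 8
        ref = brute_force_dbscan(pts, eps, min_pts)
        from sklearn.cluster import DBSCAN
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit(pts).labels_
        # same partition of core-reachable points up to label permutation
        for lab in np.unique(ref[ref >= 0]):
            members = np.flatnonzero(ref == lab)
            impl_labels = set(labels[members])
            assert len(impl_labels) == 1
            assert impl_labels != {-1}
        assert np.sum(ref == -1) == np.sum(labels == -1)

    def test_density_is_count_over_hull_area(self, rng):
        pts = rng.normal([1000, 1000], 100, (80, 2))
        foci, _ = fs.segment_foci(pts, eps_nm=500, min_pts=5)
        assert len(foci) == 1
        f = foci[0]
        assert f.density_per_um2 == pytest.approx(f.n / f.area_um2)

    def test_degenerate_hull_dropped(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [30.0, 0.0]])
        foci, qc = fs.segment_foci(pts, eps_nm=15, min_pts=3)
        assert foci == []
        assert qc["degenerate_hulls"] == 1


class TestNucleusSummaries:
    def _nucleus(self, positive=True):
        return fs.NucleusROI(fs.RectROI(0, 0, 10_000, 10_000), "n1",
                             pcna_positive=positive)

    def _focus(self, density):
        return fs.Focus(member_ids=np.arange(5), centroid_nm=(0, 0),
                        area_um2=1.0, density_per_um2=density)

    def test_single_focus_density(self):
        assert fs.per_nucleus_summary([self._focus(10.0)], self._nucleus()) == 10.0

    def test_mean_of_focus_densities(self):
        foci = [self._focus(2.0), self._focus(4.0)]
        assert fs.per_nucleus_summary(foci, self._nucleus()) == 3.0

    def test_pcna_negative_skipped(self):
        assert fs.per_nucleus_summary([self._focus(5.0)],
                                      self._nucleus(positive=False)) is None

    def test_summarize_counts_skips(self):
        pairs = [(self._nucleus(), [self._focus(2.0)]),
                 (self._nucleus(False), [self._focus(9.0)]),
                 (self._nucleus(), [])]
        table, qc = fs.summarize_nuclei(pairs)
        assert len(table) == 1
        assert qc == {"skipped_pcna_negative": 1, "skipped_no_foci": 1}

    def test_designed_density_ratio_recovered(self, rng):
        # two conditions built to differ 2x in within-focus density
        means = {}
        for cond, sigma in (("lo", 80.0), ("hi", 80.0 / np.sqrt(2))):
            summaries = []
            for _ in range(40):
                nucleus = self._nucleus()
                blobs = [rng.normal(rng.uniform(2000, 8000, 2), sigma, (60, 2))
                         for _ in range(3)]
                foci, _ = fs.segment_foci(np.vstack(blobs), eps_nm=200, min_pts=10)
                s = fs.per_nucleus_summary(foci, nucleus)
                if s is not None:
                    summaries.append(s)
            means[cond] = np.mean(summaries)
        ratio = means["hi"] / means["lo"]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_pcna_classification_threshold(self):
        nucleus = fs.NucleusROI(fs.RectROI(0, 0, 1000, 1000), "n")
        dense = np.random.default_rng(0).uniform(0, 1000, (100, 2))  # 100/um^2
        assert fs.classify_pcna_positive(nucleus, dense, background_density_per_um2=10.0)
        assert not fs.classify_pcna_positive(nucleus, dense[:20],
                                             background_density_per_um2=10.0)


class TestRender:
    def test_histogram_sums_to_event_count(self, rng):
        pts = rng.uniform(0, 1000, (37, 2))
        img = fs.render_image(pts, (0, 0, 1000, 1000), canvas_px_nm=10.0)
        assert img.sum() == 37

    def test_translation_by_one_canvas_pixel(self, rng):
        pts = rng.uniform(200, 800, (25, 2))
        img1 = fs.render_image(pts, (0, 0, 1000, 1000), canvas_px_nm=10.0)
        img2 = fs.render_image(pts + [10.0, 0.0], (0, 0, 1000, 1000),
                               canvas_px_nm=10.0)
        np.testing.assert_array_equal(img1[:, :-1], img2[:, 1:])

    def test_blur_conserves_intensity(self, rng):
        pts = rng.uniform(2000, 3000, (50, 2))  # away from borders
        img = fs.render_image(pts, (0, 0, 5000, 5000), canvas_px_nm=10.0,
                              blur_sigma_nm=143.0)
        assert img.sum() == pytest.approx(50.0, rel=1e-3)


class TestPercentChange:
    def test_reference_normalization(self):
        import pandas as pd
        df = pd.DataFrame({
            "rep": ["r1"] * 4 + ["r2"] * 4,
            "condition": ["ctrl", "ctrl", "treat", "treat"] * 2,
            "value": [1.0, 1.0, 2.0, 2.0, 2.0, 2.0, 5.0, 5.0],
        })
        pc = fs.percent_change_normalized(df, "value", "condition", "rep", "ctrl")
        # r1 normalized: ctrl 1, treat 2; r2: ctrl 1, treat 2.5; mean treat 2.25
        assert pc["ctrl"] == 0.0
        assert pc["treat"] == pytest.approx(125.0)

    def test_unknown_reference_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"rep": ["r1"], "condition": ["a"], "value": [1.0]})
        with pytest.raises(ValueError, match="reference"):
            fs.percent_change_normalized(df, "value", "condition", "rep", "zz")
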