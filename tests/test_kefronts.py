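"""KE thresholds, boundary matrices, overlap, segmentation, counts."""
import numpy as np
import pytest
from scipy import ndimage

import ecoregions as er
from ecoregions.kefronts import BoundaryMatrix, FrontMask


class TestThreshold:
    def test_constant_field(self, make_field):
        ke = make_field(np.full((24, 3, 3), 2.5))
        for q in (10, 50, 90):
            assert er.ke_threshold(ke, q) == 2.5

    def test_one_to_hundred(self, make_field):
        vals = np.arange(1.0, 101.0).reshape(4, 5, 5)
        ke = make_field(vals)
        assert er.ke_threshold(ke, 50) == pytest.approx(50.5)
        # independent linear-interpolation oracle
        s = np.sort(vals.ravel())
        h = (len(s) - 1) * 0.37
        lo = int(np.floor(h))
        expect = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert er.ke_threshold(ke, 37) == pytest.approx(expect, abs=1e-12)

    def test_monotone_in_q(self, make_field):
        rng = np.random.default_rng(0)
        ke = make_field(rng.random((24, 4, 4)))
        thr = [er.ke_threshold(ke, q) for q in (10, 30, 50, 70, 90)]
        assert all(a <= b for a, b in zip(thr, thr[1:]))

    def test_all_masked_raises(self, make_field):
        ke = make_field(np.full((24, 3, 3), np.nan), mask=np.zeros((3, 3), bool))
        with pytest.raises(ValueError, match="masked"):
            er.ke_threshold(ke, 50)


class TestBoundaryMatrix:
    def test_two_halfplane_labels(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:5] = 1
        labels[5:] = 2
        bm = er.boundary_matrix(labels, np.ones((10, 10), bool))
        expect = np.zeros((10, 10), bool)
        expect[3:7] = True  # 2-cell interface band dilated to 4 rows
        assert np.array_equal(bm.values, expect)

    def test_dilation_adds_exactly_eight_neighbors(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(12, 12))
        mask = np.ones((12, 12), bool)
        bm = er.boundary_matrix(labels, mask)
        # oracle: raw boundary by explicit 4-neighbor scan, then set arithmetic
        raw = np.zeros((12, 12), bool)
        for i in range(12):
            for j in range(12):
                for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                    if 0 <= ni < 12 and 0 <= nj < 12 and labels[ni, nj] != labels[i, j]:
                        raw[i, j] = True
        expect = set(zip(*np.nonzero(raw)))
        for (i, j) in list(expect):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if 0 <= i + di < 12 and 0 <= j + dj < 12:
                        expect = expect | {(i + di, j + dj)}
        got = set(zip(*np.nonzero(bm.values)))
        assert got == expect

    def test_single_label_boundary_at_background(self):
        labels = np.zeros((12, 12), dtype=int)
        labels[3:9, 3:9] = 1  # one domain surrounded by background ocean
        bm = er.boundary_matrix(labels, np.ones((12, 12), bool))
        assert bm.values[3, 3] and bm.values[2, 2]   # perimeter + dilation
        assert not bm.values[6, 6]                   # deep interior untouched
        # an all-covering label with no background has no boundary at all
        full = np.ones((12, 12), dtype=int)
        bm2 = er.boundary_matrix(full, np.ones((12, 12), bool))
        assert not bm2.values.any()

    def test_coast_flag(self):
        labels = np.ones((6, 6), dtype=int)
        mask = np.ones((6, 6), bool)
        mask[:, :2] = False
        labels[:, :2] = 0
        assert not er.boundary_matrix(labels, mask).values.any()
        with_coast = er.boundary_matrix(labels, mask, coast_as_boundary=True)
        assert with_coast.values[:, 2].all()


class TestOverlap:
    def _bm(self, arr):
        return BoundaryMatrix(values=np.asarray(arr, bool))

    def _fm(self, arr):
        return FrontMask(values=np.asarray(arr, bool), threshold=0.0, q=50)

    def test_front_everywhere_and_nowhere(self):
        b = np.zeros((5, 5), bool)
        b[2] = True
        assert er.overlap_fraction(self._bm(b), self._fm(np.ones((5, 5)))) == 1.0
        assert er.overlap_fraction(self._bm(b), self._fm(np.zeros((5, 5)))) == 0.0

    def test_empty_boundary_raises(self):
        with pytest.raises(ValueError, match="empty boundary"):
            er.overlap_fraction(self._bm(np.zeros((4, 4))), self._fm(np.ones((4, 4))))

    def test_independent_random_front(self):
        rng = np.random.default_rng(2)
        b = np.zeros((40, 40), bool)
        b[10:12] = True
        p = 0.3
        fracs = [
            er.overlap_fraction(self._bm(b), self._fm(rng.random((40, 40)) < p))
            for _ in range(200)
        ]
        se = np.sqrt(p * (1 - p) / (80 * 200))
        assert abs(np.mean(fracs) - p) < 3 * se


class TestKMeans:
    def test_two_valued_perfect_separation(self):
        rng = np.random.default_rng(3)
        vals = np.where(rng.random((10, 10)) < 0.3, 0.1, 0.001)
        cmap, counts, cent = er.kmeans_segment(vals, np.ones((10, 10), bool), k=2)
        assert counts[1] == (vals == 0.1).sum()
        assert np.all(np.diff(cent) > 0)
        assert (cmap[vals == 0.1] == 1).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        vals = rng.random((20, 20))
        out1 = er.kmeans_segment(vals, np.ones((20, 20), bool), k=4, seed=9)
        out2 = er.kmeans_segment(vals, np.ones((20, 20), bool), k=4, seed=9)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    def test_max_cluster_covers_jets(self, small_cfg, small_world):
        truth, _ = small_world
        u, v = er.generate_velocity(truth, small_cfg)
        ke = er.kinetic_energy(u, v)
        mean_ke = np.nanmean(ke.values, axis=0)
        cmap, counts, _ = er.kmeans_segment(mean_ke, ke.mask, k=4, seed=0)
        jm = truth.jet_mask(small_cfg.jet_halfwidth)
        assert (cmap[jm] == 3).sum() >= 0.9 * jm.sum()

    def test_too_few_distinct_values_raises(self):
        vals = np.where(np.arange(36).reshape(6, 6) % 2, 1.0, 2.0)
        with pytest.raises(ValueError, match="distinct"):
            er.kmeans_segment(vals, np.ones((6, 6), bool), k=4)


class TestFrontOccurrence:
    def test_always_above_gives_slot_length(self, make_field):
        ke = make_field(np.full((84, 3, 3), 1.0))
        counts = er.front_occurrence(ke, 0.5)
        assert (counts == 84).all()
        assert (er.front_occurrence(make_field(np.zeros((84, 3, 3))), 0.5) == 0).all()

    def test_matches_loop_oracle(self, make_field):
        rng = np.random.default_rng(5)
        ke = make_field(rng.random((24, 4, 4)))
        thr = 0.6
        counts = er.front_occurrence(ke, thr)
        for i in range(4):
            for j in range(4):
                expect = sum(1 for t in range(24) if ke.values[t, i, j] > thr)
                assert counts[i, j] == expect


class TestCorrelationMap:
    def test_identity_and_negation(self, make_field):
        rng = np.random.default_rng(6)
        f1 = make_field(rng.standard_normal((48, 4, 4)))
        cmap, mean, var, nex = er.field_correlation_map(f1, f1)
        assert np.allclose(cmap, 1.0, atol=1e-12)
        assert mean == pytest.approx(1.0) and var == pytest.approx(0.0, abs=1e-24)
        assert nex == 0
        cmap2, mean2, *_ = er.field_correlation_map(
            f1, f1.with_values(-f1.values))
        assert np.allclose(cmap2, -1.0, atol=1e-12)

    def test_attenuation_closed_form(self, make_field):
        rng = np.random.default_rng(7)
        T = 2000
        base = rng.standard_normal((T, 5, 5))
        noise = rng.standard_normal((T, 5, 5))
        f1 = make_field(base)
        f2 = make_field(0.8 * base + 0.6 * noise)
        _, mean, _, _ = er.field_correlation_map(f1, f2)
        expect = 0.8 / np.sqrt(0.8**2 + 0.6**2)
        assert mean == pytest.approx(expect, abs=0.03)

    def test_incongruent_raises(self, make_field):
        f1 = make_field(np.zeros((24, 3, 3)))
        f2 = make_field(np.zeros((24, 4, 4)))
        with pytest.raises(ValueError, match="congruent"):
            er.field_correlation_map(f1, f2)
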