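import numpy as np
import pytest
from scipy import stats

from ihcmorph import (
    CellRecord,
    build_maps,
    compare_groups,
    make_perinuclear_rings,
    measure_cells,
    segment_nuclei,
    summarize,
)
def _pair_from_disks():
    from _oracles import disk_mask

    nuclei = (
        disk_mask((100, 100), (30, 30), 9).astype(np.int32)
        + 2 * disk_mask((100, 100), (70, 68), 11).astype(np.int32)
    )
    return make_perinuclear_rings(nuclei, 7)


def _fake_record(label, area, mean, ring=50):
    return CellRecord(
        label=label,
        area_px=area,
        centroid=(0.0, 0.0),
        ring_pixels=ring,
        perinuclear_mean=mean,
        perinuclear_integrated=(mean or 0.0) * ring,
        border_flag=False,
    )


class TestMeasureCells:
    def test_constant_signal_exact_mean(self):
        pair = _pair_from_disks()
        records = measure_cells(pair, np.full(pair.nuclei.shape, 0.4))
        assert len(records) == 2
        for r in records:
            assert r.perinuclear_mean == pytest.approx(0.4)
            assert r.perinuclear_integrated == pytest.approx(0.4 * r.ring_pixels)

    def test_area_conservation(self):
        pair = _pair_from_disks()
        records = measure_cells(pair, np.zeros(pair.nuclei.shape))
        assert sum(r.area_px for r in records) == int((pair.nuclei > 0).sum())

    def test_labels_sorted_and_centroids(self):
        pair = _pair_from_disks()
        records = measure_cells(pair, np.zeros(pair.nuclei.shape))
        assert [r.label for r in records] == [1, 2]
        assert records[0].centroid == pytest.approx((30, 30), abs=0.5)
        assert records[1].centroid == pytest.approx((70, 68), abs=0.5)

    def test_enclosed_nucleus_kept_with_undefined_signal(self):
        # nucleus 2 is a core fully surrounded by nucleus 1: no ring pixels
        nuclei = np.zeros((40, 40), dtype=np.int32)
        nuclei[5:25, 5:25] = 1
        nuclei[12:18, 12:18] = 2
        pair = make_perinuclear_rings(nuclei, 7)
        records = measure_cells(pair, np.full((40, 40), 0.3))
        by_label = {r.label: r for r in records}
        assert by_label[2].ring_pixels == 0
        assert by_label[2].perinuclear_mean is None
        assert by_label[2].area_px == 36

    def test_signal_shift_property(self):
        pair = _pair_from_disks()
        rng = np.random.default_rng(1)
        sig = rng.uniform(0.1, 0.5, pair.nuclei.shape)
        base = measure_cells(pair, sig)
        shifted = measure_cells(pair, sig + 0.2)
        for a, b in zip(base, shifted):
            assert b.perinuclear_mean - a.perinuclear_mean == pytest.approx(0.2)

    def test_relabel_invariance(self):
        pair = _pair_from_disks()
        rng = np.random.default_rng(2)
        sig = rng.uniform(0, 1, pair.nuclei.shape)
        base = {r.label: r for r in measure_cells(pair, sig)}
        swapped = np.select(
            [pair.nuclei == 1, pair.nuclei == 2], [2, 1], pair.nuclei
        ).astype(np.int32)
        perm = make_perinuclear_rings(swapped, 7)
        out = {r.label: r for r in measure_cells(perm, sig)}
        assert out[2].perinuclear_mean == pytest.approx(base[1].perinuclear_mean)
        assert out[1].perinuclear_mean == pytest.approx(base[2].perinuclear_mean)

    def test_pixel_size_conversion(self):
        pair = _pair_from_disks()
        records = measure_cells(pair, np.zeros(pair.nuclei.shape), pixel_size_um=0.5)
        for r in records:
            assert r.area_um2 == pytest.approx(r.area_px * 0.25)

    def test_shape_mismatch(self):
        pair = _pair_from_disks()
        with pytest.raises(ValueError, match="shape"):
            measure_cells(pair, np.zeros((5, 5)))

    def test_intensity_tracks_ground_truth(self, small_scene, default_config):
        _, image, truth = small_scene
        maps = build_maps(image, default_config)
        labels = segment_nuclei(maps, default_config)
        pair = make_perinuclear_rings(labels, default_config.ring_width_px)
        records = measure_cells(pair, maps.signal_map)
        from scipy.spatial import cKDTree

        tree = cKDTree(truth.centers)
        meas, true = [], []
        for r in records:
            d, i = tree.query(r.centroid)
            if d < 5 and r.perinuclear_mean is not None:
                meas.append(r.perinuclear_mean)
                true.append(truth.dab_conc[i])
        assert len(meas) >= 15
        rho = stats.spearmanr(meas, true).statistic
        assert rho >= 0.9


class TestSummarize:
    def test_single_record_sem_undefined(self):
        s = summarize([_fake_record(1, 100, 0.2)])
        assert s.mean_area == 100
        assert s.sem_area is None

    def test_zero_variance(self):
        s = summarize([_fake_record(i, 100, 0.2) for i in range(1, 6)])
        assert s.mean_area == 100
        assert s.sem_area == 0.0

    def test_sampling_distribution_of_mean(self):
        rng = np.random.default_rng(12)
        areas = rng.normal(200, 20, 1000)
        recs = [
            _fake_record(i + 1, int(round(a)), 0.1) for i, a in enumerate(areas)
        ]
        s = summarize(recs)
        assert abs(s.mean_area - 200) < 3 * s.sem_area + 0.5
        assert s.area_histogram[1].sum() == 1000

    def test_undefined_signal_excluded_but_counted(self):
        recs = [_fake_record(1, 100, 0.4), _fake_record(2, 90, None, ring=0)]
        s = summarize(recs)
        assert s.n == 2
        assert s.n_signal_excluded == 1
        assert s.mean_signal == pytest.approx(0.4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])


class TestCompareGroups:
    def _group(self, rng, mu, sd, n):
        return [
            _fake_record(i + 1, int(round(a)), float(rng.uniform(0, 1)))
            for i, a in enumerate(rng.normal(mu, sd, n))
        ]

    def test_identical_groups_p_half(self):
        rng = np.random.default_rng(3)
        g = self._group(rng, 100, 10, 30)
        t, p = compare_groups(g, list(g), "area", "greater")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_separated_groups_match_closed_form(self):
        rng = np.random.default_rng(4)
        a = self._group(rng, 200, 10, 50)
        b = self._group(rng, 100, 10, 50)
        t, p = compare_groups(a, b, "area", "greater")
        assert p < 1e-3
        # independent pooled-t computation from first principles
        xa = np.array([r.area_px for r in a], float)
        xb = np.array([r.area_px for r in b], float)
        na, nb = len(xa), len(xb)
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
        t_ref = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_ref = stats.t.sf(t_ref, na + nb - 2)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_swap_with_mirrored_alternative(self):
        rng = np.random.default_rng(5)
        a = self._group(rng, 120, 15, 40)
        b = self._group(rng, 100, 15, 40)
        _, p1 = compare_groups(a, b, "area", "greater")
        _, p2 = compare_groups(b, a, "area", "less")
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(6)
        a = self._group(rng, 100, 10, 1)
        b = self._group(rng, 100, 10, 10)
        with pytest.raises(ValueError, match="n >= 2"):
            compare_groups(a, b)

    def test_signal_variable_and_welch(self):
        rng = np.random.default_rng(7)
        a = self._group(rng, 100, 10, 30)
        b = self._group(rng, 100, 10, 30)
        t, p = compare_groups(a, b, "signal", "greater", welch=True)
        assert 0.0 < p < 1.0
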