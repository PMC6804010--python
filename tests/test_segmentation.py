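"""IsoData thresholding, particle analysis, coverage and co-location."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from surfionomics.datasets import load_ion_particle_table
from surfionomics.exceptions import DegenerateImageError, EmptySitesError
from surfionomics.imgio import ChemImage
from surfionomics.segmentation import (
    BinaryMap,
    ParticleStats,
    binarize,
    colocated_site_fraction,
    coverage_fraction,
    free_fraction,
    isodata_binarize,
    isodata_threshold,
    label_particles,
)
from surfionomics.synthetic import ImageRecipe, gen_ion_map


def round_half_down(x):
    return int(np.ceil(x - 0.5))


def intermeans_fixed_points(img):
    """All fixed points of the rounded intermeans map (oracle)."""
    hist = np.bincount(np.asarray(img).ravel(), minlength=256).astype(float)
    levels = np.arange(256.0)
    occ = np.nonzero(hist)[0]
    lo, hi = occ[0], occ[-1]
    cs, cm = np.cumsum(hist), np.cumsum(hist * levels)
    total, moment = cs[-1], cm[-1]
    out = []
    for t in range(lo, hi):
        m_low = cm[t] / cs[t]
        m_high = (moment - cm[t]) / (total - cs[t])
        if t == round_half_down((m_low + m_high) / 2.0):
            out.append(t)
    return out


class TestIsodata:
    def test_two_spike_histogram(self):
        img = np.zeros((10, 10), np.uint8)
        img[:5] = 50
        img[5:] = 200
        assert isodata_threshold(img) == 125

    def test_extreme_levels(self):
        img = np.zeros((10, 10), np.uint8)
        img[:5] = 255
        # brute-force scan of candidate fixed points gives 127
        assert intermeans_fixed_points(img) == [127]
        assert isodata_threshold(img) == 127

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            isodata_threshold(np.full((8, 8), 7, np.uint8))

    @given(st.integers(0, 2**31 - 1))
    def test_fixed_point_property(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        t = isodata_threshold(img)
        assert t in intermeans_fixed_points(img)

    def test_equals_smallest_fixed_point_on_random_images(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            if rng.random() < 0.5:
                img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            else:
                img = np.clip(
                    rng.normal(rng.uniform(60, 180), rng.uniform(10, 60), (64, 64)), 0, 255
                ).astype(np.uint8)
            assert isodata_threshold(img) == intermeans_fixed_points(img)[0]


class TestBinarize:
    def test_threshold_extremes(self, rng):
        img = ChemImage(rng.integers(1, 255, (16, 16), dtype=np.uint8), 0.5)
        assert not binarize(img, 255).mask.any()
        assert binarize(img, 0).mask.all()

    def test_foreground_is_strictly_greater(self):
        img = ChemImage(np.array([[10, 11]], np.uint8), 1.0)
        assert list(binarize(img, 10).mask[0]) == [False, True]

    def test_planted_disc_area_within_5pct(self):
        recipe = ImageRecipe(
            field_size_um=50, n_aggregates=6, noise_sd=0.0,
            aggregate_radius_um=(2.0, 0.3), seed=7,
        )
        img, truth = gen_ion_map(recipe)
        bm = isodata_binarize(img)
        planted = float(np.pi * (truth.radius_um**2).sum())
        assert bm.foreground_area_um2 == pytest.approx(planted, rel=0.05)

    def test_mask_shape_must_match(self, rng):
        img = ChemImage(rng.integers(0, 256, (8, 8), dtype=np.uint8), 0.5)
        with pytest.raises(ValueError):
            BinaryMap(np.zeros((4, 4), bool), 10, img)


class TestLabelParticles:
    def test_empty_mask(self, rng):
        img = ChemImage(rng.integers(0, 200, (16, 16), dtype=np.uint8), 0.5)
        stats = label_particles(binarize(img, 255))
        assert stats.count == 0 and stats.total_area_um2 == 0.0

    def test_planted_discs_counted(self):
        recipe = ImageRecipe(
            field_size_um=50, n_aggregates=5, noise_sd=0.0,
            aggregate_radius_um=(2.0, 0.3), seed=1,
        )
        img, truth = gen_ion_map(recipe)
        stats = label_particles(isodata_binarize(img))
        assert stats.count == len(truth) == 5
        assert stats.mean_size_um2 == pytest.approx(stats.total_area_um2 / 5)

    def test_min_size_filter(self):
        mask = np.zeros((20, 20), bool)
        mask[2, 2] = True  # 1 px = 0.25 um^2
        mask[10:14, 10:14] = True  # 16 px = 4 um^2
        img = ChemImage(np.where(mask, 200, 0).astype(np.uint8), 0.5)
        bm = binarize(img, 100)
        assert label_particles(bm).count == 2
        assert label_particles(bm, min_size_um2=1.0).count == 1

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParticleStats(count=1, total_area_um2=0.0, mean_size_um2=0.0, mean_intensity=0.0)

    def test_count_invariant_to_rotation_and_translation(self, rng):
        base = np.zeros((40, 40), np.uint8)
        for r, c in [(5, 5), (20, 11), (30, 28)]:
            base[r : r + 3, c : c + 3] = 200
        img = ChemImage(base, 0.5)
        n0 = label_particles(binarize(img, 100)).count
        rot = ChemImage(np.rot90(base).copy(), 0.5)
        shifted = ChemImage(np.roll(base, (3, 4), axis=(0, 1)), 0.5)
        assert label_particles(binarize(rot, 100)).count == n0
        assert label_particles(binarize(shifted, 100)).count == n0

    def test_reference_table_row_mean_size(self):
        # 23 aggregates totalling 374.151 um^2 average 16.267 um^2
        table = load_ion_particle_table()
        row = table[(table.ion == "Na") & (table.treatment == "NaOH")].iloc[0]
        assert row["count"] == 23
        assert row.area_um2 / row["count"] == pytest.approx(row.average_size_um2, abs=5e-4)


def _pair(mask_ion, mask_sites, px=0.5):
    src = ChemImage(np.zeros(mask_ion.shape, np.uint8), px)
    return (
        BinaryMap(mask_ion, 128, src),
        BinaryMap(mask_sites, 128, src),
    )


class TestCoverage:
    def test_superset_and_disjoint(self):
        sites = np.zeros((10, 10), bool)
        sites[2:5, 2:5] = True
        ion_all = np.ones((10, 10), bool)
        ion_none = np.zeros((10, 10), bool)
        ion_none[8, 8] = True
        bi, bs = _pair(ion_all, sites)
        assert coverage_fraction(bi, bs) == 100.0
        bi, bs = _pair(ion_none, sites)
        assert coverage_fraction(bi, bs) == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_complement_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        ion = rng.random((12, 12)) < 0.4
        sites = rng.random((12, 12)) < 0.5
        if not sites.any():
            sites[0, 0] = True
        bi, bs = _pair(ion, sites)
        assert coverage_fraction(bi, bs) + free_fraction(bi, bs) == 100.0

    def test_empty_sites_error(self):
        bi, bs = _pair(np.ones((4, 4), bool), np.zeros((4, 4), bool))
        with pytest.raises(EmptySitesError):
            coverage_fraction(bi, bs)


class TestColocatedSites:
    def _four_blobs(self):
        sites = np.zeros((20, 20), bool)
        for r, c in [(2, 2), (2, 12), (12, 2), (12, 12)]:
            sites[r : r + 3, c : c + 3] = True
        return sites

    def test_all_and_none(self):
        sites = self._four_blobs()
        bi, bs = _pair(sites.copy(), sites)
        assert colocated_site_fraction(bi, bs) == 100.0
        bi, bs = _pair(np.zeros_like(sites), sites)
        assert colocated_site_fraction(bi, bs) == 0.0

    def test_half_overlapped(self):
        sites = self._four_blobs()
        ion = np.zeros_like(sites)
        ion[2, 2] = True  # touches blob 1
        ion[13, 13] = True  # touches blob 4
        bi, bs = _pair(ion, sites)
        assert colocated_site_fraction(bi, bs) == 50.0

    def test_no_sites_error(self):
        bi, bs = _pair(np.ones((4, 4), bool), np.zeros((4, 4), bool))
        with pytest.raises(EmptySitesError):
            colocated_site_fraction(bi, bs)
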