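"""Seed segmentation, void extraction, and the exclusion rules."""

import numpy as np
import pytest

import charvoid as cv
from charvoid.errors import NoSeedFound
from charvoid.segment import HoleComponent, _principal_semi_axes

from conftest import flood_fill_labels, paint_ellipsoid


class TestSegmentSeed:
    def test_solid_ellipsoid_envelope_volume(self, solid_ellipsoid_volume):
        mask = cv.segment_seed(solid_ellipsoid_volume, threshold=0.5)
        analytic_vox = 4 / 3 * np.pi * 40 * 30 * 30
        env_vox = mask.envelope.sum()
        assert env_vox == pytest.approx(analytic_vox, rel=0.02)
        assert mask.envelope_volume >= mask.material_volume > 0

    def test_otsu_equivalent_on_bimodal_volume(self, solid_ellipsoid_volume):
        m_val = cv.segment_seed(solid_ellipsoid_volume, threshold=0.5)
        m_otsu = cv.segment_seed(solid_ellipsoid_volume, threshold="otsu")
        assert np.array_equal(m_val.material, m_otsu.material)

    def test_two_blobs_keeps_larger(self):
        data = np.zeros((40, 40, 40), dtype=np.float32)
        paint_ellipsoid(data, (12, 12, 12), (8, 8, 8), 1.0)
        paint_ellipsoid(data, (30, 30, 30), (4, 4, 4), 1.0)
        mask = cv.segment_seed(cv.Volume(data, 50.0), threshold=0.5)
        assert mask.material[12, 12, 12]
        assert not mask.material[30, 30, 30]

    def test_all_zero_volume_raises(self):
        with pytest.raises(NoSeedFound):
            cv.segment_seed(cv.Volume(np.zeros((10, 10, 10)), 50.0))

    def test_envelope_single_connected_component(self, spheroid_seed_volume):
        vol, _ = spheroid_seed_volume
        mask = cv.segment_seed(vol, threshold=0.5)
        labels, n = flood_fill_labels(mask.envelope, connectivity=26)
        assert n == 1


class TestExtractVoids:
    def test_twelve_spheroids_recovered_with_volumes(self, spheroid_seed_volume):
        vol, voids = spheroid_seed_volume
        mask = cv.segment_seed(vol, threshold=0.5)
        comps = cv.extract_void_components(mask)
        assert len(comps) == 12
        comps_sorted = sorted(comps, key=lambda c: tuple(c.centroid))
        truth_sorted = sorted(voids, key=lambda v: v[0])
        for comp, (center, axes) in zip(comps_sorted, truth_sorted):
            analytic_vox = 4 / 3 * np.pi * np.prod(axes)
            assert comp.voxel_count == pytest.approx(analytic_vox, rel=0.10)
            assert np.allclose(comp.centroid, center, atol=0.5)
            assert not comp.touches_exterior

    def test_solid_seed_has_no_voids(self, solid_ellipsoid_volume):
        mask = cv.segment_seed(solid_ellipsoid_volume, threshold=0.5)
        assert cv.extract_void_components(mask) == []

    def test_open_channel_flagged_exterior(self):
        data = np.zeros((48, 48, 48), dtype=np.float32)
        paint_ellipsoid(data, (23.5, 23.5, 23.5), (18, 18, 18), 1.0)
        # narrow channel from the centre cavity out through +x
        paint_ellipsoid(data, (23.5, 23.5, 23.5), (4, 4, 4), 0.0)
        data[22:26, 22:26, 23:] = 0.0
        mask = cv.segment_seed(cv.Volume(data, 50.0), threshold=0.5,
                               closing_radius=3)
        comps = cv.extract_void_components(mask)
        assert len(comps) >= 1
        biggest = max(comps, key=lambda c: c.voxel_count)
        assert biggest.touches_exterior

    def test_volume_conservation(self, spheroid_seed_volume):
        vol, _ = spheroid_seed_volume
        mask = cv.segment_seed(vol, threshold=0.5)
        comps = cv.extract_void_components(mask)
        total = sum(c.volume for c in comps) + mask.material_volume
        assert total == pytest.approx(mask.envelope_volume, abs=1e-12)

    def test_labels_match_brute_force_flood_fill(self):
        # all fixtures <= 32^3: labelling must partition exactly like an
        # independent BFS flood fill (6-connectivity)
        rng = np.random.default_rng(9)
        for trial in range(3):
            data = np.zeros((32, 32, 32), dtype=np.float32)
            paint_ellipsoid(data, (15.5, 15.5, 15.5), (13, 12, 14), 1.0)
            for _ in range(6):
                c = 15.5 + rng.uniform(-7, 7, size=3)
                paint_ellipsoid(data, c, rng.uniform(1.5, 3.0, size=3), 0.0)
            mask = cv.segment_seed(cv.Volume(data, 50.0), threshold=0.5)
            comps, labels = cv.extract_void_components(mask, return_labels=True)
            voids = mask.envelope & ~mask.material
            ref_labels, ref_n = flood_fill_labels(voids, connectivity=6)
            assert len(comps) == ref_n
            # identical partitions: each package label maps to exactly
            # one reference label and vice versa
            pairs = set(zip(labels[voids].ravel(), ref_labels[voids].ravel()))
            assert len(pairs) == ref_n
            assert len({a for a, _ in pairs}) == ref_n
            assert len({b for _, b in pairs}) == ref_n


class TestClassification:
    def mk(self, voxels=100, planarity=0.8, touches=False, volume=1e-4):
        return HoleComponent(
            label=1, voxel_count=voxels, volume=volume,
            centroid=(0, 0, 0), semi_axes_um=(10, 8, 10 * planarity),
            planarity=planarity, touches_exterior=touches,
        )

    def test_tiny_component_is_outlier(self):
        rules = cv.ClassifierRules(n_min=10)
        assert cv.classify_component(self.mk(voxels=2), rules) == "outlier"

    def test_round_component_is_hole(self):
        assert cv.classify_component(self.mk(planarity=0.9)) == "hole"

    def test_planar_component_is_crack(self):
        assert cv.classify_component(self.mk(planarity=0.05)) == "crack"

    def test_huge_component_is_break(self):
        c = self.mk(volume=10.0)
        assert cv.classify_component(c, envelope_volume=25.0) == "break"

    def test_exterior_planar_component_is_break(self):
        c = self.mk(planarity=0.2, touches=True)
        assert cv.classify_component(c) == "break"

    def test_voxelized_plate_planarity(self):
        # plate with semi-axes (20, 20, 1) voxels: moment planarity far
        # below the crack threshold
        data = np.zeros((8, 48, 48), dtype=np.float32)
        paint_ellipsoid(data, (3.5, 23.5, 23.5), (1, 20, 20), 1.0)
        coords = np.argwhere(data > 0).astype(float)
        a, b, c = _principal_semi_axes(coords, 1.0)
        assert c / a < 0.15
        assert a == pytest.approx(20, rel=0.15)

    def test_sphere_planarity_near_one(self):
        data = np.zeros((16, 16, 16), dtype=np.float32)
        paint_ellipsoid(data, (7.5, 7.5, 7.5), (5, 5, 5), 1.0)
        coords = np.argwhere(data > 0).astype(float)
        a, b, c = _principal_semi_axes(coords, 1.0)
        assert c / a > 0.9
        assert a == pytest.approx(5, rel=0.1)


class TestCrackContamination:
    def mk(self, label, klass):
        return HoleComponent(
            label=label, voxel_count=50, volume=1e-5, centroid=(0, 0, 0),
            semi_axes_um=(10, 9, 8), planarity=0.8, touches_exterior=False,
            klass=klass,
        )

    def test_no_cracks_gives_zero(self):
        comps = [self.mk(1, "hole"), self.mk(2, "hole")]
        assert cv.crack_contamination(comps, {}) == 0.0

    def test_all_misclassified_cracks_give_one(self):
        comps = [self.mk(1, "hole"), self.mk(2, "hole")]
        truth = {1: "crack", 2: "crack"}
        assert cv.crack_contamination(comps, truth) == 1.0

    def test_no_retained_holes_is_flagged_null(self):
        comps = [self.mk(1, "crack")]
        assert cv.crack_contamination(comps, {}) is None


class TestPhantomRecovery:
    def test_resolvable_holes_recovered(self):
        # fine-voxel phantom: >= 95% of ground-truth holes that resolve
        # to >= 2*n_min voxels come back classified as holes
        rules = cv.ClassifierRules()
        total = recovered = 0
        for seed in range(3):
            spec = cv.PhantomSpec(
                protein_pct=60.0, oil_pct=5.0,
                semi_axes=(0.6, 0.65, 0.8), voxel_size=10.0, rng_seed=seed,
            )
            vol, truth = cv.generate_seed_phantom(spec)
            mask = cv.segment_seed(vol, threshold=0.5)
            comps, labels = cv.extract_void_components(mask, return_labels=True)
            cv.classify_components(comps, mask, rules)
            by_label = {c.label: c for c in comps}
            matches = cv.match_ground_truth(labels, truth)
            for h in truth.holes_of_class("hole"):
                if h.volume_mm3 / vol.voxel_volume_mm3 < 2 * rules.n_min:
                    continue
                total += 1
                idx = tuple(int(round(x)) for x in h.center_voxel)
                lab = int(labels[idx])
                if lab > 0 and by_label[lab].klass == "hole":
                    recovered += 1
            assert matches  # sanity: ground truth matched something
        assert total >= 20
        assert recovered / total >= 0.95
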