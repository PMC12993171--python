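import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pezmap import (VoxelGrid, build_pez, exclude_fluid, partition_pez,
                    suggest_fluid_threshold)
from pezmap.pez import COMPARTMENTS, DEFAULT_FLUID_THRESHOLD

from conftest import make_mask


def brute_force_rim(core, brain, width):
    """O(N * |core|) Euclidean-distance rim, independent of scipy's EDT."""
    core_pts = np.argwhere(core)
    rim = np.zeros_like(core, dtype=bool)
    for v in np.argwhere(brain):
        if core[tuple(v)]:
            continue
        d2 = ((core_pts - v) ** 2).sum(axis=1).min()
        if d2 <= width * width:
            rim[tuple(v)] = True
    return rim


class TestBuildPez:
    def test_matches_brute_force_on_irregular_core(self):
        rng = np.random.default_rng(0)
        shape = (24, 24, 24)
        idx = np.indices(shape)
        core = ((idx[0] - 10) ** 2 + (idx[1] - 12) ** 2
                + (idx[2] - 11) ** 2 <= 9)
        core |= ((idx[0] - 15) ** 2 + (idx[1] - 12) ** 2
                 + (idx[2] - 13) ** 2 <= 4)  # two fused blobs
        brain = ((idx[0] - 12) ** 2 + (idx[1] - 12) ** 2
                 + (idx[2] - 12) ** 2 <= 121)
        rim = build_pez(make_mask(core), make_mask(brain), width_voxels=5)
        expected = brute_force_rim(core, brain, 5)
        assert np.array_equal(rim.astype_bool(), expected)

    def test_single_voxel_core_matches_lattice_enumeration(self):
        # oracle: integer lattice points with 0 < x^2+y^2+z^2 <= 25
        count = sum(1 for x in range(-5, 6) for y in range(-5, 6)
                    for z in range(-5, 6)
                    if 0 < x * x + y * y + z * z <= 25)
        core = np.zeros((13, 13, 13))
        core[6, 6, 6] = 1
        rim = build_pez(make_mask(core), make_mask(np.ones((13, 13, 13))),
                        width_voxels=5)
        assert int(rim.data.sum()) == count

    def test_rim_disjoint_from_core_and_inside_brain(self, noisy_case48):
        v = noisy_case48.volumes
        rim = build_pez(v.core_mask, v.brain_mask)
        assert not (rim.astype_bool() & v.core_mask.astype_bool()).any()
        assert (rim.data <= v.brain_mask.data).all()

    def test_core_touching_boundary_is_clipped(self):
        core = np.zeros((10, 10, 10))
        core[0, 0, 0] = 1
        rim = build_pez(make_mask(core), make_mask(np.ones((10, 10, 10))),
                        width_voxels=5)
        # no wraparound: the far corner stays empty
        assert rim.data[9, 9, 9] == 0
        assert rim.data.sum() > 0

    def test_rim_distance_band(self, noisy_case48):
        from scipy.ndimage import distance_transform_edt
        v = noisy_case48.volumes
        rim = build_pez(v.core_mask, v.brain_mask, width_voxels=5)
        d = distance_transform_edt(~v.core_mask.astype_bool())
        assert d[rim.astype_bool()].max() <= 5.0
        assert d[rim.astype_bool()].min() > 0.0

    def test_enlarging_core_never_shrinks_core_plus_rim(self, sphere_mask):
        brain = make_mask(np.ones((24, 24, 24)))
        small = sphere_mask((24, 24, 24), (12, 12, 12), 4)
        big = sphere_mask((24, 24, 24), (12, 12, 12), 6)
        cr_small = (build_pez(small, brain).astype_bool()
                    | small.astype_bool())
        cr_big = build_pez(big, brain).astype_bool() | big.astype_bool()
        assert (cr_small <= cr_big).all()

    def test_empty_core_and_bad_width_rejected(self):
        brain = make_mask(np.ones((8, 8, 8)))
        with pytest.raises(ValueError):
            build_pez(make_mask(np.zeros((8, 8, 8))), brain)
        core = np.zeros((8, 8, 8))
        core[4, 4, 4] = 1
        with pytest.raises(ValueError):
            build_pez(make_mask(core), brain, width_voxels=0)


class TestExcludeFluid:
    def test_all_below_threshold_is_identity(self, sphere_mask):
        pez = sphere_mask((12, 12, 12), (6, 6, 6), 4)
        adc = VoxelGrid(np.full((12, 12, 12), 1000.0))
        cleaned, excluded = exclude_fluid(pez, adc, 2000.0)
        assert np.array_equal(cleaned.data, pez.data)
        assert excluded.data.sum() == 0

    def test_infinite_threshold_is_identity(self, sphere_mask):
        pez = sphere_mask((12, 12, 12), (6, 6, 6), 4)
        adc = VoxelGrid(np.full((12, 12, 12), 5000.0))
        cleaned, _ = exclude_fluid(pez, adc, np.inf)
        assert np.array_equal(cleaned.data, pez.data)

    def test_cleaned_and_excluded_partition_pez(self, noisy_case48):
        v = noisy_case48.volumes
        rim = build_pez(v.core_mask, v.brain_mask)
        cleaned, excluded = exclude_fluid(rim, v.adc, 2000.0)
        union = cleaned.astype_bool() | excluded.astype_bool()
        assert np.array_equal(union, rim.astype_bool())
        assert not (cleaned.astype_bool() & excluded.astype_bool()).any()

    def test_phantom_ventricle_voxels_excluded(self, noise_free_case48):
        # ground truth: the excluded set is exactly rim intersect fluid label
        v = noise_free_case48.volumes
        rim = build_pez(v.core_mask, v.brain_mask)
        _, excluded = exclude_fluid(rim, v.adc, 2000.0)
        truth_fluid = noise_free_case48.truth.class_mask("fluid")
        expected = rim.astype_bool() & truth_fluid
        assert np.array_equal(excluded.astype_bool(), expected)
        assert expected.any()  # the ventricle really abuts the rim


class TestFluidThreshold:
    def test_valley_between_bimodal_modes(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(1100, 120, 4000),
                               rng.normal(3000, 180, 1200)])
        shape = (40, 40, 4)
        adc = VoxelGrid(np.concatenate([vals, np.zeros(1200)]).reshape(shape))
        pez = np.zeros(shape)
        pez.ravel()[:5200] = 1
        thr = suggest_fluid_threshold(adc, make_mask(pez))
        assert 1100 < thr < 3000

    def test_unimodal_returns_default(self):
        rng = np.random.default_rng(2)
        shape = (20, 20, 5)
        adc = VoxelGrid(rng.normal(1000, 120, shape))
        thr = suggest_fluid_threshold(adc, make_mask(np.ones(shape)))
        assert thr == DEFAULT_FLUID_THRESHOLD

    def test_mixture_threshold_separates_components(self):
        # 0.8 N(1000,150^2) + 0.2 N(3000,200^2), n = 50000: the suggested
        # threshold falls between the components and classifies the known
        # component labels with >= 95 % accuracy
        rng = np.random.default_rng(3)
        n = 50_000
        labels = rng.random(n) < 0.2
        vals = np.where(labels, rng.normal(3000, 200, n),
                        rng.normal(1000, 150, n))
        shape = (50, 50, 20)
        adc = VoxelGrid(vals.reshape(shape))
        thr = suggest_fluid_threshold(adc, make_mask(np.ones(shape)))
        assert 1500 <= thr <= 2600
        accuracy = np.mean((vals >= thr) == labels)
        assert accuracy >= 0.95


class TestPartition:
    def test_empty_recurrence_gives_empty_t1pos(self, noisy_case48):
        v = noisy_case48.volumes
        rim = build_pez(v.core_mask, v.brain_mask)
        empty = VoxelGrid(np.zeros(rim.shape, dtype=np.uint8),
                          kind="binary_mask")
        part = partition_pez(rim, v.flair_mask, empty)
        assert part.t1pos_flairpos.data.sum() == 0
        assert part.t1pos_flairneg.data.sum() == 0
        union = (part.t1neg_flairpos.astype_bool()
                 | part.t1neg_flairneg.astype_bool())
        assert np.array_equal(union, rim.astype_bool())

    def test_flair_covering_pez_gives_empty_flairneg(self, sphere_mask):
        pez = sphere_mask((16, 16, 16), (8, 8, 8), 5)
        full = make_mask(np.ones((16, 16, 16)))
        rec = sphere_mask((16, 16, 16), (8, 8, 8), 3)
        part = partition_pez(pez, full, rec)
        assert part.t1pos_flairneg.data.sum() == 0
        assert part.t1neg_flairneg.data.sum() == 0

    def test_phantom_compartments_match_truth_labels(self, noise_free_case48):
        v = noise_free_case48.volumes
        truth = noise_free_case48.truth
        rim = build_pez(v.core_mask, v.brain_mask)
        cleaned, excl = exclude_fluid(rim, v.adc, 2000.0)
        part = partition_pez(cleaned, v.flair_mask, v.recurrence_mask,
                             excluded_fluid=excl)
        expected = {
            "t1pos_flairpos": "flairpos_recurrence",
            "t1neg_flairpos": "flairpos_stable",
            "t1pos_flairneg": "flairneg_recurrence",
            "t1neg_flairneg": "flairneg_stable",
        }
        rim_b = cleaned.astype_bool()
        for comp, cls in expected.items():
            assert np.array_equal(part.compartment(comp).astype_bool(),
                                  rim_b & truth.class_mask(cls))

    def test_grid_mismatch_rejected(self, sphere_mask):
        pez = sphere_mask((8, 8, 8), (4, 4, 4), 2)
        other = make_mask(np.zeros((9, 9, 9)))
        with pytest.raises(ValueError):
            partition_pez(pez, other, other)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 30))
    def test_partition_completeness_property(self, seed):
        # on arbitrary masks the four compartments are disjoint and their
        # union is exactly the PEZ mask
        rng = np.random.default_rng(seed)
        shape = (7, 7, 7)
        pez = make_mask(rng.random(shape) < 0.4)
        flair = make_mask(rng.random(shape) < 0.5)
        rec = make_mask(rng.random(shape) < 0.3)
        part = partition_pez(pez, flair, rec)
        total = sum(part.compartment(c).data.astype(int)
                    for c in COMPARTMENTS)
        assert total.max() <= 1
        assert np.array_equal(total > 0, pez.astype_bool())
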