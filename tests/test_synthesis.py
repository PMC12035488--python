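"""Metabolite-map synthesis: table values, compartment fidelity, pairing."""

import numpy as np
import pytest

from mrsisr.phantom import Grade, TissueSegmentation, TumorMask
from mrsisr.synthesis import (
    ConcentrationTable,
    MapType,
    MetaboliteMap,
    build_dataset,
    downsample,
    estimated_concentration,
    grade_threshold,
    normalize_map,
    synthesize_map,
    tumor_value,
)

TABLE = ConcentrationTable()

# literature ranges and their printed point estimates (all nine metabolite cells)
METABOLITE_CELLS = [
    (MapType.tCr, "GM", 6.4, 9.7, 8.05),
    (MapType.tCr, "WM", 5.2, 5.7, 5.45),
    (MapType.tCr, "Tumor", 2.5, 6.0, 4.25),
    (MapType.tCho, "GM", 1.6, 2.0, 1.8),
    (MapType.tCho, "WM", 1.3, 1.6, 1.45),
    (MapType.tCho, "Tumor", 2.5, 5.5, 4.00),
    (MapType.NAA, "GM", 8.0, 11.0, 9.5),
    (MapType.NAA, "WM", 6.0, 9.0, 7.5),
    (MapType.NAA, "Tumor", 1.5, 3.5, 2.50),
]


@pytest.mark.parametrize("map_type,compartment,lo,hi,estimate", METABOLITE_CELLS)
def test_metabolite_estimates_are_range_midpoints(map_type, compartment, lo, hi, estimate):
    assert estimated_concentration(lo, hi) == pytest.approx(estimate)
    entry = (TABLE.metabolites[map_type][compartment])
    assert (entry.lo, entry.hi) == (lo, hi)
    assert entry.estimate == pytest.approx(estimate)


def test_estimated_concentration_degenerate_and_invalid():
    assert estimated_concentration(3.3, 3.3) == 3.3
    with pytest.raises(ValueError):
        estimated_concentration(2.0, 1.0)


@pytest.mark.parametrize("map_type,lo,hi,thr", [
    (MapType.tCho_over_NAA, 0.7, 4.0, 2.35),
    (MapType.tCho_over_tCr, 0.5, 3.0, 1.75),
])
def test_grade_thresholds(map_type, lo, hi, thr):
    assert grade_threshold(lo, hi) == pytest.approx(thr)
    entry = TABLE.tumor_ratios[map_type]
    assert (entry.lo, entry.hi, entry.estimate) == (lo, hi, thr)


def test_grade_threshold_degenerate():
    assert grade_threshold(1.0, 1.0) == 1.0


def test_printed_nontumor_ratio_estimates():
    # the printed estimates, not all of which are range midpoints
    nt = TABLE.nontumor_ratios
    assert nt[MapType.tCho_over_NAA]["GM"].estimate == 0.20
    assert nt[MapType.tCho_over_NAA]["WM"].estimate == 0.22
    assert nt[MapType.tCho_over_tCr]["GM"].estimate == 0.80
    assert nt[MapType.tCho_over_tCr]["WM"].estimate == 0.50


class TestTumorValue:
    def test_ratio_grade_subranges_deterministic(self):
        # HGG sub-range [2.35, 4.0] midpoint
        v = tumor_value(TABLE, MapType.tCho_over_NAA, Grade.HGG)
        assert v == pytest.approx((2.35 + 4.0) / 2)  # 3.175
        v = tumor_value(TABLE, MapType.tCho_over_NAA, Grade.LGG)
        assert v == pytest.approx((0.7 + 2.35) / 2)

    def test_metabolite_deterministic_is_table_estimate(self):
        for grade in Grade:
            assert tumor_value(TABLE, MapType.tCho, grade) == 4.00

    def test_sampled_is_seeded_and_in_range(self):
        a = tumor_value(TABLE, MapType.tCho_over_tCr, Grade.LGG, "sampled", seed=7)
        b = tumor_value(TABLE, MapType.tCho_over_tCr, Grade.LGG, "sampled", seed=7)
        assert a == b
        assert 0.5 <= a <= 1.75  # LGG sub-range of [0.5, 3.0]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            tumor_value(TABLE, MapType.tCho, Grade.HGG, mode="other")


def _pure_pixel_fixture():
    """8x8 segmentation with one pure-GM, pure-WM, pure-CSF and tumor pixel."""
    z = np.zeros((8, 8))
    gm, wm, csf = z.copy(), z.copy(), z.copy()
    gm[1, 1] = 1.0
    wm[2, 2] = 1.0
    csf[3, 3] = 1.0
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[4, 4] = 1
    seg = TissueSegmentation(gm=gm, wm=wm, csf=csf, subject_id="fix", slice_index=0)
    return seg, TumorMask(mask=mask, grade=Grade.HGG)


def test_compartment_fidelity_all_map_types():
    """A pixel fully inside one compartment carries exactly its table value."""
    seg, tumor = _pure_pixel_fixture()
    for map_type in MapType:
        m = synthesize_map(seg, tumor, TABLE, map_type)
        assert m.values[1, 1] == pytest.approx(TABLE.tissue_entry(map_type, "GM").estimate)
        assert m.values[2, 2] == pytest.approx(TABLE.tissue_entry(map_type, "WM").estimate)
        assert m.values[3, 3] == 0.0
        assert m.values[4, 4] == pytest.approx(
            tumor_value(TABLE, map_type, Grade.HGG))
        assert m.values.min() >= 0


def test_tumor_overrides_tissue_by_default():
    seg, tumor = _pure_pixel_fixture()
    seg.gm[4, 4] = 1.0  # tissue under the tumor mask
    m = synthesize_map(seg, tumor, TABLE, MapType.NAA)
    assert m.values[4, 4] == pytest.approx(2.50)
    m_add = synthesize_map(seg, tumor, TABLE, MapType.NAA, tumor_additive=True)
    assert m_add.values[4, 4] == pytest.approx(9.5 + 2.50)


def test_shape_mismatch_rejected():
    seg, _ = _pure_pixel_fixture()
    bad = TumorMask(mask=np.zeros((4, 4), dtype=np.uint8), grade=Grade.LGG)
    with pytest.raises(ValueError):
        synthesize_map(seg, bad, TABLE, MapType.tCho)


class TestNormalize:
    def test_scales_to_unit_max(self):
        m = MetaboliteMap(values=np.array([[0.0, 2.0], [4.0, 4.0]]),
                          map_type=MapType.tCho)
        n = normalize_map(m)
        np.testing.assert_allclose(n.values, [[0, 0.5], [1, 1]])
        assert n.normalized

    def test_all_zero_unchanged(self):
        m = MetaboliteMap(values=np.zeros((4, 4)), map_type=MapType.NAA)
        n = normalize_map(m)
        assert n.normalized and n.values.sum() == 0

    def test_idempotent(self):
        m = MetaboliteMap(values=np.random.default_rng(0).random((8, 8)),
                          map_type=MapType.tCr)
        once = normalize_map(m)
        twice = normalize_map(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_negative_rejected(self):
        m = MetaboliteMap(values=np.array([[-1.0, 1.0], [0.0, 0.0]]),
                          map_type=MapType.tCho)
        with pytest.raises(ValueError):
            normalize_map(m)


class TestDownsample:
    def test_block_mean_example(self):
        vals = np.array([[1, 1, 1, 1], [1, 1, 1, 1], [3, 3, 3, 3], [3, 3, 3, 3]],
                        dtype=float)
        m = MetaboliteMap(values=vals, map_type=MapType.tCho)
        lo = downsample(m, factor=4)
        assert lo.values.shape == (1, 1)
        assert lo.values[0, 0] == pytest.approx(2.0)

    def test_constant_preserved_and_mean_conserved(self, rng):
        vals = rng.random((128, 128))
        m = MetaboliteMap(values=vals, map_type=MapType.NAA)
        lo = downsample(m)
        assert lo.values.shape == (32, 32)
        assert lo.values.mean() == pytest.approx(vals.mean(), abs=1e-12)
        const = downsample(MetaboliteMap(values=np.full((8, 8), 0.7),
                                         map_type=MapType.NAA), 4)
        np.testing.assert_allclose(const.values, 0.7)

    def test_voxel_geometry(self):
        m = MetaboliteMap(values=np.zeros((128, 128)), map_type=MapType.tCho,
                          fov_mm=220.0)
        assert m.voxel_edge_mm == pytest.approx(1.71875)
        assert downsample(m).voxel_edge_mm == pytest.approx(6.875)

    def test_indivisible_rejected(self):
        m = MetaboliteMap(values=np.zeros((10, 10)), map_type=MapType.tCho)
        with pytest.raises(ValueError):
            downsample(m, factor=4)


class TestBuildDataset:
    def test_five_examples_per_selected_slice(self, small_cohort):
        ds = build_dataset(small_cohort, mode="deterministic", seed=0)
        # 2 subjects x 3 eligible slices x 5 map types
        assert len(ds) == 30
        ex = ds[0]
        assert ex.lr_input.shape == (2, 32, 32)
        assert ex.hr_target.shape == (1, 128, 128)
        assert 0.0 <= ex.lr_input.min() and ex.lr_input.max() <= 1.0
        assert ex.hr_target.max() == pytest.approx(1.0)

    def test_deterministic_manifest(self, small_cohort):
        a = build_dataset(small_cohort, mode="sampled", seed=5)
        b = build_dataset(small_cohort, mode="sampled", seed=5)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.lr_input, eb.lr_input)
            np.testing.assert_array_equal(ea.hr_target, eb.hr_target)

    def test_lr_channel_is_block_average_of_hr(self, small_cohort):
        ds = build_dataset(small_cohort, mode="deterministic", seed=0)
        ex = ds[7]
        hr = ex.hr_target[0]
        lr = hr.reshape(32, 4, 32, 4).mean(axis=(1, 3))
        np.testing.assert_allclose(ex.lr_input[0], lr, atol=1e-6)

    def test_empty_cohort_warns(self):
        with pytest.warns(UserWarning):
            assert build_dataset([]) == []
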