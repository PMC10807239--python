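import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from icscore3d import scoring
from icscore3d.scoring import (
    LayerMasks,
    categorize,
    layer_ic_score,
    merge_tumor_area,
    pdl1_positive_ic,
    split_immune,
)


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (10.0, "positive"),
            (1.0, "positive"),  # closed lower bound at 1%
            (0.5, "borderline"),
            (0.0, "negative"),
            (100.0, "positive"),
            (0.999, "borderline"),
        ],
    )
    def test_boundaries(self, score, expected):
        assert categorize(score) == expected

    @pytest.mark.parametrize("bad", [-0.1, 100.5, float("nan"), float("inf")])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            categorize(bad)

    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_total_deterministic_partition(self, score):
        cat = categorize(score)
        assert cat in scoring.CATEGORIES
        assert cat == categorize(score)
        if score >= 1:
            assert cat == "positive"
        elif score == 0:
            assert cat == "negative"
        else:
            assert cat == "borderline"


def _oracle_close_fill(mask, radius, max_hole):
    """Independent closing + hole-fill using Euclidean distance transforms."""
    pad = radius + 2
    padded = np.pad(mask, pad)
    dilated = ndi.distance_transform_edt(~padded) <= radius
    closed = ndi.distance_transform_edt(dilated) > radius
    closed = closed[pad:-pad, pad:-pad] | mask
    labels, n = ndi.label(~closed)
    out = closed.copy()
    border_ids = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    for i in range(1, n + 1):
        hole = labels == i
        if i not in border_ids and hole.sum() <= max_hole:
            out |= hole
    return out


class TestMergeTumorArea:
    def test_donut_hole_filled(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[:64, :64]
        dist = np.hypot(yy - 32, xx - 32)
        mask[(dist <= 20) & (dist > 12)] = True
        merged = merge_tumor_area(mask, closing_radius_px=3, min_hole_px=1000)
        assert merged[dist <= 20].all()

    def test_empty_mask(self):
        out = merge_tumor_area(np.zeros((32, 32), dtype=bool))
        assert not out.any()

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            merge_tumor_area(np.zeros((8, 8), dtype=bool), closing_radius_px=-1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        gen = np.random.default_rng(seed)
        mask = ndi.binary_dilation(gen.random((64, 64)) > 0.97, iterations=2)
        got = merge_tumor_area(mask, closing_radius_px=4, min_hole_px=50)
        want = _oracle_close_fill(mask, 4, 50)
        np.testing.assert_array_equal(got, want)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_and_idempotent(self, seed):
        gen = np.random.default_rng(100 + seed)
        mask = gen.random((48, 48)) > 0.9
        merged = merge_tumor_area(mask, 5, 200)
        assert (mask & ~merged).sum() == 0  # input subset of output
        again = merge_tumor_area(merged, 5, 200)
        np.testing.assert_array_equal(merged, again)


class TestSplitImmune:
    def test_fully_inside(self):
        tumor = np.ones((10, 10), dtype=bool)
        immune = np.zeros((10, 10), dtype=bool)
        immune[2:4, 2:4] = True
        inside, outside = split_immune(immune, tumor)
        assert inside.sum() == 4 and outside.sum() == 0

    def test_disjoint(self):
        tumor = np.zeros((10, 10), dtype=bool)
        tumor[:5] = True
        immune = np.zeros((10, 10), dtype=bool)
        immune[7:, :] = True
        inside, outside = split_immune(immune, tumor)
        assert inside.sum() == 0 and outside.sum() == immune.sum()

    def test_checkerboard_counts_match_bruteforce(self, rng):
        immune = rng.random((16, 16)) > 0.5
        tumor = np.indices((16, 16)).sum(axis=0) % 2 == 0
        inside, outside = split_immune(immune, tumor)
        n_in = sum(
            immune[y, x] and tumor[y, x] for y in range(16) for x in range(16)
        )
        n_out = sum(
            immune[y, x] and not tumor[y, x] for y in range(16) for x in range(16)
        )
        assert inside.sum() == n_in and outside.sum() == n_out
        np.testing.assert_array_equal(inside | outside, immune)
        assert not (inside & outside).any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            split_immune(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestPdl1PositiveIc:
    def test_all_zero_marker(self):
        mask = np.ones((8, 8), dtype=bool)
        out = pdl1_positive_ic(np.zeros((8, 8)), mask)
        assert not out.any()

    def test_bright_marker_in_immune(self):
        marker = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:10, 5:10] = True
        marker[mask] = 200.0
        out = pdl1_positive_ic(marker, mask)
        np.testing.assert_array_equal(out, mask)

    def test_marker_outside_immune_not_counted(self):
        marker = np.zeros((20, 20))
        marker[0:3, 0:3] = 250.0  # tumor-cell marker signal: ignored
        mask = np.zeros((20, 20), dtype=bool)
        mask[10:14, 10:14] = True
        out = pdl1_positive_ic(marker, mask)
        assert not out.any()

    def test_fixed_threshold(self):
        marker = np.arange(16, dtype=float).reshape(4, 4)
        mask = np.ones((4, 4), dtype=bool)
        out = pdl1_positive_ic(marker, mask, intensity_threshold=8.0)
        assert out.sum() == 8

    def test_non_finite_threshold(self):
        with pytest.raises(ValueError):
            pdl1_positive_ic(
                np.ones((4, 4)), np.ones((4, 4), bool), intensity_threshold=np.nan
            )

    def test_cell_level_propagation(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True  # cell A, one bright pixel
        mask[6:9, 6:9] = True  # cell B, dark
        marker = np.zeros((10, 10))
        marker[2, 2] = 100.0
        out = pdl1_positive_ic(marker, mask, intensity_threshold=50.0, cell_level=True)
        assert out[1:4, 1:4].all() and not out[6:9, 6:9].any()

    def test_noise_only_yields_no_positives(self, rng):
        # Otsu alone would split the noise histogram; the background floor
        # must reject a marker-free layer
        marker = np.clip(rng.normal(0, 2.0, (64, 64)), 0, None)
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:30, 10:30] = True
        out = pdl1_positive_ic(marker, mask)
        assert not out.any()


def _layer_masks(tumor_px, pdl1_px, shape=(120, 120)):
    tumor = np.zeros(shape, dtype=bool)
    tumor.ravel()[:tumor_px] = True
    immune = np.zeros(shape, dtype=bool)
    immune.ravel()[:pdl1_px] = True
    return LayerMasks(
        z_index=0,
        tumor_cell_mask=tumor,
        tumor_area_mask=tumor,
        immune_mask=immune,
        pdl1_pos_ic_mask=immune & tumor,
    )


class TestLayerIcScore:
    def test_basic_arithmetic(self):
        score = layer_ic_score(_layer_masks(10000, 100), z_spacing_um=1.4)
        assert score.ic_score_pct == pytest.approx(1.0)
        assert score.category == "positive"

    def test_zero_positive_area(self):
        score = layer_ic_score(_layer_masks(10000, 0), z_spacing_um=1.4)
        assert score.ic_score_pct == 0.0
        assert score.category == "negative"

    def test_no_tumor_layer_is_not_zero(self):
        score = layer_ic_score(_layer_masks(0, 0), z_spacing_um=1.4)
        assert score.no_tumor
        assert score.ic_score_pct is None and score.category is None

    def test_depth(self):
        masks = _layer_masks(100, 0)
        masks.z_index = 3
        assert layer_ic_score(masks, z_spacing_um=1.4).depth_um == pytest.approx(4.2)

    def test_dcis_exclusion_direction(self):
        # 10000 px tumor, half DCIS; 100 positive px entirely in the invasive
        # half: exclusion doubles the score
        shape = (100, 200)
        tumor = np.ones(shape, dtype=bool)
        dcis = np.zeros(shape, dtype=bool)
        dcis[:, 100:] = True
        immune = np.zeros(shape, dtype=bool)
        immune[:10, :10] = True
        masks = LayerMasks(
            z_index=0,
            tumor_cell_mask=tumor,
            tumor_area_mask=tumor,
            immune_mask=immune,
            pdl1_pos_ic_mask=immune,
        )
        off = layer_ic_score(masks, 1.4, dcis_mask=dcis, exclude_dcis=False)
        on = layer_ic_score(masks, 1.4, dcis_mask=dcis, exclude_dcis=True)
        assert off.ic_score_pct == pytest.approx(0.5)
        assert on.ic_score_pct == pytest.approx(1.0)
        assert on.ic_score_pct > off.ic_score_pct

    @given(
        tumor_px=st.integers(min_value=1, max_value=14400),
        pdl1_px=st.integers(min_value=0, max_value=14400),
    )
    @settings(max_examples=30, deadline=None)
    def test_score_monotonic_in_areas(self, tumor_px, pdl1_px):
        pdl1_px = min(pdl1_px, tumor_px)
        score = layer_ic_score(_layer_masks(tumor_px, pdl1_px), 1.4)
        assert 0 <= score.ic_score_pct <= 100
        assert (score.ic_score_pct == 0) == (pdl1_px == 0)
        if pdl1_px + 1 <= tumor_px:
            bigger = layer_ic_score(_layer_masks(tumor_px, pdl1_px + 1), 1.4)
            assert bigger.ic_score_pct > score.ic_score_pct

    def test_invariant_validation(self):
        tumor = np.zeros((8, 8), dtype=bool)
        tumor[:2] = True
        cells = np.ones((8, 8), dtype=bool)  # cells not within area: invalid
        with pytest.raises(ValueError):
            LayerMasks(
                z_index=0,
                tumor_cell_mask=cells,
                tumor_area_mask=tumor,
                immune_mask=np.zeros((8, 8), bool),
            )
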