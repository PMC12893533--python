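import numpy as np
import pytest

from landfrag import (
    CategoricalRaster,
    FADConfig,
    RasterError,
    SIX_CLASS_SCHEME,
    change_profile,
    classify_fad,
    compute_fad,
    multiscale_fad,
    natural_loss_area,
    transition_matrix,
)
from landfrag.fad_fragmentation import FADRaster, box_sum

import _oracles
from conftest import NODATA, random_binary_raster


def _binary(codes):
    return CategoricalRaster.from_codes(np.array(codes, dtype=np.int32), 30.0, nodata_code=NODATA)


def test_all_forest_fad_saturates():
    raster = _binary(np.ones((5, 5), dtype=int))
    fad = compute_fad(raster, 3)
    assert np.allclose(fad.values, 100.0)  # border windows clip but stay all-forest


def test_single_hole_and_isolated_pixel():
    grid = np.ones((5, 5), dtype=int)
    grid[1, 2] = 0
    fad = compute_fad(_binary(grid), 3)
    assert fad.values[1, 1] == pytest.approx(100 * 8 / 9)
    lonely = np.zeros((5, 5), dtype=int)
    lonely[2, 2] = 1
    fad2 = compute_fad(_binary(lonely), 3)
    assert fad2.values[2, 2] == pytest.approx(100 / 9)
    # FAD defined exactly on foreground pixels
    assert np.isnan(fad2.values).sum() == 24


def test_window_validation():
    raster = _binary(np.ones((4, 4), dtype=int))
    for bad in (2, 4, 1, 0):
        with pytest.raises(RasterError):
            compute_fad(raster, bad)


def test_nodata_excluded_from_denominator():
    grid = np.ones((3, 3), dtype=int)
    grid[0, 0] = NODATA
    fad = compute_fad(_binary(grid), 3)
    # center window holds 8 valid cells, all forest
    assert fad.values[1, 1] == pytest.approx(100.0)
    assert np.isnan(fad.values[0, 0])


def test_fad_matches_naive_loop_oracle(rng):
    for _ in range(10):
        raster = random_binary_raster(
            rng, shape=(30, 30), p_forest=rng.uniform(0.3, 0.8), p_nodata=0.05
        )
        for window in (3, 7):
            got = compute_fad(raster, window).values
            want = _oracles.naive_fad(raster.codes, NODATA, window)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)


def test_fad_monotone_in_forest(rng):
    raster = random_binary_raster(rng, shape=(15, 15), p_forest=0.5)
    background = np.argwhere(raster.codes == 0)
    r, c = background[rng.integers(0, len(background))]
    more = raster.codes.copy()
    more[r, c] = 1
    before = compute_fad(raster, 5).values
    after = compute_fad(raster.with_codes(more), 5).values
    both = ~np.isnan(before) & ~np.isnan(after)
    assert (after[both] >= before[both] - 1e-12).all()


@pytest.mark.parametrize(
    "value,expected_class",
    [(0.0, 1), (9.99, 1), (10.0, 2), (39.99, 2), (40.0, 3), (60.0, 4),
     (100 * 8 / 9, 4), (90.0, 5), (99.99, 5), (100.0, 6)],
)
def test_six_class_thresholds_lower_inclusive(value, expected_class):
    values = np.array([[value]])
    fad = FADRaster(values=values, scale="3", cell_size_m=30.0,
                    nodata_mask=np.zeros((1, 1), dtype=bool))
    assert classify_fad(fad, SIX_CLASS_SCHEME).classes[0, 0] == expected_class


def test_classification_order_preserving(rng):
    vals = np.sort(rng.uniform(0, 100, size=50))
    fad = FADRaster(values=vals.reshape(1, -1), scale="3", cell_size_m=30.0,
                    nodata_mask=np.zeros((1, 50), dtype=bool))
    classes = classify_fad(fad).classes[0]
    assert (np.diff(classes) >= 0).all()


def test_classify_rejects_out_of_range():
    fad = FADRaster(values=np.array([[101.0]]), scale="3", cell_size_m=30.0,
                    nodata_mask=np.zeros((1, 1), dtype=bool))
    with pytest.raises(RasterError):
        classify_fad(fad)


def test_multiscale_average_bounds_and_intact(rng):
    raster = random_binary_raster(rng, shape=(40, 40), p_forest=0.7)
    config = FADConfig(scales=(7, 13, 27))
    per_scale, avg, avg_class = multiscale_fad(raster, config)
    fads = np.stack([compute_fad(raster, w).values for w in config.scales])
    fg = raster.codes == 1
    assert (avg.values[fg] >= fads[:, fg].min(axis=0) - 1e-12).all()
    assert (avg.values[fg] <= fads[:, fg].max(axis=0) + 1e-12).all()
    # all-forest landscape: average FAD 100, class intact at every pixel
    solid = _binary(np.ones((30, 30), dtype=int))
    _, solid_avg, solid_class = multiscale_fad(solid, FADConfig())
    assert np.allclose(solid_avg.values, 100.0)
    assert (solid_class.classes == 6).all()


def test_window_covering_grid_gives_global_proportion(rng):
    raster = random_binary_raster(rng, shape=(10, 10), p_forest=0.6, p_nodata=0.05)
    fad = compute_fad(raster, 243)
    fg = raster.codes == 1
    expected = 100.0 * fg.sum() / raster.n_data_cells
    assert np.allclose(fad.values[fg], expected)


def test_transition_identity_is_diagonal(rng):
    raster = random_binary_raster(rng, shape=(20, 20), p_forest=0.6)
    _, _, cls = multiscale_fad(raster, FADConfig(scales=(7, 13)))
    trans = transition_matrix(cls, cls)
    assert np.all(trans.counts == np.diag(np.diag(trans.counts)))
    assert trans.fragmentation_increase_cells() == 0


def test_transition_hand_count():
    # states: intact=6, interior=5, nonforest=0
    from landfrag.fad_fragmentation import FragClassRaster

    c1 = FragClassRaster(classes=np.array([[6, 6, 5, 0]], dtype=np.int8),
                         scheme=SIX_CLASS_SCHEME, provenance="t", cell_size_m=30.0)
    c2 = FragClassRaster(classes=np.array([[6, 5, 0, 0]], dtype=np.int8),
                         scheme=SIX_CLASS_SCHEME, provenance="t", cell_size_m=30.0)
    trans = transition_matrix(c1, c2)
    assert trans.counts[6, 6] == 1
    assert trans.counts[6, 5] == 1
    assert trans.counts[5, 0] == 1
    assert trans.counts[0, 0] == 1
    assert trans.counts.sum() == 4
    assert trans.fragmentation_increase_cells() == 1  # intact -> interior


def test_transition_conserves_covalid_cells(rng):
    r1 = random_binary_raster(rng, shape=(25, 25), p_forest=0.6, p_nodata=0.1)
    r2 = random_binary_raster(rng, shape=(25, 25), p_forest=0.5, p_nodata=0.1)
    _, _, c1 = multiscale_fad(r1, FADConfig(scales=(7,)))
    _, _, c2 = multiscale_fad(r2, FADConfig(scales=(7,)))
    trans = transition_matrix(c1, c2)
    covalid = (r1.data_mask & r2.data_mask).sum()
    assert trans.counts.sum() == covalid
    pct = trans.row_percent
    sums = np.nansum(pct, axis=1)
    occupied = trans.counts.sum(axis=1) > 0
    assert np.allclose(sums[occupied], 100.0)


def test_natural_loss_examples(rng):
    raster = random_binary_raster(rng, shape=(10, 10), p_forest=0.6)
    assert natural_loss_area(raster, raster) == 0.0
    codes = raster.codes.copy()
    fc = np.argwhere(codes == 1)[0]
    codes[fc[0], fc[1]] = 0
    after = raster.with_codes(codes)
    assert natural_loss_area(raster, after) == pytest.approx(0.09)
    # asymmetry: reversed order measures gain, not loss
    assert natural_loss_area(after, raster) == 0.0


def test_change_profile_sums_and_frontier_case(rng):
    raster = random_binary_raster(rng, shape=(25, 25), p_forest=0.85)
    config = FADConfig(scales=(7, 13))
    # clear a block at the edge of the forest mass (frontier deforestation)
    codes = raster.codes.copy()
    codes[0:6, 0:6] = 0
    later = raster.with_codes(codes)
    ms1 = multiscale_fad(raster, config)[0]
    ms2 = multiscale_fad(later, config)[0]
    profile = change_profile(ms1, ms2, dates=("1990", "2022"))
    sums = profile.groupby(["date", "scale"])["percent"].sum()
    assert np.allclose(sums.values, 100.0)
    intact = profile[profile["class"] == "intact"].set_index(["date", "scale"])["percent"]
    for scale in ("fad-7", "fad-13"):
        assert intact.loc[("2022", scale)] <= intact.loc[("1990", scale)] + 1e-9
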