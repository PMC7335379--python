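import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microtissue as mt
from microtissue.densitometry import (
    BandMeasurement,
    calibrate_migration,
    housekeeping_ratio,
    loading_outliers,
    mmp2_active_fraction,
    quantify_band,
)
from microtissue.gel_render import render_gel
from microtissue.params import GelSceneParams

from oracles import tukey_outliers_oracle


def bm(corrected, lane="L0", target="x", flags=None):
    return BandMeasurement(
        lane=lane, target=target, molecular_weight=62.0, raw_intensity=corrected,
        global_background=0.0, local_background=0.0,
        corrected_intensity=corrected, flags=flags or [],
    )


# ------------------------------------------------- calibrate_migration
def test_exact_log_linear_ladder_recovered(default_migration):
    scene = GelSceneParams()
    assert default_migration.slope == pytest.approx(scene.migration_calibration[1], rel=1e-9)
    assert default_migration.row_of(62.0) == pytest.approx(scene.row_of(62.0), rel=1e-9)
    assert default_migration.kda_of(default_migration.row_of(62.0)) == pytest.approx(62.0)


def test_two_point_ladder_interpolates():
    m = calibrate_migration([50.0, 200.0], [100.0, 20.0])
    assert m.row_of(100.0) == pytest.approx(50.0)
    assert m.row_of(20.0) == pytest.approx(200.0)


def test_jittered_ladder_slope_within_five_percent():
    scene = GelSceneParams()
    rng = np.random.default_rng(4)
    rows = [scene.row_of(w) + rng.normal(0, 1.5) for w in scene.ladder_weights]
    m = calibrate_migration(rows, scene.ladder_weights)
    assert m.slope == pytest.approx(scene.migration_calibration[1], rel=0.05)


def test_bad_ladders_rejected():
    with pytest.raises(ValueError):
        calibrate_migration([100.0], [50.0])
    with pytest.raises(ValueError):
        calibrate_migration([50.0, 100.0], [20.0, 100.0])   # weight rises with row


# ----------------------------------------------------- quantify_band
def test_corrected_intensity_proportional_to_amount(default_migration):
    lanes = tuple((f"L{i}", ((62.0, a),)) for i, a in enumerate((1.0, 2.0, 4.0)))
    scene = GelSceneParams(lanes=lanes, noise_sd=0.0, seed=0)
    gel = render_gel(scene)
    windows = list(scene.lane_windows().values())
    vals = [
        quantify_band(gel.image, scene.lane_window(i), 62.0, default_migration,
                      lane_windows=windows).corrected_intensity
        for i in range(3)
    ]
    assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.01)
    assert vals[2] / vals[0] == pytest.approx(4.0, rel=0.01)


def test_zero_amount_lane_flags_below_detection(default_migration):
    scene = GelSceneParams(lanes=(("L0", ((62.0, 0.0),)),), noise_sd=0.002, seed=3)
    gel = render_gel(scene)
    m = quantify_band(gel.image, scene.lane_window(0), 62.0, default_migration,
                      lane_windows=[scene.lane_window(0)])
    assert "below-detection" in m.flags
    assert m.corrected_intensity < 1.0


def test_background_gradient_invariance(default_migration):
    lanes = (("L0", ((62.0, 60.0),)),)
    flat = GelSceneParams(lanes=lanes, noise_sd=0.001, seed=6, background_level=0.25)
    grad = GelSceneParams(lanes=lanes, noise_sd=0.001, seed=6, background_level=0.25,
                          background_gradient=0.2)
    w = [flat.lane_window(0)]
    v_flat = quantify_band(render_gel(flat).image, w[0], 62.0, default_migration,
                           lane_windows=w).corrected_intensity
    v_grad = quantify_band(render_gel(grad).image, w[0], 62.0, default_migration,
                           lane_windows=w).corrected_intensity
    assert abs(v_grad - v_flat) / v_flat < 0.05


def test_additive_offset_invariance(default_migration):
    """A constant added to the whole image is removed exactly by the
    global background subtraction."""
    lanes = (("L0", ((62.0, 60.0),)),)
    scene = GelSceneParams(lanes=lanes, noise_sd=0.001, seed=6, background_level=0.2)
    img = render_gel(scene).image
    w = [scene.lane_window(0)]
    v0 = quantify_band(img, w[0], 62.0, default_migration, lane_windows=w)
    v1 = quantify_band(img + 0.17, w[0], 62.0, default_migration, lane_windows=w)
    assert v1.corrected_intensity == pytest.approx(v0.corrected_intensity, rel=1e-6)


def test_polarity_symmetry(default_migration):
    lanes = (("L0", ((62.0, 40.0), (72.0, 70.0))),)
    bright = render_gel(GelSceneParams(lanes=lanes, noise_sd=0.001, seed=8))
    w = [GelSceneParams(lanes=lanes).lane_window(0)]
    v_b = quantify_band(bright.image, w[0], 62.0, default_migration,
                        lane_windows=w).corrected_intensity
    v_d = quantify_band(1.0 - bright.image, w[0], 62.0, default_migration,
                        polarity="dark-bands-on-light", lane_windows=w).corrected_intensity
    assert v_d == pytest.approx(v_b, rel=1e-9)


def test_band_window_clipped_by_edge_rejected(default_migration):
    scene = GelSceneParams(lanes=(("L0", ((62.0, 10.0),)),))
    img = render_gel(scene).image
    with pytest.raises(ValueError, match="clipped|edge"):
        quantify_band(img, scene.lane_window(0), 400.0, default_migration)


def test_tubulin_range_window(default_migration):
    """The 50-55 kDa tubulin doublet is quantified as one spanning window."""
    scene = GelSceneParams(lanes=(("L0", ((52.5, 80.0),)),), noise_sd=0.0, seed=0)
    gel = render_gel(scene)
    m = quantify_band(gel.image, scene.lane_window(0), (50.0, 55.0),
                      default_migration, lane_windows=[scene.lane_window(0)])
    assert m.corrected_intensity > 0
    assert "below-detection" not in m.flags


# ------------------------------------------------ ratio statistics
def test_housekeeping_ratio_arithmetic():
    assert housekeeping_ratio(bm(50.0), bm(100.0)) == pytest.approx(0.5)
    t = bm(77.0)
    assert housekeeping_ratio(t, t) == pytest.approx(1.0)


def test_housekeeping_ratio_rejects_dead_control():
    with pytest.raises(ValueError):
        housekeeping_ratio(bm(50.0), bm(0.0))
    with pytest.raises(ValueError):
        housekeeping_ratio(bm(50.0), bm(10.0, flags=["below-detection"]))


def test_rendered_ratio_recovered_despite_background(default_migration):
    lanes = (("L0", ((37.0, 100.0), (52.5, 400.0))),)
    scene = GelSceneParams(lanes=lanes, noise_sd=0.001, seed=12,
                           background_level=0.3)
    gel = render_gel(scene)
    w = [scene.lane_window(0)]
    target = quantify_band(gel.image, w[0], 37.0, default_migration, lane_windows=w)
    tub = quantify_band(gel.image, w[0], (50.0, 55.0), default_migration, lane_windows=w)
    assert housekeeping_ratio(target, tub) == pytest.approx(100.0 / 400.0, rel=0.02)


def test_active_fraction_arithmetic():
    assert mmp2_active_fraction(bm(30.0), bm(70.0)) == pytest.approx(0.30)
    assert mmp2_active_fraction(bm(10.0), bm(0.0)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mmp2_active_fraction(bm(0.0), bm(0.0))


def test_rendered_active_fraction_recovered(default_migration):
    for frac in (0.2, 0.5, 0.8):
        lanes = (("L0", ((62.0, 200.0 * frac), (72.0, 200.0 * (1 - frac)))),)
        scene = GelSceneParams(lanes=lanes, noise_sd=0.002, seed=13)
        gel = render_gel(scene)
        w = [scene.lane_window(0)]
        a = quantify_band(gel.image, w[0], 62.0, default_migration, lane_windows=w)
        p = quantify_band(gel.image, w[0], 72.0, default_migration, lane_windows=w)
        assert mmp2_active_fraction(a, p) == pytest.approx(frac, abs=0.02)


@given(st.floats(0.1, 10.0))
@settings(max_examples=30, deadline=None)
def test_active_fraction_invariant_to_common_rescaling(c):
    f1 = mmp2_active_fraction(bm(30.0), bm(70.0))
    f2 = mmp2_active_fraction(bm(30.0 * c), bm(70.0 * c))
    assert 0.0 <= f1 <= 1.0
    assert f1 == pytest.approx(f2, rel=1e-9)


# ------------------------------------------------- loading outliers
def test_degenerate_iqr_flags_only_the_outlier():
    flags = loading_outliers([1.0, 1.0, 1.0, 1.0, 100.0])
    assert flags.tolist() == [False, False, False, False, True]


def test_identical_values_have_no_outliers():
    assert not loading_outliers([5.0] * 8).any()


def test_fewer_than_four_values_refused():
    with pytest.raises(ValueError):
        loading_outliers([1.0, 2.0, 3.0])


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_outlier_rule_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0.0, 1.0, size=rng.integers(4, 60))
    assert np.array_equal(loading_outliers(x), tukey_outliers_oracle(x))
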