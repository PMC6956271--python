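import numpy as np
import pytest
from scipy import stats

from ocunano.errors import DomainError, InsufficientDataError
from ocunano.release import (
    HiguchiFit,
    ReleaseCurve,
    analyze_release,
    compare_slopes,
    fit_higuchi,
    predict_release,
    read_release_csv,
)
from ocunano.simulate import gen_release_curve


def test_noiseless_curve_inverts_exactly():
    curve = gen_release_curve(3.34, intercept=1.6)
    fit = fit_higuchi(curve)
    assert fit.slope == pytest.approx(3.34, abs=1e-9)
    assert fit.intercept == pytest.approx(1.6, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.time_unit == "min"


def test_flat_curve_fits_zero_line():
    curve = ReleaseCurve(
        label="flat", replicate=0,
        times=np.arange(30.0, 301.0, 30.0),
        released_pct=np.zeros(10),
    )
    fit = fit_higuchi(curve)
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)


def test_noisy_slope_recovery_within_three_standard_errors():
    curve = gen_release_curve(2.43, noise=1.0, seed=11)
    fit = fit_higuchi(curve)
    se = stats.linregress(np.sqrt(curve.times), curve.released_pct).stderr
    assert abs(fit.slope - 2.43) < 3.0 * se


@pytest.mark.parametrize(
    "slope,intercept,t,expected",
    [
        (3.34, 1.6, 300.0, 59.45),  # five-hour cumulative release
        (3.34, 1.6, 0.0, 1.6),  # intercept at t = 0
        (10.0, 0.0, 144.0, 100.0),  # clamped at full release
    ],
)
def test_predict_release(slope, intercept, t, expected):
    fit = HiguchiFit(label="x", slope=slope, intercept=intercept, r2=1.0)
    assert predict_release(fit, t) == pytest.approx(expected, abs=0.01)


def test_fit_predict_round_trip_on_noiseless_grid():
    truth = HiguchiFit(label="x", slope=2.8, intercept=1.0, r2=1.0)
    times = np.arange(30.0, 301.0, 30.0)
    curve = ReleaseCurve(
        label="x", replicate=0, times=times,
        released_pct=[predict_release(truth, t) for t in times],
    )
    fit = fit_higuchi(curve)
    assert fit.slope == pytest.approx(truth.slope, abs=1e-9)
    assert fit.intercept == pytest.approx(truth.intercept, abs=1e-9)


def test_slope_invariant_to_grid_subsampling():
    curve = gen_release_curve(3.14, intercept=0.5)
    sub = ReleaseCurve(
        label=curve.label, replicate=0,
        times=curve.times[::2], released_pct=curve.released_pct[::2],
    )
    assert fit_higuchi(sub).slope == pytest.approx(fit_higuchi(curve).slope,
                                                   abs=1e-9)


def test_intercept_outside_observed_band_is_flagged():
    fit = fit_higuchi(gen_release_curve(3.0, intercept=5.0))
    assert fit.flags
    assert fit_higuchi(gen_release_curve(3.0, intercept=1.0)).flags == []


def test_compare_slopes_detects_printed_group_difference():
    res = compare_slopes([2.43, 2.22, 2.64], [3.34, 3.02, 3.66])
    assert res["p"] < 0.05 and res["significant"]


def test_compare_identical_groups_not_significant():
    res = compare_slopes([2.5, 2.6, 2.4], [2.5, 2.6, 2.4])
    assert res["p"] == pytest.approx(1.0)
    assert not res["significant"]


def test_compare_slopes_requires_two_replicates():
    with pytest.raises(InsufficientDataError):
        compare_slopes([2.5], [2.4, 2.6])


def test_type_one_error_near_nominal_level():
    rejections = 0
    n_sim = 1000
    for s in range(n_sim):
        ga = [
            fit_higuchi(gen_release_curve(2.43, noise=1.0, seed=4 * s + r,
                                          replicate=r)).slope
            for r in range(3)
        ]
        gb = [
            fit_higuchi(gen_release_curve(2.43, noise=1.0,
                                          seed=50000 + 4 * s + r,
                                          replicate=r)).slope
            for r in range(3)
        ]
        if compare_slopes(ga, gb)["significant"]:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07


def test_fit_requires_minutes_or_hours_and_enough_points():
    curve = gen_release_curve(3.0)
    with pytest.raises(DomainError):
        fit_higuchi(curve, time_unit="s")
    short = ReleaseCurve(
        label="s", replicate=0, times=np.array([30.0, 60.0, 90.0]),
        released_pct=np.array([5.0, 8.0, 10.0]),
    )
    with pytest.raises(InsufficientDataError):
        fit_higuchi(short)


def test_hour_unit_fit_rescales_slope():
    curve = gen_release_curve(3.34, intercept=0.0)
    fit_h = fit_higuchi(curve, time_unit="h")
    # sqrt(min) slope converts by sqrt(60) to the per-sqrt-hour scale
    assert fit_h.slope == pytest.approx(3.34 * np.sqrt(60.0), rel=1e-9)
    assert fit_h.time_unit == "h"


def test_analyze_release_summary_and_pairwise(tmp_path):
    rows = ["label,replicate,time_min,released_pct"]
    for label, slope in [("A", 3.14), ("B", 2.43)]:
        for rep in range(3):
            c = gen_release_curve(slope, noise=0.5, seed=hash_free(label, rep),
                                  label=label, replicate=rep)
            rows += [f"{label},{rep},{t},{q}"
                     for t, q in zip(c.times, c.released_pct)]
    csv = tmp_path / "release.csv"
    csv.write_text("\n".join(rows))
    curves = read_release_csv(csv)
    rep = analyze_release(curves)
    summary = rep["summary"].set_index("label")
    assert summary.loc["A", "slope"] == pytest.approx(3.14, abs=0.2)
    assert summary.loc["B", "slope"] == pytest.approx(2.43, abs=0.2)
    assert "A vs B" in rep["pairwise_p"]


def hash_free(label: str, rep: int) -> int:
    return (sum(map(ord, label)) * 131 + rep) % 2**31
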