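import math

import numpy as np
import pytest
from scipy import stats

from conftest import CONTROL_SLOPE, FORMULATION_SLOPES
from ocunano import dialysis
from ocunano.dialysis import (
    DialysisRun,
    analyze_runs,
    bound_fraction,
    calibrate_km,
    fit_log_linear,
    read_dialysis_csv,
)
from ocunano.errors import DomainError, InsufficientDataError
from ocunano.simulate import gen_dialysis_run


def _exact_run(slope, label="x", role="formulation"):
    t = np.arange(0.5, 5.01, 0.5)
    return DialysisRun(
        label=label, role=role, times=t,
        donor_conc=100.0 * np.exp(-slope * t), cd0=100.0,
    )


def test_noiseless_control_inverts_exactly():
    fit = fit_log_linear(_exact_run(0.44, role="control"))
    assert fit.slope_mag == pytest.approx(0.44, abs=1e-12)
    assert fit.intercept == pytest.approx(math.log(100.0), abs=1e-12)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_constant_donor_concentration_gives_zero_slope():
    run = DialysisRun(
        label="flat", role="formulation",
        times=np.array([1.0, 2.0, 3.0]),
        donor_conc=np.array([100.0, 100.0, 100.0]), cd0=100.0,
    )
    assert fit_log_linear(run).slope_mag == pytest.approx(0.0, abs=1e-12)


def test_noisy_slope_recovery_within_three_standard_errors():
    km, ff = 0.44, 0.52
    run = gen_dialysis_run(km, ff, noise=0.02, seed=7)
    fit = fit_log_linear(run)
    # independent OLS oracle for the standard error of the slope
    y = np.log(100.0 * run.donor_conc / run.cd0)
    se = stats.linregress(run.times, y).stderr
    assert abs(fit.slope_mag - km * ff) < 3.0 * se


def test_calibrate_km_is_control_slope():
    assert calibrate_km(fit_log_linear(_exact_run(0.44, role="control"))) == (
        pytest.approx(0.44, abs=1e-12)
    )
    with pytest.raises(DomainError):
        calibrate_km(
            dialysis.BindingResult(label="c", slope_mag=0.0, intercept=0, r2=1)
        )


@pytest.mark.parametrize(
    "slope,expected", [(s, pct) for s, pct in FORMULATION_SLOPES.values()]
)
def test_bound_fraction_reproduces_printed_interaction(slope, expected):
    fit = fit_log_linear(_exact_run(slope))
    done = bound_fraction(fit, km=CONTROL_SLOPE)
    assert round(done.interaction_pct, 1) == expected
    assert done.interaction_pct == pytest.approx(100 * (1 - done.ff), abs=1e-9)


def test_slope_equal_to_km_means_no_binding():
    done = bound_fraction(fit_log_linear(_exact_run(0.44)), km=0.44)
    assert done.interaction_pct == pytest.approx(0.0, abs=1e-9)


def test_ratio_above_one_is_clamped_with_warning():
    done = bound_fraction(fit_log_linear(_exact_run(0.5)), km=0.44)
    assert done.ff == 1.0
    assert any("clamped" in w for w in done.warnings)


def test_interaction_decreases_monotonically_with_slope():
    km = 0.44
    slopes = np.linspace(0.01, km, 25)
    pcts = [
        bound_fraction(fit_log_linear(_exact_run(s)), km).interaction_pct
        for s in slopes
    ]
    assert all(a > b for a, b in zip(pcts, pcts[1:]))


def test_ff_recovery_median_error_small_under_assay_noise():
    km = 0.44
    errs = []
    for ff in (0.52, 0.64, 0.84):
        for seed in range(200):
            run = gen_dialysis_run(km, ff, noise=0.02, seed=seed)
            errs.append(abs(fit_log_linear(run).slope_mag / km - ff))
    assert np.median(errs) < 0.05


def test_noiseless_control_intercept_matches_sink_condition():
    fit = fit_log_linear(_exact_run(0.44, role="control"))
    assert abs(fit.intercept - math.log(100.0)) < 0.1


def test_fit_rejects_nonpositive_concentration_and_short_series():
    run = _exact_run(0.3)
    run.donor_conc[2] = 0.0
    with pytest.raises(DomainError):
        fit_log_linear(run)
    with pytest.raises(InsufficientDataError):
        DialysisRun(
            label="s", role="control", times=np.array([1.0, 2.0]),
            donor_conc=np.array([90.0, 80.0]), cd0=100.0,
        )


def test_rising_donor_concentration_is_flagged_not_raised():
    run = DialysisRun(
        label="r", role="formulation", times=np.array([1.0, 2.0, 3.0]),
        donor_conc=np.array([50.0, 60.0, 70.0]), cd0=100.0,
    )
    fit = fit_log_linear(run)
    assert any("rising" in w for w in fit.warnings)
    assert fit.slope_mag > 0


def test_replicate_analysis_reports_mean_sd_and_significance(tmp_path):
    rows = []
    for label, role, ff in [("Control", "control", 1.0),
                            ("QA-Ch", "formulation", 0.523)]:
        for rep in range(4):
            run = gen_dialysis_run(
                0.44, ff, noise=0.02, seed=100 * rep + (0 if role == "control" else 7),
                label=label, role=role, replicate=rep,
            )
            rows.extend(
                f"{label},{role},{rep},{t},{c}\n"
                for t, c in zip(run.times, run.donor_conc)
            )
    csv = tmp_path / "dialysis.csv"
    csv.write_text("label,role,replicate,time_h,donor_conc\n" + "".join(rows))

    runs = read_dialysis_csv(csv)
    assert len(runs) == 8
    report = analyze_runs(runs).set_index("label")
    assert report.loc["Control", "km"] == pytest.approx(0.44, rel=0.05)
    assert report.loc["QA-Ch", "ff"] == pytest.approx(0.523, abs=0.05)
    assert report.loc["QA-Ch", "slope_sd"] > 0
    # formulation slope (~0.23) clearly differs from control (~0.44)
    assert report.loc["QA-Ch", "significant"]


def test_pooled_fit_agrees_with_replicate_mean_on_noiseless_data():
    runs = [
        gen_dialysis_run(0.44, 0.6, noise=0.0, label="F", role="formulation",
                         replicate=r)
        for r in range(3)
    ]
    runs += [gen_dialysis_run(0.44, 1.0, noise=0.0, label="C", replicate=0)]
    per_rep = analyze_runs(runs, pooled=False).set_index("label")
    pooled = analyze_runs(runs, pooled=True).set_index("label")
    assert per_rep.loc["F", "slope_mag"] == pytest.approx(
        pooled.loc["F", "slope_mag"], abs=1e-9
    )
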