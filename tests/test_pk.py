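from importlib import resources

import numpy as np
import pandas as pd
import pytest

from ocunano.errors import DegenerateTestError, DomainError
from ocunano.pk import (
    AUCResult,
    PKProfile,
    analyze_pk,
    compare_auc,
    read_pk_csv,
    relative_auc,
    trapezoid_auc,
)
from ocunano.simulate import gen_pk_profile, k_in_for_auc, pk_true_auc


def make_profile(times, conc, sd=None, n=6, label="x"):
    times = np.asarray(times, float)
    conc = np.asarray(conc, float)
    return PKProfile(
        label=label, times_h=times, mean_conc=conc,
        sd_conc=np.zeros_like(conc) if sd is None else np.asarray(sd, float),
        n_per_time=np.full(len(times), n, int),
    )


def test_constant_profile_rectangle_area():
    p = make_profile([0, 2, 4, 6, 8, 10], [0.3] * 6)
    assert trapezoid_auc(p).auc == pytest.approx(3.0, abs=1e-12)


def test_two_point_triangle_area():
    p = make_profile([0, 10], [0.0, 1.0])
    assert trapezoid_auc(p).auc == pytest.approx(5.0, abs=1e-12)


def test_missing_time_zero_prepends_zero_concentration():
    p = make_profile([1, 5, 10], [1.0, 1.0, 1.0])
    # triangle 0-1 h plus rectangle 1-10 h
    assert trapezoid_auc(p).auc == pytest.approx(0.5 + 9.0, abs=1e-12)


def test_agrees_with_fine_grid_quadrature_oracle():
    times = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0])
    conc = np.array([0.0, 0.21, 0.33, 0.35, 0.33, 0.34, 0.32, 0.30])
    p = make_profile(times, conc)
    # independent oracle: numpy trapezoid on a fine grid through the same
    # breakpoints (piecewise-linear interpolation is exact for trapezoids)
    fine = np.unique(np.concatenate([np.linspace(0, 10, 5001), times]))
    oracle = np.trapezoid(np.interp(fine, times, conc), fine)
    assert trapezoid_auc(p).auc == pytest.approx(oracle, abs=1e-9)


def test_additive_over_adjacent_windows():
    p = gen_pk_profile(0.99, seed=3, times=[0.5, 1, 2, 3, 5, 7, 10])
    full = trapezoid_auc(p, 0, 10).auc
    left = trapezoid_auc(p, 0, 5).auc
    right = trapezoid_auc(p, 5, 10).auc
    assert left + right == pytest.approx(full, abs=1e-12)


def test_invariant_to_collinear_point_insertion():
    p = make_profile([0, 4, 10], [0.0, 0.4, 1.0])
    q = make_profile([0, 2, 4, 7, 10], [0.0, 0.2, 0.4, 0.7, 1.0])
    assert trapezoid_auc(p).auc == pytest.approx(trapezoid_auc(q).auc, abs=1e-12)


def test_window_beyond_data_raises():
    p = make_profile([0, 2, 8], [0.1, 0.2, 0.1])
    with pytest.raises(DomainError):
        trapezoid_auc(p, 0, 10)


@pytest.mark.parametrize(
    "auc,control,expected",
    [(2.32, 0.62, 3.7), (3.34, 0.62, 5.4), (1.7, 1.7, 1.0)],
)
def test_relative_auc(auc, control, expected):
    r = relative_auc(AUCResult("t", auc, 0.0), AUCResult("c", control, 0.0))
    assert r == expected


def test_relative_auc_rejects_zero_control():
    with pytest.raises(DomainError):
        relative_auc(AUCResult("t", 1.0, 0.0), AUCResult("c", 0.0, 0.0))


def test_fixture_auc_table_reproduces_all_relative_aucs():
    with resources.files("ocunano.data").joinpath("aqueous_auc.csv").open() as fh:
        table = pd.read_csv(fh).set_index("label")
    control = AUCResult("Control", table.loc["Control", "auc_ug_h_ml"], 0.0)
    expected = {"TSOH": 3.7, "Ch NP+TSOH": 3.6,
                "QA-Ch NP+TSOH": 5.3, "SB-Ch NP+TSOH": 5.4}
    for label, rel in expected.items():
        test_res = AUCResult(label, table.loc[label, "auc_ug_h_ml"], 0.0)
        assert relative_auc(test_res, control) == rel


def test_identical_results_compare_as_equal():
    a = AUCResult("a", 3.0, 0.04)
    res = compare_auc(a, AUCResult("b", 3.0, 0.04))
    assert res["statistic"] == 0.0
    assert not res["significant"]


def test_zero_variances_degenerate():
    with pytest.raises(DegenerateTestError):
        compare_auc(AUCResult("a", 3.0, 0.0), AUCResult("b", 2.0, 0.0))


def test_variance_propagation_matches_monte_carlo():
    k_in = k_in_for_auc(3.30)
    aucs, var_preds = [], []
    for seed in range(1000):
        p = gen_pk_profile(k_in, seed=seed)
        r = trapezoid_auc(p)
        aucs.append(r.auc)
        var_preds.append(r.var_auc)
    empirical_sd = np.std(aucs, ddof=1)
    predicted_sd = np.sqrt(np.mean(var_preds))
    assert abs(empirical_sd / predicted_sd - 1.0) < 0.15


def test_power_against_control_like_separation():
    # exposure gap as wide as the strongest formulation vs control
    hits = 0
    n_sim = 100
    for seed in range(n_sim):
        ctrl = gen_pk_profile(k_in_for_auc(0.62), seed=2 * seed, label="c")
        test = gen_pk_profile(k_in_for_auc(3.30), seed=2 * seed + 1, label="t")
        res = compare_auc(trapezoid_auc(ctrl), trapezoid_auc(test))
        hits += res["significant"]
    assert hits / n_sim >= 0.8


def test_analyze_pk_report(tmp_path):
    rows = ["label,time_h,mean_conc_ug_ml,sd_conc,n"]
    for label, auc in [("Control", 0.62), ("QA-Ch NP+TSOH", 3.30)]:
        p = gen_pk_profile(k_in_for_auc(auc), seed=sum(map(ord, label)) % 1000,
                           label=label)
        rows += [
            f"{label},{t},{m},{s},{n}"
            for t, m, s, n in zip(p.times_h, p.mean_conc, p.sd_conc,
                                  p.n_per_time)
        ]
    csv = tmp_path / "pk.csv"
    csv.write_text("\n".join(rows))
    report = analyze_pk(read_pk_csv(csv), control_label="Control")
    report = report.set_index("label")
    assert report.loc["QA-Ch NP+TSOH", "auc_rel"] == pytest.approx(5.3, abs=1.5)
    assert report.loc["QA-Ch NP+TSOH", "significant"]


def test_satterthwaite_t_reference_available():
    a = gen_pk_profile(0.99, seed=0, label="a")
    b = gen_pk_profile(0.99, seed=1, label="b")
    res = compare_auc(trapezoid_auc(a), trapezoid_auc(b), use_t=True,
                      profiles=(a, b))
    assert res["method"].startswith("t (Satterthwaite")
    assert 0.0 <= res["p"] <= 1.0
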