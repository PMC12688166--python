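"""Time-dependent Cox engine, c-index, segmented regression and thresholds."""

import numpy as np
import pandas as pd
import pytest

from ctdna_monitor import (build_counting_process, concordance_index_td,
                           fit_os_models, fit_td_cox, segmented_changepoint,
                           simulate_threshold_cohort, subtype_hazards)
from ctdna_monitor.cohort import Cohort
from ctdna_monitor.survival import rcs_basis, rcs_knots

from conftest import make_toy_cohort


def _single_patient_cohort(sample_days, scores, scan_days, progression):
    patients = pd.DataFrame({"patient_id": ["P1"], "er_status": [1],
                             "her2_status": [0], "death_day": [np.nan],
                             "death_event": [0]})
    samples = pd.DataFrame({"patient_id": "P1", "day": sample_days,
                            "tumour_fraction": scores,
                            "ca15_3": np.nan, "max_vaf": np.nan})
    scans = pd.DataFrame({"patient_id": "P1", "day": scan_days,
                          "progression": progression,
                          "response_category": None})
    treatments = pd.DataFrame(columns=["patient_id", "regimen",
                                       "treatment_class", "start_day", "end_day"])
    return Cohort(patients=patients, treatments=treatments, samples=samples,
                  scans=scans, provenance={"aligned": True})


def test_counting_process_row_construction():
    cohort = _single_patient_cohort([0, 30], [0.02, 0.09], [0, 50], [0, 1])
    rows = build_counting_process(cohort, "PFS")
    assert [(r.start, r.stop, r.event, r.score) for r in rows.itertuples()] == [
        (0.0, 30.0, 0, 2.0), (30.0, 50.0, 1, 9.0)]


def test_counting_process_censored_patient_has_no_events():
    cohort = _single_patient_cohort([0, 30, 60], [0.02, 0.05, 0.04],
                                    [0, 90], [0, 0])
    rows = build_counting_process(cohort, "PFS")
    assert rows["event"].sum() == 0
    assert rows["stop"].max() == 90.0


def test_counting_process_partitions_followup_exactly():
    cohort = simulate_threshold_cohort(n_patients=100, seed=13)
    rows = build_counting_process(cohort, "PFS")
    for pid, grp in rows.groupby("patient_id"):
        grp = grp.sort_values("start")
        # intervals are contiguous and disjoint
        assert np.allclose(grp["start"].to_numpy()[1:], grp["stop"].to_numpy()[:-1])
        total = grp["stop"].max() - grp["start"].min()
        assert total == pytest.approx((grp["stop"] - grp["start"]).sum())
        # event only on the final interval
        assert grp["event"].to_numpy()[:-1].sum() == 0


def _binary_covariate_rows(n=700, hr=2.0, seed=0):
    """Exponential survival with a binary covariate of known hazard ratio."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    lam = 0.01 * hr**x
    t = rng.exponential(1 / lam)
    cens = rng.exponential(120, n)
    stop = np.minimum(t, cens)
    return pd.DataFrame({"patient_id": [f"S{i}" for i in range(n)],
                         "start": 0.0, "stop": stop,
                         "event": (t <= cens).astype(int),
                         "score": x.astype(float),
                         "subtype": "ER+Her2-", "her2_pos": 0.0, "tn": 0.0})


def test_cox_recovers_known_hazard_ratio():
    rows = _binary_covariate_rows(n=900, hr=2.0, seed=1)
    assert rows["event"].sum() >= 500
    fit = fit_td_cox(rows, formula="score")
    assert 1.8 <= fit.hazard_ratio("score") <= 2.2


def test_permuted_score_has_null_discrimination():
    rows = _binary_covariate_rows(n=500, hr=2.5, seed=2)
    rng = np.random.default_rng(3)
    rows["score"] = rng.permutation(rows["score"].to_numpy())
    fit = fit_td_cox(rows, formula="score")
    assert abs(fit.c_index - 0.5) < 0.05


def test_log_hazard_ratio_is_equivariant_to_score_rescaling():
    rows = _binary_covariate_rows(n=600, hr=2.0, seed=4)
    fit1 = fit_td_cox(rows, formula="score")
    rows10 = rows.assign(score=rows["score"] * 10)
    fit10 = fit_td_cox(rows10, formula="score")
    assert np.log(fit10.hazard_ratio("score")) * 10 == pytest.approx(
        np.log(fit1.hazard_ratio("score")), rel=1e-4)
    assert fit10.c_index == pytest.approx(fit1.c_index)


def test_cindex_matches_quadratic_pair_oracle():
    rng = np.random.default_rng(5)
    n = 180
    start = rng.uniform(0, 50, n)
    stop = start + rng.uniform(1, 80, n)
    event = rng.integers(0, 2, n)
    risk = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
    rows = pd.DataFrame({"start": start, "stop": stop, "event": event})

    conc = disc = ties = 0
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if start[j] < stop[i] <= stop[j] and not (stop[j] == stop[i] and event[j] == 1):
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] < risk[j]:
                    disc += 1
                else:
                    ties += 1
    expected = (conc + 0.5 * ties) / (conc + disc + ties)
    c, _ = concordance_index_td(rows, risk)
    assert c == pytest.approx(expected, abs=1e-12)


def test_no_events_is_error():
    rows = _binary_covariate_rows(n=50, seed=6)
    rows["event"] = 0
    with pytest.raises(ValueError, match="no events"):
        fit_td_cox(rows, formula="score")


# ----------------------------------------------------------------------
# restricted cubic spline


def test_rcs_basis_is_linear_beyond_outer_knots():
    knots = np.array([1.0, 2.0, 3.0, 4.0])
    x = np.array([4.5, 5.0, 5.5, 6.0])
    basis = rcs_basis(x, knots)
    for j in range(1, basis.shape[1]):
        diffs = np.diff(basis[:, j]) / 0.5
        assert np.allclose(diffs, diffs[0])  # constant slope in the tail


def test_rcs_knots_at_requested_quantiles():
    x = np.linspace(0, 100, 1001)
    knots = rcs_knots(x, 4)
    assert np.allclose(knots, [5, 35, 65, 95], atol=0.2)


# ----------------------------------------------------------------------
# segmented regression


def _piecewise(x, brk, b0, s_lo, s_hi):
    return b0 + s_lo * np.minimum(x, brk) + s_hi * np.clip(x - brk, 0, None)


def test_segmented_recovers_noiseless_breakpoint():
    x = np.round(np.linspace(0.0, 0.2, 41), 4)
    y = _piecewise(x, 0.07, 1.0, 2.0, 25.0)
    fit = segmented_changepoint(x, y)
    assert not fit.degenerate
    assert fit.breakpoint == pytest.approx(0.07, abs=0.005)
    assert fit.slope_low == pytest.approx(2.0, abs=1e-6)
    assert fit.slope_high == pytest.approx(25.0, abs=1e-4)


def test_segmented_flags_pure_straight_line():
    x = np.linspace(0, 1, 20)
    fit = segmented_changepoint(x, 3.0 + 2.0 * x)
    assert fit.degenerate
    assert fit.breakpoint == pytest.approx(0.5)


def test_segmented_matches_bruteforce_on_noisy_grids():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(10, 40)
        x = np.sort(rng.choice(np.linspace(0, 1, 200), size=n, replace=False))
        y = _piecewise(x, rng.uniform(0.2, 0.8), 0.0, rng.uniform(-2, 2),
                       rng.uniform(2, 8)) + rng.normal(0, 0.1, n)
        fit = segmented_changepoint(x, y)
        # independent brute force over the same candidate set
        best_rss, best_c = np.inf, None
        for c in x[2:-2]:
            d = np.column_stack([np.ones_like(x), x, np.clip(x - c, 0, None)])
            r = y - d @ np.linalg.pinv(d) @ y
            rss = float(r @ r)
            if rss < best_rss - 1e-15:
                best_rss, best_c = rss, c
        assert fit.breakpoint == pytest.approx(best_c)
        assert fit.rss == pytest.approx(best_rss, abs=1e-9)


def test_segmented_rejects_degenerate_grids():
    with pytest.raises(ValueError, match="at least 5"):
        segmented_changepoint([0, 1, 2, 3], [0, 1, 2, 3])
    with pytest.raises(ValueError, match="strictly increasing"):
        segmented_changepoint([0, 1, 1, 2, 3, 4], np.zeros(6))


# ----------------------------------------------------------------------
# subtype stratification and OS


def test_subtype_null_hazard_ci_covers_one():
    covered = total = 0
    for seed in range(20):
        cohort = simulate_threshold_cohort(n_patients=60, slope_low=0.0,
                                           slope_high=0.0, base_hazard=1.5e-3,
                                           seed=100 + seed)
        out = subtype_hazards(cohort, threshold=0.07)
        for info in out.values():
            if info.get("skipped"):
                continue
            lo, hi = info["hr_ci"]
            total += 1
            covered += int(lo <= 1.0 <= hi)
    assert total >= 20
    assert covered / total >= 0.9


def test_subtype_hazards_reports_expected_times():
    cohort = simulate_threshold_cohort(n_patients=150, seed=17)
    out = subtype_hazards(cohort, threshold=0.07)
    er = out["ER+Her2-"]
    assert not er["skipped"]
    assert er["hr"] > 1.0
    # persistently high score must shorten the expected time to progression
    assert er["expected_months_high"] < er["expected_months_low"]


def test_os_models_require_events():
    cohort = make_toy_cohort(align=True)
    cohort.patients["death_event"] = 0
    with pytest.raises(ValueError, match="no events"):
        fit_os_models(cohort)


def test_os_models_fit_both_formulas(sim_cohort):
    cohort, _ = sim_cohort
    fits = fit_os_models(cohort, threshold=0.07)
    assert set(fits) == {"continuous", "thresholded"}
    assert "score" in fits["continuous"].summary.index
    assert "score_high" in fits["thresholded"].summary.index
    for fit in fits.values():
        assert 0 <= fit.c_index <= 1


def test_thresholding_never_beats_continuous_discrimination():
    diffs = []
    for seed in range(8):
        cohort = simulate_threshold_cohort(n_patients=80, seed=200 + seed)
        rows = build_counting_process(cohort, "PFS")
        c_cont = fit_td_cox(rows, formula="score").c_index
        c_thr = fit_td_cox(rows, formula="threshold", threshold=10.0).c_index
        diffs.append(c_thr - c_cont)
    assert np.mean(diffs) < 0.01
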