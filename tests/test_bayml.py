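"""Two-stage Bayesian model: designs, convergence, prediction and validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ctdna_monitor import (SimConfig, align_times, check_convergence, predict_pd,
                           simulate_cohort)
from ctdna_monitor.bayml import (DAYS_PER_YEAR, SamplerConfig, auroc,
                                 build_design_matrices, fit_stage1, fit_stage2,
                                 roc_points, temporal_validation, _holdout_split,
                                 _prob_draws, _log_sigmoid)
from ctdna_monitor.cohort import Cohort

from conftest import FAST_SAMPLER, make_toy_cohort


def _mini_cohort(regimen_outcomes):
    """One patient per regimen; scans carry the given outcome sequences."""
    patients, treatments, samples, scans = [], [], [], []
    for i, (reg, outcomes) in enumerate(regimen_outcomes.items()):
        pid = f"M{i}"
        patients.append({"patient_id": pid, "er_status": i % 2,
                         "her2_status": (i + 1) % 2, "death_day": np.nan,
                         "death_event": 0})
        treatments.append({"patient_id": pid, "regimen": reg,
                           "treatment_class": "chemotherapy",
                           "start_day": -20.0, "end_day": np.nan})
        for k in range(3):
            samples.append({"patient_id": pid, "day": -10.0 + 40 * k,
                            "tumour_fraction": 0.05 + 0.02 * k + 0.01 * i,
                            "ca15_3": np.nan, "max_vaf": np.nan})
        for k, out in enumerate(outcomes):
            scans.append({"patient_id": pid, "day": 90.0 * k,
                          "progression": out, "response_category": None})
    return Cohort(patients=pd.DataFrame(patients),
                  treatments=pd.DataFrame(treatments),
                  samples=pd.DataFrame(samples), scans=pd.DataFrame(scans),
                  provenance={"aligned": True})


def test_design_matrix_shapes_and_time_units():
    cohort = _mini_cohort({"A": [0, 1], "B": [1, 0], "C": [0, 1]})
    d1, d2 = build_design_matrices(cohort, min_regimen_obs=1)
    assert d1.X.shape[0] == 9   # 3 patients x 3 samples
    assert d2.X.shape[0] == 6   # 3 patients x 2 scans
    j = d1.columns.index("time_years")
    row = np.flatnonzero(d1.days == 70.0)[0]
    assert d1.X[row, j] == pytest.approx(70.0 / DAYS_PER_YEAR)
    # a full year of follow-up is exactly 1.0 on the time axis
    assert DAYS_PER_YEAR / DAYS_PER_YEAR == 1.0
    assert set(d2.patient_ids) <= set(d1.patient_ids)


def test_separated_regimen_is_flagged_non_identifiable():
    cohort = _mini_cohort({"A": [0, 1, 0, 1], "B": [1, 0, 1, 0],
                           "Megestrol": [0, 0, 0, 0]})
    _, d2 = build_design_matrices(cohort, min_regimen_obs=1)
    assert "Megestrol" in d2.flagged_regimens
    assert not any(c == "regimen:Megestrol" for c in d2.columns)


def test_post_followup_samples_never_enter_stage1(sim_cohort):
    cohort, _ = sim_cohort
    d1, _ = build_design_matrices(cohort)
    flagged = cohort.samples[cohort.samples["post_followup"]]
    if len(flagged):
        last = cohort.scans.groupby("patient_id")["day"].max()
        pid_of_row = np.array(d1.patient_ids)[d1.patient_idx]
        assert np.all(d1.days <= last.loc[pid_of_row].to_numpy())


def test_stage1_design_invariant_to_time_origin(sim_cohort):
    cohort, _ = sim_cohort
    shifted = cohort.copy()
    shifted.samples["day"] += 1000
    shifted.scans["day"] += 1000
    shifted.treatments["start_day"] += 1000
    shifted.treatments["end_day"] += 1000
    shifted.provenance["aligned"] = False
    realigned = align_times(shifted)
    a1, a2 = build_design_matrices(cohort)
    b1, b2 = build_design_matrices(realigned)
    assert np.allclose(a1.X, b1.X) and np.allclose(a1.y, b1.y)
    assert np.allclose(a2.X, b2.X)


# ----------------------------------------------------------------------
# convergence diagnostics


def test_iid_chains_pass_convergence():
    rng = np.random.default_rng(0)
    report = check_convergence(rng.standard_normal((4, 500, 3)))
    assert report.passed and report.max_rhat < 1.05


def test_shifted_chains_fail_convergence():
    rng = np.random.default_rng(1)
    chains = rng.standard_normal((2, 500))
    chains[1] += 10.0
    report = check_convergence(chains)
    assert not report.passed and report.max_rhat > 1.5
    assert report.passed == (report.max_rhat < 1.1)


def test_single_chain_is_error():
    with pytest.raises(ValueError, match="2 chains"):
        check_convergence(np.zeros((1, 100)))


# ----------------------------------------------------------------------
# stage fits


def test_degenerate_variance_concentrates_posterior_near_zero():
    cfg = SimConfig(n_patients=80, sigma_b=(0.0, 0.0), rho_b=0.0,
                    sigma_eps=0.05, seed=5)
    cohort, _ = simulate_cohort(cfg)
    d1, _ = build_design_matrices(cohort)
    s1 = fit_stage1(d1, FAST_SAMPLER)
    q95 = np.percentile(s1.draws["sigma_b"], 95, axis=0)
    assert np.all(q95 < 0.1)


def test_thinned_draw_count_matches_configuration(small_fits):
    _, _, _, _, s1, s2 = small_fits
    assert len(s1.draws["beta"]) == FAST_SAMPLER.n_keep
    assert len(s2.draws["beta2"]) == FAST_SAMPLER.n_keep


def test_stage2_patient_missing_from_stage1_is_error(small_fits):
    cohort, _, d1, d2, s1, _ = small_fits
    orphan = dataclasses.replace(
        d2, patient_ids=d2.patient_ids + ["GHOST"],
        patient_idx=d2.patient_idx)
    with pytest.raises(ValueError, match="GHOST"):
        fit_stage2(orphan, s1, FAST_SAMPLER, force=True)


def test_stage2_refuses_unconverged_stage1(small_fits):
    _, _, _, d2, s1, _ = small_fits
    bad = dataclasses.replace(s1, convergence=dataclasses.replace(
        s1.convergence, passed=False))
    with pytest.raises(RuntimeError, match="convergence"):
        fit_stage2(d2, bad, FAST_SAMPLER)


def test_bhat_tracks_true_random_effects(small_fits):
    _, truth, _, _, s1, _ = small_fits
    merged = s1.bhat.merge(truth.effects, on="patient_id",
                           suffixes=("_est", "_true"))
    assert np.corrcoef(merged["b0_est"], merged["b0_true"])[0, 1] > 0.8
    assert np.corrcoef(merged["b1_est"], merged["b1_true"])[0, 1] > 0.6


# ----------------------------------------------------------------------
# prediction


def test_prediction_matches_direct_quadrature_oracle(small_fits):
    """For a scan with no earlier scans the prediction is a plain
    prior-weighted quadrature average -- recompute it independently."""
    cohort, _, d1, d2, s1, s2 = small_fits
    pid = d2.patient_ids[0]
    first_scan_day = d2.days[np.array(d2.patient_ids)[d2.patient_idx] == pid].min()
    pred = predict_pd(s1, s2, cohort, pid, float(first_scan_day),
                      config=FAST_SAMPLER)
    # oracle: direct numpy evaluation from the posterior draws
    from ctdna_monitor.bayml import _conditional_bhat, _stage2_row
    rows1 = np.flatnonzero((np.array(d1.patient_ids)[d1.patient_idx] == pid)
                           & (d1.days <= first_scan_day))
    bhat_i = _conditional_bhat(s1.draws, d1.X[rows1], d1.Z[rows1], d1.y[rows1],
                               np.zeros(len(rows1), dtype=int), 1)[0]
    prow = cohort.patients.set_index("patient_id").loc[pid]
    from ctdna_monitor.bayml import _patient_intervals, _treatment_at
    reg, _ = _treatment_at(_patient_intervals(cohort).get(pid, []), first_scan_day)
    x2 = _stage2_row(d2.columns, first_scan_day, float(prow["er_status"]),
                     float(prow["her2_status"]), reg)
    nodes, weights = np.polynomial.hermite.hermgauss(FAST_SAMPLER.n_quad)
    eta = s2.draws["beta2"] @ x2 + s2.draws["gamma"] @ bhat_i
    u = np.sqrt(2.0) * s2.draws["sigma_u"][:, None] * nodes[None, :]
    p_draws = ((weights / np.sqrt(np.pi))[None, :]
               / (1 + np.exp(-(eta[:, None] + u)))).sum(axis=1)
    assert pred.probability == pytest.approx(float(p_draws.mean()), abs=1e-10)
    assert pred.n_samples == len(rows1)
    assert 0 <= pred.interval[0] <= pred.probability <= pred.interval[1] <= 1


def test_prediction_is_deterministic(small_fits):
    cohort, _, _, d2, s1, s2 = small_fits
    pid = d2.patient_ids[1]
    day = float(d2.days[np.array(d2.patient_ids)[d2.patient_idx] == pid].max())
    a = predict_pd(s1, s2, cohort, pid, day, config=FAST_SAMPLER)
    b = predict_pd(s1, s2, cohort, pid, day, config=FAST_SAMPLER)
    assert a.probability == b.probability and a.interval == b.interval


def test_rising_trajectory_has_higher_pd_probability(small_fits):
    """Under the fitted model (positive gamma), a patient whose ctDNA is high
    and rising must out-risk one whose ctDNA is low and falling."""
    _, _, _, d2, _, s2 = small_fits
    assert np.all(s2.draws["gamma"].mean(axis=0) > 0)
    x2 = np.zeros(len(d2.columns))
    x2[d2.columns.index("intercept")] = 1.0
    empty = np.zeros((0, len(d2.columns)))
    rising = _prob_draws(s2, x2, np.array([0.3, 0.5]), empty, np.zeros(0),
                         np.zeros((0, 2)))
    falling = _prob_draws(s2, x2, np.array([-0.3, -0.5]), empty, np.zeros(0),
                          np.zeros((0, 2)))
    assert rising.mean() > falling.mean()


def test_flagged_regimen_prediction_is_refused():
    cohort = _mini_cohort({"A": [0, 1, 0, 1], "B": [1, 0, 1, 0],
                           "Megestrol": [0, 0, 0, 0]})
    d1, d2 = build_design_matrices(cohort, min_regimen_obs=1)
    tiny = SamplerConfig(n_chains=4, n_steps=400, n_burn=150, n_keep=50,
                         n_quad=7, seed=0)
    s1 = fit_stage1(d1, tiny)
    s2 = fit_stage2(d2, s1, tiny, force=True)
    meg = [p for p in d2.patient_ids
           if (d2.regimens[np.array(d2.patient_ids)[d2.patient_idx] == p] ==
               "Megestrol").any()][0]
    with pytest.raises(ValueError, match="Megestrol"):
        predict_pd(s1, s2, cohort, meg, 90.0, config=tiny)


# ----------------------------------------------------------------------
# ROC and temporal validation


def test_auroc_equals_mann_whitney_pair_count():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, 120)
    scores = np.round(rng.uniform(0, 1, 120), 2)  # rounding forces ties
    pos, neg = scores[y == 1], scores[y == 0]
    pairs = sum((1.0 if p > n else 0.5 if p == n else 0.0)
                for p in pos for n in neg)
    expected = pairs / (len(pos) * len(neg))
    assert auroc(y, scores) == pytest.approx(expected, abs=1e-12)


def test_perfectly_separable_predictions_reach_auroc_one():
    y = np.array([0] * 10 + [1] * 10)
    scores = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
    assert auroc(y, scores) == 1.0
    pts = roc_points(y, scores)
    assert pts["sensitivity"].iloc[-1] == 1.0
    assert pts["specificity"].iloc[0] == 1.0


def test_holdout_split_has_no_leakage():
    cohort, _ = simulate_cohort(SimConfig(n_patients=40, seed=31))
    train, held = _holdout_split(cohort)
    for _, h in held.iterrows():
        pid, day = h["patient_id"], h["day"]
        tscans = train.scans[train.scans["patient_id"] == pid]
        assert day not in set(tscans["day"])
        tsamp = train.samples[(train.samples["patient_id"] == pid)
                              & ~train.samples["post_followup"]]
        assert (tsamp["day"] <= h["preceding_scan_day"]).all()
    # every held-out patient had at least 2 scans
    counts = cohort.scans.groupby("patient_id").size()
    assert set(held["patient_id"]) == set(counts[counts >= 2].index)


def test_log_sigmoid_is_stable_at_extremes():
    x = np.array([-800.0, -30.0, 0.0, 30.0, 800.0])
    out = _log_sigmoid(x)
    assert np.all(np.isfinite(out[1:]))
    assert out[0] == pytest.approx(-800.0)
    assert out[2] == pytest.approx(np.log(0.5))
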