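"""Copy-number burden metrics: normalization, QC, z-score, t-MAD, solution
selection and the arcsine transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctdna_monitor import (BinnedProfile, CandidateSolution, PanelOfNormals,
                           Segmentation, arcsine_transform, compute_tmad,
                           compute_zscore, inverse_arcsine_transform,
                           normalize_log2, qc_filter, select_ichorcna_solution,
                           simulate_binned_profiles)
from ctdna_monitor.metrics import read_panel, read_profile, segment_profile, \
    write_panel, write_profile


def _grid(n):
    per = int(np.ceil(n / 23))
    i = np.arange(n)
    return pd.DataFrame({"chromosome": 1 + i // per,
                         "start": (i % per) * 10**6, "end": (i % per + 1) * 10**6})


def _panel(n, median=0.0, mean=0.0, sd=1.0):
    g = _grid(n)
    return PanelOfNormals(bins=g.assign(median=median, mean=mean, sd=sd),
                          n_normals=35)


def _profile(values, reads=2_000_000):
    g = _grid(len(values))
    return BinnedProfile(bins=g.assign(value=np.asarray(values, dtype=float)),
                         scale="log2-ratio", n_aligned_reads=reads)


# ----------------------------------------------------------------------
# normalization


def test_normalize_subtracts_panel_median():
    prof = _profile(np.full(50, 1.4))
    panel = _panel(50, median=0.4)
    out = normalize_log2(prof, panel)
    assert np.allclose(out.values, 1.0)


def test_normalize_panel_member_centres_on_zero():
    cna = np.full(300, 2)
    profile, panel = simulate_binned_profiles(tf=0.0, cna_profile=cna, seed=1)
    out = normalize_log2(profile, panel)
    assert abs(np.median(out.values)) < 0.05


def test_normalize_grid_mismatch_is_error():
    with pytest.raises(ValueError, match="grid"):
        normalize_log2(_profile(np.zeros(40)), _panel(41))


def test_simulated_tumour_signal_sits_in_aberrant_bins():
    cna = np.concatenate([np.full(200, 2), np.full(100, 4)])
    profile, panel = simulate_binned_profiles(tf=0.3, cna_profile=cna, seed=2,
                                              depth=5000)
    out = normalize_log2(profile, panel)
    neutral, gained = out.values[:200], out.values[200:]
    assert np.mean(np.abs(gained)) > 5 * np.mean(np.abs(neutral))


# ----------------------------------------------------------------------
# QC


def test_qc_fails_below_one_million_reads():
    res = qc_filter(_profile(np.zeros(100), reads=999_999))
    assert not res.passed and "low_reads" in res.reasons


def test_qc_zero_noise_profile_passes():
    res = qc_filter(_profile(np.zeros(100)))
    assert res.passed and res.residual_sd == 0.0


def test_qc_fails_on_injected_noise():
    rng = np.random.default_rng(3)
    res = qc_filter(_profile(rng.normal(0, 0.5, 400)), max_noise=0.3)
    assert not res.passed and "noise" in res.reasons


# ----------------------------------------------------------------------
# z-score


def test_zscore_zero_when_profile_equals_panel_mean():
    prof = _profile(np.full(60, 0.8))
    panel = _panel(60, mean=0.8, sd=0.5)
    assert compute_zscore(prof, panel, "absolute", 0.0) == pytest.approx(0.0)


def test_zscore_unit_construction():
    prof = _profile(np.full(60, 1.0))
    panel = _panel(60, mean=0.0, sd=1.0)
    assert compute_zscore(prof, panel, "absolute", 0.5) == pytest.approx(1.0)


def test_zscore_literal_filter_empties_near_diploid_profile():
    prof = _profile(np.random.default_rng(0).normal(0, 0.05, 200))
    panel = _panel(200, sd=0.05)
    with pytest.raises(ValueError, match="empty profile"):
        compute_zscore(prof, panel, "literal", 2.0)


def test_zscore_increases_along_tumour_fraction_grid():
    cna = np.array([1, 3, 4, 2] * 125)
    zs = []
    for tf in (0.0, 0.05, 0.1, 0.2, 0.4):
        profile, panel = simulate_binned_profiles(tf=tf, cna_profile=cna, seed=9,
                                                  depth=2000)
        norm = normalize_log2(profile, panel)
        zs.append(abs(compute_zscore(norm, panel, "absolute", 0.0)))
    assert all(b > a for a, b in zip(zs, zs[1:]))


def test_zscore_null_mean_near_zero_over_replicates():
    cna = np.full(300, 2)
    zs = []
    for rep in range(200):
        profile, panel = simulate_binned_profiles(tf=0.0, cna_profile=cna,
                                                  seed=5000 + rep)
        norm = normalize_log2(profile, panel)
        zs.append(compute_zscore(norm, panel, "absolute", 0.0))
    assert -0.1 < np.mean(zs) < 0.1


def test_zscore_invariant_to_bin_permutation_within_chromosome():
    rng = np.random.default_rng(11)
    values = rng.normal(0, 1, 92)
    prof = _profile(values)
    panel = _panel(92, sd=0.7)
    z0 = compute_zscore(prof, panel, "absolute", 0.0)
    # permute bins jointly (profile + panel rows) within each chromosome
    order = np.concatenate([
        rng.permutation(np.flatnonzero(prof.bins["chromosome"] == c))
        for c in sorted(prof.bins["chromosome"].unique())])
    prof2 = BinnedProfile(bins=prof.bins.iloc[order], scale="log2-ratio",
                          n_aligned_reads=prof.n_aligned_reads)
    panel2 = PanelOfNormals(bins=panel.bins.iloc[order], n_normals=35)
    assert compute_zscore(prof2, panel2, "absolute", 0.0) == pytest.approx(z0)


# ----------------------------------------------------------------------
# t-MAD


def _seg_all(n, mean=0.0):
    return Segmentation(pd.DataFrame({"chromosome": [1], "start_bin": [0],
                                      "end_bin": [n - 1], "mean": [mean]}))


def test_tmad_zero_profile():
    assert compute_tmad(_seg_all(50), np.zeros(50)) == 0.0


def test_tmad_constant_offset_is_absolute_deviation():
    assert compute_tmad(_seg_all(50), np.full(50, 0.37)) == pytest.approx(0.37)
    assert compute_tmad(_seg_all(50), np.full(50, -0.2)) == pytest.approx(0.2)


def test_tmad_nondecreasing_along_tf_grid():
    cna = np.array([1, 3, 4, 2] * 125)
    vals = []
    for tf in (0.0, 0.1, 0.2, 0.4):
        profile, panel = simulate_binned_profiles(tf=tf, cna_profile=cna, seed=8,
                                                  depth=2000)
        norm = normalize_log2(profile, panel)
        seg = segment_profile(norm.values, norm.bins["chromosome"].to_numpy())
        vals.append(compute_tmad(seg, norm.values))
    assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
    assert vals[-1] > vals[0]


def test_tmad_empty_segmentation_is_error():
    with pytest.raises(ValueError, match="empty segmentation"):
        compute_tmad(Segmentation(pd.DataFrame(
            columns=["chromosome", "start_bin", "end_bin", "mean"])), np.ones(5))


# ----------------------------------------------------------------------
# ichorCNA solution selection


def _cand(ll, tf, sc):
    return CandidateSolution(log_likelihood=ll, tumour_fraction=tf,
                             subclonal_fraction=sc)


def test_single_candidate_is_returned():
    c = _cand(-10.0, 0.1, 0.0)
    assert select_ichorcna_solution([c]) is c
    assert select_ichorcna_solution([c], mode="literal") is c


def test_interpreted_mode_prefers_less_subclonal_solution():
    high_sub = _cand(-100.0, 0.30, 0.9)
    low_sub = _cand(-100.0, 0.12, 0.0)
    chosen = select_ichorcna_solution([high_sub, low_sub], mode="interpreted")
    assert chosen is low_sub


def test_literal_mode_follows_printed_steps():
    # step 2 as printed removes every solution within 2.5% of the maximum,
    # including the maximum itself; the survivors are the clearly worse fits
    best = _cand(-100.0, 0.3, 0.8)
    worse = _cand(-110.0, 0.1, 0.1)
    worst = _cand(-150.0, 0.05, 0.0)
    assert select_ichorcna_solution([best, worse, worst], mode="literal") is worse
    # with a single candidate everything is filtered; falls back to the max
    assert select_ichorcna_solution([best], mode="literal") is best


def test_empty_candidate_list_is_error():
    with pytest.raises(ValueError, match="empty"):
        select_ichorcna_solution([])


solution_lists = st.lists(
    st.tuples(st.floats(-1e4, -1.0), st.floats(0, 1), st.floats(0, 1)),
    min_size=1, max_size=6)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(solution_lists, st.sampled_from(["literal", "interpreted"]))
def test_selection_is_closed_and_deterministic(raw, mode):
    cands = [_cand(*t) for t in raw]
    first = select_ichorcna_solution(cands, mode=mode)
    assert first in cands
    assert select_ichorcna_solution(cands, mode=mode) is first


@settings(deadline=None, max_examples=200, derandomize=True)
@given(solution_lists, st.floats(0.0, 0.5), st.floats(0.0, 1.0))
def test_dominated_candidate_never_changes_interpreted_choice(raw, dll, dsc):
    cands = [_cand(*t) for t in raw]
    chosen = select_ichorcna_solution(cands, mode="interpreted")
    dominated = _cand(chosen.log_likelihood - dll - 1e-6, chosen.tumour_fraction,
                      min(1.0, chosen.subclonal_fraction + dsc + 1e-6))
    again = select_ichorcna_solution(cands + [dominated], mode="interpreted")
    assert (again.log_likelihood, again.subclonal_fraction) == \
        (chosen.log_likelihood, chosen.subclonal_fraction)


# ----------------------------------------------------------------------
# arcsine transform


def test_arcsine_endpoints_and_roundtrip():
    assert arcsine_transform(0.0) == 0.0
    assert arcsine_transform(1.0) == pytest.approx(np.pi / 2)
    assert inverse_arcsine_transform(arcsine_transform(0.07)) == pytest.approx(
        0.07, abs=1e-12)
    with pytest.raises(ValueError):
        arcsine_transform(1.2)
    grid = np.linspace(0, 1, 50)
    assert np.all(np.diff(arcsine_transform(grid)) > 0)


# ----------------------------------------------------------------------
# profile I/O


def test_profile_and_panel_round_trip(tmp_path):
    cna = np.array([2, 3, 2, 1] * 25)
    profile, panel = simulate_binned_profiles(tf=0.2, cna_profile=cna, seed=6)
    write_profile(profile, str(tmp_path / "s.bed"))
    write_panel(panel, str(tmp_path / "p.bed"))
    p2 = read_profile(str(tmp_path / "s.bed"))
    n2 = read_panel(str(tmp_path / "p.bed"))
    assert np.allclose(p2.values, profile.values)
    assert p2.n_aligned_reads == profile.n_aligned_reads
    assert np.allclose(n2.bins["median"], panel.bins["median"])
    assert n2.n_normals == 35
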