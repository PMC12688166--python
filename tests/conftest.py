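"""Shared fixtures: synthetic cohorts and small pre-fitted Bayesian stages."""

import logging

import numpy as np
import pandas as pd
import pytest

from ctdna_monitor import Cohort, SimConfig, simulate_cohort
from ctdna_monitor.bayml import (SamplerConfig, build_design_matrices,
                                 fit_stage1, fit_stage2)

logging.getLogger("ctdna_monitor").setLevel(logging.ERROR)


#: reduced sampler settings used throughout the suite (documented problem sizes)
FAST_SAMPLER = SamplerConfig(n_chains=4, n_steps=1200, n_burn=400,
                             n_keep=300, n_quad=11, seed=0)


@pytest.fixture(scope="session")
def sim_cohort():
    """Default study-condition cohort (143 patients)."""
    cohort, truth = simulate_cohort(SimConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def small_fits():
    """An 80-patient cohort with both Bayesian stages fitted (reduced draws)."""
    cohort, truth = simulate_cohort(SimConfig(n_patients=80, seed=21))
    d1, d2 = build_design_matrices(cohort)
    s1 = fit_stage1(d1, FAST_SAMPLER)
    s2 = fit_stage2(d2, s1, FAST_SAMPLER, force=True)
    return cohort, truth, d1, d2, s1, s2


def make_toy_cohort(align: bool = False) -> Cohort:
    """Two patients with hand-written raw (unaligned) days."""
    patients = pd.DataFrame({
        "patient_id": ["P1", "P2"],
        "er_status": [1, 0],
        "her2_status": [0, 1],
        "death_day": [400.0, np.nan],
        "death_event": [1, 0],
    })
    treatments = pd.DataFrame({
        "patient_id": ["P1", "P1", "P2"],
        "regimen": ["Letrozole", "Paclitaxel", "Trastuzumab"],
        "treatment_class": ["endocrine", "chemotherapy", "targeted"],
        "start_day": [90.0, 200.0, 40.0],
        "end_day": [200.0, np.nan, np.nan],
    })
    samples = pd.DataFrame({
        "patient_id": ["P1", "P1", "P1", "P2", "P2", "P2"],
        "day": [80.0, 150.0, 260.0, 50.0, 120.0, 400.0],
        "tumour_fraction": [0.02, 0.10, 0.30, 0.05, 0.08, 0.12],
        "ca15_3": [20.0, 35.0, 60.0, 25.0, 28.0, 40.0],
        "max_vaf": [0.01, 0.04, 0.20, 0.02, 0.03, 0.06],
    })
    scans = pd.DataFrame({
        "patient_id": ["P1", "P1", "P2", "P2"],
        "day": [100.0, 200.0, 60.0, 300.0],
        "progression": [0, 1, 0, 0],
        "response_category": ["SD", "PD", "PR", "SD"],
    })
    cohort = Cohort(patients=patients, treatments=treatments,
                    samples=samples, scans=scans)
    if align:
        from ctdna_monitor import align_times
        cohort = align_times(cohort)
    return cohort
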