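"""The threshold stopping rule: predicting the next CT result from ctDNA alone.

A decision point pairs a plasma sample with the next CT scan on the same
treatment, restricted to clinically actionable windows: both must fall
between 3 weeks and 6 months after the treatment started, and the sample must
not precede the scan by more than 3 months. The rule then predicts the scan:

* response  -- score below the threshold, or at/above it but decreased from
  the previous same-treatment sample;
* progression -- score at/above the threshold and increased (or unchanged)
  from the previous sample; with no previous sample available, a score
  at/above the threshold alone predicts progression.

Sensitivity/specificity are scored against the RECIST progression flag of the
paired scan.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

WINDOW_START_DAYS = 21     # 3 weeks
WINDOW_END_DAYS = 183      # 6 months
MAX_SAMPLE_LEAD_DAYS = 91  # 3 months


@dataclasses.dataclass
class DecisionPoint:
    patient_id: str
    regimen: str
    treatment_start: float
    sample_day: float
    scan_day: float
    score: float                     # tumour fraction in [0, 1]
    previous_score: float | None     # latest prior same-treatment sample
    truth: int                       # RECIST progression flag of the scan
    same_day: bool = False
    prediction: str | None = None    # "progression" | "response"


def select_decision_points(cohort: Cohort,
                           window_start_days: float = WINDOW_START_DAYS,
                           window_end_days: float = WINDOW_END_DAYS,
                           max_sample_lead_days: float = MAX_SAMPLE_LEAD_DAYS,
                           ) -> list[DecisionPoint]:
    """All (sample, next-scan) pairs satisfying the three window constraints.

    Each eligible sample generates its own decision point (several samples may
    point to the same scan). Same-day sample/scan pairs are kept but flagged.
    Output order is deterministic: by patient, treatment start, sample day.
    """
    points: list[DecisionPoint] = []
    samples = cohort.samples.sort_values(["patient_id", "day"])
    scans = cohort.scans.sort_values(["patient_id", "day"])
    samples_by_pid = dict(tuple(samples.groupby("patient_id")))
    scans_by_pid = dict(tuple(scans.groupby("patient_id")))
    treatments = cohort.treatments.sort_values(["patient_id", "start_day"])

    for _, trt in treatments.iterrows():
        pid = trt["patient_id"]
        t0 = trt["start_day"]
        t_end = trt["end_day"] if pd.notna(trt["end_day"]) else np.inf
        lo, hi = t0 + window_start_days, t0 + window_end_days
        samp = samples_by_pid.get(pid)
        scan = scans_by_pid.get(pid)
        if samp is None or scan is None:
            continue
        in_window = samp[(samp["day"] >= lo) & (samp["day"] <= hi) & (samp["day"] < t_end)]
        for _, srow in in_window.iterrows():
            s_day = float(srow["day"])
            nxt = scan[(scan["day"] >= s_day) & (scan["day"] >= lo)
                       & (scan["day"] <= hi) & (scan["day"] < t_end)]
            if nxt.empty:
                continue
            crow = nxt.iloc[0]
            if float(crow["day"]) - s_day > max_sample_lead_days:
                continue
            prior = samp[(samp["day"] < s_day) & (samp["day"] >= t0)]
            prev = float(prior.iloc[-1]["tumour_fraction"]) if len(prior) else None
            points.append(DecisionPoint(
                patient_id=pid, regimen=str(trt["regimen"]), treatment_start=float(t0),
                sample_day=s_day, scan_day=float(crow["day"]),
                score=float(srow["tumour_fraction"]), previous_score=prev,
                truth=int(crow["progression"]), same_day=float(crow["day"]) == s_day,
            ))
    points.sort(key=lambda p: (p.patient_id, p.treatment_start, p.sample_day, p.scan_day))
    return points


def apply_stopping_rule(dp: DecisionPoint, threshold: float = 0.07) -> str:
    """Deterministic prediction for one decision point.

    Below the threshold predicts response; at/above it, a strict decrease from
    the previous same-treatment score predicts response, otherwise (increase,
    no change, or no previous score) progression.
    """
    if dp.score < threshold:
        return "response"
    if dp.previous_score is not None and dp.score < dp.previous_score:
        return "response"
    return "progression"


@dataclasses.dataclass
class StoppingRuleResult:
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_points: int
    n_patients: int
    n_treatments: int
    lead_time_days: dict[str, float]   # median sample->scan gap by decision/concordance
    sensitivity_defined: bool = True


def evaluate_stopping_rule(points: Sequence[DecisionPoint],
                           threshold: float = 0.07) -> StoppingRuleResult:
    """Confusion counts, sensitivity/specificity and lead-time medians.

    PD is the positive class: sensitivity = TP/(TP+FN) over truly progressive
    scans, specificity = TN/(TN+FP). Lead times are the days between the
    plasma sample and its paired scan, split by predicted decision and whether
    it agreed with the scan.
    """
    tp = fp = tn = fn = 0
    gaps: dict[str, list[float]] = {"stop_concordant": [], "stop_discordant": [],
                                    "continue_concordant": [], "continue_discordant": []}
    for dp in points:
        dp.prediction = apply_stopping_rule(dp, threshold)
        gap = dp.scan_day - dp.sample_day
        pred_pd = dp.prediction == "progression"
        if pred_pd and dp.truth == 1:
            tp += 1
            gaps["stop_concordant"].append(gap)
        elif pred_pd and dp.truth == 0:
            fp += 1
            gaps["stop_discordant"].append(gap)
        elif not pred_pd and dp.truth == 0:
            tn += 1
            gaps["continue_concordant"].append(gap)
        else:
            fn += 1
            gaps["continue_discordant"].append(gap)
    sens_defined = (tp + fn) > 0
    return StoppingRuleResult(
        sensitivity=tp / (tp + fn) if sens_defined else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_points=len(points),
        n_patients=len({dp.patient_id for dp in points}),
        n_treatments=len({(dp.patient_id, dp.treatment_start) for dp in points}),
        lead_time_days={k: float(np.median(v)) if v else float("nan")
                        for k, v in gaps.items()},
        sensitivity_defined=sens_defined,
    )


def decision_points_table(points: Sequence[DecisionPoint]) -> pd.DataFrame:
    """Decision points as a flat table for export / cross-checking."""
    return pd.DataFrame([dataclasses.asdict(dp) for dp in points])
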