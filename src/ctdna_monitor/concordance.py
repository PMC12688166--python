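"""Comparative analyses across tumour-burden measures.

The ichorCNA tumour fraction, serum CA15-3 and the targeted-panel maximum VAF
are measured on different schedules; comparisons interpolate each series
linearly onto the union of observation days inside the overlap window of both
series (no extrapolation) before computing per-patient Pearson correlations,
and pair near-in-time measurements for threshold-concordance rates. A
discordance audit lists the decision points where ctDNA disagreed with the
RECIST call and asks whether progression appeared on the subsequent scan
(early detection by ctDNA, with its lead time).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .stopping import DecisionPoint, apply_stopping_rule

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

#: default positivity thresholds per metric
DEFAULT_THRESHOLDS = {"tumour_fraction": 0.07, "max_vaf": 0.025, "ca15_3": 31.0}


def _series(cohort: Cohort, patient_id: str, metric: str) -> pd.DataFrame:
    s = cohort.samples
    rows = s[(s["patient_id"] == patient_id) & s[metric].notna()]
    return rows.sort_values("day")[["day", metric]]


@dataclasses.dataclass
class CorrelationResult:
    per_patient: dict[str, float]
    mean: float
    n_excluded: int


def interpolate_and_correlate(cohort: Cohort, metric_a: str = "tumour_fraction",
                              metric_b: str = "ca15_3",
                              min_points: int = 3) -> CorrelationResult:
    """Per-patient Pearson correlation between two interpolated series.

    Both series are linearly interpolated onto the union of their observation
    days restricted to the overlap of the two spans. Patients with fewer than
    ``min_points`` common grid points, or a zero-variance series, are
    excluded (counted).
    """
    per_patient: dict[str, float] = {}
    excluded = 0
    for pid in cohort.patient_ids():
        a = _series(cohort, pid, metric_a)
        b = _series(cohort, pid, metric_b)
        if a.empty or b.empty:
            continue
        lo = max(a["day"].min(), b["day"].min())
        hi = min(a["day"].max(), b["day"].max())
        grid = np.union1d(a["day"].to_numpy(), b["day"].to_numpy())
        grid = grid[(grid >= lo) & (grid <= hi)]
        if len(grid) < min_points:
            excluded += 1
            continue
        va = np.interp(grid, a["day"], a[metric_a])
        vb = np.interp(grid, b["day"], b[metric_b])
        def _constant(v):
            return np.std(v) <= 1e-10 * max(1.0, float(np.max(np.abs(v))))

        if _constant(va) or _constant(vb):
            excluded += 1
            logger.info("patient %s excluded: zero-variance series", pid)
            continue
        per_patient[pid] = float(stats.pearsonr(va, vb)[0])
    mean = float(np.mean(list(per_patient.values()))) if per_patient else float("nan")
    return CorrelationResult(per_patient=per_patient, mean=mean, n_excluded=excluded)


@dataclasses.dataclass
class ConcordanceResult:
    percent_agreement: float
    table: pd.DataFrame      # 2x2: rows metric A +/-, columns metric B +/-
    n_pairs: int


def threshold_concordance(cohort: Cohort, metric_a: str = "max_vaf",
                          metric_b: str = "tumour_fraction",
                          thresholds: dict | None = None,
                          pairing_window_days: float = 14.0) -> ConcordanceResult:
    """Percent of paired measurements on the same side of their thresholds.

    Measurements on the same row pair directly; otherwise each metric-A
    observation pairs with the nearest same-patient metric-B observation
    within the pairing window.
    """
    thr = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    pairs = []
    for pid in cohort.patient_ids():
        a = _series(cohort, pid, metric_a)
        b = _series(cohort, pid, metric_b)
        if a.empty or b.empty:
            continue
        b_days = b["day"].to_numpy(dtype=float)
        b_vals = b[metric_b].to_numpy(dtype=float)
        for _, row in a.iterrows():
            gaps = np.abs(b_days - float(row["day"]))
            j = int(np.argmin(gaps))
            if gaps[j] <= pairing_window_days:
                pairs.append((float(row[metric_a]), b_vals[j]))
    if not pairs:
        return ConcordanceResult(percent_agreement=float("nan"),
                                 table=pd.DataFrame(), n_pairs=0)
    va, vb = np.array(pairs).T
    pa, pb = va >= thr[metric_a], vb >= thr[metric_b]
    table = pd.DataFrame(
        [[int(np.sum(pa & pb)), int(np.sum(pa & ~pb))],
         [int(np.sum(~pa & pb)), int(np.sum(~pa & ~pb))]],
        index=[f"{metric_a}+", f"{metric_a}-"],
        columns=[f"{metric_b}+", f"{metric_b}-"],
    )
    agreement = float(np.mean(pa == pb) * 100)
    return ConcordanceResult(percent_agreement=agreement, table=table,
                             n_pairs=len(pairs))


@dataclasses.dataclass
class DiscordanceReport:
    high_score_stable: pd.DataFrame   # ctDNA said progression, scan said SD
    missed_progression: pd.DataFrame  # scan said PD, ctDNA said response
    n_high_score_stable: int
    n_early_detection: int            # of those, PD on the subsequent scan
    n_missed: int
    median_lead_months: float


def discordance_report(cohort: Cohort, points: list[DecisionPoint],
                       threshold: float = 0.07) -> DiscordanceReport:
    """Audit of decision points where ctDNA and RECIST disagreed.

    High-score/stable-disease instances are annotated with whether the
    *subsequent* CT showed progression (early detection) and the lead time in
    months from the stable scan to that progression scan.
    """
    scans = cohort.scans.sort_values(["patient_id", "day"])
    scans_by_pid = dict(tuple(scans.groupby("patient_id")))
    high_rows, missed_rows = [], []
    for dp in points:
        pred = apply_stopping_rule(dp, threshold)
        if pred == "progression" and dp.truth == 0:
            nxt = scans_by_pid.get(dp.patient_id)
            nxt = nxt[nxt["day"] > dp.scan_day] if nxt is not None else None
            subsequent_pd = bool(len(nxt)) and int(nxt.iloc[0]["progression"]) == 1
            lead = (float(nxt.iloc[0]["day"]) - dp.scan_day) / DAYS_PER_MONTH \
                if subsequent_pd else float("nan")
            high_rows.append({
                "patient_id": dp.patient_id, "sample_day": dp.sample_day,
                "scan_day": dp.scan_day, "score": dp.score,
                "subsequent_pd": subsequent_pd, "lead_months": lead,
            })
        elif pred == "response" and dp.truth == 1:
            missed_rows.append({
                "patient_id": dp.patient_id, "sample_day": dp.sample_day,
                "scan_day": dp.scan_day, "score": dp.score,
                "previous_score": dp.previous_score,
            })
    high = pd.DataFrame(high_rows)
    missed = pd.DataFrame(missed_rows)
    leads = high["lead_months"].dropna() if "lead_months" in high.columns else pd.Series(dtype=float)
    return DiscordanceReport(
        high_score_stable=high, missed_progression=missed,
        n_high_score_stable=len(high),
        n_early_detection=int(high["subsequent_pd"].sum()) if len(high) else 0,
        n_missed=len(missed),
        median_lead_months=float(leads.median()) if len(leads) else float("nan"),
    )
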