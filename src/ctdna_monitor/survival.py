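"""Time-dependent Cox modelling of progression and survival from ctDNA scores.

Longitudinal tumour-fraction scores enter the Cox model as a time-varying
covariate in counting-process form: each patient contributes (start, stop]
intervals carrying the last observed score (LOCF), with the event indicator
set on the final interval. Scores are modelled in percent units (0-100) so a
hazard ratio is "per percentage point of tumour fraction".

The risk threshold is discovered by fitting the score with a restricted cubic
spline, extracting the fitted log-hazard as a function of the score, and
fitting a two-slope continuous segmented regression to it; the breakpoint is
the changepoint. Repeating this over random 70-patient subsamples and
averaging gives the working threshold (rounded up to the next integer
percent, since the upstream tumour-fraction estimates are reported without
decimals), which is then validated on the held-out patients of each replicate.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

from .cohort import Cohort

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44
SUBTYPE_DUMMIES = ("Her2+", "TN")  # reference level: ER+Her2-


# ----------------------------------------------------------------------
# counting-process construction


def _endpoint_day(patient_row, scans: pd.DataFrame, endpoint: str):
    """(event_day, event_indicator) for one patient, or None when undefined."""
    if endpoint == "PFS":
        if scans.empty:
            return None
        pd_scans = scans[scans["progression"] == 1]
        if len(pd_scans):
            return float(pd_scans["day"].min()), 1
        return float(scans["day"].max()), 0
    if endpoint == "OS":
        day = patient_row.get("death_day")
        if pd.isna(day):
            return None
        return float(day), int(patient_row.get("death_event") or 0)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def build_counting_process(cohort: Cohort, endpoint: Literal["PFS", "OS"] = "PFS",
                           score_carry: Literal["locf"] = "locf") -> pd.DataFrame:
    """One (start, stop, event, score) row per inter-sample interval.

    The score (percent) observed at each plasma sample is carried forward
    until the next sample; intervals are truncated at the event/censoring day.
    Patients with no sample strictly before the event day are excluded (their
    count is logged). Subtype indicator columns (reference ER+Her2-) and the
    patient's ER/Her2 status ride along for model formulas.
    """
    if score_carry != "locf":
        raise ValueError("only last-observation-carried-forward is implemented")
    rows = []
    skipped = 0
    patients = cohort.patients.set_index("patient_id")
    samples_by_pid = dict(tuple(cohort.samples.groupby("patient_id")))
    scans_by_pid = dict(tuple(cohort.scans.groupby("patient_id")))
    for pid, prow in patients.iterrows():
        scans = scans_by_pid.get(pid, pd.DataFrame(columns=cohort.scans.columns))
        out = _endpoint_day(prow, scans, endpoint)
        if out is None:
            continue
        event_day, event = out
        samp = samples_by_pid.get(pid)
        if samp is None:
            skipped += 1
            continue
        samp = samp.sort_values("day")
        days = samp["day"].to_numpy(dtype=float)
        scores = samp["tumour_fraction"].to_numpy(dtype=float) * 100.0
        keep = days < event_day
        if not keep.any():
            skipped += 1
            continue
        days, scores = days[keep], scores[keep]
        bounds = np.append(days, event_day)
        subtype = prow.get("subtype")
        for j in range(len(days)):
            start, stop = bounds[j], bounds[j + 1]
            if stop <= start:
                continue
            rows.append({
                "patient_id": pid, "start": start, "stop": stop,
                "event": event if j == len(days) - 1 else 0,
                "score": scores[j],
                "subtype": subtype,
                "her2_pos": 1.0 if subtype == "Her2+" else 0.0,
                "tn": 1.0 if subtype == "TN" else 0.0,
            })
    if skipped:
        logger.info("%s counting process: %d patients without a pre-event sample excluded",
                    endpoint, skipped)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# restricted cubic spline basis (Harrell convention)


def rcs_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Knots at the conventional outer/inner quantiles of the observed scores."""
    qs = {3: (0.10, 0.50, 0.90),
          4: (0.05, 0.35, 0.65, 0.95),
          5: (0.05, 0.275, 0.50, 0.725, 0.95)}[n_knots]
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    if len(np.unique(knots)) < n_knots:
        raise ValueError("degenerate score distribution: duplicate spline knots")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear term plus k-2 curvature terms.

    Tails beyond the outer knots are linear; the cubic terms use the usual
    normalisation by the outer-knot span squared.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    span2 = (t[-1] - t[0]) ** 2
    cols = [x]

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    for j in range(k - 2):
        term = (pos3(x - t[j])
                - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(term / span2)
    return np.column_stack(cols)


# ----------------------------------------------------------------------
# Harrell's c-index on counting-process rows


def concordance_index_td(rows: pd.DataFrame, risk: np.ndarray) -> tuple[float, float]:
    """Harrell's c for time-varying data: for every event at its stop time,
    compare its risk score against all intervals at risk at that moment.

    Returns (c, SE) with a normal-approximation standard error based on the
    number of events.
    """
    start = rows["start"].to_numpy(dtype=float)
    stop = rows["stop"].to_numpy(dtype=float)
    event = rows["event"].to_numpy(dtype=int)
    risk = np.asarray(risk, dtype=float)
    conc = disc = ties = 0
    for i in np.flatnonzero(event == 1):
        t = stop[i]
        at_risk = (start < t) & (t <= stop) & ~((stop == t) & (event == 1))
        r = risk[at_risk]
        conc += int(np.sum(risk[i] > r))
        disc += int(np.sum(risk[i] < r))
        ties += int(np.sum(risk[i] == r))
    total = conc + disc + ties
    if total == 0:
        return float("nan"), float("nan")
    c = (conc + 0.5 * ties) / total
    n_events = int(event.sum())
    se = float(np.sqrt(c * (1 - c) / max(n_events, 1)))
    return float(c), se


# ----------------------------------------------------------------------
# Cox fits


@dataclasses.dataclass
class CoxFit:
    """Fitted time-dependent Cox model with discrimination and baseline hazard."""

    summary: pd.DataFrame          # coef, se, hr, hr_lower, hr_upper per covariate
    log_likelihood: float
    c_index: float
    c_index_se: float
    baseline_cumulative_hazard: pd.DataFrame  # columns: time, cumhaz (all-zero covariates)
    formula: str
    rows: pd.DataFrame | None = None
    spline_knots: np.ndarray | None = None
    linear_predictor: np.ndarray | None = None

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def is_degenerate(self, covariate: str, max_abs_coef: float = 10.0) -> bool:
        """Monotone-likelihood heuristic: a separated binary covariate drifts
        to an unbounded coefficient with a huge standard error."""
        row = self.summary.loc[covariate]
        return bool(abs(row["coef"]) > max_abs_coef or row["se"] > max_abs_coef
                    or not np.isfinite(row["coef"]) or not np.isfinite(row["se"]))

    def score_log_hazard(self, scores: np.ndarray) -> np.ndarray:
        """Fitted log-hazard contribution of the score at the given values
        (spline formula only)."""
        if self.spline_knots is None:
            raise ValueError("score_log_hazard requires a spline formula fit")
        basis = rcs_basis(np.asarray(scores, dtype=float), self.spline_knots)
        coefs = self.summary["coef"].to_numpy()[: basis.shape[1]]
        return basis @ coefs


def _breslow_baseline(rows: pd.DataFrame, lp: np.ndarray) -> pd.DataFrame:
    """Breslow estimator of the cumulative baseline hazard at zero covariates."""
    start = rows["start"].to_numpy(dtype=float)
    stop = rows["stop"].to_numpy(dtype=float)
    event = rows["event"].to_numpy(dtype=int)
    # centre the linear predictor for numerical stability, rescale afterwards
    shift = float(np.median(lp))
    exp_lp = np.exp(np.clip(lp - shift, -700, 700))
    times = np.sort(np.unique(stop[event == 1]))
    cumhaz = []
    total = 0.0
    for t in times:
        d = int(np.sum((stop == t) & (event == 1)))
        denom = float(np.sum(exp_lp[(start < t) & (t <= stop)]))
        total += d / max(denom, 1e-300)
        cumhaz.append(total * np.exp(-shift))
    return pd.DataFrame({"time": times, "cumhaz": cumhaz})


def fit_td_cox(rows: pd.DataFrame,
               formula: Literal["score", "score+subtype", "spline+subtype",
                                "threshold", "threshold+subtype"] = "score",
               threshold: float = 7.0, n_knots: int = 4,
               extra_covariates: Sequence[str] = ()) -> CoxFit:
    """Maximum partial likelihood (Efron ties) on counting-process rows.

    ``formula`` selects how the percent score enters: linear, restricted cubic
    spline (knots at score quantiles), or a >= ``threshold`` indicator;
    ``+subtype`` adds Her2+/TN indicators (reference ER+Her2-).
    """
    if rows.empty or rows["event"].sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")
    df = pd.DataFrame({
        "patient_id": rows["patient_id"].to_numpy(),
        "start": rows["start"].to_numpy(dtype=float),
        "stop": rows["stop"].to_numpy(dtype=float),
        "event": rows["event"].to_numpy(dtype=int),
    })
    knots = None
    base, with_subtype = formula, False
    if formula.endswith("+subtype"):
        base, with_subtype = formula[: -len("+subtype")], True
    if base == "score":
        df["score"] = rows["score"].to_numpy(dtype=float)
        covs = ["score"]
    elif base == "spline":
        knots = rcs_knots(rows["score"].to_numpy(dtype=float), n_knots)
        basis = rcs_basis(rows["score"].to_numpy(dtype=float), knots)
        covs = [f"score_rcs{j}" for j in range(basis.shape[1])]
        for j, name in enumerate(covs):
            df[name] = basis[:, j]
    elif base == "threshold":
        df["score_high"] = (rows["score"].to_numpy(dtype=float) >= threshold).astype(float)
        covs = ["score_high"]
    else:
        raise ValueError(f"unknown formula {formula!r}")
    if with_subtype:
        for col, name in (("her2_pos", "her2_pos"), ("tn", "tn")):
            vals = rows[col].to_numpy(dtype=float)
            if np.ptp(vals) > 0:  # skip constant (collinear) indicator
                df[name] = vals
                covs.append(name)
    for col in extra_covariates:
        df[col] = rows[col].to_numpy(dtype=float)
        covs.append(col)

    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(df[["patient_id", "start", "stop", "event"] + covs],
                id_col="patient_id", event_col="event",
                start_col="start", stop_col="stop")
    with np.errstate(over="ignore"):
        summary = pd.DataFrame({
            "coef": ctv.params_,
            "se": ctv.standard_errors_,
            "hr": np.exp(ctv.params_),
            "hr_lower": np.exp(ctv.params_ - 1.959964 * ctv.standard_errors_),
            "hr_upper": np.exp(ctv.params_ + 1.959964 * ctv.standard_errors_),
        })
    lp = (df[covs].to_numpy(dtype=float) @ ctv.params_.to_numpy())
    c, c_se = concordance_index_td(df, lp)
    return CoxFit(
        summary=summary,
        log_likelihood=float(ctv.log_likelihood_),
        c_index=c, c_index_se=c_se,
        baseline_cumulative_hazard=_breslow_baseline(df, lp),
        formula=formula,
        rows=rows,
        spline_knots=knots,
        linear_predictor=lp,
    )


# ----------------------------------------------------------------------
# segmented (two-slope) regression changepoint


@dataclasses.dataclass
class SegmentedFit:
    breakpoint: float
    intercept: float
    slope_low: float
    slope_change: float
    rss: float
    degenerate: bool = False

    @property
    def slope_high(self) -> float:
        return self.slope_low + self.slope_change


def segmented_changepoint(x: np.ndarray, y: np.ndarray,
                          min_points_per_side: int = 2) -> SegmentedFit:
    """Single-breakpoint continuous two-slope least-squares fit.

    Grid-searches every observed interior ``x`` value as a candidate
    breakpoint ``c``, solving the least-squares problem in the basis
    ``(1, x, (x - c)_+)`` and keeping the candidate with minimal residual sum
    of squares. Degenerate (collinear) input -- a pure straight line -- sets
    the ``degenerate`` flag and returns the midpoint of the x range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < 5:
        raise ValueError("need at least 5 grid points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x values must be strictly increasing (aggregate duplicates first)")

    # straight-line reference fit
    line_coef, line_rss, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), y,
                                              rcond=None)
    line_rss = float(line_rss[0]) if np.size(line_rss) else float(
        np.sum((y - np.column_stack([np.ones_like(x), x]) @ line_coef) ** 2))

    best = None
    for c in x[min_points_per_side: len(x) - min_points_per_side]:
        design = np.column_stack([np.ones_like(x), x, np.clip(x - c, 0.0, None)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((design @ coef - y) ** 2))
        if best is None or rss < best.rss - 1e-15:
            best = SegmentedFit(breakpoint=float(c), intercept=float(coef[0]),
                                slope_low=float(coef[1]), slope_change=float(coef[2]),
                                rss=rss)
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    if best is None or (line_rss - best.rss) / scale < 1e-9:
        mid = float(0.5 * (x[0] + x[-1]))
        return SegmentedFit(breakpoint=mid, intercept=float(line_coef[0]),
                            slope_low=float(line_coef[1]), slope_change=0.0,
                            rss=line_rss, degenerate=True)
    return best


def _fitted_score_curve(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation fitted spline log-hazard, aggregated by unique score."""
    scores = fit.rows["score"].to_numpy(dtype=float)
    fitted = fit.score_log_hazard(scores)
    df = pd.DataFrame({"score": scores, "fitted": fitted}).groupby("score", as_index=False).mean()
    return df["score"].to_numpy(), df["fitted"].to_numpy()


# ----------------------------------------------------------------------
# threshold discovery


@dataclasses.dataclass
class ThresholdDiscoveryResult:
    changepoints: np.ndarray        # percent scale, one per replicate
    mean_changepoint: float         # percent
    threshold: float                # percent, ceiling to next integer
    holdout_hrs: np.ndarray
    holdout_cindices: np.ndarray
    mean_holdout_hr: float
    median_holdout_cindex: float
    n_train: int
    reps: int


def discover_threshold(cohort: Cohort, n_train: int = 70, reps: int = 50,
                       seed: int = 0, n_knots: int = 4,
                       max_redraws: int = 200) -> ThresholdDiscoveryResult:
    """Resampled spline-Cox changepoint discovery plus held-out validation.

    Each replicate: sample ``n_train`` eligible patients without replacement,
    fit the spline+subtype time-dependent Cox model on them, run the segmented
    regression on the fitted score curve, and record the breakpoint. The
    working threshold is the smallest integer percent at or above the mean
    breakpoint. A second pass evaluates that threshold's hazard ratio and
    c-index on each replicate's held-out patients.
    """
    rows_all = build_counting_process(cohort, endpoint="PFS")
    eligible = sorted(rows_all["patient_id"].unique())
    subtyped = set(cohort.patients.loc[cohort.patients["subtype"].notna(), "patient_id"])
    eligible = [p for p in eligible if p in subtyped]
    if len(eligible) <= n_train:
        raise ValueError(f"need more than {n_train} eligible patients, have {len(eligible)}")
    rng = np.random.default_rng(seed)

    splits, changepoints = [], []
    draws = 0
    while len(splits) < reps:
        if draws >= reps + max_redraws:
            raise RuntimeError("too many replicate redraws without events")
        draws += 1
        train = rng.choice(eligible, size=n_train, replace=False)
        train_rows = rows_all[rows_all["patient_id"].isin(train)]
        if train_rows["event"].sum() < 5:
            logger.info("replicate redrawn: too few events in training subsample")
            continue
        try:
            fit = fit_td_cox(train_rows, formula="spline+subtype", n_knots=n_knots)
            xs, ys = _fitted_score_curve(fit)
            seg = segmented_changepoint(xs, ys)
        except (ValueError, ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.info("replicate redrawn: %s", exc)
            continue
        splits.append(set(train))
        changepoints.append(seg.breakpoint)

    changepoints = np.asarray(changepoints)
    mean_cp = float(np.mean(changepoints))
    threshold = float(np.ceil(mean_cp))

    hrs, cs = [], []
    for train in splits:
        test_rows = rows_all[~rows_all["patient_id"].isin(train)]
        if test_rows["event"].sum() < 2:
            continue
        try:
            fit = fit_td_cox(test_rows, formula="threshold", threshold=threshold)
        except (ValueError, ConvergenceError, np.linalg.LinAlgError):
            continue
        if fit.is_degenerate("score_high"):
            logger.info("held-out replicate dropped: separated threshold indicator")
            continue
        hrs.append(fit.hazard_ratio("score_high"))
        cs.append(fit.c_index)
    return ThresholdDiscoveryResult(
        changepoints=changepoints,
        mean_changepoint=mean_cp,
        threshold=threshold,
        holdout_hrs=np.asarray(hrs),
        holdout_cindices=np.asarray(cs),
        mean_holdout_hr=float(np.mean(hrs)) if hrs else float("nan"),
        median_holdout_cindex=float(np.median(cs)) if cs else float("nan"),
        n_train=n_train, reps=reps,
    )


# ----------------------------------------------------------------------
# subtype-stratified hazards and expected time to progression


def _rmst_months(baseline: pd.DataFrame, lp: float, tau: float) -> float:
    """Restricted mean survival time (months) of S(t) = exp(-Lambda0(t) e^lp)."""
    times = baseline["time"].to_numpy(dtype=float)
    cumhaz = baseline["cumhaz"].to_numpy(dtype=float)
    grid = np.concatenate([[0.0], times[times <= tau], [tau]])
    surv = np.ones_like(grid)
    hr = np.exp(np.clip(lp, -700, 700))
    for i, t in enumerate(grid):
        past = cumhaz[times <= t]
        surv[i] = np.exp(-np.clip((past[-1] if len(past) else 0.0) * hr, 0, 700))
    # survival is a right-continuous step function: rectangle rule
    rmst_days = float(np.sum(surv[:-1] * np.diff(grid)))
    return rmst_days / DAYS_PER_MONTH


def subtype_hazards(cohort: Cohort, threshold: float = 0.07) -> dict[str, dict]:
    """Per-subtype threshold-indicator Cox fit with expected times to progression.

    The expected time is the restricted mean survival time of the fitted curve
    for a patient persistently below vs at/above the threshold, integrated to
    the subtype's maximum follow-up, reported in months.
    """
    thr_pct = threshold * 100.0
    out: dict[str, dict] = {}
    for subtype in ("ER+Her2-", "Her2+", "TN"):
        pids = cohort.patients.loc[cohort.patients["subtype"] == subtype, "patient_id"]
        sub = cohort.subset(pids)
        rows = build_counting_process(sub, endpoint="PFS")
        if rows.empty or rows["event"].sum() < 2:
            logger.warning("subtype %s skipped: fewer than 2 events", subtype)
            out[subtype] = {"skipped": True, "n_events": int(rows["event"].sum())
                            if not rows.empty else 0}
            continue
        try:
            fit = fit_td_cox(rows, formula="threshold", threshold=thr_pct)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            logger.warning("subtype %s skipped: %s", subtype, exc)
            out[subtype] = {"skipped": True, "n_events": int(rows["event"].sum())}
            continue
        if fit.is_degenerate("score_high"):
            logger.warning("subtype %s skipped: separated threshold indicator", subtype)
            out[subtype] = {"skipped": True, "n_events": int(rows["event"].sum())}
            continue
        tau = float(rows["stop"].max())
        coef = float(fit.summary.loc["score_high", "coef"])
        out[subtype] = {
            "skipped": False,
            "hr": fit.hazard_ratio("score_high"),
            "hr_ci": (float(fit.summary.loc["score_high", "hr_lower"]),
                      float(fit.summary.loc["score_high", "hr_upper"])),
            "c_index": fit.c_index,
            "n_events": int(rows["event"].sum()),
            "expected_months_low": _rmst_months(fit.baseline_cumulative_hazard, 0.0, tau),
            "expected_months_high": _rmst_months(fit.baseline_cumulative_hazard, coef, tau),
        }
    return out


def fit_os_models(cohort: Cohort, threshold: float = 0.07) -> dict[str, CoxFit]:
    """Overall-survival Cox models with the score as a time-dependent variable:
    continuous (percent units) and thresholded."""
    rows = build_counting_process(cohort, endpoint="OS")
    if rows.empty or rows["event"].sum() == 0:
        raise ValueError("no events: overall-survival models require observed deaths")
    return {
        "continuous": fit_td_cox(rows, formula="score"),
        "thresholded": fit_td_cox(rows, formula="threshold", threshold=threshold * 100.0),
    }
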