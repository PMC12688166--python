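"""Synthetic cohorts with the statistical structure the analyses assume.

The generator draws, per patient, correlated random intercepts and slopes
``b_i ~ N(0, Sigma_b)`` on the arcsine tumour-fraction scale, builds an
irregularly sampled ctDNA trajectory around the fixed-effect mean (time since
first CT, ER/Her2 status, treatment duration, regimen), and generates the
repeated binary progressive-disease (PD) outcome at each CT scan from a
logistic model whose linear predictor loads on the *true* random effects plus
a per-patient random intercept ``u_i``. That mirrors exactly the two-stage
model the ``bayml`` module fits, so parameter recovery is testable end to end.

Sampling schedules emulate clinical practice: roughly 3-weekly plasma samples
on chemotherapy, monthly on targeted therapy, and 3-6-monthly on endocrine
therapy, with CT scans about every 3 months and geometric dropout.

A second generator produces 1-Mb binned read-count profiles at a known tumour
fraction together with a matched panel of normals, for testing the
copy-number burden metrics; and a third produces cohorts whose progression
hazard has a known slope break in the tumour-fraction score, for testing
threshold discovery.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .metrics import BinnedProfile, PanelOfNormals

DAYS_PER_YEAR = 365.25

#: default regimen catalogue: (label, treatment class)
DEFAULT_REGIMENS = (
    ("Letrozole", "endocrine"),
    ("Fulvestrant", "endocrine"),
    ("Paclitaxel", "chemotherapy"),
    ("Capecitabine", "chemotherapy"),
    ("Palbociclib/Letrozole", "targeted"),
    ("Trastuzumab/Emtansine", "targeted+chemotherapy"),
)

#: plausible regimens per subtype (labels must exist in the regimen catalogue)
_SUBTYPE_REGIMENS = {
    "ER+Her2-": ("Letrozole", "Fulvestrant", "Palbociclib/Letrozole", "Capecitabine"),
    "Her2+": ("Trastuzumab/Emtansine", "Paclitaxel", "Capecitabine"),
    "TN": ("Paclitaxel", "Capecitabine"),
}


@dataclasses.dataclass
class GroundTruth:
    """True parameter values and per-patient random effects behind a simulation."""

    beta1: dict[str, float]
    sigma_b: tuple[float, float]
    rho_b: float
    sigma_eps: float
    beta2: dict[str, float]
    gamma: tuple[float, float]
    sigma_u: float
    effects: pd.DataFrame  # patient_id, b0, b1, u

    @property
    def Sigma_b(self) -> np.ndarray:
        s1, s2 = self.sigma_b
        return np.array([
            [s1**2, self.rho_b * s1 * s2],
            [self.rho_b * s1 * s2, s2**2],
        ])


@dataclasses.dataclass
class SimConfig:
    """Study-condition knobs for :func:`simulate_cohort`.

    Defaults emulate a metastatic breast cancer monitoring cohort: 143
    patients, subtype mix dominated by ER+Her2-, ~2-year follow-up, scans
    every ~3 months, and sampling cadence tied to the treatment class. The
    outcome-model defaults give roughly 30-50%% PD scans.
    """

    n_patients: int = 143
    subtype_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"ER+Her2-": 0.60, "Her2+": 0.25, "TN": 0.15})
    regimens: Sequence[tuple[str, str]] = DEFAULT_REGIMENS
    sampling_interval_days: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"endocrine": 120.0, "targeted": 28.0,
                                 "chemotherapy": 21.0, "targeted+chemotherapy": 21.0})
    #: after this long on one regimen, sampling relaxes to the sparse cadence
    sampling_intense_phase_days: float = 84.0
    sampling_sparse_interval_days: float = 90.0
    scan_interval_days: float = 90.0
    horizon_days: float = 730.0
    switch_fraction: float = 0.5
    dropout_prob_per_scan: float = 0.08
    # stage-1 (arcsine-scale trajectory) truth
    beta1: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"intercept": 0.26, "time_years": 0.12, "er": -0.03,
                                 "her2": 0.03, "tx_duration_years": -0.10})
    beta1_regimen: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"Paclitaxel": -0.03, "Trastuzumab/Emtansine": -0.04,
                                 "Palbociclib/Letrozole": -0.02})
    sigma_b: tuple[float, float] = (0.12, 0.12)
    rho_b: float = 0.3
    sigma_eps: float = 0.04
    # stage-2 (logistic PD) truth
    beta2: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"intercept": -1.1, "time_years": 0.25, "er": -0.2,
                                 "her2": 0.2})
    beta2_regimen: Mapping[str, float] = dataclasses.field(default_factory=dict)
    gamma: tuple[float, float] = (1.5, 3.0)
    sigma_u: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.subtype_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"subtype probabilities must sum to 1, got {total}")
        if any(v <= 0 for v in self.sampling_interval_days.values()):
            raise ValueError("sampling cadences must be positive")
        if self.scan_interval_days <= 0 or self.horizon_days <= 0:
            raise ValueError("scan cadence and horizon must be positive")
        if self.sigma_eps < 0 or self.sigma_u < 0:
            raise ValueError("sigma_eps and sigma_u must be nonnegative")
        s1, s2 = self.sigma_b
        if s1 < 0 or s2 < 0 or not -1 <= self.rho_b <= 1:
            raise ValueError("invalid random-effect covariance parameters")
        cov = np.array([[s1**2, self.rho_b * s1 * s2], [self.rho_b * s1 * s2, s2**2]])
        if np.min(np.linalg.eigvalsh(cov)) < -1e-12:
            raise ValueError("Sigma_b is not positive semi-definite")


def _trajectory_mean(cfg: SimConfig, day, er, her2, tx_duration_years, regimen) -> float:
    b = cfg.beta1
    return (b["intercept"] + b["time_years"] * day / DAYS_PER_YEAR + b["er"] * er
            + b["her2"] * her2 + b["tx_duration_years"] * tx_duration_years
            + cfg.beta1_regimen.get(regimen, 0.0))


def _pd_linpred(cfg: SimConfig, day, er, her2, regimen) -> float:
    b = cfg.beta2
    return (b["intercept"] + b["time_years"] * day / DAYS_PER_YEAR + b["er"] * er
            + b["her2"] * her2 + cfg.beta2_regimen.get(regimen, 0.0))


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None
                    ) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort plus the ground truth that produced it.

    Trajectories are simulated on the arcsine scale and back-transformed with
    ``sin(y)**2`` after clipping to [0, pi/2] (i.e. tumour fractions truncated
    to [0, 1]). PD outcomes use the true ``b_i``, so downstream fits can be
    scored for parameter recovery.
    """
    cfg = config or SimConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    subtype_labels = list(cfg.subtype_probs)
    subtype_p = np.array([cfg.subtype_probs[s] for s in subtype_labels])
    regimen_class = dict(cfg.regimens)
    cov_b = np.array([
        [cfg.sigma_b[0]**2, cfg.rho_b * cfg.sigma_b[0] * cfg.sigma_b[1]],
        [cfg.rho_b * cfg.sigma_b[0] * cfg.sigma_b[1], cfg.sigma_b[1]**2],
    ])

    patients, treatments, samples, scans, effects = [], [], [], [], []
    for i in range(cfg.n_patients):
        pid = f"SIM{i:04d}"
        subtype = subtype_labels[rng.choice(len(subtype_labels), p=subtype_p)]
        er = 1 if subtype in ("ER+Her2-",) else (1 if subtype == "Her2+" and rng.random() < 0.5 else 0)
        her2 = 1 if subtype == "Her2+" else 0

        # svd handles positive semi-definite covariances (degenerate configs)
        b0, b1 = rng.multivariate_normal(np.zeros(2), cov_b, method="svd")
        u = rng.normal(0.0, cfg.sigma_u) if cfg.sigma_u > 0 else 0.0

        # follow-up: scans every scan_interval (jittered), geometric dropout
        n_sched = max(1, int(cfg.horizon_days / cfg.scan_interval_days) + 1)
        if cfg.dropout_prob_per_scan > 0:
            n_scans = min(n_sched, 1 + rng.geometric(cfg.dropout_prob_per_scan))
        else:
            n_scans = n_sched
        scan_days = [0.0]
        for k in range(1, n_scans):
            scan_days.append(min(cfg.horizon_days,
                                 k * cfg.scan_interval_days + rng.uniform(-10, 10)))
        scan_days = sorted(set(round(d) for d in scan_days))
        followup_end = max(scan_days)

        # treatments: first regimen starts shortly before the baseline scan,
        # optionally one mid-follow-up switch
        allowed = [r for r in _SUBTYPE_REGIMENS.get(subtype, ()) if r in regimen_class]
        if not allowed:
            allowed = [label for label, _ in cfg.regimens]
        reg1 = allowed[rng.choice(len(allowed))]
        start1 = -float(rng.integers(14, 42))
        intervals = []
        if cfg.switch_fraction > 0 and rng.random() < cfg.switch_fraction and followup_end > 120:
            switch_day = float(rng.integers(int(0.25 * followup_end), int(0.7 * followup_end)))
            others = [r for r in allowed if r != reg1] or allowed
            reg2 = others[rng.choice(len(others))]
            intervals.append((reg1, start1, switch_day))
            end2 = np.nan if rng.random() < 0.5 else followup_end + float(rng.integers(1, 30))
            intervals.append((reg2, switch_day, end2))
        else:
            end1 = np.nan if rng.random() < 0.5 else followup_end + float(rng.integers(1, 30))
            intervals.append((reg1, start1, end1))
        for reg, s, e in intervals:
            treatments.append({"patient_id": pid, "regimen": reg,
                               "treatment_class": regimen_class.get(reg, "unknown"),
                               "start_day": s, "end_day": e})

        def active_regimen(day):
            for reg, s, e in intervals:
                if s <= day and (np.isnan(e) or day < e):
                    return reg, s
            # before first start or after last end: nearest preceding, else first
            prior = [(reg, s) for reg, s, e in intervals if s <= day]
            return prior[-1] if prior else (intervals[0][0], intervals[0][1])

        # plasma samples: baseline draw, then cadence of the active regimen
        sample_days = [start1 + float(rng.integers(3, 14))]
        day = 0.0
        while day <= followup_end:
            reg, reg_start = active_regimen(day)
            cadence = cfg.sampling_interval_days[regimen_class.get(reg, "chemotherapy")]
            if day - reg_start > cfg.sampling_intense_phase_days:
                cadence = max(cadence, cfg.sampling_sparse_interval_days)
            day += cadence * float(rng.uniform(0.85, 1.15))
            if day <= followup_end + 0.5 * cadence:
                sample_days.append(round(day))
        sample_days = sorted(set(round(d) for d in sample_days))

        for day in sample_days:
            reg, reg_start = active_regimen(day)
            tx_dur = max(0.0, day - reg_start) / DAYS_PER_YEAR
            mean = _trajectory_mean(cfg, day, er, her2, tx_dur, reg)
            y = mean + b0 + b1 * day / DAYS_PER_YEAR + rng.normal(0.0, cfg.sigma_eps)
            tf = float(np.sin(np.clip(y, 0.0, np.pi / 2)) ** 2)
            samples.append({"patient_id": pid, "day": day, "tumour_fraction": tf,
                            "ca15_3": np.nan, "max_vaf": np.nan,
                            "post_followup": day > followup_end})

        for day in scan_days:
            reg, _ = active_regimen(day)
            eta = (_pd_linpred(cfg, day, er, her2, reg)
                   + cfg.gamma[0] * b0 + cfg.gamma[1] * b1 + u)
            pd_flag = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            scans.append({"patient_id": pid, "day": day, "progression": pd_flag,
                          "response_category": "PD" if pd_flag else "SD"})

        death_event = int(rng.random() < 0.25)
        death_day = followup_end + float(rng.integers(5, 200)) if death_event else followup_end
        patients.append({"patient_id": pid, "er_status": er, "her2_status": her2,
                         "death_day": death_day, "death_event": death_event})
        effects.append({"patient_id": pid, "b0": b0, "b1": b1, "u": u})

    cohort = Cohort(
        patients=pd.DataFrame(patients),
        treatments=pd.DataFrame(treatments),
        samples=pd.DataFrame(samples),
        scans=pd.DataFrame(scans),
        provenance={"synthetic": True, "seed": int(seed), "aligned": True,
                    "generator": "simulate_cohort"},
    )
    truth = GroundTruth(
        beta1=dict(cfg.beta1, **{f"regimen:{k}": v for k, v in cfg.beta1_regimen.items()}),
        sigma_b=cfg.sigma_b, rho_b=cfg.rho_b, sigma_eps=cfg.sigma_eps,
        beta2=dict(cfg.beta2, **{f"regimen:{k}": v for k, v in cfg.beta2_regimen.items()}),
        gamma=cfg.gamma, sigma_u=cfg.sigma_u,
        effects=pd.DataFrame(effects),
    )
    return cohort, truth


# ----------------------------------------------------------------------
# binned copy-number profiles


def simulate_binned_profiles(tf: float, cna_profile: Sequence[int], n_normals: int = 35,
                             depth: float = 1000.0, seed: int = 0,
                             noise: Literal["poisson", "negative-binomial"] = "poisson",
                             nb_dispersion: float = 20.0,
                             ) -> tuple[BinnedProfile, PanelOfNormals]:
    """Simulate a 1-Mb binned sWGS profile at tumour fraction ``tf`` plus a panel.

    Expected reads per bin are ``depth * (tf * CN/2 + (1 - tf))`` with Poisson
    (or negative-binomial) noise; normals are simulated at CN = 2 everywhere.
    Values are returned on the log2 scale (``log2(count / depth)``); subtract
    the panel baseline with :func:`ctdna_monitor.metrics.normalize_log2`.
    """
    if not 0 <= tf <= 1:
        raise ValueError("tumour fraction must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    cna = np.asarray(cna_profile, dtype=float)
    if cna.ndim != 1 or len(cna) == 0:
        raise ValueError("cna_profile must be a nonempty 1-D array of copy numbers")
    rng = np.random.default_rng(seed)
    n_bins = len(cna)

    def draw(mu, size):
        mu = np.broadcast_to(mu, size)
        if noise == "poisson":
            return rng.poisson(mu)
        if noise == "negative-binomial":
            p = nb_dispersion / (nb_dispersion + mu)
            return rng.negative_binomial(nb_dispersion, p)
        raise ValueError(f"unknown noise model {noise!r}")

    def to_log2(counts):
        return np.log2(np.maximum(counts, 0.5) / depth)

    mu_sample = depth * (tf * cna / 2.0 + (1.0 - tf))
    sample_log2 = to_log2(draw(mu_sample, (n_bins,)))
    normals_log2 = to_log2(draw(depth, (n_normals, n_bins)))

    # genome grid: bins split evenly over chromosomes 1..23
    per_chrom = int(np.ceil(n_bins / 23))
    chrom = 1 + np.arange(n_bins) // per_chrom
    within = np.arange(n_bins) % per_chrom
    grid = pd.DataFrame({"chromosome": chrom, "start": within * 1_000_000,
                         "end": (within + 1) * 1_000_000})

    median = np.median(normals_log2, axis=0)
    centred = normals_log2 - median
    panel = PanelOfNormals(
        bins=grid.assign(median=median, mean=centred.mean(axis=0),
                         sd=np.maximum(centred.std(axis=0, ddof=1), 1e-6)),
        n_normals=n_normals,
    )
    profile = BinnedProfile(
        bins=grid.assign(value=sample_log2),
        scale="log2-ratio",
        n_aligned_reads=int(round(depth * n_bins)),
    )
    return profile, panel


# ----------------------------------------------------------------------
# cohorts with a known hazard slope break


def simulate_threshold_cohort(n_patients: int = 150, break_tf: float = 0.10,
                              slope_low: float = 0.05, slope_high: float = 0.5,
                              base_hazard: float = 3e-4, horizon_days: float = 720.0,
                              sample_interval_days: float = 30.0,
                              scan_interval_days: float = 60.0,
                              seed: int = 0) -> Cohort:
    """Cohort whose progression hazard has a slope break at ``break_tf``.

    Tumour fractions follow a per-patient bounded random walk (percent scale);
    the instantaneous progression hazard is ``base_hazard * exp(f(score))``
    where ``f`` is piecewise linear in the percent score with a break at
    ``break_tf * 100``, the low slope below and the high slope above. Event
    times are drawn by piecewise-exponential inversion; progression is
    recorded as a PD scan at the event time, with routine PD=0 scans before.
    """
    rng = np.random.default_rng(seed)
    brk = break_tf * 100.0

    def log_rel_hazard(x_pct):
        return slope_low * min(x_pct, brk) + slope_high * max(x_pct - brk, 0.0)

    patients, samples, scans = [], [], []
    subtype_choices = [(1, 0), (1, 1), (0, 1), (0, 0)]
    for i in range(n_patients):
        pid = f"THR{i:04d}"
        er, her2 = subtype_choices[rng.choice(len(subtype_choices), p=[0.55, 0.2, 0.1, 0.15])]
        sample_days = [-7.0] + list(np.arange(sample_interval_days, horizon_days,
                                              sample_interval_days))
        x = float(rng.uniform(0.0, 25.0))
        scores = []
        for _ in sample_days:
            scores.append(x)
            x = float(np.clip(x + rng.normal(0.0, 2.5), 0.0, 40.0))

        # piecewise-exponential event time with LOCF hazard
        exp_draw = rng.exponential(1.0)
        cum, event_day = 0.0, None
        bounds = [0.0] + [d for d in sample_days if d > 0] + [horizon_days]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            idx = max(j for j, d in enumerate(sample_days) if d <= lo)
            lam = base_hazard * math.exp(log_rel_hazard(scores[idx]))
            if cum + lam * (hi - lo) >= exp_draw:
                event_day = lo + (exp_draw - cum) / lam
                break
            cum += lam * (hi - lo)

        scan_days = [0.0] + list(np.arange(scan_interval_days, horizon_days,
                                           scan_interval_days))
        if event_day is not None:
            scan_days = [d for d in scan_days if d < event_day] + [round(event_day)]
        for d in scan_days:
            is_event = event_day is not None and d == scan_days[-1]
            scans.append({"patient_id": pid, "day": d, "progression": int(is_event),
                          "response_category": "PD" if is_event else "SD"})
        last_scan = max(d for d in scan_days)
        for d, s in zip(sample_days, scores):
            if d <= last_scan:
                samples.append({"patient_id": pid, "day": d, "tumour_fraction": s / 100.0,
                                "ca15_3": np.nan, "max_vaf": np.nan})
        patients.append({"patient_id": pid, "er_status": er, "her2_status": her2,
                         "death_day": np.nan, "death_event": 0})

    return Cohort(
        patients=pd.DataFrame(patients),
        treatments=pd.DataFrame(columns=["patient_id", "regimen", "treatment_class",
                                         "start_day", "end_day"]),
        samples=pd.DataFrame(samples),
        scans=pd.DataFrame(scans),
        provenance={"synthetic": True, "seed": int(seed), "aligned": True,
                    "generator": "simulate_threshold_cohort",
                    "break_tf": break_tf},
    )
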