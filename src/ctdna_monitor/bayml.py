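"""Two-stage Bayesian model predicting progressive disease from ctDNA trajectories.

Stage 1 is a linear random-slopes-and-intercepts model of the
arcsine-transformed tumour fraction ``y_i(s) = X1_i(s) b1 + Z1_i(s) b_i + e``,
with ``b_i = (b_i0, b_i1) ~ N(0, Sigma_b)`` (per-patient baseline level and
per-year trend) and i.i.d. Gaussian measurement error. Stage 2 is a
random-intercept logistic model of the repeated binary progressive-disease
(PD) outcome at each CT scan,
``logit P(PD_i(t) = 1) = X2_i(t) b2 + u_i + gamma' bhat_i``,
where ``bhat_i`` are the stage-1 posterior means of the random effects
(plug-in two-stage linkage): patients whose ctDNA level is high at baseline
or rising steeply are more likely to progress.

Priors: non-intercept coefficients N(0, 10^2); intercepts Student-t(3, 0,
2.5); random-effect standard deviations half-Cauchy(2); the residual SD
half-Student-t(3, 0, 2.5); the random-effect correlation uniform (the
2-dimensional LKJ(1) prior).

Posteriors are sampled on the marginal scale: the stage-1 random effects are
integrated out analytically (the marginal of a linear-Gaussian model), and
the stage-2 random intercept is integrated by Gauss-Hermite quadrature, so
the sampled posterior has only the fixed effects and variance components.
Per-patient effects are recovered afterwards from their exact conditional
distributions, draw by draw.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import Cohort
from .metrics import arcsine_transform
from .mcmc import (RHAT_LIMIT, EnsembleResult, half_cauchy_logpdf,
                   half_student_t_logpdf, normal_logpdf, run_chains,
                   split_rhat, student_t_logpdf)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


# ----------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class SamplerConfig:
    """Ensemble-sampler and prior settings for both stages."""

    n_chains: int = 6
    n_steps: int = 3000
    n_burn: int = 1000
    n_keep: int = 400          # thinned draws used for effects and prediction
    n_quad: int = 15           # Gauss-Hermite nodes for the stage-2 integral
    seed: int = 0
    coef_prior_sd: float = 10.0
    intercept_prior_df: float = 3.0
    intercept_prior_scale: float = 2.5
    sd_prior_scale: float = 2.0        # half-Cauchy scale for random-effect SDs
    resid_prior_df: float = 3.0        # half-Student-t for the residual SD
    resid_prior_scale: float = 2.5


# ----------------------------------------------------------------------
# design matrices


@dataclasses.dataclass
class Stage1Data:
    y: np.ndarray              # arcsine-transformed tumour fraction
    X: np.ndarray              # fixed-effect design
    Z: np.ndarray              # random-effect design (intercept, years)
    patient_idx: np.ndarray    # row -> patient position
    patient_ids: list[str]
    columns: list[str]
    days: np.ndarray


@dataclasses.dataclass
class Stage2Data:
    y: np.ndarray              # PD flag per scan
    X: np.ndarray
    patient_idx: np.ndarray
    patient_ids: list[str]
    columns: list[str]
    days: np.ndarray
    regimens: np.ndarray       # regimen label per scan row
    flagged_regimens: list[str]
    ref_regimen: str


def _treatment_at(intervals: list[tuple[str, float, float]], day: float):
    """(regimen, start_day) of the interval covering ``day``; else the most
    recent preceding interval; else None."""
    for reg, s, e in intervals:
        if s <= day and (np.isnan(e) or day < e):
            return reg, s
    prior = [(reg, s) for reg, s, e in intervals if s <= day]
    return prior[-1] if prior else (None, None)


def _patient_intervals(cohort: Cohort) -> dict[str, list[tuple[str, float, float]]]:
    out: dict[str, list] = {}
    for pid, grp in cohort.treatments.groupby("patient_id"):
        grp = grp.sort_values("start_day")
        out[pid] = [(str(r["regimen"]), float(r["start_day"]),
                     float(r["end_day"]) if pd.notna(r["end_day"]) else float("nan"))
                    for _, r in grp.iterrows()]
    return out


def build_design_matrices(cohort: Cohort, min_regimen_obs: int = 5,
                          ref_regimen: str | None = None
                          ) -> tuple[Stage1Data, Stage2Data]:
    """Long-format design matrices for both stages.

    Stage 1: one row per plasma sample (post-follow-up samples excluded),
    response = arcsine-transformed tumour fraction; covariates are time since
    first CT (years), ER, Her2, treatment duration (years) and regimen
    dummies against the most frequent regimen. Stage 2: one row per CT scan
    with the PD flag as response and the same covariates minus treatment
    duration. Regimen levels whose stage-2 outcomes are constant (separation)
    or that have fewer than ``min_regimen_obs`` scans are flagged
    non-identifiable: their dummies are dropped (rows kept at the reference
    level) and predictions for them are refused.
    """
    patients = cohort.patients
    usable = patients[patients["er_status"].notna() & patients["her2_status"].notna()]
    dropped = len(patients) - len(usable)
    if dropped:
        logger.info("bayml: %d patients without ER/Her2 status excluded", dropped)
    er = dict(zip(usable["patient_id"], usable["er_status"].astype(float)))
    her2 = dict(zip(usable["patient_id"], usable["her2_status"].astype(float)))
    intervals = _patient_intervals(cohort)

    samples = cohort.samples
    if "post_followup" in samples.columns:
        samples = samples[~samples["post_followup"].fillna(False).astype(bool)]
    samples = samples[samples["patient_id"].isin(er)]
    scans = cohort.scans[cohort.scans["patient_id"].isin(er)]

    def regimen_and_duration(pid, day):
        reg, start = _treatment_at(intervals.get(pid, []), day)
        if reg is None:
            return "none", 0.0
        return reg, max(0.0, day - start) / DAYS_PER_YEAR

    s1 = []
    for _, row in samples.iterrows():
        pid, day = row["patient_id"], float(row["day"])
        reg, dur = regimen_and_duration(pid, day)
        s1.append((pid, day, float(row["tumour_fraction"]), reg, dur))
    s1_df = pd.DataFrame(s1, columns=["pid", "day", "tf", "regimen", "tx_dur"])
    if s1_df.empty:
        raise ValueError("no usable plasma samples for stage 1")

    if ref_regimen is None:
        ref_regimen = s1_df["regimen"].value_counts().idxmax()
    regimen_levels = sorted(set(s1_df["regimen"]) - {ref_regimen})

    pids = sorted(s1_df["pid"].unique())
    pid_pos = {p: i for i, p in enumerate(pids)}

    cols1 = ["intercept", "time_years", "er", "her2", "tx_duration_years"] + [
        f"regimen:{r}" for r in regimen_levels]
    X1 = np.zeros((len(s1_df), len(cols1)))
    X1[:, 0] = 1.0
    X1[:, 1] = s1_df["day"].to_numpy() / DAYS_PER_YEAR
    X1[:, 2] = s1_df["pid"].map(er).to_numpy(dtype=float)
    X1[:, 3] = s1_df["pid"].map(her2).to_numpy(dtype=float)
    X1[:, 4] = s1_df["tx_dur"].to_numpy()
    for j, r in enumerate(regimen_levels):
        X1[:, 5 + j] = (s1_df["regimen"] == r).to_numpy(dtype=float)
    # drop constant (unidentifiable) columns other than the intercept
    keep1 = [0] + [j for j in range(1, len(cols1)) if np.ptp(X1[:, j]) > 0]
    stage1 = Stage1Data(
        y=arcsine_transform(s1_df["tf"].to_numpy()),
        X=X1[:, keep1],
        Z=np.column_stack([np.ones(len(s1_df)), s1_df["day"].to_numpy() / DAYS_PER_YEAR]),
        patient_idx=s1_df["pid"].map(pid_pos).to_numpy(dtype=int),
        patient_ids=pids,
        columns=[cols1[j] for j in keep1],
        days=s1_df["day"].to_numpy(dtype=float),
    )

    s2 = []
    for _, row in scans.iterrows():
        pid, day = row["patient_id"], float(row["day"])
        if pid not in pid_pos:
            continue  # no stage-1 information for this patient
        reg, _ = regimen_and_duration(pid, day)
        s2.append((pid, day, int(row["progression"]), reg))
    s2_df = pd.DataFrame(s2, columns=["pid", "day", "pd", "regimen"])
    if s2_df.empty:
        raise ValueError("no usable CT scans for stage 2")

    flagged = []
    for reg, grp in s2_df.groupby("regimen"):
        if reg == ref_regimen:
            continue
        if len(grp) < min_regimen_obs or grp["pd"].nunique() < 2:
            flagged.append(str(reg))
    if flagged:
        logger.warning("bayml: regimens flagged non-identifiable in stage 2: %s",
                       ", ".join(sorted(flagged)))
    levels2 = [r for r in regimen_levels if r in set(s2_df["regimen"]) and r not in flagged]

    cols2 = ["intercept", "time_years", "er", "her2"] + [f"regimen:{r}" for r in levels2]
    X2 = np.zeros((len(s2_df), len(cols2)))
    X2[:, 0] = 1.0
    X2[:, 1] = s2_df["day"].to_numpy() / DAYS_PER_YEAR
    X2[:, 2] = s2_df["pid"].map(er).to_numpy(dtype=float)
    X2[:, 3] = s2_df["pid"].map(her2).to_numpy(dtype=float)
    for j, r in enumerate(levels2):
        X2[:, 4 + j] = (s2_df["regimen"] == r).to_numpy(dtype=float)
    keep2 = [0] + [j for j in range(1, len(cols2)) if np.ptp(X2[:, j]) > 0]
    stage2 = Stage2Data(
        y=s2_df["pd"].to_numpy(dtype=int),
        X=X2[:, keep2],
        patient_idx=s2_df["pid"].map(pid_pos).to_numpy(dtype=int),
        patient_ids=pids,
        columns=[cols2[j] for j in keep2],
        days=s2_df["day"].to_numpy(dtype=float),
        regimens=s2_df["regimen"].to_numpy(),
        flagged_regimens=sorted(flagged),
        ref_regimen=str(ref_regimen),
    )
    return stage1, stage2


# ----------------------------------------------------------------------
# convergence report


@dataclasses.dataclass
class ConvergenceReport:
    rhat: Mapping[str, float]
    max_rhat: float
    n_chains: int
    divergences: int
    passed: bool

    def __str__(self):
        status = "PASS" if self.passed else "FAIL"
        return f"ConvergenceReport({status}, max R-hat = {self.max_rhat:.3f})"


def check_convergence(posterior) -> ConvergenceReport:
    """Split-R-hat report; passes iff every parameter's R-hat < 1.1.

    Accepts a fitted stage posterior, an :class:`EnsembleResult`, or a raw
    (n_chains, n_draws[, n_params]) array. At least 2 chains are required.
    """
    if isinstance(posterior, (Stage1Posterior, Stage2Posterior)):
        chain, names = posterior.result.chain, posterior.result.param_names
    elif isinstance(posterior, EnsembleResult):
        chain, names = posterior.chain, posterior.param_names
    else:
        chain = np.asarray(posterior, dtype=float)
        if chain.ndim == 2:
            chain = chain[:, :, None]
        names = [f"param{i}" for i in range(chain.shape[2])]
    if chain.shape[0] < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    rhat = split_rhat(chain)
    return ConvergenceReport(
        rhat=dict(zip(names, map(float, np.atleast_1d(rhat)))),
        max_rhat=float(np.max(rhat)),
        n_chains=int(chain.shape[0]),
        divergences=0,
        passed=bool(np.max(rhat) < RHAT_LIMIT),
    )


# ----------------------------------------------------------------------
# stage 1: marginal linear mixed model


def _sigma_b_from(s1, s2, rho):
    """(..., 2, 2) covariance from SDs and correlation (broadcasting over draws)."""
    out = np.empty(np.shape(s1) + (2, 2))
    out[..., 0, 0] = s1**2
    out[..., 1, 1] = s2**2
    out[..., 0, 1] = out[..., 1, 0] = rho * s1 * s2
    return out


@dataclasses.dataclass
class Stage1Posterior:
    result: EnsembleResult
    columns: list[str]
    draws: dict[str, np.ndarray]    # beta (D, p), sigma_b (D, 2), rho (D,), sigma_eps (D,)
    bhat: pd.DataFrame              # patient_id, b0, b1, n_samples (posterior means)
    data: Stage1Data
    convergence: ConvergenceReport

    @property
    def converged(self) -> bool:
        return self.convergence.passed


@dataclasses.dataclass
class _Stage1Suffstats:
    """Per-patient sufficient statistics of the marginal Gaussian likelihood.

    With V_i = se^2 I + Z_i Sigma Z_i' (rank-2 update), the Woodbury and
    determinant identities reduce the likelihood to 2x2 algebra over
    (y'y, X'y, X'X, Z'Z, Z'y, Z'X, m) per patient.
    """

    yy: np.ndarray    # (g,)
    Xy: np.ndarray    # (g, p)
    XX: np.ndarray    # (g, p, p)
    ZZ: np.ndarray    # (g, 2, 2)
    Zy: np.ndarray    # (g, 2)
    ZX: np.ndarray    # (g, 2, p)
    m: np.ndarray     # (g,) rows per patient


def _suffstats(X, Z, y, patient_idx, n_patients) -> _Stage1Suffstats:
    g, p = n_patients, X.shape[1]
    st = _Stage1Suffstats(
        yy=np.zeros(g), Xy=np.zeros((g, p)), XX=np.zeros((g, p, p)),
        ZZ=np.zeros((g, 2, 2)), Zy=np.zeros((g, 2)), ZX=np.zeros((g, 2, p)),
        m=np.zeros(g))
    for i in range(g):
        rows = patient_idx == i
        Xi, Zi, yi = X[rows], Z[rows], y[rows]
        st.yy[i] = yi @ yi
        st.Xy[i] = Xi.T @ yi
        st.XX[i] = Xi.T @ Xi
        st.ZZ[i] = Zi.T @ Zi
        st.Zy[i] = Zi.T @ yi
        st.ZX[i] = Zi.T @ Xi
        st.m[i] = rows.sum()
    return st


def _marginal_pieces(st: _Stage1Suffstats, beta, s1, s2, rho, se):
    """(log-likelihood per walker, conditional b-hat (w, g, 2)).

    Uses b | y ~ N(A^-1 Z'r / se^2, A^-1) with A = Sigma^-1 + Z'Z / se^2 and
    log det V = m log se^2 + log det Sigma + log det A.
    """
    se2 = se**2
    det_sig = (s1 * s2)**2 * (1 - rho**2)
    # Sigma^-1 elements (closed form 2x2)
    i11 = s2**2 / det_sig
    i22 = s1**2 / det_sig
    i12 = -rho * s1 * s2 / det_sig
    A11 = i11[:, None] + st.ZZ[None, :, 0, 0] / se2[:, None]
    A12 = i12[:, None] + st.ZZ[None, :, 0, 1] / se2[:, None]
    A22 = i22[:, None] + st.ZZ[None, :, 1, 1] / se2[:, None]
    detA = A11 * A22 - A12**2

    rr = (st.yy[None, :] - 2 * np.einsum("gp,wp->wg", st.Xy, beta)
          + np.einsum("gpq,wp,wq->wg", st.XX, beta, beta))
    Zr = st.Zy[None, :, :] - np.einsum("gap,wp->wga", st.ZX, beta)
    # A^-1 Zr (2x2 closed form)
    sol0 = (A22 * Zr[..., 0] - A12 * Zr[..., 1]) / detA
    sol1 = (A11 * Zr[..., 1] - A12 * Zr[..., 0]) / detA
    quad = rr / se2[:, None] - (Zr[..., 0] * sol0 + Zr[..., 1] * sol1) / se2[:, None]**2
    logdetV = (st.m[None, :] * np.log(se2)[:, None]
               + np.log(det_sig)[:, None] + np.log(detA))
    ll = -0.5 * np.sum(logdetV + quad + st.m[None, :] * np.log(2 * np.pi), axis=1)
    bhat = np.stack([sol0, sol1], axis=-1) / se2[:, None, None]
    return ll, bhat


def _stage1_log_prob_factory(data: Stage1Data, cfg: SamplerConfig):
    p = data.X.shape[1]
    st = _suffstats(data.X, data.Z, data.y, data.patient_idx, len(data.patient_ids))

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = (np.all(np.abs(theta[:, :p]) < 100, axis=1)
              & np.all((theta[:, p:p + 2] > -12) & (theta[:, p:p + 2] < 4), axis=1)
              & (np.abs(theta[:, p + 2]) < 6)
              & (theta[:, p + 3] > -12) & (theta[:, p + 3] < 4))
        if not ok.any():
            return out
        th = theta[ok]
        beta = th[:, :p]
        s1, s2 = np.exp(th[:, p]), np.exp(th[:, p + 1])
        rho = np.tanh(th[:, p + 2])
        se = np.exp(th[:, p + 3])
        ll, _ = _marginal_pieces(st, beta, s1, s2, rho, se)

        prior = (student_t_logpdf(beta[:, 0], cfg.intercept_prior_df,
                                  cfg.intercept_prior_scale)
                 + np.sum(normal_logpdf(beta[:, 1:], cfg.coef_prior_sd), axis=1)
                 + half_cauchy_logpdf(s1, cfg.sd_prior_scale) + th[:, p]
                 + half_cauchy_logpdf(s2, cfg.sd_prior_scale) + th[:, p + 1]
                 + np.log1p(-rho**2)   # tanh Jacobian; uniform (LKJ zeta=1) on rho
                 + half_student_t_logpdf(se, cfg.resid_prior_df, cfg.resid_prior_scale)
                 + th[:, p + 3])
        out[ok] = ll + prior
        return out

    return log_prob


def _conditional_bhat(draws: dict[str, np.ndarray], X, Z, y, patient_idx,
                      n_patients: int) -> np.ndarray:
    """Posterior-mean random effects, averaged over retained parameter draws."""
    st = _suffstats(X, Z, y, patient_idx, n_patients)
    _, bhat = _marginal_pieces(st, draws["beta"], draws["sigma_b"][:, 0],
                               draws["sigma_b"][:, 1], draws["rho"],
                               draws["sigma_eps"])
    return bhat.mean(axis=0)


def fit_stage1(data: Stage1Data, config: SamplerConfig | None = None) -> Stage1Posterior:
    """Sample the stage-1 posterior and compute per-patient random-effect means.

    The random effects are integrated out, so the sampled space is
    ``(beta1, log sigma_b0, log sigma_b1, atanh rho, log sigma_eps)``; the
    per-patient ``bhat_i`` are recovered from the exact Gaussian conditional
    under each retained draw and averaged.
    """
    cfg = config or SamplerConfig()
    p = data.X.shape[1]
    names = list(data.columns) + ["log_sigma_b0", "log_sigma_b1", "atanh_rho",
                                  "log_sigma_eps"]
    beta0, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    resid_sd = float(np.std(data.y - data.X @ beta0)) or 0.05
    x0 = np.concatenate([beta0,
                         [np.log(max(resid_sd, 1e-3))] * 2,
                         [0.0],
                         [np.log(max(0.7 * resid_sd, 1e-3))]])
    result = run_chains(_stage1_log_prob_factory(data, cfg), x0, names,
                        n_chains=cfg.n_chains, n_steps=cfg.n_steps,
                        n_burn=cfg.n_burn, seed=cfg.seed)
    thin = result.thin(cfg.n_keep)
    draws = {
        "beta": thin[:, :p],
        "sigma_b": np.exp(thin[:, p:p + 2]),
        "rho": np.tanh(thin[:, p + 2]),
        "sigma_eps": np.exp(thin[:, p + 3]),
    }
    bhat = _conditional_bhat(draws, data.X, data.Z, data.y, data.patient_idx,
                             len(data.patient_ids))
    counts = np.bincount(data.patient_idx, minlength=len(data.patient_ids))
    bhat_df = pd.DataFrame({"patient_id": data.patient_ids,
                            "b0": bhat[:, 0], "b1": bhat[:, 1],
                            "n_samples": counts})
    post = Stage1Posterior(result=result, columns=list(data.columns), draws=draws,
                           bhat=bhat_df, data=data,
                           convergence=check_convergence(result))
    if not post.converged:
        logger.warning("stage 1 did not converge: max R-hat %.3f",
                       post.convergence.max_rhat)
    return post


# ----------------------------------------------------------------------
# stage 2: marginal random-intercept logistic model


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


@dataclasses.dataclass
class Stage2Posterior:
    result: EnsembleResult
    columns: list[str]
    draws: dict[str, np.ndarray]    # beta2 (D, p), gamma (D, 2) | None, sigma_u (D,)
    u_draws: np.ndarray             # (D, n_patients) conditional-mean intercepts
    bhat: pd.DataFrame
    data: Stage2Data
    convergence: ConvergenceReport
    use_ctdna: bool = True

    @property
    def converged(self) -> bool:
        return self.convergence.passed


def _stage2_log_prob_factory(data: Stage2Data, bhat: np.ndarray, cfg: SamplerConfig,
                             use_ctdna: bool):
    p = data.X.shape[1]
    q = 2 if use_ctdna else 0
    nodes, weights = np.polynomial.hermite.hermgauss(cfg.n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    # rows ordered by patient so per-patient sums are segment reductions
    order = np.argsort(data.patient_idx, kind="stable")
    Xs = data.X[order]
    ys = data.y[order].astype(float)
    idx_s = data.patient_idx[order]
    bhat_rows = bhat[idx_s]
    starts = np.concatenate([[0], 1 + np.flatnonzero(np.diff(idx_s))])
    sign_y = np.where(ys == 1, 1.0, -1.0)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = (np.all(np.abs(theta[:, :p + q]) < 100, axis=1)
              & (theta[:, -1] > -12) & (theta[:, -1] < 4))
        if not ok.any():
            return out
        th = theta[ok]
        beta = th[:, :p]
        gamma = th[:, p:p + q] if use_ctdna else None
        su = np.exp(th[:, -1])
        u_nodes = np.sqrt(2.0) * su[:, None] * nodes[None, :]      # (w, q)

        eta = beta @ Xs.T                                          # (w, N)
        if use_ctdna:
            eta = eta + gamma @ bhat_rows.T
        full = sign_y[None, :, None] * (eta[:, :, None] + u_nodes[:, None, :])
        logp = np.add.reduceat(_log_sigmoid(full), starts, axis=1)  # (w, g, q)
        ll = logsumexp(logp + log_w[None, None, :], axis=2).sum(axis=1)

        prior = (student_t_logpdf(beta[:, 0], cfg.intercept_prior_df,
                                  cfg.intercept_prior_scale)
                 + np.sum(normal_logpdf(beta[:, 1:], cfg.coef_prior_sd), axis=1)
                 + half_cauchy_logpdf(su, cfg.sd_prior_scale) + th[:, -1])
        if use_ctdna:
            prior = prior + np.sum(normal_logpdf(gamma, cfg.coef_prior_sd), axis=1)
        out[ok] = ll + prior
        return out

    return log_prob


def _u_posterior_weights(eta_rows: np.ndarray, y_rows: np.ndarray,
                         u_nodes: np.ndarray, log_w: np.ndarray) -> np.ndarray:
    """Normalised posterior weights over quadrature nodes for one patient.

    ``eta_rows`` (D, k): per-draw linear predictors of the conditioning scans;
    ``u_nodes`` (D, q). With no conditioning scans returns the prior weights.
    """
    if eta_rows.shape[1] == 0:
        w = np.exp(log_w)
        return np.tile(w / w.sum(), (u_nodes.shape[0], 1))
    sign = np.where(y_rows[None, :, None] == 1, 1.0, -1.0)
    logp = _log_sigmoid(sign * (eta_rows[:, :, None] + u_nodes[:, None, :])).sum(axis=1)
    logpost = logp + log_w[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return np.exp(logpost)


def fit_stage2(data: Stage2Data, stage1: Stage1Posterior,
               config: SamplerConfig | None = None, use_ctdna: bool = True,
               force: bool = False) -> Stage2Posterior:
    """Sample the stage-2 posterior given the stage-1 random-effect summaries.

    Refuses to run on an unconverged stage 1 unless ``force=True``. Every
    stage-2 patient must appear in stage 1 (their ``bhat`` is a covariate).
    """
    cfg = config or SamplerConfig()
    if not stage1.converged and not force:
        raise RuntimeError("stage 1 did not pass convergence; rerun or pass force=True")
    missing = set(data.patient_ids) - set(stage1.bhat["patient_id"])
    if missing:
        raise ValueError(f"stage-2 patients missing from stage 1: {sorted(missing)}")
    bhat_map = stage1.bhat.set_index("patient_id")
    bhat = bhat_map.loc[data.patient_ids, ["b0", "b1"]].to_numpy(dtype=float)

    p = data.X.shape[1]
    names = list(data.columns)
    if use_ctdna:
        names += ["gamma_intercept", "gamma_slope"]
    names += ["log_sigma_u"]
    # initialise from a crude logistic regression (few Newton steps)
    Xinit = np.column_stack([data.X, bhat[data.patient_idx]]) if use_ctdna else data.X
    coef = _newton_logistic(Xinit, data.y)
    x0 = np.concatenate([coef, [np.log(0.5)]])
    result = run_chains(
        _stage2_log_prob_factory(data, bhat, cfg, use_ctdna), x0, names,
        n_chains=cfg.n_chains, n_steps=cfg.n_steps, n_burn=cfg.n_burn,
        seed=cfg.seed + 1)
    thin = result.thin(cfg.n_keep)
    draws = {
        "beta2": thin[:, :p],
        "gamma": thin[:, p:p + 2] if use_ctdna else None,
        "sigma_u": np.exp(thin[:, -1]),
    }

    # conditional-mean random intercepts per retained draw
    nodes, weights = np.polynomial.hermite.hermgauss(cfg.n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    u_nodes = np.sqrt(2.0) * draws["sigma_u"][:, None] * nodes[None, :]
    n_draws = len(thin)
    u_draws = np.zeros((n_draws, len(data.patient_ids)))
    eta_all = np.einsum("kp,wp->wk", data.X, draws["beta2"])
    if use_ctdna:
        eta_all = eta_all + np.einsum("ka,wa->wk", bhat[data.patient_idx], draws["gamma"])
    for i in range(len(data.patient_ids)):
        rows = np.flatnonzero(data.patient_idx == i)
        w_post = _u_posterior_weights(eta_all[:, rows], data.y[rows], u_nodes, log_w)
        u_draws[:, i] = np.sum(w_post * u_nodes, axis=1)

    post = Stage2Posterior(result=result, columns=list(data.columns), draws=draws,
                           u_draws=u_draws, bhat=stage1.bhat, data=data,
                           convergence=check_convergence(result), use_ctdna=use_ctdna)
    if not post.converged:
        logger.warning("stage 2 did not converge: max R-hat %.3f",
                       post.convergence.max_rhat)
    return post


def _newton_logistic(X: np.ndarray, y: np.ndarray, n_iter: int = 25,
                     ridge: float = 1e-4) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-6)
        H = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
        g = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


# ----------------------------------------------------------------------
# prediction


@dataclasses.dataclass
class PDPrediction:
    patient_id: str
    day: float
    probability: float
    interval: tuple[float, float]    # central 95%
    n_samples: int                   # ctDNA samples informing bhat


def _prob_draws(stage2: Stage2Posterior, x2: np.ndarray, bhat_i: np.ndarray,
                cond_X: np.ndarray, cond_y: np.ndarray, cond_bhat: np.ndarray,
                n_quad: int = 21) -> np.ndarray:
    """Per-draw PD probabilities for one scan, integrating the random intercept
    over its conditional posterior given the patient's conditioning scans."""
    draws = stage2.draws
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    u_nodes = np.sqrt(2.0) * draws["sigma_u"][:, None] * nodes[None, :]
    eta_new = draws["beta2"] @ x2
    eta_cond = np.einsum("kp,wp->wk", cond_X, draws["beta2"]) if len(cond_X) else \
        np.zeros((len(eta_new), 0))
    if stage2.use_ctdna:
        eta_new = eta_new + draws["gamma"] @ bhat_i
        if len(cond_X):
            eta_cond = eta_cond + np.einsum("ka,wa->wk", cond_bhat, draws["gamma"])
    w_post = _u_posterior_weights(eta_cond, cond_y, u_nodes, log_w)
    probs = 1.0 / (1.0 + np.exp(-(eta_new[:, None] + u_nodes)))
    return np.sum(w_post * probs, axis=1)


def _stage2_row(columns: list[str], day: float, er: float, her2: float,
                regimen: str) -> np.ndarray:
    x = np.zeros(len(columns))
    for j, col in enumerate(columns):
        if col == "intercept":
            x[j] = 1.0
        elif col == "time_years":
            x[j] = day / DAYS_PER_YEAR
        elif col == "er":
            x[j] = er
        elif col == "her2":
            x[j] = her2
        elif col == f"regimen:{regimen}":
            x[j] = 1.0
    return x


def predict_pd(stage1: Stage1Posterior, stage2: Stage2Posterior, cohort: Cohort,
               patient_id: str, day: float,
               config: SamplerConfig | None = None) -> PDPrediction:
    """Posterior PD probability for a patient at a time point.

    Conditions only on the patient's data up to ``day``: ``bhat_i`` is
    recomputed from plasma samples at or before ``day`` under each stage-1
    draw, and the random intercept on earlier scans. Refuses patients whose
    current regimen was flagged non-identifiable.
    """
    cfg = config or SamplerConfig()
    pid = str(patient_id)
    prow = cohort.patients.set_index("patient_id").loc[pid]
    intervals = _patient_intervals(cohort).get(pid, [])
    reg, start = _treatment_at(intervals, day)
    reg = reg if reg is not None else "none"
    if reg in stage2.data.flagged_regimens:
        raise ValueError(f"prediction refused: regimen {reg!r} is not identifiable "
                         "in the fitted model")

    samp = cohort.samples[(cohort.samples["patient_id"] == pid)
                          & (cohort.samples["day"] <= day)].sort_values("day")
    if samp.empty:
        raise ValueError(f"patient {pid} has no ctDNA sample at or before day {day}")
    d1 = stage1.data
    rows1 = np.flatnonzero((np.array(d1.patient_ids)[d1.patient_idx] == pid)
                           & (d1.days <= day))
    if len(rows1) == 0:
        raise ValueError(f"patient {pid} has no stage-1 rows at or before day {day}")
    sub_idx = np.zeros(len(rows1), dtype=int)
    bhat_i = _conditional_bhat(stage1.draws, d1.X[rows1], d1.Z[rows1], d1.y[rows1],
                               sub_idx, 1)[0]

    d2 = stage2.data
    pid_arr = np.array(d2.patient_ids)[d2.patient_idx]
    cond = np.flatnonzero((pid_arr == pid) & (d2.days < day))
    cond_bhat = np.tile(bhat_i, (len(cond), 1))
    x2 = _stage2_row(d2.columns, day, float(prow["er_status"]),
                     float(prow["her2_status"]), reg)
    draws = _prob_draws(stage2, x2, bhat_i, d2.X[cond], d2.y[cond], cond_bhat,
                        n_quad=cfg.n_quad)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PDPrediction(patient_id=pid, day=float(day),
                        probability=float(np.mean(draws)),
                        interval=(float(lo), float(hi)),
                        n_samples=len(rows1))


# ----------------------------------------------------------------------
# ROC utilities


def roc_points(y: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """Sensitivity/specificity at every threshold (descending score sweep)."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pos, neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        rows.append({"threshold": t,
                     "sensitivity": tp / pos if pos else np.nan,
                     "specificity": 1 - fp / neg if neg else np.nan})
    return pd.DataFrame(rows)


def auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal sweep (equals the Mann-Whitney
    statistic with ties counted half)."""
    pts = roc_points(y, scores)
    fpr = 1 - pts["specificity"].to_numpy()
    tpr = pts["sensitivity"].to_numpy()
    return float(np.trapezoid(tpr, fpr))


# ----------------------------------------------------------------------
# temporal validation


@dataclasses.dataclass
class TemporalValidationResult:
    predictions: pd.DataFrame          # patient, day, prob, lower, upper, truth, n_samples
    predictions_covonly: pd.DataFrame
    roc: pd.DataFrame
    auroc: float
    auroc_covonly: float
    sensitivity_at_specificity: float
    operating_specificity: float
    operating_cutoff: float
    confusion_per_100: dict[str, float]
    n_test: int
    n_excluded_flagged: int
    stage1: Stage1Posterior
    stage2: Stage2Posterior
    stage2_covonly: Stage2Posterior


def _holdout_split(cohort: Cohort) -> tuple[Cohort, pd.DataFrame]:
    """Hold out each patient's last CT scan (patients with >= 2 scans) and
    strip their ctDNA samples after the preceding scan from the training set."""
    scans = cohort.scans.sort_values(["patient_id", "day"])
    held_rows = []
    train = cohort.copy()
    drop_scan_idx = []
    for pid, grp in scans.groupby("patient_id"):
        if len(grp) < 2:
            continue
        last = grp.iloc[-1]
        preceding_day = float(grp.iloc[-2]["day"])
        held_rows.append({"patient_id": pid, "day": float(last["day"]),
                          "truth": int(last["progression"]),
                          "preceding_scan_day": preceding_day})
        drop_scan_idx.append(last.name)
        mask = (train.samples["patient_id"] == pid) & (train.samples["day"] > preceding_day)
        train.samples = train.samples[~mask]
    train.scans = train.scans.drop(index=drop_scan_idx)
    # refresh the post-follow-up flag against the training scan horizon
    last_train = train.scans.groupby("patient_id")["day"].max()
    ref = train.samples["patient_id"].map(last_train)
    train.samples = train.samples.copy()
    train.samples["post_followup"] = train.samples["day"] > ref.fillna(np.inf)
    train.samples = train.samples.reset_index(drop=True)
    train.scans = train.scans.reset_index(drop=True)
    return train, pd.DataFrame(held_rows)


def temporal_validation(cohort: Cohort, config: SamplerConfig | None = None,
                        operating_specificity: float = 0.66,
                        min_regimen_obs: int = 5) -> TemporalValidationResult:
    """Train on everything but each patient's last CT scan; predict those scans.

    Mirrors clinical deployment: the chronologically last observation per
    patient is the test set. Reports the ROC over held-out predictions, the
    AUROC with and without the ctDNA random-effect terms (covariates-only
    ablation), the sensitivity achievable at the requested specificity, and a
    true/false positive/negative table normalised per 100 patients at the
    training-calibrated probability cut-off.
    """
    cfg = config or SamplerConfig()
    train, held = _holdout_split(cohort)
    if held.empty:
        raise ValueError("temporal validation requires patients with at least 2 scans")
    d1, d2 = build_design_matrices(train, min_regimen_obs=min_regimen_obs)
    stage1 = fit_stage1(d1, cfg)
    stage2 = fit_stage2(d2, stage1, cfg, use_ctdna=True, force=True)
    stage2_cov = fit_stage2(d2, stage1, cfg, use_ctdna=False, force=True)

    er = dict(zip(cohort.patients["patient_id"], cohort.patients["er_status"]))
    her2 = dict(zip(cohort.patients["patient_id"], cohort.patients["her2_status"]))
    intervals = _patient_intervals(cohort)
    pid_arr = np.array(d2.patient_ids)[d2.patient_idx]
    bhat_map = stage1.bhat.set_index("patient_id")

    def predict_rows(stage2_fit):
        rows, excluded = [], 0
        for _, h in held.iterrows():
            pid, day = h["patient_id"], float(h["day"])
            if pid not in bhat_map.index or pd.isna(er.get(pid)) or pd.isna(her2.get(pid)):
                continue
            reg, _ = _treatment_at(intervals.get(pid, []), day)
            reg = reg if reg is not None else "none"
            if reg in stage2_fit.data.flagged_regimens:
                excluded += 1
                continue
            bhat_i = bhat_map.loc[pid, ["b0", "b1"]].to_numpy(dtype=float)
            cond = np.flatnonzero((pid_arr == pid) & (d2.days < day))
            x2 = _stage2_row(d2.columns, day, float(er[pid]), float(her2[pid]), reg)
            draws = _prob_draws(stage2_fit, x2, bhat_i, d2.X[cond], d2.y[cond],
                                np.tile(bhat_i, (len(cond), 1)), n_quad=cfg.n_quad)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append({"patient_id": pid, "day": day,
                         "prob": float(np.mean(draws)), "lower": float(lo),
                         "upper": float(hi), "truth": int(h["truth"]),
                         "n_samples": int(bhat_map.loc[pid, "n_samples"])})
        return pd.DataFrame(rows), excluded

    preds, n_excl = predict_rows(stage2)
    preds_cov, _ = predict_rows(stage2_cov)
    if preds.empty:
        raise ValueError("no held-out scans could be predicted")

    roc = roc_points(preds["truth"].to_numpy(), preds["prob"].to_numpy())
    area = auroc(preds["truth"].to_numpy(), preds["prob"].to_numpy())
    area_cov = auroc(preds_cov["truth"].to_numpy(), preds_cov["prob"].to_numpy()) \
        if not preds_cov.empty else float("nan")
    ok_spec = roc[roc["specificity"] >= operating_specificity]
    sens_at_spec = float(ok_spec["sensitivity"].max()) if len(ok_spec) else float("nan")

    # training-calibrated operating cut-off: in-sample fitted probabilities
    fitted = _in_sample_probs(stage2, cfg)
    cutoff = _cutoff_for_specificity(d2.y, fitted, operating_specificity)
    pred_pos = preds["prob"].to_numpy() >= cutoff
    truth = preds["truth"].to_numpy()
    n = len(preds)
    confusion = {
        "tp": float(np.sum(pred_pos & (truth == 1)) / n * 100),
        "fp": float(np.sum(pred_pos & (truth == 0)) / n * 100),
        "tn": float(np.sum(~pred_pos & (truth == 0)) / n * 100),
        "fn": float(np.sum(~pred_pos & (truth == 1)) / n * 100),
    }
    return TemporalValidationResult(
        predictions=preds, predictions_covonly=preds_cov, roc=roc,
        auroc=area, auroc_covonly=area_cov,
        sensitivity_at_specificity=sens_at_spec,
        operating_specificity=operating_specificity,
        operating_cutoff=cutoff, confusion_per_100=confusion,
        n_test=n, n_excluded_flagged=n_excl,
        stage1=stage1, stage2=stage2, stage2_covonly=stage2_cov,
    )


def _in_sample_probs(stage2: Stage2Posterior, cfg: SamplerConfig) -> np.ndarray:
    """Posterior-mean fitted PD probability for every training scan row."""
    d2 = stage2.data
    draws = stage2.draws
    eta = np.einsum("kp,wp->wk", d2.X, draws["beta2"])
    if stage2.use_ctdna:
        bhat = stage2.bhat.set_index("patient_id").loc[
            np.array(d2.patient_ids)[d2.patient_idx], ["b0", "b1"]].to_numpy(dtype=float)
        eta = eta + np.einsum("ka,wa->wk", bhat, draws["gamma"])
    eta = eta + stage2.u_draws[:, d2.patient_idx]
    return (1.0 / (1.0 + np.exp(-eta))).mean(axis=0)


def _cutoff_for_specificity(y: np.ndarray, probs: np.ndarray, target: float) -> float:
    """Smallest cut-off achieving at least the target specificity on (y, probs)."""
    neg = np.sort(probs[np.asarray(y) == 0])
    if len(neg) == 0:
        return 0.5
    k = int(np.ceil(target * len(neg)))
    if k <= 0:
        return float(neg[0])
    return float(np.nextafter(neg[min(k, len(neg)) - 1], np.inf))
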