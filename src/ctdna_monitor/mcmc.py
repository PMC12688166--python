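"""MCMC utilities for the Bayesian models.

The two-stage model's posteriors are reduced to a low-dimensional marginal
(random effects integrated out analytically or by quadrature), which makes a
classical Metropolis-Hastings scheme both fast and reliable: the posterior
mode and curvature are located first (quasi-Newton with batched
finite-difference gradients), and several independent chains then sample with
a mixture kernel -- an independence proposal (multivariate Student-t centred
on the mode with the Laplace covariance) for near-i.i.d. mixing on these
near-Gaussian posteriors, plus preconditioned random-walk steps for
robustness when the posterior deviates from the Gaussian approximation.

Convergence is monitored with the split-R-hat (Gelman-Rubin) diagnostic over
the independent chains; values below 1.1 are taken as converged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

RHAT_LIMIT = 1.1


# ----------------------------------------------------------------------
# prior log-densities (vectorized)


def normal_logpdf(x, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


def student_t_logpdf(x, df, scale):
    z = x / scale
    return (gammaln((df + 1) / 2) - gammaln(df / 2)
            - 0.5 * np.log(df * np.pi) - np.log(scale)
            - (df + 1) / 2 * np.log1p(z * z / df))


def half_cauchy_logpdf(x, scale):
    """log density of |Cauchy(0, scale)| for x >= 0."""
    return np.log(2.0) - np.log(np.pi * scale * (1 + (x / scale) ** 2))


def half_student_t_logpdf(x, df, scale):
    return np.log(2.0) + student_t_logpdf(x, df, scale)


# ----------------------------------------------------------------------
# results container and diagnostics


@dataclasses.dataclass
class EnsembleResult:
    """Post-burn-in draws from independent chains plus split-R-hat diagnostics."""

    chain: np.ndarray           # (n_chains, n_kept_steps, n_dim)
    param_names: list[str]
    rhat: np.ndarray            # per parameter
    acceptance: float

    @property
    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    @property
    def converged(self) -> bool:
        return bool(np.all(self.rhat < RHAT_LIMIT))

    def thin(self, n_keep: int, seed: int = 0) -> np.ndarray:
        """Evenly thinned draws interleaving the chains."""
        # transpose to (steps, chains, dim) so thinning spans all chains
        steps_first = np.moveaxis(self.chain, 0, 1).reshape(-1, self.chain.shape[-1])
        if len(steps_first) <= n_keep:
            return steps_first
        idx = np.linspace(0, len(steps_first) - 1, n_keep).astype(int)
        return steps_first[idx]


def split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter for a (n_chains, n_draws, n_dim) array."""
    chain = np.asarray(chain, dtype=float)
    if chain.ndim == 2:
        chain = chain[:, :, None]
    if chain.shape[0] < 2:
        raise ValueError("split-R-hat requires at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.rhat(az.convert_to_dataset(chain))
    return np.asarray(ds["x"].values, dtype=float)


# ----------------------------------------------------------------------
# mode finding and curvature


def _batched_gradient(log_prob, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    d = len(x)
    pts = np.concatenate([x + h * np.eye(d), x - h * np.eye(d)])
    vals = log_prob(pts)
    return (vals[:d] - vals[d:]) / (2 * h)


def _batched_hessian(log_prob, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x)
    pts, index = [], []
    for i in range(d):
        for j in range(i, d):
            ei, ej = h * np.eye(d)[i], h * np.eye(d)[j]
            pts += [x + ei + ej, x + ei - ej, x - ei + ej, x - ei - ej]
            index.append((i, j))
    vals = log_prob(np.asarray(pts)).reshape(-1, 4)
    H = np.zeros((d, d))
    for (i, j), (fpp, fpm, fmp, fmm) in zip(index, vals):
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def _laplace_approximation(log_prob, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a positive-definite Laplace covariance.

    The negative-Hessian eigenvalues are clipped to keep the proposal
    covariance well conditioned even when some direction is flat (e.g. a
    variance component piled up near zero).
    """

    def neg(x):
        val = log_prob(x[None, :])[0]
        return np.inf if not np.isfinite(val) else -val

    res = minimize(neg, x0, method="BFGS",
                   jac=lambda x: -_batched_gradient(log_prob, x),
                   options={"maxiter": 300, "gtol": 1e-6})
    xmap = res.x if np.isfinite(res.fun) else x0
    H = -_batched_hessian(log_prob, xmap)
    H = 0.5 * (H + H.T)
    eigval, eigvec = np.linalg.eigh(H)
    floor = max(np.max(eigval), 1.0) * 1e-8
    eigval = np.clip(eigval, floor, None)
    cov = (eigvec / eigval) @ eigvec.T
    return xmap, 0.5 * (cov + cov.T)


def _mvt_logpdf(x: np.ndarray, mu: np.ndarray, chol: np.ndarray, df: float) -> np.ndarray:
    """Multivariate Student-t log density for rows of ``x`` (Cholesky supplied)."""
    d = len(mu)
    sol = np.linalg.solve(chol, (x - mu).T).T
    maha = np.sum(sol**2, axis=1)
    logdet = np.sum(np.log(np.diag(chol)))
    return (gammaln((df + d) / 2) - gammaln(df / 2) - 0.5 * d * np.log(df * np.pi)
            - logdet - 0.5 * (df + d) * np.log1p(maha / df))


# ----------------------------------------------------------------------
# sampler


def run_chains(log_prob, x0: np.ndarray, param_names: list[str],
               n_chains: int = 6, n_steps: int = 3000, n_burn: int = 1000,
               seed: int = 0, proposal_df: float = 7.0,
               independence_weight: float = 0.7,
               proposal_scale: float = 1.3) -> EnsembleResult:
    """Sample the posterior with independent Metropolis-Hastings chains.

    ``log_prob`` maps an (n, n_dim) array to (n,) log densities and is called
    once per step for all chains jointly. Each step proposes, per chain,
    either an independence draw from a multivariate-t centred on the Laplace
    mode (probability ``independence_weight``) or a preconditioned
    random-walk step; both kernels leave the posterior invariant.
    Deterministic for a fixed seed.
    """
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)

    xmap, cov = _laplace_approximation(log_prob, x0)
    chol_ind = np.linalg.cholesky(proposal_scale * cov)
    chol_rw = np.linalg.cholesky((2.38**2 / d) * cov)

    # start each chain from an overdispersed draw around the mode
    state = xmap[None, :] + 1.5 * (rng.standard_normal((n_chains, d)) @ chol_ind.T)
    lp = log_prob(state)
    bad = ~np.isfinite(lp)
    for _ in range(100):
        if not bad.any():
            break
        state[bad] = xmap[None, :] + 0.1 * (
            rng.standard_normal((int(bad.sum()), d)) @ chol_ind.T)
        lp = log_prob(state)
        bad = ~np.isfinite(lp)
    if bad.any():
        raise RuntimeError("could not find finite starting points for the sampler")
    logq = _mvt_logpdf(state, xmap, chol_ind, proposal_df)

    kept = np.empty((n_chains, n_steps - n_burn, d))
    n_accept = 0
    for step in range(n_steps):
        use_ind = rng.random(n_chains) < independence_weight
        z = rng.standard_normal((n_chains, d))
        t_scale = np.sqrt(proposal_df / rng.chisquare(proposal_df, n_chains))
        prop_ind = xmap[None, :] + (z * t_scale[:, None]) @ chol_ind.T
        prop_rw = state + rng.standard_normal((n_chains, d)) @ chol_rw.T
        prop = np.where(use_ind[:, None], prop_ind, prop_rw)

        lp_prop = log_prob(prop)
        logq_prop = _mvt_logpdf(prop, xmap, chol_ind, proposal_df)
        # independence kernel corrects by the proposal ratio; the walk is symmetric
        log_alpha = lp_prop - lp + np.where(use_ind, logq - logq_prop, 0.0)
        accept = np.log(rng.random(n_chains)) < log_alpha
        state = np.where(accept[:, None], prop, state)
        lp = np.where(accept, lp_prop, lp)
        logq = np.where(accept, logq_prop, logq)
        n_accept += int(accept.sum())
        if step >= n_burn:
            kept[:, step - n_burn] = state

    return EnsembleResult(
        chain=kept,
        param_names=list(param_names),
        rhat=split_rhat(kept),
        acceptance=n_accept / (n_steps * n_chains),
    )

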