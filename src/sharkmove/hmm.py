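"""Covariate-dependent hidden Markov model for step/angle series.

The observation model follows standard practice for discrete-time animal
movement: per hidden behavioural state, step lengths are gamma-distributed
with a point mass at zero (the *zero-mass* parameter, accommodating frames
in which the animal does not move) and turning angles are von Mises.  The
hidden state evolves as a Markov chain whose transition probabilities depend
on a binary covariate (human presence) through a multinomial-logit link with
the diagonal as reference category:

    eta_ij = beta0_ij + beta1_ij * c   (j != i),   eta_ii = 0
    Gamma_ij(c) = exp(eta_ij) / sum_k exp(eta_ik)

Fitting maximises the exact forward-algorithm likelihood over all sequences
jointly, by quasi-Newton search on unconstrained transformed parameters
(log for mu, sigma, kappa; logit for zeta and the initial distribution;
identity for beta and theta), from many random starting points drawn inside
data-driven plausible ranges.  Standard errors come from the inverse of the
finite-difference observed information at the optimum.

State labels are canonicalized by ascending mean step length, so fitted
models are comparable across runs and against generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize, special, stats

from .preprocess import StepSeries

__all__ = [
    "EmissionParams",
    "TransitionModel",
    "HMMModel",
    "FitConfig",
    "gamma_reparam",
    "gamma_unreparam",
    "emission_logdensity",
    "transition_matrix",
    "forward_loglik",
    "fit_hmm",
    "select_model",
    "stationary",
    "StationaryResult",
    "viterbi",
    "wald_tests",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EmissionParams:
    """Per-state emission parameters, stored as length-K arrays.

    mu, sigma : mean / SD of the (nonzero) gamma step length
    theta     : von Mises mean turning angle, (-pi, pi]
    kappa     : von Mises concentration (>= 0)
    zeta      : zero-mass probability
    """

    mu: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    zeta: np.ndarray

    def __post_init__(self):
        for name in ("mu", "sigma", "theta", "kappa", "zeta"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (len(self.mu) == len(self.sigma) == len(self.theta) == len(self.kappa) == len(self.zeta)):
            raise ValueError("emission parameter arrays must share one length")
        if np.any(self.mu <= 0) or np.any(self.sigma <= 0):
            raise ValueError("mu and sigma must be positive")
        if np.any(self.kappa < 0):
            raise ValueError("kappa must be >= 0")
        if np.any((self.zeta < 0) | (self.zeta > 1)):
            raise ValueError("zeta must be in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.mu)


@dataclass
class TransitionModel:
    """Multinomial-logit transition coefficients.

    ``beta0`` and ``beta1`` are K x K matrices over ordered state pairs;
    diagonal entries are the reference category (logit 0) and ignored.
    ``beta1`` is all zeros for a null (covariate-free) model.
    """

    beta0: np.ndarray
    beta1: np.ndarray
    covariate_name: str = "human_present"

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.beta0.shape != self.beta1.shape or self.beta0.ndim != 2:
            raise ValueError("beta0 and beta1 must be equal-shape square matrices")

    @property
    def n_states(self) -> int:
        return self.beta0.shape[0]


def transition_matrix(tm: TransitionModel, covariate: int) -> np.ndarray:
    """Row-stochastic transition matrix under the given covariate value."""
    eta = tm.beta0 + tm.beta1 * covariate
    eta = eta.copy()
    np.fill_diagonal(eta, 0.0)
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


@dataclass
class HMMModel:
    """A fitted (or constructed) covariate HMM."""

    emissions: EmissionParams
    transitions: TransitionModel
    delta_init: np.ndarray
    use_covariate: bool = True
    log_likelihood: float = float("nan")
    aic: float = float("nan")
    n_parameters: int = 0
    convergence_info: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None   # working-scale parameter covariance
    data_fingerprint: tuple | None = None

    def __post_init__(self):
        self.delta_init = np.asarray(self.delta_init, dtype=float)
        k = self.emissions.n_states
        if self.transitions.n_states != k or len(self.delta_init) != k:
            raise ValueError("emissions, transitions and delta_init disagree on K")
        if self.n_parameters == 0:
            self.n_parameters = n_free_parameters(k, self.use_covariate)

    @property
    def n_states(self) -> int:
        return self.emissions.n_states

    def transition_matrix(self, covariate: int) -> np.ndarray:
        return transition_matrix(self.transitions, covariate)


def n_free_parameters(k: int, use_covariate: bool) -> int:
    """5K emission + K(K-1) per transition coefficient set + (K-1) initial."""
    per_set = k * (k - 1)
    return 5 * k + per_set * (2 if use_covariate else 1) + (k - 1)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def gamma_reparam(mu: float, sigma: float) -> tuple[float, float]:
    """(mean, SD) -> (shape, rate) of the gamma distribution."""
    if mu <= 0 or sigma <= 0:
        raise ValueError("mu and sigma must be positive")
    return mu * mu / (sigma * sigma), mu / (sigma * sigma)


def gamma_unreparam(shape: float, rate: float) -> tuple[float, float]:
    """(shape, rate) -> (mean, SD); inverse of :func:`gamma_reparam`."""
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    return shape / rate, math.sqrt(shape) / rate


def _log_i0(kappa):
    """log I0(kappa), overflow-safe (exponentially scaled Bessel)."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(kappa)) + kappa


def emission_logdensity(step, angle, mu, sigma, theta, kappa, zeta):
    """Log-density of one state's emission at (step, angle).

    Step part: ``log zeta`` at step 0, else ``log(1 - zeta)`` plus the gamma
    log-density.  Angle part: von Mises(theta, kappa), which at kappa = 0
    degenerates to the uniform density 1/(2 pi); a missing (NaN) angle
    contributes 0.  Vectorised over step/angle.
    """
    step = np.asarray(step, dtype=float)
    angle = np.asarray(angle, dtype=float)
    shape, rate = gamma_reparam(mu, sigma)
    with np.errstate(divide="ignore"):
        nonzero_part = np.log1p(-zeta) + stats.gamma.logpdf(step, a=shape, scale=1.0 / rate)
        zero_part = np.log(zeta) if zeta > 0 else -np.inf
    step_ll = np.where(step == 0.0, zero_part, nonzero_part)
    ang_ll = np.where(
        np.isnan(angle),
        0.0,
        kappa * np.cos(np.where(np.isnan(angle), 0.0, angle) - theta)
        - np.log(2.0 * np.pi)
        - _log_i0(kappa),
    )
    out = step_ll + ang_ll
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Data packing and the numba likelihood kernel
# ---------------------------------------------------------------------------


class PackedData:
    """Concatenated step/angle arrays of many sequences, kernel-ready."""

    def __init__(self, sequences: list[StepSeries]):
        if not sequences:
            raise ValueError("sequences must be nonempty")
        steps, angles, covs, starts = [], [], [], [0]
        for s in sequences:
            if len(s) < 2:
                raise ValueError(f"{s.video_id}: need at least 2 steps per sequence")
            steps.append(s.step)
            angles.append(s.angle)
            covs.append(int(s.covariate[0]))
            starts.append(starts[-1] + len(s))
        self.step = np.concatenate(steps)
        self.angle = np.concatenate(angles)
        self.seq_start = np.asarray(starts, dtype=np.int64)
        self.seq_cov = np.asarray(covs, dtype=np.int64)
        self.is_zero = self.step == 0.0
        with np.errstate(divide="ignore"):
            self.log_step = np.where(self.is_zero, 0.0, np.log(self.step))
        self.ang_missing = np.isnan(self.angle)
        # trig arrays are zeroed at missing angles so posterior-weighted sums
        # over observed angles reduce to plain matrix products
        self.cos_ang = np.where(self.ang_missing, 0.0, np.cos(np.nan_to_num(self.angle)))
        self.sin_ang = np.where(self.ang_missing, 0.0, np.sin(np.nan_to_num(self.angle)))
        self.n_obs = len(self.step)
        self.n_seq = len(sequences)

    @property
    def fingerprint(self) -> tuple:
        return (
            self.n_seq,
            self.n_obs,
            round(float(self.step.sum()), 9),
            round(float(np.nansum(self.angle)), 9),
        )


def _emission_matrix(data: PackedData, em: EmissionParams) -> np.ndarray:
    """Per-observation, per-state emission log-densities (n_obs x K)."""
    shape = em.mu**2 / em.sigma**2
    rate = em.mu / em.sigma**2
    log_gnorm = shape * np.log(rate) - special.gammaln(shape)
    with np.errstate(divide="ignore"):
        log_zeta = np.where(em.zeta > 0, np.log(np.maximum(em.zeta, 1e-300)), -np.inf)
    log_1mzeta = np.log1p(-np.minimum(em.zeta, 1.0 - 1e-16))
    log_vmnorm = -np.log(2.0 * np.pi) - _log_i0(em.kappa)
    step_part = np.where(
        data.is_zero[:, None],
        log_zeta[None, :],
        log_1mzeta[None, :]
        + np.outer(data.log_step, shape - 1.0)
        - np.outer(data.step, rate)
        + log_gnorm[None, :],
    )
    ang_part = (
        np.outer(data.cos_ang, em.kappa * np.cos(em.theta))
        + np.outer(data.sin_ang, em.kappa * np.sin(em.theta))
        + log_vmnorm[None, :]
    )
    ang_part[data.ang_missing] = 0.0
    return step_part + ang_part


@njit(cache=True)
def _forward(logp, seq_start, seq_cov, gamma0, gamma1, delta):
    K = delta.shape[0]
    alpha = np.empty(K)
    tmp = np.empty(K)
    ll = 0.0
    for s in range(seq_cov.shape[0]):
        G = gamma1 if seq_cov[s] == 1 else gamma0
        start = seq_start[s]
        end = seq_start[s + 1]
        for t in range(start, end):
            m = logp[t, 0]
            for k in range(1, K):
                if logp[t, k] > m:
                    m = logp[t, k]
            if not np.isfinite(m):
                return -np.inf
            if t == start:
                for k in range(K):
                    tmp[k] = delta[k] * np.exp(logp[t, k] - m)
            else:
                for j in range(K):
                    acc = 0.0
                    for i in range(K):
                        acc += alpha[i] * G[i, j]
                    tmp[j] = acc * np.exp(logp[t, j] - m)
            c = 0.0
            for k in range(K):
                c += tmp[k]
            if not (c > 0.0) or not np.isfinite(c):
                return -np.inf
            ll += np.log(c) + m
            for k in range(K):
                alpha[k] = tmp[k] / c
    return ll


@njit(cache=True)
def _forward_backward(logp, seq_start, seq_cov, gamma0, gamma1, delta):
    """Scaled forward-backward.

    Returns (ll, post, xi0, xi1, firstpost):
      post      — posterior state probabilities, n_obs x K
      xi0, xi1  — transition-pair posteriors summed over transitions, per
                  covariate class (K x K each)
      firstpost — first-frame posteriors summed over sequences (K,)
    """
    n, K = logp.shape
    ahat = np.empty((n, K))
    w = np.empty((n, K))
    cs = np.empty(n)
    post = np.empty((n, K))
    xi0 = np.zeros((K, K))
    xi1 = np.zeros((K, K))
    firstpost = np.zeros(K)
    ll = 0.0
    for s in range(seq_cov.shape[0]):
        G = gamma1 if seq_cov[s] == 1 else gamma0
        start = seq_start[s]
        end = seq_start[s + 1]
        for t in range(start, end):
            m = logp[t, 0]
            for k in range(1, K):
                if logp[t, k] > m:
                    m = logp[t, k]
            if not np.isfinite(m):
                return -np.inf, post, xi0, xi1, firstpost
            for k in range(K):
                w[t, k] = np.exp(logp[t, k] - m)
            if t == start:
                for k in range(K):
                    ahat[t, k] = delta[k] * w[t, k]
            else:
                for j in range(K):
                    acc = 0.0
                    for i in range(K):
                        acc += ahat[t - 1, i] * G[i, j]
                    ahat[t, j] = acc * w[t, j]
            c = 0.0
            for k in range(K):
                c += ahat[t, k]
            if not (c > 0.0) or not np.isfinite(c):
                return -np.inf, post, xi0, xi1, firstpost
            cs[t] = c
            ll += np.log(c) + m
            for k in range(K):
                ahat[t, k] /= c
        # backward pass and posterior accumulation for this sequence
        bhat = np.ones(K)
        bprev = np.empty(K)
        for k in range(K):
            post[end - 1, k] = ahat[end - 1, k]
        xi = xi1 if seq_cov[s] == 1 else xi0
        for t in range(end - 2, start - 1, -1):
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += G[i, j] * w[t + 1, j] * bhat[j]
                bprev[i] = acc / cs[t + 1]
            for i in range(K):
                for j in range(K):
                    xi[i, j] += (
                        ahat[t, i] * G[i, j] * w[t + 1, j] * bhat[j] / cs[t + 1]
                    )
            for k in range(K):
                bhat[k] = bprev[k]
                post[t, k] = ahat[t, k] * bhat[k]
        for k in range(K):
            firstpost[k] += post[start, k]
    return ll, post, xi0, xi1, firstpost


def _packed_loglik(model: HMMModel, data: PackedData) -> float:
    logp = _emission_matrix(data, model.emissions)
    return float(
        _forward(
            logp, data.seq_start, data.seq_cov,
            model.transition_matrix(0), model.transition_matrix(1),
            model.delta_init,
        )
    )


def state_posteriors(model: HMMModel, sequences: list[StepSeries]) -> np.ndarray:
    """Smoothed posterior state probabilities (n_total_steps x K)."""
    data = PackedData(sequences)
    logp = _emission_matrix(data, model.emissions)
    ll, post, *_ = _forward_backward(
        logp, data.seq_start, data.seq_cov,
        model.transition_matrix(0), model.transition_matrix(1), model.delta_init,
    )
    if not np.isfinite(ll):
        raise ValueError("non-finite likelihood")
    return post


def forward_loglik(model: HMMModel, sequences: list[StepSeries]) -> float:
    """Exact log-likelihood of the model over independent sequences.

    Scaled forward recursion in normalized-alpha form; missing angles
    contribute only the step part of the emission density.

    Raises
    ------
    ValueError
        If a non-finite density arises (the error names the first offending
        sequence and frame).
    """
    data = PackedData(sequences)
    ll = _packed_loglik(model, data)
    if not np.isfinite(ll):
        _locate_bad_frame(model, sequences)
        raise ValueError("non-finite likelihood")
    return ll


def _locate_bad_frame(model: HMMModel, sequences):
    for s in sequences:
        for t in range(len(s)):
            dens = [
                emission_logdensity(
                    s.step[t], s.angle[t],
                    model.emissions.mu[k], model.emissions.sigma[k],
                    model.emissions.theta[k], model.emissions.kappa[k],
                    model.emissions.zeta[k],
                )
                for k in range(model.n_states)
            ]
            if not np.isfinite(max(dens)):
                raise ValueError(
                    f"non-finite emission density at sequence {s.video_id!r}, "
                    f"frame transition {t} (step={s.step[t]}, angle={s.angle[t]})"
                )


# ---------------------------------------------------------------------------
# Parameter vector <-> model
# ---------------------------------------------------------------------------


def _offdiag_index(k: int):
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def _pack(model: HMMModel) -> np.ndarray:
    em = model.emissions
    k = model.n_states
    parts = [
        np.log(em.mu),
        np.log(em.sigma),
        em.theta,
        np.log(np.maximum(em.kappa, 1e-10)),
        special.logit(np.clip(em.zeta, 1e-13, 1.0 - 1e-13)),
    ]
    if k > 1:
        idx = _offdiag_index(k)
        parts.append(np.array([model.transitions.beta0[i, j] for i, j in idx]))
        if model.use_covariate:
            parts.append(np.array([model.transitions.beta1[i, j] for i, j in idx]))
        d = np.clip(model.delta_init, 1e-12, None)
        parts.append(np.log(d[:-1]) - np.log(d[-1]))
    return np.concatenate(parts)


def _unpack(x: np.ndarray, k: int, use_covariate: bool) -> HMMModel:
    pos = 0

    def take(n):
        nonlocal pos
        out = x[pos : pos + n]
        pos += n
        return out

    em = EmissionParams(
        mu=np.exp(take(k)),
        sigma=np.exp(take(k)),
        theta=take(k).copy(),
        kappa=np.exp(take(k)),
        zeta=special.expit(take(k)),
    )
    beta0 = np.zeros((k, k))
    beta1 = np.zeros((k, k))
    delta = np.ones(k) / k
    if k > 1:
        idx = _offdiag_index(k)
        b0 = take(len(idx))
        for v, (i, j) in zip(b0, idx):
            beta0[i, j] = v
        if use_covariate:
            b1 = take(len(idx))
            for v, (i, j) in zip(b1, idx):
                beta1[i, j] = v
        dl = np.concatenate([take(k - 1), [0.0]])
        dl -= dl.max()
        delta = np.exp(dl) / np.exp(dl).sum()
    return HMMModel(
        emissions=em,
        transitions=TransitionModel(beta0=beta0, beta1=beta1),
        delta_init=delta,
        use_covariate=use_covariate,
    )


def _negll_and_grad(x: np.ndarray, k: int, use_covariate: bool, data: PackedData):
    """Negative log-likelihood and its exact gradient on the working scale.

    The gradient uses Fisher's identity: the score of the marginal
    likelihood equals the posterior expectation of the complete-data score,
    so one forward-backward pass yields all partial derivatives at once.
    """
    model = _unpack(x, k, use_covariate)
    em = model.emissions
    logp = _emission_matrix(data, em)
    g0 = model.transition_matrix(0)
    g1 = model.transition_matrix(1)
    ll, post, xi0, xi1, firstpost = _forward_backward(
        logp, data.seq_start, data.seq_cov, g0, g1, model.delta_init
    )
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(x)

    nzf = (~data.is_zero).astype(float)
    notmf = (~data.ang_missing).astype(float)
    total = post.sum(axis=0)
    P1 = post.T @ nzf
    P0 = total - P1
    Pa = post.T @ notmf
    Sx = post.T @ data.step
    Slx = post.T @ data.log_step
    Sc = post.T @ data.cos_ang
    Ss = post.T @ data.sin_ang

    shape = em.mu**2 / em.sigma**2
    rate = em.mu / em.sigma**2
    d_shape = Slx + P1 * (np.log(rate) - special.digamma(shape))
    d_rate = -Sx + P1 * shape / rate
    g_logmu = 2.0 * shape * d_shape + rate * d_rate
    g_logsigma = -2.0 * shape * d_shape - 2.0 * rate * d_rate
    cth, sth = np.cos(em.theta), np.sin(em.theta)
    g_theta = em.kappa * (cth * Ss - sth * Sc)
    bessel_ratio = special.i1e(em.kappa) / special.i0e(em.kappa)
    g_logkappa = em.kappa * (cth * Sc + sth * Ss - Pa * bessel_ratio)
    g_logitzeta = P0 * (1.0 - em.zeta) - P1 * em.zeta

    parts = [g_logmu, g_logsigma, g_theta, g_logkappa, g_logitzeta]
    if k > 1:
        idx = _offdiag_index(k)
        row0 = xi0.sum(axis=1)
        row1 = xi1.sum(axis=1)
        gb0 = (xi0 - g0 * row0[:, None]) + (xi1 - g1 * row1[:, None])
        parts.append(np.array([gb0[i, j] for i, j in idx]))
        if use_covariate:
            gb1 = xi1 - g1 * row1[:, None]
            parts.append(np.array([gb1[i, j] for i, j in idx]))
        g_delta = firstpost[:-1] - data.n_seq * model.delta_init[:-1]
        parts.append(g_delta)
    grad = np.concatenate(parts)
    return -ll, -grad


def _working_bounds(k: int, use_covariate: bool):
    b = []
    b += [(-25.0, 8.0)] * k          # log mu
    b += [(-25.0, 8.0)] * k          # log sigma
    b += [(-np.pi, np.pi)] * k       # theta
    b += [(-12.0, 6.0)] * k          # log kappa
    b += [(-30.0, 8.0)] * k          # logit zeta
    if k > 1:
        n_off = k * (k - 1)
        b += [(-20.0, 20.0)] * n_off
        if use_covariate:
            b += [(-20.0, 20.0)] * n_off
        b += [(-20.0, 20.0)] * (k - 1)
    return b


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Multi-start optimisation settings.

    Random starts are drawn inside plausible ranges identified from the data
    itself: mu and sigma log-uniform between the 10th and 90th percentile of
    nonzero step lengths, kappa log-uniform on [0.01, 20], theta uniform on
    (-pi, pi], beta0 uniform on [-5, 0] (sticky chains), beta1 uniform on
    [-2, 2].  zeta is not randomised: every start begins at the pooled
    observed zero-step proportion.
    """

    n_starts: int = 75
    seed: int = 0
    maxiter: int = 1000
    mu_quantiles: tuple[float, float] = (0.10, 0.90)
    kappa_range: tuple[float, float] = (0.01, 20.0)
    beta0_range: tuple[float, float] = (-5.0, 0.0)
    beta1_range: tuple[float, float] = (-2.0, 2.0)
    tol: float = 1e-8
    compute_hessian: bool = True


def _draw_start(rng, data: PackedData, k: int, use_covariate: bool, cfg: FitConfig):
    nz = data.step[~data.is_zero]
    if len(nz) == 0:
        raise ValueError("all step lengths are zero; nothing to fit")
    qlo, qhi = np.quantile(nz, cfg.mu_quantiles)
    qlo = max(qlo, 1e-12)
    qhi = max(qhi, qlo * (1 + 1e-9))
    log_mu = rng.uniform(np.log(qlo), np.log(qhi), size=k)
    log_sigma = rng.uniform(np.log(qlo), np.log(qhi), size=k)
    theta = rng.uniform(-np.pi, np.pi, size=k)
    log_kappa = rng.uniform(np.log(cfg.kappa_range[0]), np.log(cfg.kappa_range[1]), size=k)
    zero_prop = float(data.is_zero.mean())
    zero_prop = min(max(zero_prop, 1.0 / (2.0 * data.n_obs)), 1.0 - 1e-6)
    logit_zeta = np.full(k, special.logit(zero_prop))
    parts = [log_mu, log_sigma, theta, log_kappa, logit_zeta]
    if k > 1:
        n_off = k * (k - 1)
        parts.append(rng.uniform(*cfg.beta0_range, size=n_off))
        if use_covariate:
            parts.append(rng.uniform(*cfg.beta1_range, size=n_off))
        parts.append(np.zeros(k - 1))
    return np.concatenate(parts)


def _canonical_permutation(model: HMMModel) -> np.ndarray:
    return np.argsort(model.emissions.mu, kind="stable")


def canonicalize(model: HMMModel) -> HMMModel:
    """Relabel states by ascending mean step length (mu).

    The likelihood is invariant under state relabelling; ordering by mu
    makes fitted labels deterministic and comparable across runs.
    """
    perm = _canonical_permutation(model)
    em = model.emissions
    new_em = EmissionParams(
        mu=em.mu[perm], sigma=em.sigma[perm], theta=em.theta[perm],
        kappa=em.kappa[perm], zeta=em.zeta[perm],
    )
    tm = TransitionModel(
        beta0=model.transitions.beta0[np.ix_(perm, perm)],
        beta1=model.transitions.beta1[np.ix_(perm, perm)],
        covariate_name=model.transitions.covariate_name,
    )
    return replace(
        model,
        emissions=new_em,
        transitions=tm,
        delta_init=model.delta_init[perm],
        covariance=None,  # recomputed at the canonical parameter point
    )


def _fd_hessian(grad_f, x, rel_step=1e-5):
    """Hessian by central finite differences of an exact gradient."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i] = (grad_f(x + ei) - grad_f(x - ei)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def fit_hmm(
    sequences: list[StepSeries],
    n_states: int,
    use_covariate: bool = True,
    config: FitConfig | None = None,
) -> HMMModel:
    """Maximum-likelihood fit of the covariate HMM by multi-start quasi-Newton.

    Each of ``config.n_starts`` random initializations is optimised with
    L-BFGS-B on the working (transformed) scale; the best-likelihood
    converged fit is returned, canonicalized by ascending mu, with AIC and —
    when ``config.compute_hessian`` — the working-scale parameter covariance
    (inverse observed information) attached for Wald tests and bootstrap
    intervals.  Deterministic given ``config.seed``.
    """
    cfg = config or FitConfig()
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    data = PackedData(sequences)
    k = n_states
    rng = np.random.default_rng(cfg.seed)
    bounds = _working_bounds(k, use_covariate)

    def objective(x):
        return _negll_and_grad(x, k, use_covariate, data)

    best = None
    diagnostics = []
    for s in range(cfg.n_starts):
        x0 = _draw_start(rng, data, k, use_covariate, cfg)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": cfg.maxiter, "ftol": cfg.tol, "maxfun": 10**6},
        )
        converged = bool(res.success) and res.fun < 1e11
        diagnostics.append(
            {"start": s, "loglik": -float(res.fun), "converged": converged,
             "message": str(res.message)}
        )
        if converged and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "no start converged; per-start diagnostics: " + repr(diagnostics)
        )

    model = _unpack(best.x, k, use_covariate)
    model = canonicalize(model)
    x_hat = _pack(model)
    ll = -float(best.fun)
    model.log_likelihood = ll
    model.n_parameters = n_free_parameters(k, use_covariate)
    model.aic = -2.0 * ll + 2.0 * model.n_parameters
    model.data_fingerprint = data.fingerprint
    model.convergence_info = {
        "n_starts": cfg.n_starts,
        "n_converged": sum(d["converged"] for d in diagnostics),
        "best_start": int(np.argmax([d["loglik"] for d in diagnostics])),
        "seed": cfg.seed,
        "starts": diagnostics,
    }
    if cfg.compute_hessian:
        H = _fd_hessian(
            lambda x: -_negll_and_grad(x, k, use_covariate, data)[1], x_hat
        )
        model.covariance = _safe_inverse_information(H)
    return model


def _safe_inverse_information(hessian_ll: np.ndarray) -> np.ndarray:
    """Pseudo-inverse of the observed information -H, floored to PSD.

    Near-flat directions (e.g. theta of a nearly uniform-angle state, or
    zeta of a state that never emitted a zero step) give tiny curvature;
    the pseudo-inverse then yields honestly large standard errors rather
    than failing.
    """
    info = -hessian_ll
    info = 0.5 * (info + info.T)
    eigval, eigvec = np.linalg.eigh(info)
    eigval = np.maximum(eigval, 1e-12)
    return (eigvec / eigval) @ eigvec.T


# ---------------------------------------------------------------------------
# Standard errors on the natural scale
# ---------------------------------------------------------------------------


def emission_standard_errors(model: HMMModel) -> dict:
    """Delta-method SEs of (mu, sigma, theta, kappa, zeta) per state."""
    if model.covariance is None:
        raise ValueError("model has no covariance; refit with compute_hessian=True")
    k = model.n_states
    se_work = np.sqrt(np.clip(np.diag(model.covariance), 0.0, None))
    em = model.emissions
    jac = np.concatenate([
        em.mu,                       # d mu / d log mu
        em.sigma,
        np.ones(k),                  # theta: identity
        em.kappa,
        em.zeta * (1.0 - em.zeta),   # d expit / d logit
    ])
    se = se_work[: 5 * k] * jac
    return {
        "mu": se[0:k], "sigma": se[k:2 * k], "theta": se[2 * k:3 * k],
        "kappa": se[3 * k:4 * k], "zeta": se[4 * k:5 * k],
    }


def _beta_slice(k: int, use_covariate: bool) -> tuple[slice, slice | None]:
    n_off = k * (k - 1)
    b0 = slice(5 * k, 5 * k + n_off)
    b1 = slice(5 * k + n_off, 5 * k + 2 * n_off) if use_covariate else None
    return b0, b1


# ---------------------------------------------------------------------------
# Model selection, stationary distribution, decoding, Wald tests
# ---------------------------------------------------------------------------


def select_model(fits: list[HMMModel]):
    """Pick the minimum-AIC model; return it with a comparison table.

    All fits must have been estimated on the same data (checked via the
    stored data fingerprint).
    """
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were estimated on different data")
    best = min(fits, key=lambda f: f.aic)
    table = pd.DataFrame(
        {
            "n_states": [f.n_states for f in fits],
            "covariate": [f.use_covariate for f in fits],
            "n_parameters": [f.n_parameters for f in fits],
            "loglik": [f.log_likelihood for f in fits],
            "aic": [f.aic for f in fits],
        }
    )
    table["delta_aic"] = table["aic"] - best.aic
    table["delta_loglik"] = table["loglik"] - best.log_likelihood
    return best, table.sort_values("aic").reset_index(drop=True)


@dataclass
class StationaryResult:
    """Long-run state distribution under one covariate level, with 95% CIs."""

    covariate: int
    delta: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Solve delta @ Gamma = delta, delta >= 0, sum(delta) = 1."""
    k = gamma.shape[0]
    a = gamma.T - np.eye(k)
    if np.linalg.matrix_rank(a, tol=1e-10) < k - 1:
        raise ValueError("transition matrix is (numerically) reducible; "
                         "stationary distribution not unique")
    A = np.vstack([a, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


def stationary(
    model: HMMModel, covariate: int, n_boot: int = 500, seed: int = 0
) -> StationaryResult:
    """Long-run state occupancy under a covariate level, with bootstrap CIs.

    The point estimate solves delta @ Gamma(c) = delta.  Confidence
    intervals come from a parametric bootstrap that resamples the transition
    coefficients from their asymptotic normal distribution (covariance block
    of the inverse observed information), recomputes delta for each draw,
    and takes the 2.5/97.5 percentiles.  Requires a fitted model with
    covariance information when ``n_boot > 0``.
    """
    gamma = model.transition_matrix(covariate)
    delta = stationary_distribution(gamma)
    if n_boot <= 0:
        return StationaryResult(covariate=covariate, delta=delta)
    if model.covariance is None:
        raise ValueError("model has no covariance; refit with compute_hessian=True "
                         "or call with n_boot=0")
    k = model.n_states
    b0_sl, b1_sl = _beta_slice(k, model.use_covariate)
    idx = list(range(b0_sl.start, b0_sl.stop))
    if b1_sl is not None:
        idx += list(range(b1_sl.start, b1_sl.stop))
    x_hat = _pack(model)
    mean = x_hat[idx]
    cov = model.covariance[np.ix_(idx, idx)]
    cov = 0.5 * (cov + cov.T)
    rng = np.random.default_rng(seed)
    # near-flat likelihood directions leave the covariance PSD only up to
    # rounding at huge dynamic range; the SVD sampler handles that safely
    draws = rng.multivariate_normal(
        mean, cov, size=n_boot, method="svd", check_valid="ignore"
    )
    offs = _offdiag_index(k)
    n_off = len(offs)
    sims = np.empty((n_boot, k))
    for r in range(n_boot):
        beta0 = np.zeros((k, k))
        beta1 = np.zeros((k, k))
        for v, (i, j) in zip(draws[r, :n_off], offs):
            beta0[i, j] = v
        if model.use_covariate:
            for v, (i, j) in zip(draws[r, n_off:], offs):
                beta1[i, j] = v
        g = transition_matrix(
            TransitionModel(beta0=beta0, beta1=beta1), covariate
        )
        try:
            sims[r] = stationary_distribution(g)
        except ValueError:
            sims[r] = delta
    lo = np.minimum(np.percentile(sims, 2.5, axis=0), delta)
    hi = np.maximum(np.percentile(sims, 97.5, axis=0), delta)
    return StationaryResult(covariate=covariate, delta=delta, ci_lower=lo, ci_upper=hi)


def viterbi(model: HMMModel, seq: StepSeries) -> np.ndarray:
    """Most probable hidden state path (1-based labels), one per step."""
    k = model.n_states
    n = len(seq)
    logd = np.column_stack(
        [
            emission_logdensity(
                seq.step, seq.angle,
                model.emissions.mu[j], model.emissions.sigma[j],
                model.emissions.theta[j], model.emissions.kappa[j],
                model.emissions.zeta[j],
            )
            for j in range(k)
        ]
    )
    with np.errstate(divide="ignore"):
        log_gamma = np.log(model.transition_matrix(int(seq.covariate[0])))
        log_delta = np.log(np.maximum(model.delta_init, 1e-300))
    score = log_delta + logd[0]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = score[:, None] + log_gamma
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(k)] + logd[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path + 1


def wald_tests(model: HMMModel, alpha: float = 0.05):
    """Wald z-tests of the covariate effect on each transition logit.

    The transition model is itself a multinomial-logit regression of the
    next state on the covariate; its beta1 coefficients govern how human
    presence shifts each transition probability.  SEs are read from the
    inverse observed information at the optimum.
    """
    import pandas as pd

    if not model.use_covariate:
        raise ValueError("model has no covariate effects to test")
    if model.covariance is None:
        raise ValueError("model has no covariance; refit with compute_hessian=True")
    k = model.n_states
    _, b1_sl = _beta_slice(k, True)
    se = np.sqrt(np.clip(np.diag(model.covariance)[b1_sl], 0.0, None))
    if np.any(se == 0):
        raise ValueError("degenerate (zero) SE; check identifiability and refit")
    rows = []
    for (i, j), s in zip(_offdiag_index(k), se):
        b = model.transitions.beta1[i, j]
        z = b / s
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "transition": f"{i + 1}->{j + 1}",
                "beta1": b,
                "se": s,
                "z": z,
                "p_value": p,
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows).set_index("transition")
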