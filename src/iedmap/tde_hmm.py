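"""Variational-Bayes inference of a K-state Gaussian-observation hidden
Markov model on time-delay-embedded PCA scores.

The observation model is a full-covariance multivariate Gaussian per state in
component space; because the components span a lagged window of the sensor
data, state covariances capture spectral (autocovariance) structure as well
as variance and cross-channel covariance.  Conjugate priors are used
throughout (Dirichlet rows for the transition matrix and initial
distribution; Normal-Wishart for each state's mean and precision), so every
update is closed form and the variational free energy — the negative
evidence lower bound — decreases monotonically across iterations.

State time courses are binarized at a posterior-probability threshold that
is strictly above 1/2, which guarantees at most one active state per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import digamma, gammaln

from ._fb import _fb_core
from .exceptions import DomainError, InferenceError, ParameterError
from .preprocess import EmbeddedData

__all__ = [
    "HMMConfig",
    "HMMModel",
    "StateTimeCourse",
    "TransitionStats",
    "fit_hmm",
    "forward_backward",
    "free_energy",
    "binarize_states",
    "transition_stats",
    "empirical_transition_matrix",
]


@dataclass
class HMMConfig:
    """Inference configuration.

    ``window_ms`` and ``n_components`` describe the embedding the scores came
    from (recorded for provenance; the sweep range of interest is 33-207 ms
    and 3-9 states).  ``probability_threshold`` must be in (0.5, 1] so that
    binarized states are mutually exclusive.
    """

    n_states: int = 5
    window_ms: float = 73.0
    n_components: int = 50
    max_iter: int = 200
    free_energy_tol: float = 1e-6  # relative change
    n_restarts: int = 5
    seed: int = 0
    probability_threshold: float = 2.0 / 3.0
    dirichlet_alpha: float = 1.0
    dirichlet_diag_boost: float = 0.0  # optional stickiness prior
    beta0: float = 1e-3
    covariance_floor: float = 1e-10  # relative jitter if a scatter update is singular

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ParameterError("need at least 2 states")
        if not 0.5 < self.probability_threshold <= 1.0:
            raise ParameterError("probability threshold must be in (0.5, 1]")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")


@dataclass
class HMMModel:
    """Fitted model: posterior expectations plus the full conjugate posterior."""

    K: int
    means: np.ndarray  # (K, D) posterior mean of state means
    covariances: np.ndarray  # (K, D, D) posterior expected covariance
    transmat: np.ndarray  # (K, K) posterior-mean transition matrix
    pi: np.ndarray  # (K,)
    gamma: np.ndarray  # (T, K) posterior state probabilities
    xi_sums: np.ndarray  # (K, K) expected transition counts
    free_energy_trace: np.ndarray
    # conjugate posterior parameters
    alpha_trans: np.ndarray = field(default=None)  # (K, K) Dirichlet
    alpha_init: np.ndarray = field(default=None)  # (K,)
    beta: np.ndarray = field(default=None)  # (K,)
    nu: np.ndarray = field(default=None)  # (K,)
    wishart_w: np.ndarray = field(default=None)  # (K, D, D)
    config: Optional[HMMConfig] = None

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[-1])


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


def forward_backward(
    log_obs: np.ndarray, A: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact smoothed posteriors for a hidden Markov chain.

    ``log_obs`` is (T, K) log observation densities (finite); ``A`` may be a
    proper row-stochastic matrix or the sub-stochastic geometric-mean
    weights used inside VB.  Returns (gamma, xi_sums, log_evidence).
    """
    log_obs = np.asarray(log_obs, dtype=float)
    if log_obs.ndim != 2:
        raise ParameterError("log_obs must be (T, K)")
    if not np.all(np.isfinite(log_obs)):
        raise DomainError("log observation densities must be finite")
    T, K = log_obs.shape
    A = np.asarray(A, dtype=float).reshape(K, K)
    pi = np.asarray(pi, dtype=float).reshape(K)
    if np.any(A < 0) or np.any(pi < 0):
        raise ParameterError("transition/initial weights must be non-negative")
    if K == 1:
        return np.ones((T, 1)), np.array([[float(T - 1)]]), float(log_obs.sum())
    shift = log_obs.max(axis=1)
    B = np.exp(log_obs - shift[:, None])
    gamma, xi, log_norm = _fb_core(B, A, pi)
    return gamma, xi, float(log_norm + shift.sum())


# ---------------------------------------------------------------------------
# conjugate machinery
# ---------------------------------------------------------------------------


def _log_wishart_b(W: np.ndarray, nu: float) -> float:
    D = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    i = np.arange(1, D + 1)
    return float(
        -0.5 * nu * logdet
        - 0.5 * nu * D * np.log(2.0)
        - 0.25 * D * (D - 1) * np.log(np.pi)
        - np.sum(gammaln(0.5 * (nu + 1 - i)))
    )


def _e_logdet_lambda(W: np.ndarray, nu: float) -> float:
    D = W.shape[0]
    _, logdet = np.linalg.slogdet(W)
    i = np.arange(1, D + 1)
    return float(np.sum(digamma(0.5 * (nu + 1 - i))) + D * np.log(2.0) + logdet)


def _kl_dirichlet(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    aq0, ap0 = alpha_q.sum(), alpha_p.sum()
    return float(
        gammaln(aq0)
        - np.sum(gammaln(alpha_q))
        - gammaln(ap0)
        + np.sum(gammaln(alpha_p))
        + np.sum((alpha_q - alpha_p) * (digamma(alpha_q) - digamma(aq0)))
    )


class _Prior:
    """Weakly informative conjugate prior scaled to the data covariance."""

    def __init__(self, X: np.ndarray, cfg: HMMConfig):
        T, D = X.shape
        self.D = D
        self.m0 = X.mean(axis=0)
        self.beta0 = cfg.beta0
        self.nu0 = D + 2.0
        S = np.cov(X, rowvar=False)
        S = np.atleast_2d(S) + cfg.covariance_floor * np.trace(np.atleast_2d(S)) / D * np.eye(D)
        # E[Lambda] under the prior equals inv(S): W0 = inv(S) / nu0
        self.w0 = np.linalg.inv(S) / self.nu0
        self.w0_inv = S * self.nu0
        self.alpha_trans = np.full((cfg.n_states, cfg.n_states), cfg.dirichlet_alpha)
        if cfg.dirichlet_diag_boost > 0:
            self.alpha_trans += cfg.dirichlet_diag_boost * np.eye(cfg.n_states)
        self.alpha_init = np.full(cfg.n_states, cfg.dirichlet_alpha)
        self.log_b0 = _log_wishart_b(self.w0, self.nu0)


class _Posterior:
    """Conjugate posterior q(theta); updated in closed form from expected counts."""

    def __init__(self, prior: _Prior, K: int):
        self.prior = prior
        self.K = K
        D = prior.D
        self.m = np.tile(prior.m0, (K, 1))
        self.beta = np.full(K, prior.beta0)
        self.nu = np.full(K, prior.nu0)
        self.w = np.tile(prior.w0, (K, 1, 1))
        self.alpha_trans = prior.alpha_trans.copy()
        self.alpha_init = prior.alpha_init.copy()

    def m_step(self, X: np.ndarray, gamma: np.ndarray, xi_sums: np.ndarray) -> None:
        p = self.prior
        K, D = self.K, p.D
        Nk = gamma.sum(axis=0) + 1e-12
        xbar = (gamma.T @ X) / Nk[:, None]
        self.beta = p.beta0 + Nk
        self.nu = p.nu0 + Nk
        self.m = (p.beta0 * p.m0[None, :] + Nk[:, None] * xbar) / self.beta[:, None]
        for k in range(K):
            Xc = X - xbar[k]
            Sk = (Xc * gamma[:, k : k + 1]).T @ Xc
            dm = (xbar[k] - p.m0)[:, None]
            w_inv = p.w0_inv + Sk + (p.beta0 * Nk[k] / self.beta[k]) * (dm @ dm.T)
            w_inv = 0.5 * (w_inv + w_inv.T)
            try:
                self.w[k] = np.linalg.inv(w_inv)
            except np.linalg.LinAlgError:
                w_inv += np.trace(w_inv) / D * 1e-8 * np.eye(D)
                try:
                    self.w[k] = np.linalg.inv(w_inv)
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise InferenceError("singular covariance update") from exc
        self.alpha_trans = p.alpha_trans + xi_sums
        self.alpha_init = p.alpha_init + gamma[0]

    def expected_log_obs(self, X: np.ndarray) -> np.ndarray:
        """E_q[log N(x_t | mu_k, Lambda_k^-1)] for every t, k."""
        T, D = X.shape
        out = np.empty((T, self.K))
        for k in range(self.K):
            e_logdet = _e_logdet_lambda(self.w[k], self.nu[k])
            Xc = X - self.m[k]
            # nu (x-m)^T W (x-m) via Cholesky of W
            L = np.linalg.cholesky(self.w[k])
            Y = Xc @ L
            quad = self.nu[k] * np.einsum("td,td->t", Y, Y)
            out[:, k] = 0.5 * (e_logdet - D / self.beta[k] - quad - D * np.log(2 * np.pi))
        return out

    def expected_log_weights(self) -> tuple[np.ndarray, np.ndarray]:
        logA = digamma(self.alpha_trans) - digamma(self.alpha_trans.sum(axis=1, keepdims=True))
        logpi = digamma(self.alpha_init) - digamma(self.alpha_init.sum())
        return logA, logpi

    def kl_to_prior(self) -> float:
        p = self.prior
        D = p.D
        kl = _kl_dirichlet(self.alpha_init, p.alpha_init)
        for k in range(self.K):
            kl += _kl_dirichlet(self.alpha_trans[k], p.alpha_trans[k])
            e_logdet = _e_logdet_lambda(self.w[k], self.nu[k])
            dm = self.m[k] - p.m0
            quad = p.beta0 * self.nu[k] * dm @ self.w[k] @ dm
            kl_gauss = 0.5 * (
                D * p.beta0 / self.beta[k] + quad - D + D * np.log(self.beta[k] / p.beta0)
            )
            kl_wish = (
                0.5 * (self.nu[k] - p.nu0) * e_logdet
                - 0.5 * self.nu[k] * D
                + 0.5 * self.nu[k] * np.trace(p.w0_inv @ self.w[k])
                + _log_wishart_b(self.w[k], self.nu[k])
                - p.log_b0
            )
            kl += kl_gauss + kl_wish
        return float(kl)


def _vb_e_step(post: _Posterior, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    log_obs = post.expected_log_obs(X)
    logA, logpi = post.expected_log_weights()
    gamma, xi_sums, log_norm = forward_backward(log_obs, np.exp(logA), np.exp(logpi))
    f = -(log_norm - post.kl_to_prior())
    return gamma, xi_sums, f


def fit_hmm(scores: "np.ndarray | EmbeddedData", cfg: Optional[HMMConfig] = None) -> HMMModel:
    """Variational-Bayes EM with random restarts.

    Each restart initializes random responsibilities, runs conjugate
    E/M updates to convergence (relative free-energy change below
    ``free_energy_tol`` or ``max_iter`` iterations), and the restart with the
    lowest final free energy is kept.  Fully reproducible given the seed.
    """
    cfg = cfg or HMMConfig()
    if isinstance(scores, EmbeddedData):
        if scores.scores is None:
            raise ParameterError("EmbeddedData has no PCA scores; run pca_reduce first")
        X = scores.scores
    else:
        X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ParameterError("scores must be (T, D)")
    if not np.all(np.isfinite(X)):
        raise DomainError("scores must be finite")
    T, D = X.shape
    K = cfg.n_states
    if T <= 10 * K:
        raise ParameterError(f"need more than {10 * K} samples for {K} states")

    prior = _Prior(X, cfg)
    root = np.random.default_rng(cfg.seed)
    best: Optional[HMMModel] = None
    for rng in root.spawn(max(1, cfg.n_restarts)):
        post = _Posterior(prior, K)
        resp = rng.dirichlet(np.ones(K), size=T)
        resp = 0.9 * resp + 0.1 / K
        xi0 = resp[:-1].T @ resp[1:]
        post.m_step(X, resp, xi0)
        trace: list[float] = []
        gamma = resp
        xi_sums = xi0
        for _ in range(cfg.max_iter):
            gamma, xi_sums, f = _vb_e_step(post, X)
            trace.append(f)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.free_energy_tol * abs(trace[-2]):
                break
            post.m_step(X, gamma, xi_sums)
        model = HMMModel(
            K=K,
            means=post.m.copy(),
            covariances=np.stack(
                [np.linalg.inv(post.nu[k] * post.w[k]) for k in range(K)]
            ),
            transmat=post.alpha_trans / post.alpha_trans.sum(axis=1, keepdims=True),
            pi=post.alpha_init / post.alpha_init.sum(),
            gamma=gamma,
            xi_sums=xi_sums,
            free_energy_trace=np.asarray(trace),
            alpha_trans=post.alpha_trans.copy(),
            alpha_init=post.alpha_init.copy(),
            beta=post.beta.copy(),
            nu=post.nu.copy(),
            wishart_w=post.w.copy(),
            config=cfg,
        )
        if best is None or model.free_energy < best.free_energy:
            best = model
    return best


def free_energy(model: HMMModel, scores: "np.ndarray | EmbeddedData") -> float:
    """Variational free energy of the model's posterior on the given scores."""
    X = scores.scores if isinstance(scores, EmbeddedData) else np.asarray(scores, dtype=float)
    if X.shape[1] != model.means.shape[1]:
        raise DomainError("score dimensionality does not match the model")
    cfg = model.config or HMMConfig(n_states=model.K)
    prior = _Prior(X, cfg)
    post = _Posterior(prior, model.K)
    post.m = model.means
    post.beta = model.beta
    post.nu = model.nu
    post.w = model.wishart_w
    post.alpha_trans = model.alpha_trans
    post.alpha_init = model.alpha_init
    _, _, f = _vb_e_step(post, X)
    return f


# ---------------------------------------------------------------------------
# state time courses
# ---------------------------------------------------------------------------


@dataclass
class StateTimeCourse:
    """Binary state activations aligned to lag-0 samples of the embedding."""

    active: np.ndarray  # (T, K) bool
    fs: float
    valid_offset: int  # samples trimmed at each edge of the original run

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_states(self) -> int:
        return self.active.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time (s) of each valid sample in the original run's clock."""
        return (self.valid_offset + np.arange(self.active.shape[0])) / self.fs

    def visits(self, state: int) -> list[tuple[int, int]]:
        """Maximal runs of consecutive active samples, as (start, end) indices
        (end inclusive)."""
        a = self.active[:, state].astype(int)
        d = np.diff(np.concatenate([[0], a, [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1) - 1
        return list(zip(starts.tolist(), ends.tolist()))

    def visit_intervals(self, state: int) -> list[tuple[float, float]]:
        """Visits in seconds (first to last active sample)."""
        t = self.times
        return [(float(t[i0]), float(t[i1])) for i0, i1 in self.visits(state)]


def binarize_states(
    gamma: np.ndarray,
    threshold: float = 2.0 / 3.0,
    fs: float = 150.0,
    valid_offset: int = 0,
) -> StateTimeCourse:
    """State k is active at t iff gamma[t, k] > threshold (strict).

    A threshold above 1/2 makes activations mutually exclusive.
    """
    if not 0.5 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0.5, 1] to guarantee mutual exclusivity")
    gamma = np.asarray(gamma, dtype=float)
    return StateTimeCourse(active=gamma > threshold, fs=fs, valid_offset=valid_offset)


# ---------------------------------------------------------------------------
# transition statistics
# ---------------------------------------------------------------------------


@dataclass
class TransitionStats:
    matrix: np.ndarray  # (K, K) row-stochastic on defined rows
    row_defined: np.ndarray  # (K,) bool: state had at least one outgoing visit
    occupancy: np.ndarray  # (K,) fraction of valid samples active
    n_visits: np.ndarray  # (K,)
    mean_visit_duration: np.ndarray  # (K,) seconds (NaN when no visits)
    kind: str  # "model" or "empirical"


def empirical_transition_matrix(stc: StateTimeCourse) -> TransitionStats:
    """Visit-sequence transition matrix from binarized time courses.

    Visits of all states are ordered by onset (they cannot overlap); the
    matrix counts consecutive-visit transitions.  Rows without outgoing
    transitions are zero and flagged undefined rather than NaN.
    """
    K = stc.n_states
    events: list[tuple[int, int, int]] = []  # (start, end, state)
    durations = [[] for _ in range(K)]
    for k in range(K):
        for i0, i1 in stc.visits(k):
            events.append((i0, i1, k))
            durations[k].append((i1 - i0 + 1) / stc.fs)
    events.sort()
    counts = np.zeros((K, K))
    for (_, _, k_prev), (_, _, k_next) in zip(events[:-1], events[1:]):
        counts[k_prev, k_next] += 1
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    matrix = np.zeros_like(counts)
    matrix[defined] = counts[defined] / row_sums[defined, None]
    occupancy = stc.active.mean(axis=0)
    n_visits = np.array([len(d) for d in durations])
    mean_dur = np.array([float(np.mean(d)) if d else np.nan for d in durations])
    return TransitionStats(matrix, defined, occupancy, n_visits, mean_dur, kind="empirical")


def transition_stats(
    model: Optional[HMMModel] = None, stc: Optional[StateTimeCourse] = None
) -> TransitionStats:
    """Model-based (Dirichlet posterior mean) or empirical transition stats.

    Pass ``stc`` alone for the empirical visit-sequence variant; pass the
    fitted model for the posterior-mean matrix (with occupancy from ``stc``
    when available, else from thresholding gamma at the configured value).
    """
    if model is None and stc is None:
        raise ParameterError("need a fitted model or a state time course")
    if model is None:
        return empirical_transition_matrix(stc)
    matrix = model.alpha_trans / model.alpha_trans.sum(axis=1, keepdims=True)
    if stc is None:
        thr = (model.config or HMMConfig(n_states=model.K)).probability_threshold
        stc = binarize_states(model.gamma, thr)
    emp = empirical_transition_matrix(stc)
    return TransitionStats(
        matrix=matrix,
        row_defined=np.ones(model.K, bool),
        occupancy=emp.occupancy,
        n_visits=emp.n_visits,
        mean_visit_duration=emp.mean_visit_duration,
        kind="model",
    )
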