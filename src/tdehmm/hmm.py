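"""Variational Bayes inference for a K-state Gaussian hidden Markov model.

The observation model is a zero-mean multivariate Gaussian per state on the
PCA-reduced time-delay embedded data, so each state is a pattern of lagged
auto/cross-covariance (i.e. of spectral power and phase-coupling).  Only the
covariance is modelled; conjugate priors are a Wishart on each state
precision and Dirichlet distributions on the transition-matrix rows (with a
diagonal bonus favouring persistence) and the initial distribution.

Inference alternates exact forward-backward smoothing (in the scaled domain,
with expected log parameters) with closed-form conjugate updates.  The
variational free energy (negative evidence lower bound; lower is better) is
recorded every iteration and is non-increasing; run-to-run variability is
handled by fitting from several seeded initializations and keeping the
lowest-free-energy solution.

The model/results split follows the statsmodels convention:
:class:`TimeDelayEmbeddedHMM` is built from data, its :meth:`fit` returns an
:class:`HMMResults` carrying estimates, uncertainties (posterior state
probabilities), diagnostics and ``summary()``; spectral and temporal-metric
post-processing hang off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import digamma, gammaln, multigammaln

from .data import SubjectTimeSeries
from .embedding import EmbeddingConfig, embed, fit_pca, lag_offset

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]

__all__ = ["HmmConfig", "HMMResults", "TimeDelayEmbeddedHMM",
           "forward_backward", "viterbi", "fit_hmm", "best_of_runs",
           "free_energy", "match_states"]

_SCALE_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# forward-backward / Viterbi kernels (numba-jitted with numpy fallback)
# ---------------------------------------------------------------------------

def _forward_impl(B, A, pi):
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    s = a.sum()
    if s < _SCALE_FLOOR:
        s = _SCALE_FLOOR
    c[0] = s
    alpha[0] = a / s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s = a.sum()
        if s < _SCALE_FLOOR:
            s = _SCALE_FLOOR
        c[t] = s
        alpha[t] = a / s
    return alpha, c


def _backward_impl(B, A, c):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


def _viterbi_impl(logB, logA, logpi):
    T, K = logB.shape
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for k in range(K):
            best, arg = -np.inf, 0
            for j in range(K):
                v = delta[j] + logA[j, k]
                if v > best:  # strict: ties resolve to the lower index
                    best, arg = v, j
            new[k] = best + logB[t, k]
            psi[t, k] = arg
        delta = new
    path = np.empty(T, dtype=np.int64)
    best, arg = -np.inf, 0
    for k in range(K):
        if delta[k] > best:
            best, arg = delta[k], k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


if _HAVE_NUMBA:
    _forward = njit(cache=True)(_forward_impl)
    _backward = njit(cache=True)(_backward_impl)
    _viterbi_kernel = njit(cache=True)(_viterbi_impl)
else:  # pragma: no cover
    _forward, _backward, _viterbi_kernel = (_forward_impl, _backward_impl,
                                            _viterbi_impl)


def _check_loglik(loglik: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(loglik).all(axis=1))
    if bad.size:
        raise ValueError(
            f"non-finite state log-likelihood at time point {int(bad[0])}")


def forward_backward(state_loglikelihoods: np.ndarray,
                     transition_matrix: np.ndarray,
                     initial_distribution: np.ndarray,
                     return_xi: str = "full"):
    """Exact posterior smoothing for one chain.

    Parameters are the per-sample state log-likelihoods (T x K), a
    row-stochastic transition matrix and an initial distribution.  Returns
    ``(gamma, xi, log_evidence)`` where ``gamma`` is T x K posterior
    marginals and ``xi`` the posterior transition marginals, either the full
    (T-1) x K x K array (``return_xi='full'``) or their K x K sum
    (``'sum'``, memory-safe for very long chains).

    Computed with scaled forward/backward recursions (scale floor 1e-300),
    so chains with T up to ~1e6 do not underflow.
    """
    loglik = np.ascontiguousarray(state_loglikelihoods, dtype=np.float64)
    _check_loglik(loglik)
    A = np.ascontiguousarray(transition_matrix, dtype=np.float64)
    pi = np.ascontiguousarray(initial_distribution, dtype=np.float64)
    T, K = loglik.shape
    m = loglik.max(axis=1)
    B = np.exp(loglik - m[:, None])
    alpha, c = _forward(B, A, pi)
    beta = _backward(B, A, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    log_evidence = float(np.log(c).sum() + m.sum())
    if T == 1:
        xi = (np.zeros((0, K, K)) if return_xi == "full"
              else np.zeros((K, K)))
        return gamma, xi, log_evidence
    w = B[1:] * beta[1:] / c[1:, None]
    if return_xi == "sum":
        xi = A * (alpha[:-1].T @ w)
    elif return_xi == "full":
        xi = alpha[:-1, :, None] * A[None, :, :] * w[:, None, :]
    else:
        raise ValueError("return_xi must be 'full' or 'sum'")
    return gamma, xi, log_evidence


def viterbi(state_loglikelihoods: np.ndarray, transition_matrix: np.ndarray,
            initial_distribution: np.ndarray) -> np.ndarray:
    """Maximum a posteriori state path (values 1..K); ties break toward the
    lower state index."""
    loglik = np.ascontiguousarray(state_loglikelihoods, dtype=np.float64)
    _check_loglik(loglik)
    with np.errstate(divide="ignore"):
        logA = np.log(np.maximum(transition_matrix, _SCALE_FLOOR))
        logpi = np.log(np.maximum(initial_distribution, _SCALE_FLOOR))
    return _viterbi_kernel(loglik, np.ascontiguousarray(logA),
                           np.ascontiguousarray(logpi)) + 1


# ---------------------------------------------------------------------------
# configuration and results containers
# ---------------------------------------------------------------------------

@dataclass
class HmmConfig:
    """Inference settings.

    ``K`` states; ``n_runs`` seeded restarts (the lowest-free-energy run is
    kept); convergence when the relative free-energy change falls below
    ``tolerance``.  ``prior_diag_bonus`` is added to the Dirichlet prior on
    the diagonal of the transition matrix, encoding a weak preference for
    persistent states; ``prior_trans_alpha`` is the symmetric base count.
    ``batch_subjects`` enables stochastic (mini-batch over subjects)
    updates; the full-batch default is exact and monotone in free energy.
    """
    K: int = 12
    n_runs: int = 10
    max_iterations: int = 100
    tolerance: float = 1e-5
    seed: int = 0
    batch_subjects: int | str = "all"
    prior_trans_alpha: float = 1.0
    prior_diag_bonus: float = 10.0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


class _Posterior:
    """Variational posterior over HMM parameters."""

    def __init__(self, K: int, d: int, config: HmmConfig):
        self.K, self.d = K, d
        self.nu0 = d + 2.0
        self.W0_inv = np.eye(d) * self.nu0   # prior E[precision] = I
        a = np.full((K, K), config.prior_trans_alpha)
        a[np.diag_indices(K)] += config.prior_diag_bonus
        self.trans_alpha0 = a
        self.init_alpha0 = np.ones(K)
        self.nu = np.full(K, self.nu0)
        self.W_inv = np.tile(self.W0_inv, (K, 1, 1))
        self.trans_alpha = a.copy()
        self.init_alpha = np.ones(K)
        self._chol = None

    # -- expected parameters ------------------------------------------------
    def expected_log_trans(self) -> np.ndarray:
        return (digamma(self.trans_alpha)
                - digamma(self.trans_alpha.sum(axis=1, keepdims=True)))

    def expected_log_init(self) -> np.ndarray:
        return digamma(self.init_alpha) - digamma(self.init_alpha.sum())

    def _chols(self):
        if self._chol is None:
            self._chol = [cholesky(self.W_inv[k], lower=True)
                          for k in range(self.K)]
        return self._chol

    def expected_logdet_precision(self) -> np.ndarray:
        out = np.empty(self.K)
        i = np.arange(1, self.d + 1)
        for k, L in enumerate(self._chols()):
            logdet_winv = 2.0 * np.log(np.diag(L)).sum()
            out[k] = (digamma((self.nu[k] + 1 - i) / 2.0).sum()
                      + self.d * np.log(2.0) - logdet_winv)
        return out

    def expected_emission_loglik(self, X: np.ndarray) -> np.ndarray:
        """E_q[log N(x | 0, Lambda_k^-1)] for every sample; X is T x d."""
        T = X.shape[0]
        out = np.empty((T, self.K))
        elogdet = self.expected_logdet_precision()
        for k, L in enumerate(self._chols()):
            Y = solve_triangular(L, X.T, lower=True)
            quad = self.nu[k] * np.einsum("it,it->t", Y, Y)
            out[:, k] = 0.5 * (elogdet[k] - self.d * np.log(2 * np.pi)
                               - quad)
        return out

    # -- updates ------------------------------------------------------------
    def update(self, N: np.ndarray, S: np.ndarray, xi_sum: np.ndarray,
               init_counts: np.ndarray) -> None:
        self.nu = self.nu0 + N
        self.W_inv = self.W0_inv[None] + S
        # symmetrize against accumulation round-off
        self.W_inv = 0.5 * (self.W_inv + np.swapaxes(self.W_inv, 1, 2))
        self._chol = None
        try:
            self._chols()
        except np.linalg.LinAlgError:  # pragma: no cover - safety net
            warnings.warn("non-PD covariance update; regularizing")
            self.W_inv += 1e-8 * np.trace(
                self.W_inv, axis1=1, axis2=2)[:, None, None] * np.eye(self.d)
            self._chol = None
        self.trans_alpha = self.trans_alpha0 + xi_sum
        self.init_alpha = self.init_alpha0 + init_counts

    # -- KL penalties -------------------------------------------------------
    @staticmethod
    def _kl_dirichlet(q: np.ndarray, p: np.ndarray) -> float:
        q = np.atleast_2d(q)
        p = np.atleast_2d(p)
        s_q = q.sum(axis=1, keepdims=True)
        kl = (gammaln(s_q[:, 0]) - gammaln(q).sum(axis=1)
              - gammaln(p.sum(axis=1)) + gammaln(p).sum(axis=1)
              + ((q - p) * (digamma(q) - digamma(s_q))).sum(axis=1))
        return float(kl.sum())

    def _kl_wishart(self) -> float:
        d = self.d
        total = 0.0
        i = np.arange(1, d + 1)
        logdet_W0inv = d * np.log(self.nu0)  # W0_inv = nu0 * I
        for k, L in enumerate(self._chols()):
            nu1 = self.nu[k]
            logdet_W1inv = 2.0 * np.log(np.diag(L)).sum()
            elogdet = (digamma((nu1 + 1 - i) / 2.0).sum()
                       + d * np.log(2.0) - logdet_W1inv)
            # E[Lambda] = nu1 * W1;  tr(W0^-1 E[Lambda])
            W1 = solve_triangular(
                L, solve_triangular(L, np.eye(d), lower=True).T, lower=True).T
            tr = nu1 * np.trace(self.W0_inv @ W1)
            log_B1 = (0.5 * nu1 * logdet_W1inv - 0.5 * nu1 * d * np.log(2.0)
                      - multigammaln(nu1 / 2.0, d))
            log_B0 = (0.5 * self.nu0 * logdet_W0inv
                      - 0.5 * self.nu0 * d * np.log(2.0)
                      - multigammaln(self.nu0 / 2.0, d))
            total += (log_B1 - log_B0
                      + 0.5 * (nu1 - self.nu0) * elogdet
                      + 0.5 * (tr - nu1 * d))
        return float(total)

    def kl_total(self) -> float:
        return (self._kl_dirichlet(self.trans_alpha, self.trans_alpha0)
                + self._kl_dirichlet(self.init_alpha, self.init_alpha0)
                + self._kl_wishart())

    # -- point summaries ----------------------------------------------------
    def transition_matrix(self) -> np.ndarray:
        return self.trans_alpha / self.trans_alpha.sum(axis=1, keepdims=True)

    def initial_distribution(self) -> np.ndarray:
        return self.init_alpha / self.init_alpha.sum()

    def state_covariances(self) -> np.ndarray:
        denom = np.maximum(self.nu - self.d - 1.0, 1e-6)
        return self.W_inv / denom[:, None, None]


@dataclass
class HMMResults:
    """Fitted-model container (estimates, diagnostics, post-processing)."""

    config: HmmConfig
    gamma: np.ndarray                  # T_total x K posterior probabilities
    xi_sum: np.ndarray                 # expected transition counts, K x K
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    state_covariances: np.ndarray      # K x d x d posterior-mean covariances
    free_energy_trace: np.ndarray
    all_free_energies: np.ndarray      # one entry per restart
    subject_slices: list               # [(subject_id, slice into gamma rows)]
    n_iter: int
    converged: bool
    run_seed: int
    posterior: "_Posterior" = field(repr=False, default=None)
    data: list = field(repr=False, default=None)   # projected per subject
    subjects: list = field(repr=False, default=None)
    pca_model: object = field(repr=False, default=None)
    offset: int = 0                    # embedding edge offset (L-1)/2
    run_traces: list = field(repr=False, default=None)  # per-restart traces
    _viterbi_cache: dict = field(repr=False, default_factory=dict)

    @property
    def K(self) -> int:
        return self.gamma.shape[1]

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[-1])

    @property
    def subject_ids(self) -> list:
        return [sid for sid, _ in self.subject_slices]

    def subject_gamma(self, subject, aligned: bool = False,
                      total_len: int | None = None) -> np.ndarray:
        """Posterior state probabilities for one subject.

        With ``aligned=True`` the rows are re-indexed to the original
        samples: the embedding drops ``offset`` samples at each edge, so the
        edge rows are replicated outward to restore length ``total_len``
        (or ``T + 2*offset`` if omitted).
        """
        idx = {sid: sl for sid, sl in self.subject_slices}
        key = subject if subject in idx else self.subject_ids[subject]
        g = self.gamma[idx[key]]
        if not aligned:
            return g
        n = total_len if total_len is not None else g.shape[0] + 2 * self.offset
        pre = n - g.shape[0] - self.offset
        return np.vstack([np.tile(g[0], (pre, 1)), g,
                          np.tile(g[-1], (self.offset, 1))])

    def viterbi_path(self, subject) -> np.ndarray:
        """Hard MAP state path (values 1..K) in embedded-sample indexing."""
        idx = {sid: i for i, (sid, _) in enumerate(self.subject_slices)}
        i = idx[subject] if subject in idx else int(subject)
        if i not in self._viterbi_cache:
            X = self.data[i]
            loglik = self.posterior.expected_emission_loglik(X)
            A = np.exp(self.posterior.expected_log_trans())
            A /= A.sum(axis=1, keepdims=True)
            pi = np.exp(self.posterior.expected_log_init())
            pi /= pi.sum()
            self._viterbi_cache[i] = viterbi(loglik, A, pi)
        return self._viterbi_cache[i]

    def fractional_occupancy(self) -> np.ndarray:
        """Subjects x K mean posterior state probability."""
        return np.stack([self.subject_gamma(sid).mean(axis=0)
                         for sid in self.subject_ids])

    def temporal_metrics(self, fs: float | None = None,
                         censor_edges: bool = False):
        """Chronnectome metrics computed from this fit (see
        :mod:`tdehmm.metrics`)."""
        from .metrics import cohort_temporal_metrics
        if fs is None:
            if not self.subjects:
                raise ValueError("fs is required when no subjects attached")
            fs = self.subjects[0].fs
        paths = {sid: self.viterbi_path(sid) for sid in self.subject_ids}
        groups = {ts.subject_id: ts.group for ts in (self.subjects or [])}
        return cohort_temporal_metrics(
            paths, self.fractional_occupancy(), self.subject_ids, fs,
            groups=groups, censor_edges=censor_edges)

    def state_spectra(self, mt_config=None, subjects=None):
        """State-wise multitaper spectra for the attached (or provided)
        subjects, with gamma re-aligned to original samples."""
        from .spectral import MultitaperConfig, cohort_spectra
        subjects = subjects if subjects is not None else self.subjects
        if subjects is None:
            raise ValueError("no subjects attached to the fit")
        mt_config = mt_config or MultitaperConfig()
        gammas = [self.subject_gamma(ts.subject_id, aligned=True,
                                     total_len=ts.n_samples)
                  for ts in subjects]
        return cohort_spectra(subjects, gammas, mt_config)

    def summary(self) -> str:
        fo = self.fractional_occupancy().mean(axis=0)
        lines = [
            "Time-delay embedded Gaussian HMM (variational Bayes)",
            "=" * 56,
            f"states (K):            {self.K}",
            f"subjects:              {len(self.subject_slices)}",
            f"samples modelled:      {self.gamma.shape[0]}",
            f"restarts:              {self.all_free_energies.size}"
            f"  (kept run seed {self.run_seed})",
            f"free energy:           {self.free_energy:.2f}",
            f"iterations:            {self.n_iter}"
            f"  converged: {self.converged}",
            "",
            "state   frac.occupancy   self-transition",
        ]
        for k in range(self.K):
            lines.append(f"{k + 1:>5}   {fo[k]:>14.3f}   "
                         f"{self.transition_matrix[k, k]:>15.3f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("gamma", data=self.gamma)
            f.create_dataset("xi_sum", data=self.xi_sum)
            f.create_dataset("transition_matrix",
                             data=self.transition_matrix)
            f.create_dataset("initial_distribution",
                             data=self.initial_distribution)
            f.create_dataset("state_covariances",
                             data=self.state_covariances)
            f.create_dataset("free_energy_trace",
                             data=self.free_energy_trace)
            f.create_dataset("all_free_energies",
                             data=self.all_free_energies)
            for name in ("K", "n_runs", "max_iterations", "tolerance",
                         "seed"):
                f.attrs[name] = getattr(self.config, name)
            f.attrs["subject_ids"] = ",".join(self.subject_ids)
            f.attrs["subject_lengths"] = [
                sl.stop - sl.start for _, sl in self.subject_slices]
            f.attrs["offset"] = self.offset


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _as_subject_list(data):
    if isinstance(data, np.ndarray):
        return [np.ascontiguousarray(data, dtype=np.float64)]
    return [np.ascontiguousarray(X, dtype=np.float64) for X in data]


def _init_gamma(X: np.ndarray, K: int, rs: int, window: int = 25
                ) -> np.ndarray:
    """Seeded k-means on windowed log-power features -> smoothed one-hot."""
    from sklearn.cluster import KMeans
    T, d = X.shape
    n_win = max(T // window, 1)
    usable = n_win * window
    feats = np.log(
        (X[:usable] ** 2).reshape(n_win, window, d).mean(axis=1) + 1e-12)
    if n_win < K:
        rng = np.random.default_rng(rs)
        g = rng.dirichlet(np.ones(K), size=T)
        return g
    labels = KMeans(n_clusters=K, n_init=3, random_state=rs).fit_predict(
        feats)
    lab = np.repeat(labels, window)
    lab = np.concatenate([lab, np.full(T - usable, labels[-1])])
    g = np.full((T, K), 0.05 / max(K - 1, 1))
    g[np.arange(T), lab] = 0.95
    return g / g.sum(axis=1, keepdims=True)


def _accumulate(Xs, gammas):
    K = gammas[0].shape[1]
    d = Xs[0].shape[1]
    N = np.zeros(K)
    S = np.zeros((K, d, d))
    xi_sum = np.zeros((K, K))
    init = np.zeros(K)
    for X, g in zip(Xs, gammas):
        N += g.sum(axis=0)
        for k in range(K):
            Xw = X * g[:, k:k + 1]
            S[k] += Xw.T @ X
        xi_sum += g[:-1].T @ g[1:]
        init += g[0]
    return N, S, xi_sum, init


def fit_hmm(data, config: HmmConfig, run_seed: int | None = None
            ) -> HMMResults:
    """One variational EM fit from a single seeded initialization.

    ``data`` is a projected (T x n_pcs) array or a list of them, one per
    subject; chains restart at subject boundaries.  Raises if the free
    energy increases beyond tolerance (a diverged fit).
    """
    Xs = _as_subject_list(data)
    d = Xs[0].shape[1]
    K = config.K
    T_total = sum(X.shape[0] for X in Xs)
    if T_total < 10 * K:
        raise ValueError("need at least 10 samples per state")
    for X in Xs:
        if not np.isfinite(X).all():
            raise ValueError("data contains non-finite values")
    rs = config.seed if run_seed is None else run_seed
    rs = int(rs) % (2 ** 31)

    post = _Posterior(K, d, config)
    gammas0 = [_init_gamma(X, K, rs) for X in Xs]
    post.update(*_accumulate(Xs, gammas0))

    stochastic = (config.batch_subjects != "all"
                  and int(config.batch_subjects) < len(Xs))
    batch = len(Xs) if not stochastic else int(config.batch_subjects)
    rng = np.random.default_rng(rs)
    stats_avg = None

    trace = []
    converged = False
    gammas = gammas0
    n_iter = 0
    for it in range(config.max_iterations):
        n_iter = it + 1
        if stochastic:
            sel = rng.choice(len(Xs), size=batch, replace=False)
        else:
            sel = np.arange(len(Xs))
        ElogA = post.expected_log_trans()
        A_tilde = np.exp(ElogA)
        pi_tilde = np.exp(post.expected_log_init())
        logZ = 0.0
        new_gammas = list(gammas)
        sub_xs, sub_g = [], []
        for i in sel:
            loglik = post.expected_emission_loglik(Xs[i])
            g, xi, lz = forward_backward(loglik, A_tilde, pi_tilde,
                                         return_xi="sum")
            new_gammas[i] = g
            sub_xs.append(Xs[i])
            sub_g.append((g, xi))
            logZ += lz
        gammas = new_gammas
        # free energy with the parameter posterior the E-step used
        scale = len(Xs) / len(sel)
        F = -(scale * logZ) + post.kl_total()
        if trace and not stochastic:
            if F > trace[-1] + config.tolerance * abs(trace[-1]):
                raise RuntimeError(
                    f"free energy increased at iteration {it} "
                    f"({trace[-1]:.6f} -> {F:.6f}): diverged fit")
        done = bool(trace and abs(trace[-1] - F)
                    <= config.tolerance * abs(trace[-1]))
        trace.append(F)
        if done and not stochastic:
            # stop before the M-step so the stored posterior is exactly the
            # one whose E-step produced the final free energy
            converged = True
            break

        N = np.zeros(K)
        S = np.zeros((K, d, d))
        xi_sum = np.zeros((K, K))
        init = np.zeros(K)
        for X, (g, xi) in zip(sub_xs, sub_g):
            N += g.sum(axis=0)
            for k in range(K):
                S[k] += (X * g[:, k:k + 1]).T @ X
            xi_sum += xi
            init += g[0]
        stats = (scale * N, scale * S, scale * xi_sum, scale * init)
        if stochastic:
            rho = (it + 2.0) ** -0.6
            if stats_avg is None:
                stats_avg = stats
            else:
                stats_avg = tuple((1 - rho) * a + rho * s
                                  for a, s in zip(stats_avg, stats))
            stats = stats_avg
        post.update(*stats)
        if done:  # stochastic path: stop after the averaged update
            converged = True
            break

    gamma = np.vstack(gammas)
    slices = []
    start = 0
    for i, X in enumerate(Xs):
        slices.append((f"sub{i:03d}", slice(start, start + X.shape[0])))
        start += X.shape[0]
    return HMMResults(
        config=config, gamma=gamma, xi_sum=post.trans_alpha
        - post.trans_alpha0, transition_matrix=post.transition_matrix(),
        initial_distribution=post.initial_distribution(),
        state_covariances=post.state_covariances(),
        free_energy_trace=np.asarray(trace),
        all_free_energies=np.asarray([trace[-1]]),
        subject_slices=slices, n_iter=n_iter, converged=converged,
        run_seed=rs, posterior=post, data=Xs)


def free_energy(results: HMMResults, data=None) -> float:
    """Recompute the variational free energy of a fit on its data.

    Matches the final entry of ``free_energy_trace`` up to one further
    E-step refinement (equal within the convergence tolerance for a
    converged fit)."""
    Xs = _as_subject_list(data) if data is not None else results.data
    post = results.posterior
    A_tilde = np.exp(post.expected_log_trans())
    pi_tilde = np.exp(post.expected_log_init())
    logZ = 0.0
    for X in Xs:
        loglik = post.expected_emission_loglik(X)
        _, _, lz = forward_backward(loglik, A_tilde, pi_tilde,
                                    return_xi="sum")
        logZ += lz
    return float(-logZ + post.kl_total())


def best_of_runs(data, config: HmmConfig) -> HMMResults:
    """Fit ``config.n_runs`` times from distinct seeded initializations and
    return the lowest-free-energy fit (all free energies attached)."""
    fits, fes, errors = [], [], []
    for r in range(config.n_runs):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(r,))
        rs = int(ss.generate_state(1)[0] % (2 ** 31))
        try:
            fit = fit_hmm(data, config, run_seed=rs)
        except RuntimeError as e:
            errors.append(e)
            continue
        fits.append(fit)
        fes.append(fit.free_energy)
    if not fits:
        raise RuntimeError(f"all {config.n_runs} runs diverged: {errors}")
    best = fits[int(np.argmin(fes))]
    best.all_free_energies = np.asarray(fes)
    best.run_traces = [f.free_energy_trace for f in fits]
    return best


def match_states(fit_a: HMMResults, fit_b: HMMResults) -> np.ndarray:
    """Optimal state correspondence between two fits.

    If both fits cover the same samples the assignment maximizes summed
    gamma correlation; otherwise it maximizes cosine similarity of the
    vectorized state covariances.  Returns ``perm`` with ``perm[i]`` the
    state of ``fit_b`` matched to state ``i`` of ``fit_a`` (0-based).
    Smaller-K fits are padded with unmatched states.
    """
    from scipy.optimize import linear_sum_assignment
    Ka, Kb = fit_a.K, fit_b.K
    K = max(Ka, Kb)
    sim = np.full((K, K), -1e9)
    if fit_a.gamma.shape[0] == fit_b.gamma.shape[0]:
        ga = fit_a.gamma - fit_a.gamma.mean(axis=0)
        gb = fit_b.gamma - fit_b.gamma.mean(axis=0)
        denom = np.outer(np.linalg.norm(ga, axis=0),
                         np.linalg.norm(gb, axis=0))
        sim[:Ka, :Kb] = (ga.T @ gb) / np.maximum(denom, 1e-30)
    else:
        Va = fit_a.state_covariances.reshape(Ka, -1)
        Vb = fit_b.state_covariances.reshape(Kb, -1)
        na = np.linalg.norm(Va, axis=1, keepdims=True)
        nb = np.linalg.norm(Vb, axis=1, keepdims=True)
        sim[:Ka, :Kb] = (Va / np.maximum(na, 1e-30)) @ (
            Vb / np.maximum(nb, 1e-30)).T
    row, col = linear_sum_assignment(-sim)
    perm = np.empty(K, dtype=np.int64)
    perm[row] = col
    return perm[:Ka]


def matched_gamma_correlations(fit_a: HMMResults, fit_b: HMMResults
                               ) -> np.ndarray:
    """Per-state gamma correlation after optimal matching (fits on the same
    samples)."""
    perm = match_states(fit_a, fit_b)
    out = np.empty(fit_a.K)
    for k in range(fit_a.K):
        out[k] = np.corrcoef(fit_a.gamma[:, k],
                             fit_b.gamma[:, perm[k]])[0, 1]
    return out


# ---------------------------------------------------------------------------
# model class
# ---------------------------------------------------------------------------

class TimeDelayEmbeddedHMM:
    """Brain-state model over a cohort of parcellated recordings.

    Standardizes each subject, time-delay embeds with L lags, reduces the
    embedded space with group-level PCA, and fits the variational Gaussian
    HMM with best-of-``n_runs`` restart selection.

    Examples
    --------
    >>> model = TimeDelayEmbeddedHMM(subjects,
    ...     embedding=EmbeddingConfig(n_lags=15),
    ...     config=HmmConfig(K=12, n_runs=10, seed=0))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, subjects: list[SubjectTimeSeries],
                 embedding: EmbeddingConfig | None = None,
                 config: HmmConfig | None = None):
        if not subjects:
            raise ValueError("need at least one subject")
        self.subjects = subjects
        self.embedding = embedding or EmbeddingConfig()
        self.config = config or HmmConfig()
        self.pca_model = None
        self.projections = None

    @classmethod
    def from_arrays(cls, arrays: list[np.ndarray], fs: float,
                    groups: list | None = None, **kwargs
                    ) -> "TimeDelayEmbeddedHMM":
        subjects = [
            SubjectTimeSeries(data=a, fs=fs, subject_id=f"sub{i:03d}",
                              group=None if groups is None else groups[i])
            for i, a in enumerate(arrays)]
        return cls(subjects, **kwargs)

    def prepare(self):
        """Standardize, embed, and fit the group PCA (idempotent)."""
        if self.projections is not None:
            return self
        cfg = self.embedding
        pre = [s.standardized() if cfg.standardize else s
               for s in self.subjects]
        embedded = [embed(s, cfg.n_lags) for s in pre]
        n_pcs = cfg.resolved_n_pcs(self.subjects[0].n_channels)
        self.pca_model, self.projections = fit_pca(
            embedded, n_pcs, whiten=cfg.whiten)
        return self

    def fit(self, n_runs: int | None = None) -> HMMResults:
        self.prepare()
        config = self.config if n_runs is None else replace(
            self.config, n_runs=n_runs)
        res = best_of_runs(self.projections, config)
        res.subjects = self.subjects
        res.pca_model = self.pca_model
        res.offset = lag_offset(self.embedding.n_lags)
        res.subject_slices = [
            (ts.subject_id, sl)
            for ts, (_, sl) in zip(self.subjects, res.subject_slices)]
        return res
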