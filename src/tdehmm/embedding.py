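"""Sign disambiguation, standardization, time-delay embedding and PCA.

The observation model downstream is a zero-mean Gaussian on a time-delay
embedding of the channels: each channel is replicated at L lags symmetric
around the sample of interest, so the state covariance captures lagged
auto- and cross-covariance (i.e. spectral content), not just instantaneous
covariance.  Before any group-level covariance modelling the arbitrary
per-subject channel polarity of source-reconstructed data must be
harmonized, which :func:`align_signs` does by maximizing the agreement of
lagged cross-covariance structure across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import SubjectTimeSeries

__all__ = ["EmbeddingConfig", "PcaModel", "align_signs", "embed", "fit_pca",
           "lag_offset"]


@dataclass
class EmbeddingConfig:
    """Embedding window and PCA reduction.

    ``n_lags`` (L) must be odd: the window covers lags
    ``-(L-1)/2 .. +(L-1)/2`` around each sample.  ``n_pcs`` defaults to
    twice the channel count when left as ``None``.
    """
    n_lags: int = 15
    n_pcs: int | None = None
    standardize: bool = True
    whiten: bool = False

    def __post_init__(self):
        if self.n_lags < 1 or self.n_lags % 2 == 0:
            raise ValueError("n_lags must be odd and >= 1")

    def resolved_n_pcs(self, n_channels: int) -> int:
        n = 2 * n_channels if self.n_pcs is None else self.n_pcs
        if n > n_channels * self.n_lags:
            raise ValueError("n_pcs cannot exceed channels x n_lags")
        return n


@dataclass
class PcaModel:
    """Top principal directions of the embedded data (group level)."""
    loadings: np.ndarray                 # (channels*L) x n_pcs, orthonormal
    eigenvalues: np.ndarray              # all eigenvalues, descending
    explained_variance_fraction: np.ndarray   # per retained component
    per_subject_explained: np.ndarray    # fraction per subject
    mean: np.ndarray                     # embedded-space mean removed
    whiten: bool = False

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_fraction)

    def project(self, embedded: np.ndarray) -> np.ndarray:
        """Project an (embedded_dim x T) matrix onto the components,
        returning T x n_pcs."""
        Y = (embedded - self.mean[:, None]).T @ self.loadings
        if self.whiten:
            lam = self.eigenvalues[: self.loadings.shape[1]]
            Y = Y / np.sqrt(np.maximum(lam, 1e-12))
        return Y


def lag_offset(n_lags: int) -> int:
    """Samples dropped at each edge by the embedding: (L-1)/2."""
    return (n_lags - 1) // 2


def embed(ts: SubjectTimeSeries | np.ndarray, n_lags: int) -> np.ndarray:
    """Time-delay embed a channels x T matrix with L lags.

    Returns a ``(channels*L) x (T - L + 1)`` matrix; row ``c*L + k`` holds
    channel ``c`` shifted by lag ``k - (L-1)/2``.  Edge samples without a
    full window are dropped.
    """
    X = ts.data if isinstance(ts, SubjectTimeSeries) else np.asarray(ts)
    if n_lags < 1 or n_lags % 2 == 0:
        raise ValueError("n_lags must be odd and >= 1")
    C, T = X.shape
    if T <= n_lags:
        raise ValueError(f"T={T} too short for L={n_lags} embedding")
    win = np.lib.stride_tricks.sliding_window_view(X, n_lags, axis=1)
    # win: C x (T-L+1) x L -> rows (c, k)
    emb = np.transpose(win, (0, 2, 1)).reshape(C * n_lags, T - n_lags + 1)
    return np.ascontiguousarray(emb)


def fit_pca(embedded_list: list[np.ndarray], n_pcs: int,
            whiten: bool = False):
    """Group-level PCA of embedded data concatenated over subjects.

    The covariance is accumulated subject by subject (no concatenated copy
    is materialized) and eigendecomposed.  Returns
    ``(PcaModel, [T_s x n_pcs projections])``.
    """
    d = embedded_list[0].shape[0]
    if n_pcs > d:
        raise ValueError("n_pcs cannot exceed embedded dimension")
    n_total = sum(E.shape[1] for E in embedded_list)
    mean = sum(E.sum(axis=1) for E in embedded_list) / n_total
    S = np.zeros((d, d))
    for E in embedded_list:
        Ec = E - mean[:, None]
        S += Ec @ Ec.T
    S /= n_total
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    rank = int(np.sum(evals > 1e-10 * max(evals[0], 1e-30)))
    if n_pcs > rank:
        raise ValueError(
            f"requested n_pcs={n_pcs} exceeds data rank {rank}")
    W = evecs[:, :n_pcs]
    total = evals.sum()
    frac = evals[:n_pcs] / total if total > 0 else np.zeros(n_pcs)
    model = PcaModel(loadings=W, eigenvalues=evals,
                     explained_variance_fraction=frac,
                     per_subject_explained=np.empty(0), mean=mean,
                     whiten=whiten)
    projections, per_subj = [], []
    for E in embedded_list:
        Ec = E - mean[:, None]
        Y = Ec.T @ W
        tot_s = float(np.sum(Ec ** 2))
        per_subj.append(float(np.sum(Y ** 2)) / tot_s if tot_s > 0 else 1.0)
        if whiten:
            Y = Y / np.sqrt(np.maximum(evals[:n_pcs], 1e-12))
        projections.append(Y)
    model.per_subject_explained = np.asarray(per_subj)
    return model, projections


def _lagged_covariances(X: np.ndarray, n_lags: int) -> np.ndarray:
    """Stack of cross-covariance matrices C_l[i,j] = cov(x_i(t), x_j(t+l))
    for l = 0..n_lags.  X is channels x T, assumed zero mean."""
    C, T = X.shape
    out = np.empty((n_lags + 1, C, C))
    for l in range(n_lags + 1):
        out[l] = X[:, : T - l] @ X[:, l:].T / (T - l)
    return out


def _score(Cs: np.ndarray, signs: np.ndarray, template: np.ndarray) -> float:
    flipped = Cs * signs[None, :, None] * signs[None, None, :]
    return float(np.sum(flipped * template))


def align_signs(subjects: list[SubjectTimeSeries], reference_lags: int = 7,
                max_sweeps: int = 20, n_outer: int = 4,
                exhaustive: bool = False):
    """Harmonize per-subject channel polarity across a cohort.

    Builds an across-subject template of lagged cross-covariance matrices
    and, for each subject, searches over per-channel sign vectors to
    maximize the inner product of its (sign-adjusted) lagged covariances
    with the template.  Greedy coordinate descent by default (deterministic
    sweep order, ties broken toward no flip); ``exhaustive=True`` enumerates
    all 2^C sign vectors per subject (only sensible for small C).

    Returns ``(aligned_subjects, flips, score)`` where ``flips`` maps
    subject id to the applied per-channel +-1 vector.
    """
    if len(subjects) < 2:
        warnings.warn("single subject: sign alignment is the identity")
        return ([s.copy() for s in subjects],
                {s.subject_id: np.ones(s.n_channels, dtype=np.int64)
                 for s in subjects}, 0.0)
    C = subjects[0].n_channels
    if any(s.n_channels != C for s in subjects):
        raise ValueError("subjects must share the channel count")
    Z = [s.standardized().data for s in subjects]
    covs = [_lagged_covariances(X, reference_lags) for X in Z]
    signs = [np.ones(C) for _ in subjects]

    def adjusted(i):
        return covs[i] * signs[i][None, :, None] * signs[i][None, None, :]

    score = -np.inf
    for _ in range(n_outer):
        for i in range(len(subjects)):
            template = (sum(adjusted(j) for j in range(len(subjects))
                            if j != i) / (len(subjects) - 1))
            if exhaustive:
                best, best_v = -np.inf, signs[i]
                for bits in range(2 ** C):
                    v = 1.0 - 2.0 * ((bits >> np.arange(C)) & 1)
                    sc = _score(covs[i], v, template)
                    if sc > best + 1e-12:
                        best, best_v = sc, v
                signs[i] = best_v
            else:
                for _sweep in range(max_sweeps):
                    improved = False
                    for c in range(C):
                        cur = _score(covs[i], signs[i], template)
                        signs[i][c] *= -1.0
                        new = _score(covs[i], signs[i], template)
                        if new > cur + 1e-12:
                            improved = True
                        else:
                            signs[i][c] *= -1.0  # revert (ties -> no flip)
                    if not improved:
                        # escape single-flip local optima with pair moves
                        for c in range(C):
                            for c2 in range(c + 1, C):
                                cur = _score(covs[i], signs[i], template)
                                signs[i][c] *= -1.0
                                signs[i][c2] *= -1.0
                                if _score(covs[i], signs[i],
                                          template) > cur + 1e-12:
                                    improved = True
                                else:
                                    signs[i][c] *= -1.0
                                    signs[i][c2] *= -1.0
                        if not improved:
                            break
        new_score = sum(
            _score(covs[i], signs[i],
                   sum(adjusted(j) for j in range(len(subjects)) if j != i)
                   / (len(subjects) - 1))
            for i in range(len(subjects)))
        if new_score <= score + 1e-9 * max(abs(score), 1.0):
            score = new_score
            break
        score = new_score

    aligned, flips = [], {}
    for ts, v in zip(subjects, signs):
        new = ts.copy()
        new.data *= v[:, None]
        aligned.append(new)
        flips[ts.subject_id] = v.astype(np.int64)
    return aligned, flips, float(score)
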