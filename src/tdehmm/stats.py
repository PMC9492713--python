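"""Permutation statistics for state-resolved spectral and temporal measures.

Four families of tests:

* state-vs-rest: is a value (power, coherence, a temporal metric) stronger
  in one state than in the others, permuting state labels within subject,
  corrected over the tested family (max-statistic by default, BH optional);
* two-group permutation t tests with Cohen's d and bootstrap BCa 95% CIs;
* Benjamini-Hochberg FDR over the states x bands family;
* the network-based statistic (NBS): edge-wise t thresholding, connected
  components of supra-threshold edges in the region graph, FWER-corrected
  component p-values from the permutation null of the maximal component
  size.

All permutation p-values are computed as (1 + #{|null| >= |obs|})/(N + 1)
and every test is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "NbsResult", "state_vs_rest_test",
           "group_permutation_test", "cohens_d_bca", "fdr_bh", "nbs_test",
           "band_power_group_tests"]


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n_permutations: int
    effect_size_d: float = np.nan
    d_ci_low: float = np.nan
    d_ci_high: float = np.nan
    corrected: bool = False


@dataclass
class NbsResult:
    components: list                   # list of edge-index arrays
    component_sizes: np.ndarray        # edge counts
    fwer_p: np.ndarray                 # per component
    edge_threshold: float
    n_permutations: int
    edge_t: np.ndarray                 # observed edge-wise t values


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (null.size + 1.0)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _welch_t_matrix(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Vectorized Welch t for many label permutations.

    ``values``: (n_subjects, n_vars); ``masks``: (n_perm, n_subjects)
    boolean, True = group A.  Returns (n_perm, n_vars).
    """
    v = np.atleast_2d(values.T).T          # S x V
    m = masks.astype(np.float64)           # P x S
    na = m.sum(axis=1, keepdims=True)
    nb = m.shape[1] - na
    sa = m @ v                             # P x V
    sb = v.sum(axis=0)[None, :] - sa
    sqa = m @ (v ** 2)
    sqb = (v ** 2).sum(axis=0)[None, :] - sqa
    ma, mb = sa / na, sb / nb
    va = (sqa - na * ma ** 2) / (na - 1)
    vb = (sqb - nb * mb ** 2) / (nb - 1)
    va = np.maximum(va, 0.0)
    vb = np.maximum(vb, 0.0)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def group_permutation_test(values_a, values_b, n_perm: int = 5000,
                           seed: int = 0, statistic: str = "welch_t",
                           exact: bool = False,
                           compute_effect: bool = True,
                           n_boot: int = 5000) -> StatResult:
    """Two-sided two-sample permutation test.

    The observed statistic (Welch t by default, plain mean difference with
    ``statistic='mean_diff'``) is compared with its null distribution under
    random relabelings of the pooled subjects.  ``exact=True`` enumerates
    every split (feasible for small groups).  Cohen's d with a BCa CI is
    attached unless ``compute_effect=False``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")

    def stat(x, y):
        if statistic == "welch_t":
            return _welch_t(x, y)
        return float(x.mean() - y.mean())

    obs = stat(a, b)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    if exact:
        null = np.array([
            stat(pooled[list(idx)],
                 pooled[[i for i in range(n) if i not in set(idx)]])
            for idx in combinations(range(n), na)])
        # the observed labelling is one of the enumerated splits
        n_used = null.size
        p = np.sum(np.abs(null) >= abs(obs) - 1e-12) / null.size
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for r in range(n_perm):
            masks[r, rng.permutation(n)[:na]] = True
        if statistic == "welch_t":
            null = _welch_t_matrix(pooled[:, None], masks)[:, 0]
        else:
            m = masks.astype(float)
            null = (m @ pooled) / na - ((1 - m) @ pooled) / (n - na)
        p = _perm_pvalue(obs, null)
        n_used = n_perm
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        p = 1.0

    res = StatResult(statistic=obs, p_value=float(p), n_permutations=n_used)
    if compute_effect:
        try:
            d, lo, hi = cohens_d_bca(a, b, n_boot=n_boot, seed=seed)
            res.effect_size_d, res.d_ci_low, res.d_ci_high = d, lo, hi
        except ValueError:
            res.effect_size_d = 0.0
    return res


def _pooled_d(a, b, axis=-1):
    na = a.shape[axis] if a.ndim else a.size
    nb = b.shape[axis] if b.ndim else b.size
    va = a.var(ddof=1, axis=axis)
    vb = b.var(ddof=1, axis=axis)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (a.mean(axis=axis) - b.mean(axis=axis)) / sp


def cohens_d_bca(values_a, values_b, n_boot: int = 5000, seed: int = 0):
    """Cohen's d (pooled SD, n-1 denominators) with a 95% bias-corrected
    and accelerated bootstrap confidence interval.

    Returns ``(d, ci_low, ci_high)``.  Raises on zero pooled SD.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    d = float(_pooled_d(a, b))
    if not np.isfinite(d):
        raise ValueError("pooled standard deviation is zero")
    import warnings as _warnings
    rng = np.random.default_rng(seed)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        boot = sps.bootstrap(
            (a, b), _pooled_d, n_resamples=n_boot, method="BCa",
            confidence_level=0.95, vectorized=True, axis=-1, rng=rng)
        lo = float(boot.confidence_interval.low)
        hi = float(boot.confidence_interval.high)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            # BCa degenerates on very small samples (constant resamples);
            # fall back to the percentile interval over finite replicates
            rng2 = np.random.default_rng(seed)
            reps = _pooled_d(
                a[rng2.integers(a.size, size=(n_boot, a.size))],
                b[rng2.integers(b.size, size=(n_boot, b.size))])
            reps = reps[np.isfinite(reps)]
            lo, hi = (float(np.percentile(reps, 2.5)),
                      float(np.percentile(reps, 97.5)))
    return d, lo, hi


def state_vs_rest_test(values: np.ndarray, n_perm: int = 5000, seed: int = 0,
                       correction: str = "maxstat",
                       exact: bool = False) -> list:
    """Is each state's value elevated (or depressed) relative to the rest?

    ``values`` is subjects x states (one scalar per subject per state, e.g.
    wideband power).  The observed statistic per state is the mean over
    subjects of (state value - mean of the other states); the null permutes
    state labels *within subject*.  Two-sided p-values are corrected over
    states with the max-statistic method (default) or BH.  ``exact=True``
    enumerates all within-subject permutations (tiny inputs only).

    Returns one :class:`StatResult` per state (``corrected=True``).
    """
    v = np.asarray(values, dtype=np.float64)
    S, K = v.shape
    if K < 2 or S < 2:
        raise ValueError("need >= 2 states and >= 2 subjects")

    def stat(mat):
        tot = mat.sum(axis=1, keepdims=True)
        rest = (tot - mat) / (K - 1)
        return (mat - rest).mean(axis=0)

    obs = stat(v)
    if exact:
        from itertools import permutations, product
        perms = list(permutations(range(K)))
        null = np.array([stat(np.stack([v[s, list(p)] for s, p in
                                        zip(range(S), combo)]))
                         for combo in product(perms, repeat=S)])
        n_used = null.shape[0]
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, K))
        for r in range(n_perm):
            null[r] = stat(rng.permuted(v, axis=1))
        n_used = n_perm
    results = []
    max_null = np.abs(null).max(axis=1)
    add = 0.0 if exact else 1.0   # identity is in the exact enumeration
    raw_p = np.array([
        (add + np.sum(np.abs(null[:, k]) >= abs(obs[k]) - 1e-12))
        / (n_used + add) for k in range(K)])
    if correction == "maxstat":
        p_corr = np.array([
            (add + np.sum(max_null >= abs(obs[k]) - 1e-12))
            / (n_used + add) for k in range(K)])
    elif correction == "bh":
        p_corr = multipletests(raw_p, method="fdr_bh")[1]
    else:
        raise ValueError("correction must be 'maxstat' or 'bh'")
    for k in range(K):
        results.append(StatResult(statistic=float(obs[k]),
                                  p_value=float(p_corr[k]),
                                  n_permutations=n_used, corrected=True))
    return results


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask over a p-value family
    (any shape; the family is the flattened array)."""
    p = np.asarray(p_values, dtype=np.float64)
    mask = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0]
    return mask.reshape(p.shape)


def _max_component_size(t_vals: np.ndarray, thresh: float,
                        edges: np.ndarray, n_nodes: int) -> int:
    supra = np.abs(t_vals) >= thresh
    if not supra.any():
        return 0
    e = edges[supra]
    adj = coo_matrix((np.ones(e.shape[0]), (e[:, 0], e[:, 1])),
                     shape=(n_nodes, n_nodes))
    n_comp, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[e[:, 0]]
    return int(np.bincount(comp_of_edge).max())


def nbs_test(edge_values: np.ndarray, groups: np.ndarray,
             edges: list, n_nodes: int, edge_threshold: float | None = None,
             edge_alpha: float = 0.01, n_perm: int = 5000, seed: int = 0
             ) -> NbsResult:
    """Network-based statistic for edge-wise group differences.

    ``edge_values`` is subjects x edges; ``edges`` maps each column to a
    ``(node_i, node_j)`` pair of the region graph (node-level measures may
    be passed as self-edges ``(i, i)``).  Edge-wise two-sample t statistics
    are thresholded at ``edge_threshold`` (default: the two-sided critical
    t at ``edge_alpha`` uncorrected); supra-threshold edges form a graph
    whose connected components are scored by edge count against the
    permutation null of the maximal component size (FWER control).
    """
    v = np.asarray(edge_values, dtype=np.float64)
    g = np.asarray(groups)
    is_a = g == g[0]   # two-sided statistics: label orientation is moot
    S, E = v.shape
    edges_arr = np.asarray(edges, dtype=np.int64)
    if edges_arr.shape != (E, 2):
        raise ValueError("edges must give one (i, j) pair per column")
    na, nb = int(is_a.sum()), int((~is_a).sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 subjects")
    if edge_threshold is None:
        edge_threshold = float(sps.t.ppf(1 - edge_alpha / 2, na + nb - 2))

    t_obs = _welch_t_matrix(v, is_a[None, :])[0]
    supra = np.abs(t_obs) >= edge_threshold
    comps, sizes = [], []
    if supra.any():
        e = edges_arr[supra]
        idx = np.flatnonzero(supra)
        adj = coo_matrix((np.ones(e.shape[0]), (e[:, 0], e[:, 1])),
                         shape=(n_nodes, n_nodes))
        _, labels = connected_components(adj, directed=False)
        for lab in np.unique(labels[e[:, 0]]):
            members = idx[labels[e[:, 0]] == lab]
            comps.append(members)
            sizes.append(members.size)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    masks = np.zeros((n_perm, S), dtype=bool)
    for r in range(n_perm):
        masks[r, rng.permutation(S)[:na]] = True
    t_null = _welch_t_matrix(v, masks)
    for r in range(n_perm):
        null_max[r] = _max_component_size(t_null[r], edge_threshold,
                                          edges_arr, n_nodes)
    fwer = np.array([
        (1.0 + np.sum(null_max >= s)) / (n_perm + 1.0) for s in sizes])
    order = np.argsort(fwer) if fwer.size else np.array([], dtype=int)
    return NbsResult(
        components=[comps[i] for i in order],
        component_sizes=np.asarray(sizes)[order].astype(int)
        if sizes else np.empty(0, dtype=int),
        fwer_p=fwer[order], edge_threshold=edge_threshold,
        n_permutations=n_perm, edge_t=t_obs)


def band_power_group_tests(band_values: np.ndarray, groups,
                           band_labels: list, n_perm: int = 5000,
                           seed: int = 0, q: float = 0.05,
                           exclude_gamma: bool = True,
                           compute_effect: bool = True,
                           n_boot: int = 2000) -> pd.DataFrame:
    """Group comparison per state x band with BH-FDR over the family.

    ``band_values``: subjects x states x bands (scalars, e.g. band power
    averaged over channels).  Returns a tidy frame with one row per family
    member: state, band, t, p, p at the family level (BH mask), Cohen's d
    and its BCa CI.
    """
    v = np.asarray(band_values, dtype=np.float64)
    S, K, M = v.shape
    g = np.asarray(groups)
    labels = list(band_labels)
    use = [m for m in range(M)
           if not (exclude_gamma and labels[m] == "low-gamma")]
    is_a = g == g[0]
    rows = []
    for k in range(K):
        for m in use:
            a, b = v[is_a, k, m], v[~is_a, k, m]
            sub_seed = (seed + 7919 * (k * M + m)) % (2 ** 31)
            res = group_permutation_test(
                a, b, n_perm=n_perm, seed=sub_seed,
                compute_effect=compute_effect, n_boot=n_boot)
            rows.append({
                "state": k + 1, "band": labels[m], "t": res.statistic,
                "p": res.p_value, "d": res.effect_size_d,
                "d_ci_low": res.d_ci_low, "d_ci_high": res.d_ci_high})
    df = pd.DataFrame(rows)
    df["significant_fdr"] = fdr_bh(df["p"].to_numpy(), q=q)
    return df
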