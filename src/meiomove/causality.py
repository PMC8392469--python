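"""Per-particle causal discovery and presence-weighted aggregation.

Three routes assess directed relations among track descriptors:

* :class:`PCAlgorithm` — constraint-based structure learning for
  observational data without hidden variables: a stable skeleton phase of
  partial-correlation (Fisher-z) independence tests, v-structure
  orientation, and Meek rules R1-R3. Only arrowheaded (directed) edges of
  the resulting CPDAG count as causal claims.
* :func:`vl_granger` — variable-lag Granger causality: the source series
  is aligned to the target by dynamic time warping constrained to strictly
  positive lags bounded by ``max_lag``, then nested autoregressions with
  and without the aligned source are compared by an F-test.
* :func:`vl_transfer_entropy` — variable-lag transfer entropy: the same
  alignment feeds a plug-in estimate of
  TE = sum p(y_t, y_{t-1}, x~_t) log2 [ p(y_t | y_{t-1}, x~_t) /
  p(y_t | y_{t-1}) ] in bits, with significance from circular-shift
  permutations of the aligned series.

Each particle yields a binary adjacency A (a_ij = 1 when i -> j is
significant after multiplicity adjustment, Bonferroni by default); the
entrywise mean over particles is the presence matrix A-hat, thresholded
into the reported directed weighted graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import iter_tracks

__all__ = [
    "CITestResult",
    "VariableLagResult",
    "AdjacencyStack",
    "AggregateCausalGraph",
    "ci_test",
    "PCAlgorithm",
    "pc_algorithm",
    "vl_granger",
    "vl_transfer_entropy",
    "adjust_pvalues",
    "causality_scan",
    "aggregate_adjacency",
    "export_graph",
]


@dataclass
class CITestResult:
    i: int
    j: int
    conditioning: tuple[int, ...]
    partial_corr: float
    fisher_z: float
    statistic: float
    p_value: float


@dataclass
class VariableLagResult:
    source: str
    target: str
    lags: np.ndarray                 # per-time alignment lag, all within [1, max_lag]
    statistic: float                 # F (VLGC) or TE in bits (VLTE)
    p_value: float
    direction: bool                  # median lag > 0 (VLGC) / TE fwd > rev (VLTE)
    reverse_statistic: float = np.nan

    @property
    def median_lag(self) -> float:
        return float(np.median(self.lags)) if self.lags.size else np.nan


@dataclass
class AdjacencyStack:
    """Per-particle binary causal claims for one algorithm run."""

    matrices: np.ndarray             # (n_particles, p, p), diagonal 0
    variables: tuple[str, ...]
    algorithm: str
    alpha: float = 0.01
    adjust: str = "bonferroni"
    particles: list = field(default_factory=list)


@dataclass
class AggregateCausalGraph:
    """Presence-weighted directed graph over the variable set."""

    a_hat: pd.DataFrame
    threshold: float
    algorithm: str = ""

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"source": i, "target": j, "weight": float(self.a_hat.loc[i, j])}
            for i in self.a_hat.index
            for j in self.a_hat.columns
            if i != j and self.a_hat.loc[i, j] >= self.threshold
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.a_hat.index)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, weight=row.weight)
        return g


def ci_test(data: np.ndarray, i: int, j: int, conditioning: tuple[int, ...] = (),
            ) -> CITestResult:
    """Fisher-z partial-correlation test of independence of columns i, j
    given a conditioning set, via regression residuals."""
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    S = tuple(conditioning)
    if n <= len(S) + 3:
        raise ValueError("too few observations for the conditioning set")
    xi, xj = X[:, i], X[:, j]
    if S:
        Z = np.column_stack([np.ones(n), X[:, list(S)]])
        coef_i, *_ = np.linalg.lstsq(Z, xi, rcond=None)
        coef_j, *_ = np.linalg.lstsq(Z, xj, rcond=None)
        xi = xi - Z @ coef_i
        xj = xj - Z @ coef_j
    denom = np.sqrt(np.sum(xi**2) * np.sum(xj**2))
    r = float(np.sum(xi * xj) / denom) if denom > 0 else 0.0
    r = min(max(r, -0.999999), 0.999999)
    z = 0.5 * np.log((1 + r) / (1 - r))
    stat = np.sqrt(max(n - len(S) - 3, 1)) * abs(z)
    p = 2.0 * sps.norm.sf(stat)
    return CITestResult(i, j, S, r, z, float(stat), float(p))


class PCAlgorithm(BaseEstimator):
    """Stable-PC causal structure learning on iid-treated observations.

    Parameters
    ----------
    alpha : float
        Significance level of the conditional-independence tests.
    max_cond : int or None
        Cap on conditioning-set size (None: unlimited).

    Attributes
    ----------
    cpdag_ : networkx.DiGraph with both directions present for undirected
        edges and a single arc for oriented ones.
    adjacency_ : (p, p) binary ndarray; 1 only for directed i -> j claims.
    sepsets_ : dict mapping frozen pairs to their separating set.
    """

    def __init__(self, alpha: float = 0.01, max_cond: int | None = None):
        self.alpha = alpha
        self.max_cond = max_cond

    def fit(self, X: np.ndarray, var_names: list[str] | None = None) -> "PCAlgorithm":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least 2 variables")
        names = list(var_names) if var_names else [f"v{i}" for i in range(p)]
        adj = {i: set(range(p)) - {i} for i in range(p)}
        sepsets: dict[frozenset, tuple] = {}
        level = 0
        while True:
            if self.max_cond is not None and level > self.max_cond:
                break
            frozen = {i: set(adj[i]) for i in range(p)}  # stable variant
            if all(len(frozen[i]) - 1 < level for i in range(p)):
                break
            removed_any = False
            for i in range(p):
                for j in sorted(frozen[i]):
                    if j not in adj[i]:
                        continue
                    pool = sorted(frozen[i] - {j})
                    if len(pool) < level:
                        continue
                    for S in itertools.combinations(pool, level):
                        if n <= level + 3:
                            continue
                        try:
                            res = ci_test(X, i, j, S)
                        except np.linalg.LinAlgError:
                            warnings.warn("singular conditioning set skipped; "
                                          "treated as dependent", RuntimeWarning,
                                          stacklevel=2)
                            continue
                        if res.p_value > self.alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepsets[frozenset((i, j))] = S
                            removed_any = True
                            break
            level += 1
            if not removed_any and level > p:
                break

        # CPDAG as a directed graph; undirected edges carry both arcs
        g = nx.DiGraph()
        g.add_nodes_from(range(p))
        for i in range(p):
            for j in adj[i]:
                g.add_edge(i, j)
        # v-structures: i -> k <- j for nonadjacent i, j with k not in sepset
        for k in range(p):
            for i, j in itertools.combinations(sorted(adj[k]), 2):
                if j in adj[i]:
                    continue
                S = sepsets.get(frozenset((i, j)), ())
                if k not in S:
                    g.remove_edges_from([(k, i), (k, j)])

        def _undirected(a, b):
            return g.has_edge(a, b) and g.has_edge(b, a)

        changed = True
        while changed:  # Meek rules R1-R3
            changed = False
            for a, b in list(g.edges):
                if not _undirected(a, b):
                    continue
                # R1: c -> a, c not adjacent to b  =>  a -> b
                for c in g.predecessors(a):
                    if c != b and not _undirected(c, a) and \
                            not (g.has_edge(c, b) or g.has_edge(b, c)):
                        g.remove_edge(b, a)
                        changed = True
                        break
                if changed:
                    continue
                # R2: a -> c -> b with a - b undirected  =>  a -> b
                for c in g.successors(a):
                    if c != b and not _undirected(a, c) and g.has_edge(c, b) \
                            and not _undirected(c, b):
                        g.remove_edge(b, a)
                        changed = True
                        break
                if changed:
                    continue
                # R3: a - c -> b and a - d -> b, c,d nonadjacent  =>  a -> b
                mids = [c for c in g.successors(a)
                        if _undirected(a, c) and g.has_edge(c, b)
                        and not _undirected(c, b)]
                for c, d in itertools.combinations(mids, 2):
                    if not (g.has_edge(c, d) or g.has_edge(d, c)):
                        g.remove_edge(b, a)
                        changed = True
                        break

        A = np.zeros((p, p), dtype=int)
        for a, b in g.edges:
            if not g.has_edge(b, a):
                A[a, b] = 1
        self.cpdag_ = nx.relabel_nodes(g, dict(enumerate(names)))
        self.adjacency_ = A
        self.sepsets_ = sepsets
        self.var_names_ = names
        return self


def pc_algorithm(data: np.ndarray, alpha: float = 0.01,
                 var_names: list[str] | None = None) -> tuple[nx.DiGraph, np.ndarray]:
    """Functional wrapper: (CPDAG, binary directed-claim matrix)."""
    est = PCAlgorithm(alpha=alpha).fit(data, var_names)
    return est.cpdag_, est.adjacency_


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def dtw_align(x: np.ndarray, y: np.ndarray, max_lag: int, min_lag: int = 1,
              step_penalty: float = 4.0) -> np.ndarray:
    """Monotone DTW alignment of source x to target y under a lag band.

    Returns, for each target index t in [min_lag, n), the aligned source
    index lag Δ(t) = t − i_t with min_lag <= Δ(t) <= max_lag; earlier
    targets have no admissible source and are reported as −1. Match cost
    is |x_i − y_t| on z-normalised copies; each change of lag between
    consecutive targets pays ``step_penalty``, so the warping is a single
    smooth path rather than a free per-time value match — without the
    penalty the alignment can chase value coincidences in independent
    noise and every downstream test loses calibration.
    """
    xz, yz = _znorm(np.asarray(x, float)), _znorm(np.asarray(y, float))
    n = xz.size
    if yz.size != n:
        raise ValueError("series must have equal length")
    if not (0 <= min_lag <= max_lag):
        raise ValueError("need 0 <= min_lag <= max_lag")
    W = max_lag - min_lag + 1
    INF = np.inf
    lag_vals = np.arange(min_lag, max_lag + 1)
    D = np.full((n, W), INF)      # D[t, l]: best cost with lag(t) = min_lag + l
    B = np.zeros((n, W), dtype=np.int8)
    t0 = min_lag if min_lag > 0 else 0
    first = True
    for t in range(t0, n):
        admissible = lag_vals <= t
        if not admissible.any():
            continue
        c = np.full(W, INF)
        idx = np.flatnonzero(admissible)
        c[idx] = np.abs(xz[t - lag_vals[idx]] - yz[t])
        if first:
            D[t] = c
            first = False
            continue
        prev = D[t - 1]
        stay = prev
        up = np.concatenate([[INF], prev[:-1]]) + step_penalty    # lag increased
        down = np.concatenate([prev[1:], [INF]]) + step_penalty   # lag decreased
        stacked = np.vstack([stay, up, down])
        move = np.argmin(stacked, axis=0)
        best = stacked[move, np.arange(W)]
        D[t] = best + c
        B[t] = move
    t_first = next(t for t in range(t0, n) if np.isfinite(D[t]).any())
    lags_out = np.full(n, -1, dtype=int)
    t = n - 1
    l_idx = int(np.argmin(D[t]))
    while t >= t_first:
        lags_out[t] = min_lag + l_idx
        move = B[t, l_idx]
        if move == 1:
            l_idx -= 1
        elif move == 2:
            l_idx += 1
        t -= 1
    return lags_out


def _granger_F(x: np.ndarray, y: np.ndarray, max_lag: int, variable_lag: bool,
               step_penalty: float) -> tuple[float, np.ndarray]:
    """F statistic of the nested Granger regressions; returns (F, lags)."""
    n = x.size
    p_order = max_lag
    if variable_lag:
        lags = dtw_align(x, y, max_lag, min_lag=1, step_penalty=step_penalty)
        xt = np.full(n, np.nan)
        ok = lags > 0
        xt[ok] = x[np.arange(n)[ok] - lags[ok]]
        x_terms = [np.roll(xt, k) for k in range(p_order)]   # x~(t), x~(t-1), ...
    else:
        lags = np.full(n, -1)
        x_terms = [np.roll(x, k + 1) for k in range(p_order)]  # x(t-1..p)
    y_terms = [np.roll(y, k + 1) for k in range(p_order)]
    rows = slice(max_lag + p_order, n)
    Y = y[rows]
    base = np.column_stack([np.ones(Y.size)] + [v[rows] for v in y_terms])
    full = np.column_stack([base] + [v[rows] for v in x_terms])
    if not np.isfinite(full).all():
        keep = np.isfinite(full).all(axis=1)
        Y, base, full = Y[keep], base[keep], full[keep]
    rss0 = float(np.sum((Y - base @ np.linalg.lstsq(base, Y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((Y - full @ np.linalg.lstsq(full, Y, rcond=None)[0]) ** 2))
    df1 = full.shape[1] - base.shape[1]
    df2 = Y.size - full.shape[1]
    if df2 <= 0 or rss1 <= 1e-300:
        F = np.inf if rss0 > rss1 + 1e-300 else 0.0
    else:
        F = max((rss0 - rss1) / df1, 0.0) / (rss1 / df2)
    return F, lags


def vl_granger(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 10,
    alpha: float = 0.01,
    variable_lag: bool = True,
    n_perm: int = 200,
    seed: int = 0,
    step_penalty: float = 4.0,
) -> VariableLagResult:
    """Variable-lag Granger causality x -> y.

    The aligned source x~(t) = x(t − Δ(t)) (Δ from the penalised DTW band,
    Δ >= 1, so x~ is strictly past information) enters a nested
    regression: y(t) ~ y(t−1..p) versus y(t) ~ y(t−1..p) + x~(t−0..p−1),
    compared by an F statistic on the residual sum of squares reduction.
    Because the alignment is itself data-adaptive, the analytic F
    reference is not valid for the variable-lag statistic; significance
    is therefore calibrated by ``n_perm`` circular-shift permutations of
    the source, each re-aligned and re-fitted (``n_perm=0`` falls back to
    the analytic F distribution, which is exact for the fixed-lag
    variant). The direction flag requires a positive median alignment lag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n <= 3 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    if x.std() == 0 or y.std() == 0:
        return VariableLagResult("x", "y", np.array([]), 0.0, 1.0, False)
    F, lags = _granger_F(x, y, max_lag, variable_lag, step_penalty)
    if n_perm > 0 and variable_lag:
        rng = np.random.default_rng(seed)
        count = 0
        lo, hi = max_lag + 1, n - max_lag - 1
        for _ in range(n_perm):
            shift = int(rng.integers(lo, hi)) if hi > lo else int(rng.integers(1, n))
            Fp, _ = _granger_F(np.roll(x, shift), y, max_lag, True, step_penalty)
            if Fp >= F - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        p_order = max_lag
        df1, df2 = p_order, max(n - max_lag - p_order - (2 * p_order + 1), 1)
        p = float(sps.f.sf(F, df1, df2))
    direction = bool(np.median(lags[lags > 0]) > 0) if (lags > 0).any() else False
    return VariableLagResult("x", "y", lags[lags > 0], float(F), float(p), direction)


def _discretize(v: np.ndarray, bins: int) -> np.ndarray:
    uniq = np.unique(v)
    if uniq.size <= bins:
        return np.searchsorted(uniq, v)
    qs = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, v, side="right")


def _plugin_te(yt: np.ndarray, yp: np.ndarray, xp: np.ndarray, bins: int) -> float:
    """Plug-in transfer entropy (bits) from discretised triples."""
    code = (yt * bins + yp) * bins + xp
    c_xyz = np.bincount(code, minlength=bins**3).astype(float).reshape(bins, bins, bins)
    n = c_xyz.sum()
    p_xyz = c_xyz / n
    p_yz = c_xyz.sum(axis=0) / n           # (y_prev, x)
    p_ty = c_xyz.sum(axis=2) / n           # (y_t, y_prev)
    p_y = c_xyz.sum(axis=(0, 2)) / n       # y_prev
    te = 0.0
    for a in range(bins):
        for b in range(bins):
            for c in range(bins):
                pj = p_xyz[a, b, c]
                if pj <= 0:
                    continue
                num = pj / p_yz[b, c]
                den = p_ty[a, b] / p_y[b]
                te += pj * np.log2(num / den)
    return max(float(te), 0.0)


def vl_transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 10,
    bins: int = 3,
    n_perm: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    step_penalty: float = 4.0,
) -> VariableLagResult:
    """Variable-lag transfer entropy x -> y with permutation significance.

    The source is DTW-aligned into x~ (strictly positive lags up to
    ``max_lag``, smooth-path penalty as in :func:`dtw_align`); both series
    are quantile-discretised into ``bins`` states (series with fewer
    distinct values use those directly); TE is the plug-in estimate over
    (y_t, y_{t-1}, x~_t) triples with history length one. p is the
    fraction of circular-shift permutations of the source whose re-aligned
    TE is at least the observed value — re-alignment keeps the null
    distribution comparable to the data-adaptive observed statistic. The
    direction flag additionally requires the forward TE to exceed the
    reverse one.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n <= 3 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    rng = np.random.default_rng(seed)

    def _aligned_te(src: np.ndarray, tgt_d: tuple) -> tuple[float, np.ndarray]:
        tgt_cont = tgt_d[1]
        tgt_codes = tgt_d[0]
        lags = dtw_align(src, tgt_cont, max_lag, min_lag=1,
                         step_penalty=step_penalty)
        t_idx = np.arange(n)
        ok = (lags > 0) & (t_idx >= 1)
        src_codes = _discretize(src, bins)
        xt_d = src_codes[t_idx[ok] - lags[ok]]
        yt_d = tgt_codes[t_idx[ok]]
        yp_d = tgt_codes[t_idx[ok] - 1]
        return _plugin_te(yt_d, yp_d, xt_d, bins), lags

    y_pack = (_discretize(y, bins), y)
    x_pack = (_discretize(x, bins), x)
    te_fwd, lags = _aligned_te(x, y_pack)
    te_rev, _ = _aligned_te(y, x_pack)
    count = 0
    lo, hi = max_lag + 1, n - max_lag - 1
    for _ in range(n_perm):
        shift = int(rng.integers(lo, hi)) if hi > lo else int(rng.integers(1, n))
        te_p, _ = _aligned_te(np.roll(x, shift), y_pack)
        if te_p >= te_fwd - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return VariableLagResult("x", "y", lags[lags > 0], te_fwd, float(p),
                             bool(te_fwd > te_rev), reverse_statistic=te_rev)


def adjust_pvalues(p_matrix: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Adjust the off-diagonal p-values of one particle's test matrix.

    bonferroni: p' = min(1, m p) with m the number of tested (finite,
    off-diagonal) entries; holm and BH via the standard step procedures.
    """
    P = np.asarray(p_matrix, dtype=float).copy()
    p_dim = P.shape[0]
    mask = ~np.eye(p_dim, dtype=bool) & np.isfinite(P)
    vals = P[mask]
    if vals.size == 0:
        return P
    if method == "bonferroni":
        adj = np.minimum(vals * vals.size, 1.0)
    elif method in {"holm", "BH", "fdr_bh"}:
        sm_method = {"holm": "holm", "BH": "fdr_bh", "fdr_bh": "fdr_bh"}[method]
        adj = multipletests(vals, method=sm_method)[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    P[mask] = adj
    return P


def causality_scan(
    table: pd.DataFrame,
    variables: list[str],
    method: str = "vlte",
    max_lag: int = 10,
    alpha: float = 0.01,
    adjust: str = "bonferroni",
    bins: int = 3,
    n_perm: int = 100,
    seed: int = 0,
    detrend: bool = False,
) -> AdjacencyStack:
    """Run one causality algorithm per particle over all variable pairs.

    Produces the per-particle binary adjacency stack: for 'vlgc'/'vlte'
    each ordered pair is tested, p-values are adjusted per particle, and
    a_ij = 1 when the adjusted p < alpha (and, for VLTE, the forward TE
    exceeds the reverse). For 'pc' the directed CPDAG claims are used
    as-is (its error control lives in the test level alpha).
    """
    if method not in {"pc", "vlgc", "vlte"}:
        raise ValueError("method must be one of pc, vlgc, vlte")
    p_dim = len(variables)
    mats, particles = [], []
    for part_idx, (key, sub) in enumerate(iter_tracks(table)):
        X = sub[variables].to_numpy(dtype=float)
        keep = np.isfinite(X).all(axis=1)
        X = X[keep]
        if detrend:
            t = np.arange(X.shape[0])
            for c in range(p_dim):
                X[:, c] = X[:, c] - np.polyval(np.polyfit(t, X[:, c], 1), t)
        A = np.zeros((p_dim, p_dim), dtype=int)
        if method == "pc":
            est = PCAlgorithm(alpha=alpha).fit(X, variables)
            A = est.adjacency_
        else:
            P = np.full((p_dim, p_dim), np.nan)
            direction = np.zeros((p_dim, p_dim), dtype=bool)
            for i in range(p_dim):
                for j in range(p_dim):
                    if i == j:
                        continue
                    if method == "vlgc":
                        res = vl_granger(X[:, i], X[:, j], max_lag, alpha)
                    else:
                        pair_seed = int(np.random.SeedSequence(
                            [seed & 0x7FFFFFFF, part_idx, i, j]
                        ).generate_state(1)[0] & 0x7FFFFFFF)
                        res = vl_transfer_entropy(
                            X[:, i], X[:, j], max_lag, bins, n_perm, alpha,
                            seed=pair_seed,
                        )
                    P[i, j] = res.p_value
                    direction[i, j] = res.direction
            P_adj = adjust_pvalues(P, adjust)
            A = ((P_adj < alpha) & direction).astype(int)
        np.fill_diagonal(A, 0)
        mats.append(A)
        particles.append(key)
    return AdjacencyStack(np.array(mats), tuple(variables), method, alpha, adjust,
                          particles)


def aggregate_adjacency(stack: AdjacencyStack, threshold: float = 0.8
                        ) -> AggregateCausalGraph:
    """Entrywise mean of the binary stack, thresholded into edges."""
    if stack.matrices.shape[0] < 1:
        raise ValueError("empty adjacency stack")
    a_hat = stack.matrices.mean(axis=0)
    df = pd.DataFrame(a_hat, index=stack.variables, columns=stack.variables)
    return AggregateCausalGraph(df, threshold, stack.algorithm)


def export_graph(graph: AggregateCausalGraph, out_dir, prefix: str = "causality"):
    """Write the presence matrix (CSV), retained edges (CSV) and GraphML."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_path = out_dir / f"{prefix}_adjacency.csv"
    graph.a_hat.round(6).to_csv(matrix_path)
    edges_path = out_dir / f"{prefix}_edges.csv"
    graph.edges.to_csv(edges_path, index=False)
    gml_path = out_dir / f"{prefix}_graph.graphml"
    nx.write_graphml(graph.to_networkx(), gml_path)
    return {"adjacency": matrix_path, "edges": edges_path, "graphml": gml_path}
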