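"""Group-comparison statistics for segmented track datasets.

Cluster-composition differences between two groups are tested with a
family of binomial GLMs (logistic regressions) on per-segment predictors —
behavioural cluster, start/end time and proportion of the track — each
compared to the intercept-only model by an analysis-of-deviance chi-squared
test. The remaining summaries (spectral densities and spectrograms,
velocity densities, the Mann-Whitney U location test, MSD curves) are
time-ensemble views, and a simulation harness estimates the statistical
power of either route on the synthetic Type I/II fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import spectral
from .io import derive_velocities, iter_tracks
from .segmentation import SegmentationParams, SegmentationResult, segment_dataset
from .synthetic import SyntheticConfig, generate_track

__all__ = [
    "LRTestResult",
    "PowerResult",
    "COMPOSITION_MODELS",
    "fit_composition_models",
    "periodogram",
    "spectrogram",
    "ensemble_spectrogram",
    "spectral_density_test",
    "velocity_density",
    "velocity_u_test",
    "msd",
    "assess_power",
]

periodogram = spectral.periodogram
spectrogram = spectral.spectrogram

#: model family, headline (cluster x start x end interaction) first
COMPOSITION_MODELS = (
    "cluster_x_start_x_end",
    "time",
    "cluster_x_proportion",
    "cluster",
    "intercept_only",
)


@dataclass
class LRTestResult:
    """One composition model versus the intercept-only baseline."""

    formula_id: str
    deviance: float
    df_model: int
    null_deviance: float
    p_value: float
    test: str = "chisq"
    separation_flag: bool = False


@dataclass
class PowerResult:
    """Power estimate with its per-replicate evidence."""

    test: str
    n_per_group: int
    n_replicates: int
    alpha: float
    p_values: np.ndarray
    seeds: np.ndarray

    @property
    def power(self) -> float:
        return float(np.mean(self.p_values < self.alpha))


def _fit_logit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-4,
               max_iter: int = 100) -> tuple[np.ndarray, float, bool]:
    """Penalised IRLS for a binomial GLM with intercept.

    A small ridge penalty on the slope coefficients (never the intercept)
    stabilises separation-prone fits. Returns (beta, deviance, separation
    flag); the deviance is the unpenalised −2·loglik at the estimate.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / W
        XtW = X.T * W
        H = XtW @ X + np.diag(pen)
        new = np.linalg.solve(H, XtW @ z + 0.0)
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    dev = -2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
    separated = bool(np.max(np.abs(beta[1:])) > 15) if p > 1 else False
    return beta, float(dev), separated


def _design(segments: pd.DataFrame, formula_id: str) -> np.ndarray:
    """Design matrix (with intercept) for one composition model.

    Continuous predictors are z-scaled for numerical conditioning — this
    leaves the deviance tests unchanged.
    """
    n = len(segments)

    def _z(col: str) -> np.ndarray:
        v = segments[col].to_numpy(dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    cols: list[np.ndarray] = [np.ones(n)]
    if formula_id == "intercept_only":
        return np.column_stack(cols)
    s, e, pr = _z("start_time"), _z("end_time"), _z("proportion")
    C = pd.get_dummies(segments["cluster"], drop_first=True).to_numpy(dtype=float)
    if formula_id == "cluster":
        cols.append(C)
    elif formula_id == "time":
        cols += [s[:, None], e[:, None], (s * e)[:, None]]
    elif formula_id == "cluster_x_proportion":
        cols += [C, pr[:, None], C * pr[:, None]]
    elif formula_id == "cluster_x_start_x_end":
        cols += [C, s[:, None], e[:, None], C * s[:, None], C * e[:, None],
                 (s * e)[:, None], C * (s * e)[:, None]]
    else:
        raise ValueError(f"unknown formula_id {formula_id!r}")
    return np.column_stack(cols)


def fit_composition_models(
    result: SegmentationResult | pd.DataFrame,
    group_a: str,
    group_b: str,
    test: str = "chisq",
    models: Sequence[str] = COMPOSITION_MODELS,
    ridge: float = 1e-4,
) -> dict[str, LRTestResult]:
    """Fit the composition model family and test each against intercept-only.

    The observation unit is the segment; the binary response indicates
    membership of ``group_b``. Both the chi-squared (default) and
    likelihood-ratio variants use the same analysis-of-deviance statistic
    (difference of binomial deviances on a chi-squared reference).
    """
    if test not in {"chisq", "LRT"}:
        raise ValueError("test must be 'chisq' or 'LRT'")
    segments = result.segments if isinstance(result, SegmentationResult) else result
    seg = segments[segments["group_id"].isin([group_a, group_b])].reset_index(drop=True)
    if seg["group_id"].nunique() < 2:
        raise ValueError("both groups must be present in the segment table")
    y = (seg["group_id"] == group_b).to_numpy(dtype=float)

    X0 = _design(seg, "intercept_only")
    _, dev0, _ = _fit_logit(X0, y, ridge)
    out: dict[str, LRTestResult] = {}
    for fid in models:
        X = _design(seg, fid)
        _, dev, flag = _fit_logit(X, y, ridge)
        dev = min(dev, dev0)  # numerical guard: candidate nests the null
        df = X.shape[1] - 1
        if df == 0:
            p = 1.0
        else:
            p = float(sps.chi2.sf(dev0 - dev, df))
        out[fid] = LRTestResult(fid, dev, df, dev0, p, test, flag)
    return out


def ensemble_spectrogram(
    table: pd.DataFrame,
    var: str = "x",
    window: float = 30.0,
    hop: int = 1,
    by_cluster: SegmentationResult | None = None,
    normalize: str | None = "slice",
) -> dict:
    """Average short-time spectrograms across particles, per group.

    Tracks must share a common-zero time alignment; slices are binned on
    the common time axis. With ``normalize='slice'`` each time slice is
    scaled to [0, 1] for display. Returns
    {group: {"times", "periods", "S"}} (and per-cluster keys when a
    segmentation result is supplied).
    """
    out: dict = {}
    for group, gtab in table.groupby("group_id", observed=True):
        acc: dict[float, list[np.ndarray]] = {}
        periods = None
        for (g, p), sub in iter_tracks(gtab):
            x = sub[var].to_numpy(dtype=float)
            t = sub["time_min"].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size < max(8, int(window)):
                continue
            times, periods, S = spectral.spectrogram(x, t[1] - t[0], window, hop)
            for k, tc in enumerate(times + t[0]):
                acc.setdefault(round(float(tc), 6), []).append(S[:, k])
        if not acc:
            continue
        times = np.array(sorted(acc))
        S = np.column_stack([np.mean(acc[tc], axis=0) for tc in sorted(acc)])
        if normalize == "slice":
            peak = S.max(axis=0)
            S = S / np.where(peak > 0, peak, 1.0)
        out[group] = {"times": times, "periods": periods, "S": S}
    return out


def _band_powers(x: np.ndarray, dt: float, n_bands: int = 4) -> np.ndarray:
    """log10 total power in octave period bands [2,4), [4,8), ... minutes."""
    periods, power = spectral.periodogram(x, dt)
    edges = 2.0 * 2.0 ** np.arange(n_bands + 1)
    out = np.empty(n_bands)
    for b in range(n_bands):
        lo, hi = edges[b], edges[b + 1]
        mask = (periods >= lo) & (periods < hi) if b < n_bands - 1 else (periods >= lo)
        out[b] = np.log10(power[mask].sum() + 1e-12)
    return out


def spectral_density_test(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    var: str = "x",
    n_bands: int = 4,
) -> float:
    """GLM test for different spectral densities between two groups.

    Each particle contributes its log band powers in octave period bands;
    a binomial GLM of group on band powers is compared to intercept-only
    by analysis of deviance. Returns the p-value.
    """
    rows, ys = [], []
    for (g, p), sub in iter_tracks(table[table["group_id"].isin([group_a, group_b])]):
        x = sub[var].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        t = sub["time_min"].to_numpy(dtype=float)
        if x.size < 8:
            continue
        rows.append(_band_powers(x, t[1] - t[0], n_bands))
        ys.append(1.0 if g == group_b else 0.0)
    y = np.array(ys)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 particles per group")
    F = np.array(rows)
    F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) > 0, F.std(axis=0), 1.0)
    X = np.column_stack([np.ones(len(y)), F])
    _, dev0, _ = _fit_logit(X[:, :1], y)
    _, dev1, _ = _fit_logit(X, y)
    return float(sps.chi2.sf(max(dev0 - dev1, 0.0), F.shape[1]))


def velocity_density(
    table: pd.DataFrame,
    var: str = "linear_velocity",
    by: str = "group",
    over_time: bool = False,
    grid_size: int = 100,
    result: SegmentationResult | None = None,
) -> dict:
    """Kernel density estimates of a velocity descriptor per stratum.

    ``by`` is 'group' or 'group_and_cluster' (the latter needs a
    segmentation result to map frames to behavioural clusters). With
    ``over_time`` a (time x velocity) grid is returned instead, each time
    column normalised to integrate to 1.
    """
    if var not in table.columns:
        table = derive_velocities(table)
    work = table[np.isfinite(table[var])].copy()
    if by == "group_and_cluster":
        if result is None:
            raise ValueError("group_and_cluster stratification needs a SegmentationResult")
        labels = np.full(len(work), -1)
        for (g, p), sub in iter_tracks(work):
            fl = result.frame_labels(g, p, len(sub))
            labels[work.index.get_indexer(sub.index)] = fl
        work["cluster"] = labels
        keys = ["group_id", "cluster"]
    elif by == "group":
        keys = ["group_id"]
    else:
        raise ValueError(f"unknown stratification {by!r}")

    out: dict = {}
    for key, sub in work.groupby(keys, observed=True):
        v = sub[var].to_numpy(dtype=float)
        if v.size < 2:
            warnings.warn(f"stratum {key!r} empty or singleton; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        name = key if len(keys) > 1 else key[0] if isinstance(key, tuple) else key
        if over_time:
            t = sub["time_min"].to_numpy(dtype=float)
            t_edges = np.linspace(t.min(), t.max(), grid_size + 1)
            v_edges = np.linspace(v.min(), v.max() + 1e-12, grid_size + 1)
            H, _, _ = np.histogram2d(t, v, bins=[t_edges, v_edges], density=False)
            widths = np.diff(v_edges)
            col_mass = (H * widths).sum(axis=1, keepdims=True)
            D = np.divide(H, col_mass, out=np.zeros_like(H), where=col_mass > 0)
            out[name] = {"time_edges": t_edges, "velocity_edges": v_edges,
                         "density": D}
        else:
            if np.ptp(v) == 0:
                out[name] = {"values": v, "kde": None, "point_mass": float(v[0])}
                continue
            out[name] = {"values": v, "kde": sps.gaussian_kde(v)}
    return out


def velocity_u_test(table: pd.DataFrame, group_a: str, group_b: str,
                    var: str = "linear_velocity") -> float:
    """Two-sided Mann-Whitney U on pooled per-frame velocities."""
    if var not in table.columns:
        table = derive_velocities(table)
    va = table.loc[table["group_id"] == group_a, var].dropna().to_numpy()
    vb = table.loc[table["group_id"] == group_b, var].dropna().to_numpy()
    if va.size == 0 or vb.size == 0:
        raise ValueError("both groups must contribute velocities")
    if np.array_equal(np.sort(va), np.sort(vb)):
        return 1.0  # identical pooled samples: no location shift by definition
    return float(sps.mannwhitneyu(va, vb, alternative="two-sided").pvalue)


def msd(
    table: pd.DataFrame,
    max_lag: float | None = None,
    scope: str = "global",
    result: SegmentationResult | None = None,
) -> pd.DataFrame:
    """Mean squared displacement over particles and overlapping start times.

    Returns a tidy frame with columns ``lag_min``, ``msd`` (and ``cluster``,
    ``n_pairs`` for per-cluster scope). Per-cluster curves assign each
    (t, t+tau) pair to the cluster of its start frame, so the pair-count
    weighted average over clusters recovers the global curve exactly.
    """
    track_list = [
        (key, sub[["x", "y"]].to_numpy(dtype=float),
         sub["time_min"].to_numpy(dtype=float))
        for key, sub in iter_tracks(table)
    ]
    step = track_list[0][2][1] - track_list[0][2][0]
    shortest = min(len(xy) for _, xy, _ in track_list)
    max_steps = shortest - 1
    if max_lag is not None:
        want = int(round(max_lag / step))
        if want > max_steps:
            warnings.warn(f"max_lag truncated to {max_steps * step} min",
                          RuntimeWarning, stacklevel=2)
        else:
            max_steps = want
    lags = np.arange(0, max_steps + 1)

    per_cluster = scope == "cluster"
    if per_cluster and result is None:
        raise ValueError("per-cluster MSD needs a SegmentationResult")
    sums: dict = {}
    counts: dict = {}
    for key, xy, t in track_list:
        labels = (result.frame_labels(*key, len(xy)) if per_cluster
                  else np.zeros(len(xy), dtype=int))
        for lag in lags[1:]:
            d = xy[lag:] - xy[:-lag]
            sq = (d**2).sum(axis=1)
            lab = labels[:len(sq)]
            for c in np.unique(lab):
                m = lab == c
                sums[(c, lag)] = sums.get((c, lag), 0.0) + sq[m].sum()
                counts[(c, lag)] = counts.get((c, lag), 0) + int(m.sum())
    rows = []
    clusters = sorted({c for c, _ in sums}) if sums else [0]
    for c in clusters:
        rows.append({"cluster": c, "lag_min": 0.0, "msd": 0.0, "n_pairs": 0})
        for lag in lags[1:]:
            if (c, lag) in sums:
                rows.append({"cluster": c, "lag_min": lag * step,
                             "msd": sums[(c, lag)] / counts[(c, lag)],
                             "n_pairs": counts[(c, lag)]})
    out = pd.DataFrame(rows)
    if not per_cluster:
        out = out.drop(columns=["cluster"])
    return out


def composition_p_value(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    covariates: Sequence[str] = ("x",),
    params: SegmentationParams | None = None,
    cluster_range: Iterable[int] = range(1, 11),
    random_state: int = 0,
    model: str = "cluster_x_start_x_end",
) -> float:
    """Full segmentation → clustering → composition-ANOVA pipeline p-value."""
    if any(c not in table.columns for c in covariates):
        table = derive_velocities(table)
    res = segment_dataset(table, covariates, params, cluster_range, random_state)
    tests = fit_composition_models(res, group_a, group_b, models=(model,))
    return tests[model].p_value


def assess_power(
    config: SyntheticConfig | None = None,
    n_per_group: int = 60,
    n_replicates: int = 100,
    alpha: float = 0.05,
    test: str = "composition",
    seed: int = 0,
    covariates: Sequence[str] = ("linear_velocity",),
    params: SegmentationParams | None = None,
    cluster_range: Iterable[int] = range(1, 11),
) -> PowerResult:
    """Estimate the power of a two-group test on replicate synthetic datasets.

    Per replicate, a fresh Type I / Type II dataset pair is generated at
    ``n_per_group`` tracks each and the named test is run end-to-end
    ('composition': segmentation, GMM clustering and the headline
    composition ANOVA; 'global_velocity': pooled Mann-Whitney U on linear
    velocities). Power is the fraction of replicates with p < alpha; the
    per-replicate seeds and p-values are retained so the estimate is
    exactly recomputable.
    """
    if test not in {"composition", "global_velocity"}:
        raise ValueError("test must be 'composition' or 'global_velocity'")
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0xA55E55])
    rep_seeds = np.array([int(s.generate_state(1)[0] & 0x7FFFFFFF)
                          for s in ss.spawn(n_replicates)])
    pvals = np.empty(n_replicates)
    for r, rseed in enumerate(rep_seeds):
        cfg = replace(config, seed=int(rseed), n_tracks_per_type=n_per_group)
        frames = []
        for type_ in ("I", "II"):
            for idx in range(n_per_group):
                tab, _ = generate_track(cfg, type_, track_seed=idx)
                frames.append(tab)
        data = pd.concat(frames, ignore_index=True)
        from .io import align_time

        data = align_time(data, "last_common_zero")
        if test == "composition":
            pvals[r] = composition_p_value(
                data, "TypeI", "TypeII", covariates, params, cluster_range,
                random_state=int(rseed) % 2**31,
            )
        else:
            data = derive_velocities(data)
            pvals[r] = velocity_u_test(data, "TypeI", "TypeII")
    return PowerResult(test, n_per_group, n_replicates, alpha, pvals, rep_seeds)
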