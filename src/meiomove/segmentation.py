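"""Behavioural segmentation of particle tracks and segment clustering.

Two change-point engines are provided as sklearn-style estimators:

* :class:`LavielleSegmenter` — dynamic programming over a heteroscedastic
  Gaussian contrast (per-segment mean and variance, summed over up to two
  channels), with the number of segments selected by Lavielle's
  second-difference criterion on the normalised contrast curve.
* :class:`MultivariateSegmenter` — for three or more channels: time points
  are first clustered into states by k-means, then a dynamic programme
  maximises the within-segment similarity to the best state minus a
  per-segment penalty.

Discovered segments are summarised (mean, sd, dominant period, dominant
power fraction per covariate, plus duration) and clustered across the whole
dataset by a Gaussian mixture with BIC model selection
(:class:`SegmentClusterer`), yielding behavioural cluster labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .io import iter_tracks
from .spectral import dominant_period

__all__ = [
    "SegmentationParams",
    "LavielleSegmenter",
    "MultivariateSegmenter",
    "SegmentClusterer",
    "SegmentationResult",
    "segment_lavielle",
    "segment_multivariate",
    "extract_segment_features",
    "cluster_segments",
    "segment_dataset",
]

_VAR_FLOOR = 1e-10


@dataclass
class SegmentationParams:
    """Tunable knobs of the change-point search."""

    k_max: int = 10
    l_min: int = 5
    threshold: float = 0.75
    mode: str = "auto"  # 'lavielle_1d' | 'lavielle_2d' | 'multivariate' | 'auto'
    n_states: int = 4
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")


def _gaussian_cost_matrix(X: np.ndarray, l_min: int) -> np.ndarray:
    """cost[i, j] = Gaussian NLL of x[i..j] (inclusive) as one segment.

    Per channel: (L/2)·(log(2·pi·var) + 1) with the MLE variance floored at
    1e-10; entries with fewer than ``l_min`` frames are +inf.
    """
    n, d = X.shape
    s1 = np.vstack([np.zeros(d), np.cumsum(X, axis=0)])
    s2 = np.vstack([np.zeros(d), np.cumsum(X**2, axis=0)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    L = (j - i + 1).astype(float)
    cost = np.zeros((n, n))
    for ch in range(d):
        seg_sum = s1[j + 1, ch] - s1[i, ch]
        seg_sq = s2[j + 1, ch] - s2[i, ch]
        with np.errstate(invalid="ignore", divide="ignore"):
            var = seg_sq / L - (seg_sum / L) ** 2
        var = np.maximum(var, _VAR_FLOOR)
        cost += 0.5 * L * (np.log(2.0 * np.pi * var) + 1.0)
    cost[L < l_min] = np.inf
    return cost


def _lavielle_select(J: np.ndarray, threshold: float) -> int:
    """Lavielle's criterion: the largest k whose normalised second
    difference exceeds ``threshold`` (1 when none qualifies).

    J[k-1] is the optimal contrast with k segments, k = 1..K.
    """
    K = len(J)
    if K < 3:
        return 1
    denom = J[0] - J[-1]
    if not np.isfinite(denom) or denom <= 1e-12:
        return 1
    Jt = (J - J[-1]) / denom * (K - 1) + 1
    best = 1
    for k in range(2, K):  # second difference defined for 1 < k < K
        D = Jt[k - 2] - 2 * Jt[k - 1] + Jt[k]
        if D > threshold:
            best = k
    return best


class LavielleSegmenter(BaseEstimator):
    """Optimal Gaussian-contrast segmentation of a 1- or 2-channel series.

    Parameters
    ----------
    k_max : int
        Maximum number of segments searched (reduced, with a warning, when
        the series is too short for ``k_max * l_min`` frames).
    l_min : int
        Minimum segment length in frames.
    threshold : float
        Lavielle second-difference threshold for selecting the number of
        segments.

    Attributes
    ----------
    breakpoints_ : list of (start, end) inclusive frame-index pairs
    n_segments_ : int, selected number of segments
    contrast_ : ndarray, optimal contrast J(k) for k = 1..k_max_effective
    """

    def __init__(self, k_max: int = 10, l_min: int = 5, threshold: float = 0.75):
        self.k_max = k_max
        self.l_min = l_min
        self.threshold = threshold

    def fit(self, X: np.ndarray, y=None) -> "LavielleSegmenter":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1:
            X = X.T
        n, d = X.shape
        if d > 2:
            raise ValueError(
                "LavielleSegmenter handles 1 or 2 channels; use MultivariateSegmenter"
            )
        if not np.isfinite(X).all():
            raise ValueError("series contains missing values; trim edges first")
        if n < 2 * self.l_min:
            raise ValueError(f"series of {n} frames too short for l_min={self.l_min}")
        k_eff = min(self.k_max, n // self.l_min)
        if k_eff < self.k_max:
            warnings.warn(
                f"k_max reduced from {self.k_max} to {k_eff} for a series of {n} frames",
                RuntimeWarning, stacklevel=2,
            )
        cost = _gaussian_cost_matrix(X, self.l_min)

        J = np.full((k_eff + 1, n), np.inf)
        back = np.zeros((k_eff + 1, n), dtype=int)
        J[1] = cost[0]
        for k in range(2, k_eff + 1):
            cand = J[k - 1][: n - 1, None] + cost[1:, :]
            arg = np.argmin(cand, axis=0)
            J[k] = cand[arg, np.arange(n)]
            back[k] = arg + 1
        feasible = np.isfinite(J[1:, n - 1])
        Jk = J[1:, n - 1][feasible]
        ks = np.arange(1, k_eff + 1)[feasible]
        k_star = ks[_lavielle_select(Jk, self.threshold) - 1] if len(ks) else 1

        bounds = []
        j = n - 1
        for k in range(k_star, 0, -1):
            i = back[k, j] if k > 1 else 0
            bounds.append((int(i), int(j)))
            j = i - 1
        self.breakpoints_ = bounds[::-1]
        self.n_segments_ = int(k_star)
        self.contrast_ = J[1:, n - 1].copy()
        self.n_samples_ = n
        return self

    def predict(self, X=None) -> np.ndarray:
        """Per-frame segment index of the fitted series."""
        labels = np.empty(self.n_samples_, dtype=int)
        for s, (i, j) in enumerate(self.breakpoints_):
            labels[i:j + 1] = s
        return labels


class MultivariateSegmenter(BaseEstimator):
    """Two-stage segmentation for three or more channels.

    Channels are standardised; time points are clustered into ``n_states``
    states by k-means; a dynamic programme then maximises
    sum over segments of [max_state sum_t sim(t, state)] − lam·(#segments),
    where sim is the Pearson correlation of a time point's channel vector
    with a state centroid, subject to the minimum segment length. The
    penalty defaults to 0.5·l_min·d.
    """

    def __init__(self, n_states: int = 4, l_min: int = 5, lam: float | None = None,
                 random_state: int = 0):
        self.n_states = n_states
        self.l_min = l_min
        self.lam = lam
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "MultivariateSegmenter":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValueError("MultivariateSegmenter requires >= 3 channels; "
                             "use LavielleSegmenter for 1-2 channels")
        n, d = X.shape
        if n < 2 * self.l_min:
            raise ValueError(f"series of {n} frames too short for l_min={self.l_min}")
        sd = X.std(axis=0)
        if np.all(sd < 1e-12):
            self.breakpoints_ = [(0, n - 1)]
            self.n_segments_ = 1
            self.n_samples_ = n
            return self
        Z = (X - X.mean(axis=0)) / np.where(sd < 1e-12, 1.0, sd)
        n_states = min(self.n_states, len(np.unique(Z, axis=0)))
        km = KMeans(n_clusters=n_states, n_init=5, random_state=self.random_state)
        km.fit(Z)
        cent = km.cluster_centers_

        def _rowcorr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
            A0 = A - A.mean(axis=1, keepdims=True)
            B0 = B - B.mean(axis=1, keepdims=True)
            na = np.linalg.norm(A0, axis=1)
            nb = np.linalg.norm(B0, axis=1)
            out = (A0 @ B0.T) / np.outer(np.where(na < 1e-12, 1, na),
                                         np.where(nb < 1e-12, 1, nb))
            out[na < 1e-12, :] = 0.0
            out[:, nb < 1e-12] = 0.0
            return out

        sim = _rowcorr(Z, cent)  # (n, S)
        lam = self.lam if self.lam is not None else 0.5 * self.l_min * d
        P = np.vstack([np.zeros(sim.shape[1]), np.cumsum(sim, axis=0)])  # (n+1, S)

        best = np.full(n, -np.inf)
        back = np.zeros(n, dtype=int)
        best0 = np.concatenate([[0.0], np.full(n, -np.inf)])  # best0[i] = best over x[0..i-1]
        for j in range(self.l_min - 1, n):
            i_max = j - self.l_min + 1
            i_vec = np.arange(0, i_max + 1)
            score = (P[j + 1][:, None] - P.T[:, i_vec]).max(axis=0)
            cand = best0[i_vec] + score - lam
            arg = int(np.argmax(cand))
            best[j] = cand[arg]
            back[j] = i_vec[arg]
            best0[j + 1] = best[j]

        bounds = []
        j = n - 1
        while j >= 0:
            i = back[j]
            bounds.append((int(i), int(j)))
            j = i - 1
        self.breakpoints_ = bounds[::-1]
        self.n_segments_ = len(self.breakpoints_)
        self.n_samples_ = n
        return self

    predict = LavielleSegmenter.predict


def segment_lavielle(series: np.ndarray, params: SegmentationParams | None = None
                     ) -> list[tuple[int, int]]:
    """Functional wrapper: breakpoints of a 1-2 channel series."""
    params = params or SegmentationParams()
    est = LavielleSegmenter(params.k_max, params.l_min, params.threshold)
    return est.fit(series).breakpoints_


def segment_multivariate(series: np.ndarray, params: SegmentationParams | None = None,
                         n_states: int | None = None) -> list[tuple[int, int]]:
    """Functional wrapper: breakpoints of a >= 3 channel series."""
    params = params or SegmentationParams()
    est = MultivariateSegmenter(n_states or params.n_states, params.l_min, params.lam)
    return est.fit(series).breakpoints_


def extract_segment_features(
    table: pd.DataFrame,
    segments: pd.DataFrame,
    covariates: Sequence[str],
    dt: float | None = None,
) -> pd.DataFrame:
    """One feature row per segment: per covariate mean, sd, dominant period
    and dominant power fraction (mean-removed periodogram), plus duration.

    Segments shorter than 4 frames get missing spectral features (their
    summary features are kept). Spectral features of constant stretches are
    reported as period NaN / power fraction 0 and later imputed.
    """
    rows = []
    tracks = {key: sub for key, sub in iter_tracks(table)}
    for seg in segments.itertuples(index=False):
        sub = tracks[(seg.group_id, seg.particle_id)]
        t = sub["time_min"].to_numpy(dtype=float)
        step = dt if dt is not None else (t[1] - t[0] if len(t) > 1 else 1.0)
        sl = slice(int(seg.start_idx), int(seg.end_idx) + 1)
        row = {}
        for cov in covariates:
            v = sub[cov].to_numpy(dtype=float)[sl]
            v = v[np.isfinite(v)]
            row[f"{cov}_mean"] = float(np.mean(v)) if v.size else np.nan
            row[f"{cov}_sd"] = float(np.std(v)) if v.size else np.nan
            period, frac = dominant_period(v, step)
            row[f"{cov}_dom_period"] = period
            row[f"{cov}_dom_power_frac"] = frac
        row["duration"] = float((seg.end_idx - seg.start_idx + 1) * step)
        rows.append(row)
    return pd.DataFrame(rows, index=segments.index)


class SegmentClusterer(BaseEstimator):
    """Gaussian-mixture clustering of segment features with BIC selection.

    Features are z-scored (constant columns left at 0); missing spectral
    features are imputed to 0 after scaling. For each candidate number of
    components a full-covariance Gaussian mixture is fitted with
    ``n_restarts`` seeded EM restarts and scored by
    BIC = 2·loglik − p·log(n); the candidate maximising BIC wins (smallest
    k on ties). Labels are maximum-posterior component indices.
    """

    def __init__(self, k_range: Iterable[int] = range(1, 11), n_restarts: int = 5,
                 random_state: int = 0, reg_covar: float = 1e-6):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.reg_covar = reg_covar

    def _scale(self, F: np.ndarray) -> np.ndarray:
        Z = (F - self.feature_means_) / self.feature_sds_
        return np.nan_to_num(Z, nan=0.0, posinf=0.0, neginf=0.0)

    def fit(self, F: pd.DataFrame | np.ndarray, y=None) -> "SegmentClusterer":
        if isinstance(F, pd.DataFrame):
            self.feature_names_ = list(F.columns)
            F = F.to_numpy(dtype=float)
        else:
            F = np.asarray(F, dtype=float)
            self.feature_names_ = [f"f{i}" for i in range(F.shape[1])]
        n = F.shape[0]
        if n < 2:
            raise ValueError("need at least 2 segments to cluster")
        self.feature_means_ = np.nanmean(F, axis=0)
        sds = np.nanstd(F, axis=0)
        self.feature_sds_ = np.where(sds < 1e-12, 1.0, sds)
        Z = self._scale(F)

        ks = sorted(set(int(k) for k in self.k_range))
        usable = [k for k in ks if k <= n]
        if len(usable) < len(ks):
            warnings.warn(f"cluster range truncated to <= {n} (number of segments)",
                          RuntimeWarning, stacklevel=2)
        self.bic_table_ = {}
        best = None
        for k in usable:
            gm = GaussianMixture(
                n_components=k, covariance_type="full", n_init=self.n_restarts,
                random_state=self.random_state, reg_covar=self.reg_covar,
            ).fit(Z)
            loglik = gm.score(Z) * n
            p = gm._n_parameters()
            bic = 2.0 * loglik - p * np.log(n)
            self.bic_table_[k] = float(bic)
            if best is None or bic > best[0] + 1e-9:
                best = (bic, k, gm)
        self.bic_, self.n_clusters_, self.model_ = best
        self.weights_ = self.model_.weights_
        self.means_ = self.model_.means_
        self.covariances_ = self.model_.covariances_
        self.labels_ = self.model_.predict(Z)
        return self

    def predict(self, F: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(F, pd.DataFrame):
            F = F.to_numpy(dtype=float)
        return self.model_.predict(self._scale(np.asarray(F, dtype=float)))


def cluster_segments(features: pd.DataFrame | np.ndarray,
                     k_range: Iterable[int] = range(1, 11),
                     random_state: int = 0) -> SegmentClusterer:
    """Functional wrapper around :class:`SegmentClusterer`."""
    return SegmentClusterer(k_range=k_range, random_state=random_state).fit(features)


@dataclass
class SegmentationResult:
    """Discovered segments with features and behavioural cluster labels."""

    segments: pd.DataFrame           # one row per segment, incl. 'cluster'
    clusterer: SegmentClusterer
    covariates: tuple[str, ...]
    params: SegmentationParams

    @property
    def n_clusters(self) -> int:
        return self.clusterer.n_clusters_

    def frame_labels(self, group_id, particle_id, n_frames: int) -> np.ndarray:
        """Per-frame cluster labels of one track (−1 where unsegmented)."""
        out = np.full(n_frames, -1, dtype=int)
        sel = self.segments[
            (self.segments["group_id"] == group_id)
            & (self.segments["particle_id"] == particle_id)
        ]
        for seg in sel.itertuples(index=False):
            out[int(seg.start_idx):int(seg.end_idx) + 1] = int(seg.cluster)
        return out


def segment_dataset(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("x",),
    params: SegmentationParams | None = None,
    cluster_range: Iterable[int] = range(1, 11),
    random_state: int = 0,
) -> SegmentationResult:
    """Segment every track on the selected covariates, then cluster segments.

    The segmentation engine follows the channel count (or ``params.mode``):
    Lavielle dynamic programming for 1-2 channels, the two-stage state-based
    programme for 3 or more. Edge frames with missing covariate values
    (e.g. final-frame velocities) are trimmed before segmentation.
    """
    params = params or SegmentationParams()
    covariates = tuple(covariates)
    d = len(covariates)
    mode = params.mode
    if mode == "auto":
        mode = "multivariate" if d >= 3 else ("lavielle_2d" if d == 2 else "lavielle_1d")
    seg_rows = []
    for (g, p), sub in iter_tracks(table):
        X = sub[list(covariates)].to_numpy(dtype=float)
        t = sub["time_min"].to_numpy(dtype=float)
        finite = np.isfinite(X).all(axis=1)
        lo, hi = np.argmax(finite), len(finite) - np.argmax(finite[::-1]) - 1
        Xv = X[lo:hi + 1]
        if not np.isfinite(Xv).all():
            raise ValueError(f"interior missing values in track ({g!r}, {p!r})")
        if mode == "multivariate":
            est = MultivariateSegmenter(params.n_states, params.l_min, params.lam,
                                        random_state)
        else:
            est = LavielleSegmenter(params.k_max, params.l_min, params.threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est.fit(Xv)
        step = t[1] - t[0] if len(t) > 1 else 1.0
        total = len(t) * step
        for (i, j) in est.breakpoints_:
            i, j = i + lo, j + lo
            seg_rows.append({
                "group_id": g, "particle_id": p,
                "start_idx": i, "end_idx": j,
                "start_time": t[i], "end_time": t[j],
                "duration": (j - i + 1) * step,
                "proportion": (j - i + 1) * step / total,
            })
    segments = pd.DataFrame(seg_rows)
    feats = extract_segment_features(table, segments, covariates)
    clusterer = SegmentClusterer(k_range=cluster_range, random_state=random_state)
    clusterer.fit(feats)
    segments = pd.concat([segments, feats], axis=1)
    segments["cluster"] = clusterer.labels_
    return SegmentationResult(segments, clusterer, covariates, params)
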