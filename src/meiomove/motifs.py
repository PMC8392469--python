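"""Matrix-profile computation and motif/discord discovery.

The matrix profile of a series records, for every window start, the
z-normalised Euclidean distance to its nearest non-trivial neighbouring
window; minima mark motifs (recurring patterns), maxima mark discords
(anomalies). An exact profile is computed by a streaming diagonal pass
(O(n^2) with O(n) memory); the approximate variant runs a sampled
anchor phase plus a budgeted fraction of the diagonals and is a pointwise
upper bound of the exact profile that converges to it as the budget grows.

Tracks (or all segments of one behavioural cluster) are concatenated into
a single series before discovery; window positions spanning a
concatenation junction are masked out of both the search and the
neighbour set. Correlation rho and z-normalised distance d are related by
d^2 = 2 w (1 - rho) for window length w.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import iter_tracks

__all__ = [
    "ConcatSeries",
    "MatrixProfileResult",
    "Motif",
    "MotifSet",
    "concat_series",
    "matrix_profile",
    "discover_motifs",
    "discover_discords",
    "motif_location_distribution",
]

_NEAR_CONSTANT_VAR = 1e-12


@dataclass
class ConcatSeries:
    """A concatenated series with provenance back to (particle, time)."""

    values: np.ndarray
    window: int
    boundary_mask: np.ndarray        # True at window positions crossing a junction
    provenance: pd.DataFrame         # per concat index: group_id, particle_id, time_min
    junctions: np.ndarray            # concat indices where a new piece starts

    def locate(self, pos: int) -> tuple:
        row = self.provenance.iloc[pos]
        return row["group_id"], row["particle_id"], float(row["time_min"])


def concat_series(
    table: pd.DataFrame,
    var: str = "x",
    window: int = 20,
    result=None,
    cluster: int | None = None,
) -> ConcatSeries:
    """Concatenate tracks (or one cluster's segments) into a single series.

    With ``result`` and ``cluster`` given, only the segments carrying that
    behavioural cluster label are concatenated. Window positions whose
    ``window`` frames span a junction between pieces are masked.
    """
    if var not in table.columns:
        raise KeyError(f"variable {var!r} not in table")
    pieces: list[pd.DataFrame] = []
    if cluster is not None:
        if result is None:
            raise ValueError("per-cluster concatenation needs a SegmentationResult")
        segs = result.segments[result.segments["cluster"] == cluster]
        if segs.empty:
            raise ValueError(f"cluster {cluster} has no segments")
        tracks = {key: sub for key, sub in iter_tracks(table)}
        for seg in segs.itertuples(index=False):
            sub = tracks[(seg.group_id, seg.particle_id)]
            pieces.append(sub.iloc[int(seg.start_idx):int(seg.end_idx) + 1])
    else:
        for _, sub in iter_tracks(table):
            pieces.append(sub)
    values, prov, junctions = [], [], []
    pos = 0
    for sub in pieces:
        v = sub[var].to_numpy(dtype=float)
        keep = np.isfinite(v)
        sub = sub[keep]
        v = v[keep]
        if v.size == 0:
            continue
        junctions.append(pos)
        values.append(v)
        prov.append(sub[["group_id", "particle_id", "time_min"]])
        pos += v.size
    series = np.concatenate(values)
    provenance = pd.concat(prov, ignore_index=True)
    n_pos = max(series.size - window + 1, 0)
    mask = np.zeros(n_pos, dtype=bool)
    for j in junctions[1:]:
        lo = max(j - window + 1, 0)
        mask[lo:min(j, n_pos)] = True
    return ConcatSeries(series, window, mask, provenance, np.array(junctions))


@dataclass
class MatrixProfileResult:
    """Distance/index profile of one series."""

    profile: np.ndarray
    index: np.ndarray
    window: int
    method: str
    series: np.ndarray
    mask: np.ndarray                  # True where excluded (junction or padding)
    exclusion_zone: int
    max_distance: float               # the variance-floor sentinel 2*sqrt(w)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask & np.isfinite(self.profile)


def _window_stats(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    mu = (c1[w:] - c1[:-w]) / w
    var = (c2[w:] - c2[:-w]) / w - mu**2
    return mu, np.maximum(var, 0.0)


def _pair_distance(x: np.ndarray, w: int, i: int, j: int,
                   mu: np.ndarray, sig: np.ndarray, max_d: float) -> float:
    if sig[i] <= 0 or sig[j] <= 0:
        return max_d
    q = float(np.dot(x[i:i + w], x[j:j + w]))
    rho = (q - w * mu[i] * mu[j]) / (w * sig[i] * sig[j])
    rho = min(max(rho, -1.0), 1.0)
    return float(np.sqrt(max(2.0 * w * (1.0 - rho), 0.0)))


def matrix_profile(
    series: np.ndarray | ConcatSeries,
    window: int = 20,
    method: str = "mpx_exact",
    boundary_mask: np.ndarray | None = None,
    approx_budget: float = 0.25,
    seed: int = 0,
) -> MatrixProfileResult:
    """Compute the z-normalised matrix profile of a series.

    Neighbours must be at least the exclusion zone ceil(w/2) away from
    their own position. Near-constant windows (variance < 1e-12) are
    assigned the maximal distance 2*sqrt(w) instead of a degenerate
    z-normalisation. ``scrimp_pp_approx`` evaluates a deterministic grid
    of anchor windows plus a seeded random fraction ``approx_budget`` of
    the diagonals, and upper-bounds the exact profile pointwise.
    """
    if isinstance(series, ConcatSeries):
        boundary_mask = series.boundary_mask if boundary_mask is None else boundary_mask
        if series.window != window:
            raise ValueError("ConcatSeries was masked for a different window size")
        series = series.values
    x = np.asarray(series, dtype=float)
    w = int(window)
    if w < 4:
        raise ValueError("window must be >= 4")
    n = x.size
    if n < 2 * w:
        raise ValueError(f"series of {n} frames shorter than two windows of {w}")
    m = n - w + 1
    ez = int(np.ceil(w / 2))
    max_d = 2.0 * np.sqrt(w)
    mu, var = _window_stats(x, w)
    sig = np.sqrt(var)
    degenerate = var < _NEAR_CONSTANT_VAR
    mask = np.zeros(m, dtype=bool) if boundary_mask is None else boundary_mask.astype(bool).copy()
    if mask.shape != (m,):
        raise ValueError("boundary_mask length must equal the number of window positions")

    P = np.full(m, np.inf)
    I = np.full(m, -1, dtype=int)
    usable = ~mask & ~degenerate

    def _update_diag(k: int) -> None:
        """min-update P along diagonal j - i = k (k >= ez)."""
        ln = m - k
        if ln <= 0:
            return
        prod = x[:n - k] * x[k:]
        cp = np.concatenate([[0.0], np.cumsum(prod)])
        q = cp[w:w + ln] - cp[:ln]
        i_idx = np.arange(ln)
        j_idx = i_idx + k
        ok = usable[i_idx] & usable[j_idx]
        if not ok.any():
            return
        rho = np.clip(
            (q[ok] - w * mu[i_idx[ok]] * mu[j_idx[ok]])
            / (w * sig[i_idx[ok]] * sig[j_idx[ok]]),
            -1.0, 1.0,
        )
        d = np.sqrt(np.maximum(2.0 * w * (1.0 - rho), 0.0))
        ii, jj = i_idx[ok], j_idx[ok]
        better_i = d < P[ii]
        P[ii[better_i]] = d[better_i]
        I[ii[better_i]] = jj[better_i]
        better_j = d < P[jj]
        P[jj[better_j]] = d[better_j]
        I[jj[better_j]] = ii[better_j]

    diagonals = np.arange(ez, m)
    if method == "mpx_exact":
        for k in diagonals:
            _update_diag(k)
    elif method == "scrimp_pp_approx":
        rng = np.random.default_rng(seed)
        # PRE phase: distance profiles of anchor windows on a w/4 grid
        stride = max(int(np.ceil(w / 4)), 1)
        for a in range(0, m, stride):
            if not usable[a]:
                continue
            d_prof = _distance_profile(x, w, a, mu, sig, usable, ez, max_d)
            better = d_prof < P
            P[better] = d_prof[better]
            I[better] = a
            if d_prof.size:
                b = int(np.argmin(d_prof))
                if d_prof[b] < P[a]:
                    P[a] = d_prof[b]
                    I[a] = b
        n_extra = int(np.ceil(approx_budget * diagonals.size))
        for k in rng.choice(diagonals, size=min(n_extra, diagonals.size), replace=False):
            _update_diag(k)
    else:
        raise ValueError(f"unknown method {method!r}")

    P[degenerate & ~mask] = max_d
    I[degenerate & ~mask] = -1
    P[mask] = np.inf
    I[mask] = -1
    return MatrixProfileResult(P, I, w, method, x, mask, ez, max_d)


def _distance_profile(x, w, a, mu, sig, usable, ez, max_d):
    """z-normalised distances of window ``a`` to every usable window."""
    m = mu.size
    qa = x[a:a + w]
    q = np.convolve(x, qa[::-1], mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (q - w * mu[a] * mu) / (w * sig[a] * sig)
    d = np.sqrt(np.maximum(2.0 * w * (1.0 - np.clip(rho, -1.0, 1.0)), 0.0))
    d[~usable] = np.inf
    lo, hi = max(a - ez + 1, 0), min(a + ez, m)
    d[lo:hi] = np.inf  # trivial self-matches
    return d


@dataclass
class Motif:
    """A recurring pattern: a representative window and its matches."""

    rank: int
    representative: int
    matches: np.ndarray            # window starts incl. the representative pair
    correlations: np.ndarray       # Pearson r of each match with the representative
    profile_value: float


@dataclass
class MotifSet:
    motifs: list[Motif] = field(default_factory=list)
    discords: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    discord_values: np.ndarray = field(default_factory=lambda: np.array([]))
    window: int = 20
    corr_threshold: float = 0.98
    n_samples: int = 1


def discover_motifs(
    mp: MatrixProfileResult,
    n_motifs: int = 3,
    corr_threshold: float = 0.98,
    n_samples: int = 1,
) -> MotifSet:
    """Iteratively extract the top motifs from a matrix profile.

    The unmasked position with the smallest profile value seeds each motif;
    every window correlating at least ``corr_threshold`` with the seed
    joins it (greedy, nearest first, overlaps within the exclusion zone
    suppressed), and the matched regions are removed from further search.
    ``n_samples`` is the approximate-phase sample budget kept for interface
    parity; it does not alter the exact search.
    """
    x, w, ez = mp.series, mp.window, mp.exclusion_zone
    mu, var = _window_stats(x, w)
    sig = np.sqrt(var)
    usable = mp.valid & (var >= _NEAR_CONSTANT_VAR)
    work = np.where(usable & (mp.profile < mp.max_distance), mp.profile, np.inf)
    motifs: list[Motif] = []
    for rank in range(n_motifs):
        if not np.isfinite(work).any():
            warnings.warn(f"only {rank} non-trivial motifs found", RuntimeWarning,
                          stacklevel=2)
            break
        seed_pos = int(np.argmin(work))
        d_prof = _distance_profile(x, w, seed_pos, mu, sig,
                                   usable & np.isfinite(work), ez, mp.max_distance)
        d_limit = np.sqrt(2.0 * w * (1.0 - corr_threshold))
        cand = np.flatnonzero(d_prof <= d_limit)
        order = cand[np.argsort(d_prof[cand])]
        picked = [seed_pos]
        for c in order:
            if all(abs(c - q) >= ez for q in picked):
                picked.append(int(c))
        picked_arr = np.array(sorted(picked))
        corrs = np.array([
            1.0 if p == seed_pos else
            1.0 - _pair_distance(x, w, seed_pos, p, mu, sig, mp.max_distance) ** 2 / (2 * w)
            for p in picked_arr
        ])
        motifs.append(Motif(rank + 1, seed_pos, picked_arr, corrs,
                            float(mp.profile[seed_pos])))
        for p in picked_arr:  # suppress this motif's neighbourhood
            lo, hi = max(p - ez + 1, 0), min(p + ez, work.size)
            work[lo:hi] = np.inf
    return MotifSet(motifs, window=w, corr_threshold=corr_threshold,
                    n_samples=n_samples)


def discover_discords(mp: MatrixProfileResult, n_discords: int = 3) -> MotifSet:
    """Ranked discords: largest finite profile values, mutually separated
    by at least the exclusion zone; variance-floored positions (the
    max-distance sentinel) are not reported."""
    work = np.where(mp.valid & (mp.profile < mp.max_distance), mp.profile, -np.inf)
    positions, values = [], []
    for _ in range(n_discords):
        if not np.isfinite(work).any() or np.all(work == -np.inf):
            break
        pos = int(np.argmax(work))
        positions.append(pos)
        values.append(float(work[pos]))
        lo, hi = max(pos - mp.exclusion_zone + 1, 0), min(pos + mp.exclusion_zone, work.size)
        work[lo:hi] = -np.inf
    ms = MotifSet(window=mp.window)
    ms.discords = np.array(positions, dtype=int)
    ms.discord_values = np.array(values)
    return ms


def motif_location_distribution(
    motifs: MotifSet,
    concat: ConcatSeries,
    groups: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group distributions of motif match locations, with U-tests.

    Match start positions are mapped through the provenance table to
    (group, particle, common-zero start time). Returns ``(locations,
    tests)``: one row per match, and one row per (motif, group pair) with
    the two-sided Mann-Whitney p-value on the match start times. Groups
    without matches for a motif are excluded from its tests and reported
    with a warning.
    """
    rows = []
    for motif in motifs.motifs:
        for pos in motif.matches:
            g, p, t = concat.locate(int(pos))
            rows.append({"motif": motif.rank, "group_id": g, "particle_id": p,
                         "start_time_min": t, "position": int(pos)})
    locations = pd.DataFrame(rows)
    tests = []
    if not locations.empty:
        all_groups = groups or sorted(locations["group_id"].unique())
        for motif_id, sub in locations.groupby("motif"):
            present = [g for g in all_groups if (sub["group_id"] == g).any()]
            absent = set(all_groups) - set(present)
            if absent:
                warnings.warn(
                    f"motif {motif_id}: no matches in group(s) {sorted(absent)}",
                    RuntimeWarning, stacklevel=2,
                )
            for a_i in range(len(present)):
                for b_i in range(a_i + 1, len(present)):
                    ga, gb = present[a_i], present[b_i]
                    ta = sub.loc[sub["group_id"] == ga, "start_time_min"].to_numpy()
                    tb = sub.loc[sub["group_id"] == gb, "start_time_min"].to_numpy()
                    if np.array_equal(np.sort(ta), np.sort(tb)):
                        p = 1.0
                    else:
                        p = float(sps.mannwhitneyu(ta, tb, alternative="two-sided").pvalue)
                    tests.append({"motif": motif_id, "group_a": ga, "group_b": gb,
                                  "p_value": p, "n_a": ta.size, "n_b": tb.size})
    return locations, pd.DataFrame(tests)
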