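"""Synthetic piecewise trajectories with known behavioural ground truth.

Tracks are built from four behavioural stages (labelled A-D), each a
Gaussian random walk plus a sinusoid with per-segment random period,
amplitude and phase, optionally damped by the reciprocal of (segment-local)
time. Two orderings of the same stages define the Type I and Type II
groups: Type II swaps the first two stages, so stage-order-sensitive
methods can be benchmarked against ensemble summaries that match by
construction.

The per-stage random draws are keyed by (master seed, track index, stage
label), not by play order, so a Type I track and its Type II counterpart
share walk increments and sinusoid parameters exactly and differ only in
stage order. ``share_draws=False`` decouples the two groups (independent
draws), which is what a null/calibration experiment needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentSpec",
    "SyntheticConfig",
    "TrackTruth",
    "default_segment_specs",
    "generate_track",
    "generate_dataset",
    "generate_coupled_covariates",
]


@dataclass(frozen=True)
class SegmentSpec:
    """One behavioural stage of the piecewise generator.

    duration is in time steps; period_range in minutes; amplitude and the
    walk step standard deviation in arbitrary distance units. ``decay``
    damps the sinusoid by 1/(1 + k*dt) with k counted from segment start.
    """

    label: str
    duration: int
    period_range: tuple[float, float]
    amplitude_range: tuple[float, float]
    walk_sd: float
    decay: bool = False

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("segment duration must be >= 1")
        for name, (lo, hi) in (("period_range", self.period_range),
                               ("amplitude_range", self.amplitude_range)):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive with min <= max")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be >= 0")


def default_segment_specs() -> tuple[SegmentSpec, ...]:
    """Default stages emulating wild-type-like meiotic prophase movement.

    A: fast, high-amplitude oscillation (early horsetail, ~6 min period);
    B: slower, lower-amplitude oscillation (~10 min period);
    C: decaying oscillation (transition out of horsetail);
    D: near-pure low-sd walk (confined/Brownian, post-horsetail-like).
    """
    return (
        SegmentSpec("A", 50, (5.0, 7.0), (2.0, 3.0), 0.15),
        SegmentSpec("B", 50, (8.0, 12.0), (1.0, 1.5), 0.15),
        SegmentSpec("C", 40, (6.0, 10.0), (1.0, 2.0), 0.15, decay=True),
        SegmentSpec("D", 40, (8.0, 12.0), (0.01, 0.02), 0.10),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator specification for a Type I/II dataset."""

    n_timepoints: int = 180
    dt: float = 1.0
    segment_specs: tuple[SegmentSpec, ...] = field(default_factory=default_segment_specs)
    order_type_I: tuple[str, ...] = ("A", "B", "C", "D")
    order_type_II: tuple[str, ...] = ("B", "A", "C", "D")
    n_tracks_per_type: int = 200
    seed: int = 0
    y_walk_sd: float = 0.05
    share_draws: bool = True

    def __post_init__(self) -> None:
        labels = {s.label for s in self.segment_specs}
        for order in (self.order_type_I, self.order_type_II):
            if set(order) != labels:
                raise ValueError("segment order must use exactly the configured labels")
        if len(self.order_type_I) >= 2:
            swapped = list(self.order_type_I)
            swapped[0], swapped[1] = swapped[1], swapped[0]
            if self.order_type_II not in (tuple(swapped), self.order_type_I):
                raise ValueError(
                    "order_type_II must equal order_type_I with the first two stages exchanged"
                )
        if sum(s.duration for s in self.segment_specs) != self.n_timepoints:
            raise ValueError("segment durations must sum to n_timepoints")

    def spec_for(self, label: str) -> SegmentSpec:
        return next(s for s in self.segment_specs if s.label == label)

    def order_for(self, type_: str) -> tuple[str, ...]:
        if type_ in ("I", "TypeI"):
            return self.order_type_I
        if type_ in ("II", "TypeII"):
            return self.order_type_II
        raise ValueError(f"unknown type {type_!r}")


@dataclass
class TrackTruth:
    """Ground truth emitted alongside one generated track."""

    group_id: str
    particle_id: str
    labels: tuple[str, ...]            # stage labels in play order
    boundaries: tuple[int, ...]        # start index of each stage, plus n at the end
    draws: dict                        # per-label {period, amplitude, phase}

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "particle_id": self.particle_id,
            "labels": list(self.labels),
            "boundaries": list(self.boundaries),
            "draws": {k: dict(v) for k, v in self.draws.items()},
        }


def _label_stream(master_seed: int, track_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([master_seed & 0x7FFFFFFF, track_seed, ord(label)])


def generate_track(
    config: SyntheticConfig,
    type_: str = "I",
    track_seed: int = 0,
    group_id: str | None = None,
    particle_id: str | None = None,
) -> tuple[pd.DataFrame, TrackTruth]:
    """Generate one synthetic track and its ground truth.

    Within a stage starting at step t0 with base value b (the previous
    stage's final value), x(t0+k) = b + W(k) + osc(k) − osc(0), where W is
    the cumulative Gaussian walk and osc(k) = Amp·sin(2π k·dt/P + φ)·g(k)
    with g(k) = 1/(1+k·dt) when decay is on. Subtracting osc(0) makes the
    trajectory continuous at joins for any phase. Draws come from
    per-(track, label) seeded streams so the same track index yields the
    same stage content in both orderings.
    """
    order = config.order_for(type_)
    is_type_II = type_ in ("II", "TypeII")
    group_id = group_id or ("TypeII" if is_type_II else "TypeI")
    particle_id = particle_id or f"track{track_seed:04d}"

    draw_salt = 1_000_003 if (is_type_II and not config.share_draws) else 0
    x = np.empty(config.n_timepoints)
    base = 0.0
    pos = 0
    boundaries = [0]
    draws: dict[str, dict] = {}
    for label in order:
        spec = config.spec_for(label)
        rng = _label_stream(config.seed, track_seed + draw_salt, label)
        period = rng.uniform(*spec.period_range)
        amp = rng.uniform(*spec.amplitude_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        incr = rng.normal(0.0, spec.walk_sd, spec.duration - 1)
        k = np.arange(spec.duration)
        walk = np.concatenate([[0.0], np.cumsum(incr)])
        gain = 1.0 / (1.0 + k * config.dt) if spec.decay else np.ones_like(k, dtype=float)
        osc = amp * np.sin(2.0 * np.pi * k * config.dt / period + phase) * gain
        seg = base + walk + osc - osc[0]
        x[pos:pos + spec.duration] = seg
        base = seg[-1]
        pos += spec.duration
        boundaries.append(pos)
        draws[label] = {"period": float(period), "amplitude": float(amp),
                        "phase": float(phase)}

    rng_y = _label_stream(config.seed, track_seed + draw_salt, "y")
    y = np.concatenate([[0.0], np.cumsum(rng_y.normal(0.0, config.y_walk_sd,
                                                      config.n_timepoints - 1))])
    table = pd.DataFrame({
        "group_id": group_id,
        "particle_id": particle_id,
        "time_min": np.arange(config.n_timepoints) * config.dt,
        "x": x,
        "y": y,
    })
    truth = TrackTruth(group_id, particle_id, tuple(order), tuple(boundaries), draws)
    return table, truth


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, list[TrackTruth]]:
    """Generate ``n_tracks_per_type`` tracks for each of TypeI and TypeII.

    Per-track seeds are the track indices; reproducibility and the Type I/II
    draw-sharing property both follow from the (seed, index, label) keying.
    """
    frames: list[pd.DataFrame] = []
    truths: list[TrackTruth] = []
    for type_ in ("I", "II"):
        for idx in range(config.n_tracks_per_type):
            tab, truth = generate_track(config, type_, track_seed=idx)
            frames.append(tab)
            truths.append(truth)
    return pd.concat(frames, ignore_index=True), truths


def generate_coupled_covariates(
    table: pd.DataFrame,
    lag: int = 5,
    coupling: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    source: str = "linear_velocity",
    name: str = "coupled",
) -> tuple[pd.DataFrame, dict]:
    """Add a channel m(t) = coupling·v(t−lag) + N(0, noise_sd²) per particle.

    ``v`` is the ``source`` descriptor (linear velocity by default, derived
    on the fly when absent). For t < lag, and wherever v(t−lag) is
    undefined, m is pure noise. Returns the augmented table and the
    ground-truth edge metadata (source → name at the given lag).
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if source not in table.columns:
        from .io import derive_velocities

        table = derive_velocities(table)
    out = table.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    values = np.empty(len(out))
    for (_, _), sub in out.groupby(["group_id", "particle_id"], sort=True, observed=True):
        v = sub[source].to_numpy(dtype=float)
        n = len(v)
        if lag >= n:
            raise ValueError(f"lag {lag} >= track length {n}")
        shifted = np.full(n, np.nan)
        if lag == 0:
            shifted[:] = v
        else:
            shifted[lag:] = v[:-lag]
        m = coupling * np.nan_to_num(shifted, nan=0.0)
        m = m + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
        pos = out.index.get_indexer(sub.index)
        values[pos] = m
    out[name] = values
    truth = {"source": source, "target": name, "lag": int(lag),
             "coupling": float(coupling), "noise_sd": float(noise_sd)}
    return out, truth


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """A copy of ``config`` in which the two groups are exchangeable:

    identical stage order and independent draws, so any between-group test
    should reject at about its nominal level.
    """
    return replace(config, order_type_II=config.order_type_I, share_draws=False)


__all__.append("null_config")
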