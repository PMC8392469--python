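"""Reading, validation and normalisation of particle-track tables.

A track table is a long-format :class:`pandas.DataFrame` with one row per
(group, particle, frame). The canonical columns are ``group_id``,
``particle_id``, ``time_min``, ``x``, ``y``; any further numeric columns
(area, circularity, convexity, major/minor axis, derived velocities, ...)
are carried along as descriptors.

All functions here return new frames sorted by (group, particle, time) and
never mutate their input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ["group_id", "particle_id", "time_min", "x", "y"]

__all__ = [
    "CANONICAL_COLUMNS",
    "NormalizationSpec",
    "TrackValidationError",
    "read_tracks",
    "validate_tracks",
    "write_tracks",
    "align_time",
    "rotate_to_principal_axis",
    "derive_velocities",
    "normalize_values",
    "descriptor_columns",
    "iter_tracks",
]


class TrackValidationError(ValueError):
    """Raised when a track table violates a structural invariant."""


@dataclass
class NormalizationSpec:
    """How to standardise a dataset before analysis.

    value_method : {'none', 'minmax01', 'zscore'}
        Column-wise value normalisation, applied per dataset (pooled across
        groups) unless ``per_particle`` is set.
    time_zero_mode : {'first_common_zero', 'last_common_zero'}
        Whether tracks start at 0 or end at 0 after time alignment.
    rotate_axes : bool
        Rotate each track so its principal axis of positional variance lies
        along x.
    """

    value_method: str = "none"
    time_zero_mode: str = "last_common_zero"
    rotate_axes: bool = False
    per_particle: bool = False

    def __post_init__(self) -> None:
        if self.value_method not in {"none", "minmax01", "zscore"}:
            raise ValueError(f"unknown value_method {self.value_method!r}")
        if self.time_zero_mode not in {"first_common_zero", "last_common_zero"}:
            raise ValueError(f"unknown time_zero_mode {self.time_zero_mode!r}")


def descriptor_columns(table: pd.DataFrame) -> list[str]:
    """Names of the non-canonical (descriptor) columns of ``table``."""
    return [c for c in table.columns if c not in CANONICAL_COLUMNS]


def iter_tracks(table: pd.DataFrame):
    """Yield ``((group_id, particle_id), sub-frame)`` per particle, in order."""
    yield from table.groupby(["group_id", "particle_id"], sort=True, observed=True)


def validate_tracks(table: pd.DataFrame, *, allow_missing: Iterable[str] = ()) -> pd.DataFrame:
    """Validate and canonically sort a track table.

    Checks the structural invariants: required columns present, numeric
    fields finite (columns listed in ``allow_missing`` may contain NaN,
    e.g. edge-undefined velocities), unique and strictly increasing time
    within each particle. Returns a sorted copy.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrackValidationError(f"missing required column(s): {', '.join(missing)}")
    table = table.copy()
    allow_missing = set(allow_missing)
    num_cols = ["time_min", "x", "y"] + descriptor_columns(table)
    for col in num_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any() and col not in allow_missing:
            rows = table.index[bad][:5].tolist()
            raise TrackValidationError(
                f"non-finite values in column {col!r} at rows {rows}"
                " (rows are rejected, not dropped; clean the input)"
            )
        table[col] = values
    table = table.sort_values(["group_id", "particle_id", "time_min"], kind="mergesort")
    dup = table.duplicated(["group_id", "particle_id", "time_min"])
    if dup.any():
        g, p, t = table.loc[dup.idxmax(), ["group_id", "particle_id", "time_min"]]
        raise TrackValidationError(
            f"duplicated (group, particle, time) record: ({g!r}, {p!r}, t={t})"
        )
    for (g, p), sub in iter_tracks(table):
        if not np.all(np.diff(sub["time_min"].to_numpy()) > 0):
            raise TrackValidationError(
                f"time not strictly increasing within particle {p!r} of group {g!r}"
            )
    return table.reset_index(drop=True)


def read_tracks(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read a CSV/TSV/XLSX track file into a validated canonical table.

    ``column_map`` maps canonical names (``group_id``, ``particle_id``,
    ``time_min``, ``x``, ``y``, plus optional descriptors) to the column
    names used in the file. Unmapped file columns are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv",
                  ".xlsx": "xlsx", ".xls": "xlsx"}.get(path.suffix.lower(), "csv")
    if format == "csv":
        raw = pd.read_csv(path)
    elif format == "tsv":
        raw = pd.read_csv(path, sep="\t")
    elif format == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unsupported format {format!r}")
    if column_map:
        absent = [src for src in column_map.values() if src not in raw.columns]
        if absent:
            raise TrackValidationError(
                f"mapped column(s) not found in {path.name}: {', '.join(absent)}"
            )
        raw = raw[[*column_map.values()]].rename(
            columns={src: dst for dst, src in column_map.items()}
        )
    ordered = [c for c in CANONICAL_COLUMNS if c in raw.columns]
    ordered += [c for c in raw.columns if c not in ordered]
    return validate_tracks(raw[ordered])


def write_tracks(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a track table as canonical long-format CSV (fixed column order)."""
    path = Path(path)
    cols = CANONICAL_COLUMNS + descriptor_columns(table)
    table[cols].to_csv(path, index=False)
    return path


def align_time(table: pd.DataFrame, mode: str = "last_common_zero") -> pd.DataFrame:
    """Shift each particle's clock to a common zero.

    ``last_common_zero`` subtracts the per-track maximum, so every track ends
    at 0 with negative times (the meiosis-I-onset convention);
    ``first_common_zero`` subtracts the minimum, so tracks start at 0.
    """
    if mode not in {"first_common_zero", "last_common_zero"}:
        raise ValueError(f"unknown time_zero_mode {mode!r}")
    table = table.copy()
    grp = table.groupby(["group_id", "particle_id"], observed=True)["time_min"]
    ref = grp.transform("max" if mode == "last_common_zero" else "min")
    table["time_min"] = table["time_min"] - ref
    return table


def rotate_to_principal_axis(table: pd.DataFrame) -> pd.DataFrame:
    """Rotate each track so its direction of maximal variance lies along x.

    Coordinates are centred on the per-track mean, then rotated (a rigid,
    det=+1 transform) so the leading eigenvector of the positional
    covariance maps to the x axis; the sign is fixed so the first nonzero
    displacement has non-negative x. Degenerate tracks (all positions
    identical) are returned unchanged with a warning.
    """
    table = table.copy()
    for (g, p), sub in iter_tracks(table):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        centred = xy - xy.mean(axis=0)
        cov = np.cov(centred.T) if len(xy) > 1 else np.zeros((2, 2))
        if np.allclose(cov, 0):
            warnings.warn(
                f"degenerate track ({g!r}, {p!r}): all positions identical; left unrotated",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        major = evecs[:, np.argmax(evals)]
        rot = np.array([[major[0], major[1]], [-major[1], major[0]]])  # maps major -> e_x
        new = centred @ rot.T
        disp = np.diff(new, axis=0)
        nz = np.flatnonzero(np.linalg.norm(disp, axis=1) > 0)
        if nz.size and disp[nz[0], 0] < 0:
            new = -new  # rotate by pi, still det +1
        table.loc[sub.index, ["x", "y"]] = new
    return table


def derive_velocities(table: pd.DataFrame, dt: float | None = None) -> pd.DataFrame:
    """Add ``linear_velocity`` and ``angular_velocity`` descriptor columns.

    linear_velocity(t) = |r(t+dt) − r(t)| / dt.  The heading is the angle of
    the displacement vector; angular_velocity(t) is the wrapped heading
    difference across one step, in (−pi, pi] radians per minute, signed.
    Zero-displacement frames keep the previous heading (no turn). Velocities
    undefined at the track edge are NaN, never zero-filled.
    """
    table = table.reset_index(drop=True)
    lin = np.full(len(table), np.nan)
    ang = np.full(len(table), np.nan)
    for (g, p), sub in iter_tracks(table):
        t = sub["time_min"].to_numpy(dtype=float)
        if len(t) < 2:
            continue
        steps = np.diff(t)
        dt_track = steps[0] if dt is None else dt
        if not np.allclose(steps, dt_track, rtol=1e-6, atol=1e-9):
            bad = np.flatnonzero(~np.isclose(steps, dt_track, rtol=1e-6, atol=1e-9))
            gaps = [(t[i], t[i + 1]) for i in bad[:5]]
            raise TrackValidationError(
                f"non-uniform sampling for particle {p!r} of group {g!r}; gaps at {gaps}"
            )
        d = np.diff(sub[["x", "y"]].to_numpy(dtype=float), axis=0)
        speed = np.linalg.norm(d, axis=1) / dt_track
        heading = np.arctan2(d[:, 1], d[:, 0])
        still = speed == 0
        if still.any():  # carry previous heading across zero-displacement frames
            idx = np.arange(len(heading))
            valid = ~still
            if valid.any():
                last = np.maximum.accumulate(np.where(valid, idx, -1))
                first_valid = idx[valid][0]
                filled = np.where(last >= 0, heading[np.maximum(last, 0)], heading[first_valid])
                heading = filled
            else:
                heading = np.zeros_like(heading)
        dtheta = np.diff(heading)
        dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
        dtheta[dtheta == -np.pi] = np.pi  # wrap into (-pi, pi]
        pos = table.index.get_indexer(sub.index)
        lin[pos[:-1]] = speed
        ang[pos[:-2]] = dtheta / dt_track
    table["linear_velocity"] = lin
    table["angular_velocity"] = ang
    return table


def normalize_values(
    table: pd.DataFrame,
    method: str = "minmax01",
    columns: Iterable[str] | None = None,
    per_particle: bool = False,
) -> pd.DataFrame:
    """Normalise selected numeric columns, pooled across groups by default.

    ``minmax01`` maps to [0, 1]; ``zscore`` to mean 0, sd 1. Constant
    columns trigger a warning and map to all-zero (no NaN propagation).
    """
    if method == "none":
        return table.copy()
    if method not in {"minmax01", "zscore"}:
        raise ValueError(f"unknown value_method {method!r}")
    table = table.copy()
    if columns is None:
        columns = ["x", "y"] + descriptor_columns(table)

    def _norm(values: pd.Series) -> pd.Series:
        v = values.to_numpy(dtype=float)
        if method == "minmax01":
            lo, hi = np.nanmin(v), np.nanmax(v)
            span = hi - lo
            if span == 0:
                warnings.warn(
                    f"constant column {values.name!r}: min-max normalisation degenerate, set to 0",
                    RuntimeWarning, stacklevel=3,
                )
                return pd.Series(np.zeros_like(v), index=values.index)
            return pd.Series((v - lo) / span, index=values.index)
        mu, sd = np.nanmean(v), np.nanstd(v)
        if sd == 0:
            warnings.warn(
                f"constant column {values.name!r}: z-score normalisation degenerate, set to 0",
                RuntimeWarning, stacklevel=3,
            )
            return pd.Series(np.zeros_like(v), index=values.index)
        return pd.Series((v - mu) / sd, index=values.index)

    for col in columns:
        if per_particle:
            table[col] = (
                table.groupby(["group_id", "particle_id"], observed=True, group_keys=False)[col]
                .apply(_norm)
            )
        else:
            table[col] = _norm(table[col])
    return table


def apply_normalization(table: pd.DataFrame, spec: NormalizationSpec) -> pd.DataFrame:
    """Apply a full :class:`NormalizationSpec`: time zero, rotation, values."""
    out = align_time(table, spec.time_zero_mode)
    if spec.rotate_axes:
        out = rotate_to_principal_axis(out)
    if spec.value_method != "none":
        out = normalize_values(out, spec.value_method, per_particle=spec.per_particle)
    return out


__all__.append("apply_normalization")
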