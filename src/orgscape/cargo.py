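"""Endocytic cargo analysis: positivity thresholds, filters, time courses.

Cargo positivity (EGF / transferrin) is defined against untreated control
particles: the threshold is the 99th percentile of the control intensity
distribution, so ~1% of pure background exceeds it by construction.
Particles missing any required endosomal marker (RAB5 / RAB7 / RAB11 zero)
are removed, the surviving cargo-positive particles are tallied per
(condition, timepoint, cluster, cargo), and display scaling uses the square
root of percent-of-maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ParticleTable

__all__ = [
    "CargoThresholds",
    "background_threshold",
    "filter_cargo_particles",
    "cluster_proportions",
    "sqrt_percent_max",
]

DEFAULT_CARGO_CHANNELS = ("EGF", "TF")
DEFAULT_REQUIRED_NONZERO = ("RAB5", "RAB7", "RAB11")


class CargoError(ValueError):
    pass


@dataclass
class CargoThresholds:
    """Per-cargo positivity thresholds derived from control particles."""

    thresholds: dict[str, float]  # cargo channel -> intensity threshold
    percentile: float
    control_n: dict[str, int]

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise CargoError("percentile must lie in (0, 100)")
        if any(t < 0 for t in self.thresholds.values()):
            raise CargoError("thresholds must be >= 0")


def background_threshold(
    control_intensities: dict[str, np.ndarray] | np.ndarray,
    percentile: float = 99.0,
) -> CargoThresholds:
    """Empirical percentile threshold from untreated-control intensities.

    Uses linear interpolation between order statistics (the common "type 7"
    percentile), e.g. values 1..100 at the 99th percentile give 99.01.
    Accepts either a single array (threshold keyed ``"cargo"``) or a mapping
    of cargo channel name to control values.  Requires >= 100 control
    values per channel.
    """
    if not isinstance(control_intensities, dict):
        control_intensities = {"cargo": np.asarray(control_intensities)}
    thresholds, ns = {}, {}
    for name, vals in control_intensities.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise CargoError(f"empty control sample for {name!r}")
        if vals.size < 100:
            raise CargoError(
                f"need >= 100 control values for {name!r}, got {vals.size}"
            )
        thresholds[name] = float(
            np.percentile(vals, percentile, method="linear")
        )
        ns[name] = int(vals.size)
    return CargoThresholds(thresholds=thresholds, percentile=percentile, control_n=ns)


def filter_cargo_particles(
    table: ParticleTable,
    thresholds: CargoThresholds,
    required_nonzero: tuple[str, ...] = DEFAULT_REQUIRED_NONZERO,
    mode: str = "mean",
) -> ParticleTable:
    """Keep particles with all required markers > 0 and at least one cargo
    channel above its positivity threshold.

    ``mode`` selects the intensity the thresholds are compared against:
    ``"mean"`` (summed intensity / area, the default) or ``"sum"``; use the
    mode the control sample was thresholded on.  Per-cargo positivity flags
    are recorded as ``<cargo>_positive`` columns.  Idempotent.
    """
    if mode not in ("mean", "sum"):
        raise CargoError(f"mode must be 'mean' or 'sum', got {mode!r}")
    df = table.data
    missing = [c for c in thresholds.thresholds if c not in df.columns]
    if missing:
        raise CargoError(f"missing cargo columns: {missing}")
    for m in required_nonzero:
        if m not in df.columns:
            raise CargoError(f"missing required marker column: {m}")

    if mode == "mean" and "area" not in df.columns:
        raise CargoError("mode='mean' needs an area column")
    keep = np.ones(len(df), dtype=bool)
    for m in required_nonzero:
        keep &= df[m].to_numpy(dtype=float) > 0
    any_pos = np.zeros(len(df), dtype=bool)
    flags = {}
    for cargo, thr in thresholds.thresholds.items():
        vals = df[cargo].to_numpy(dtype=float)
        if mode == "mean":
            vals = vals / df["area"].to_numpy(dtype=float)
        pos = vals >= thr
        flags[f"{cargo}_positive"] = pos
        any_pos |= pos
    keep &= any_pos
    out = df.loc[keep].copy()
    for col, pos in flags.items():
        out[col] = pos[keep]
    return ParticleTable(out.reset_index(drop=True), list(table.markers))


def cluster_proportions(
    table: ParticleTable,
    cargo_channels: tuple[str, ...] = DEFAULT_CARGO_CHANNELS,
    by: tuple[str, ...] = ("condition", "timepoint"),
) -> pd.DataFrame:
    """Per-cluster counts and proportions of cargo-positive particles.

    For each cargo channel and each combination of ``by`` columns, counts
    the positive particles per cluster and the cluster's share of all
    positives in that group.  Proportions sum to 1 within every group that
    has at least one positive particle; a group/cluster with no positives
    appears with count 0 and proportion NaN.

    The table must carry ``cluster`` labels (e.g. from the landscape
    pipeline or query mapping) and ``<cargo>_positive`` flags (from
    :func:`filter_cargo_particles`).
    """
    df = table.data
    if "cluster" not in df.columns:
        raise CargoError("particles are unlabeled: no cluster column")
    if df["cluster"].isna().any():
        raise CargoError("some particles have no cluster label")
    group_cols = [c for c in by if c in df.columns]
    clusters = np.sort(df["cluster"].unique())

    records = []
    keys = df.groupby(list(group_cols)).groups.keys() if group_cols else [()]
    for key in keys:
        if group_cols:
            key_t = key if isinstance(key, tuple) else (key,)
            sel = np.ones(len(df), dtype=bool)
            for c, v in zip(group_cols, key_t):
                sel &= (df[c] == v).to_numpy()
        else:
            key_t = ()
            sel = np.ones(len(df), dtype=bool)
        for cargo in cargo_channels:
            flag_col = f"{cargo}_positive"
            if flag_col not in df.columns:
                raise CargoError(f"missing positivity flags: {flag_col}")
            pos = sel & df[flag_col].to_numpy(dtype=bool)
            total = int(pos.sum())
            for cl in clusters:
                cnt = int((pos & (df["cluster"] == cl).to_numpy()).sum())
                records.append(
                    dict(zip(group_cols, key_t))
                    | {
                        "cargo": cargo,
                        "cluster": cl,
                        "count": cnt,
                        "proportion": cnt / total if total else np.nan,
                    }
                )
    return pd.DataFrame.from_records(records)


def sqrt_percent_max(values: np.ndarray) -> np.ndarray:
    """Display scaling: ``sqrt(100 * v / max(v))``; the maximum maps to 10.

    All-zero input maps to all zeros (no division by zero); negative values
    are invalid.
    """
    values = np.asarray(values, dtype=float)
    if values.size and values.min() < 0:
        raise CargoError("values must be >= 0")
    m = values.max() if values.size else 0.0
    if m == 0:
        return np.zeros_like(values)
    return np.sqrt(100.0 * values / m)
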