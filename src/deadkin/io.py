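"""Tabular and figure I/O.

TimeCourse matrices travel as TSV with a ``position`` first column
(species index 1..N+1) and one column per reaction time, headed by the
time in minutes.  Rate profiles travel as TSV with ``position``,
``lambda`` and ``se`` columns.  Heatmaps follow the assay figures:
species on the vertical axis with position 1 at the top, time on the
horizontal axis, viridis colormap, column-normalized input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .densitometry import LaneProfile, normalize_columns
from .kinetics import RateProfile, TimeCourseMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_rates",
    "write_rates",
    "read_lane_profile",
    "write_lane_profile",
    "plot_heatmap",
    "write_report",
]


def write_matrix(tc: TimeCourseMatrix, path) -> None:
    tc.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(path, normalized: str | None = None) -> TimeCourseMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    if "position" not in df.columns:
        raise ValueError(f"{path}: missing 'position' column")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row "
                f"{row + 2}, column {col!r}"
            )
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna())[0])
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
    if (df.drop(columns="position").to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative intensity values")
    if df["position"].duplicated().any():
        dup = df["position"][df["position"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate position {dup}")
    return TimeCourseMatrix.from_frame(df, normalized=normalized)


def write_rates(rates: RateProfile, path) -> None:
    rates.to_frame().to_csv(path, sep="\t", index=False)


def read_rates(path) -> RateProfile:
    df = pd.read_csv(path, sep="\t")
    if not {"position", "lambda"} <= set(df.columns):
        raise ValueError(f"{path}: need 'position' and 'lambda' columns")
    return RateProfile.from_frame(df)


def write_lane_profile(profile: LaneProfile, path) -> None:
    pd.DataFrame(
        {"row": np.arange(len(profile)), "intensity": profile.intensity}
    ).to_csv(path, index=False)


def read_lane_profile(path) -> LaneProfile:
    df = pd.read_csv(path)
    if "intensity" not in df.columns:
        raise ValueError(f"{path}: need an 'intensity' column")
    if "row" in df.columns:
        df = df.sort_values("row")
    return LaneProfile(df["intensity"].to_numpy(dtype=float))


def plot_heatmap(tc: TimeCourseMatrix, path, figsize=(4.0, 5.0), dpi=150):
    """Species x time heatmap, viridis, position 1 at the top.

    Input is expected column-normalized; anything else is normalized on
    the fly with a notice.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if tc.normalized != "columns":
        import warnings

        warnings.warn("input not column-normalized; normalizing for display", stacklevel=2)
        tc = normalize_columns(tc)
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    im = ax.imshow(
        tc.values, aspect="auto", cmap="viridis", origin="upper",
        interpolation="nearest", vmin=0.0, vmax=1.0,
    )
    ax.set_xticks(np.arange(tc.n_times), [f"{t:g}" for t in tc.times])
    step = max(1, tc.n_species // 11)
    ax.set_yticks(np.arange(0, tc.n_species, step), tc.species[::step])
    ax.set_xlabel("time (min)")
    ax.set_ylabel("position from the 3' end")
    fig.colorbar(im, ax=ax, label="relative intensity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def write_report(data: dict, path) -> None:
    """JSON report with numpy types coerced to plain Python."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(data, indent=2, default=default) + "\n")
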