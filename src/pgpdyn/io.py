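"""CSV readers/writers for event samples, growth curves and trajectories.

All outputs are comma-separated UTF-8 with a mandatory header row and
``#``-prefixed comment headers embedding the package version, the
parameter-set checksum and the seed, so every file is traceable to the
run that produced it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import ActivityGrid
from .params import ProcessParameters
from .solver import Trajectory
from .synth import EventSample, GrowthCurve

__all__ = [
    "write_events",
    "read_events",
    "write_growth_curve",
    "read_growth_curve",
    "write_trajectory_long",
    "write_trajectory_summary",
]

EVENT_COLUMNS = ["event_id", "activity", "label", "condition"]


def _header(meta: dict[str, object]) -> str:
    lines = [f"# pgpdyn v{__version__}"]
    lines += [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def _read_meta(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_events(
    sample: EventSample,
    path: str | Path,
    params: ProcessParameters | None = None,
    grid: ActivityGrid | None = None,
) -> None:
    """Write an event sample as CSV (columns event_id, activity, label, condition)."""
    grid = grid or ActivityGrid()
    meta: dict[str, object] = {
        "seed": sample.seed,
        "condition": sample.condition,
        "x_min": grid.x_min,
        "x_max": grid.x_max,
    }
    if params is not None:
        meta["params_sha256"] = params.checksum()
    frame = pd.DataFrame(
        {
            "event_id": np.arange(sample.n_events),
            "activity": sample.activities,
            "label": sample.labels,
            "condition": sample.condition,
        }
    )
    buf = _io.StringIO()
    frame.to_csv(buf, index=False)
    Path(path).write_text(_header(meta) + buf.getvalue())


def read_events(path: str | Path) -> EventSample:
    """Read an event-sample CSV; round-trips :func:`write_events` exactly.

    Malformed rows and out-of-range activities raise errors naming the
    offending row numbers (0-based within the data section).
    """
    meta = _read_meta(path)
    frame = pd.read_csv(path, comment="#", dtype={"condition": str})
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    activity = pd.to_numeric(frame["activity"], errors="coerce")
    bad = frame.index[activity.isna()].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric activity in rows {bad[:20]}")
    x_min = float(meta.get("x_min", 0.0))
    x_max = float(meta.get("x_max", 1.0))
    out = frame.index[(activity < x_min) | (activity > x_max)].tolist()
    if out:
        raise ValueError(
            f"{path}: activity outside [{x_min}, {x_max}] in rows {out[:20]}"
        )
    labels = pd.to_numeric(frame["label"], errors="coerce")
    bad = frame.index[~labels.isin([0, 1, 2])].tolist()
    if bad:
        raise ValueError(f"{path}: invalid label in rows {bad[:20]}")
    condition = meta.get("condition", "")
    if not condition and len(frame):
        condition = str(frame["condition"].iloc[0])
        if condition == "nan":
            condition = ""
    return EventSample(
        activities=activity.to_numpy(float),
        labels=labels.to_numpy(int),
        condition=condition,
        seed=int(meta.get("seed", -1)),
    )


def write_growth_curve(
    curve: GrowthCurve, path: str | Path, params: ProcessParameters | None = None
) -> None:
    meta: dict[str, object] = {"seed": curve.seed, "dose_nM": curve.dose}
    if params is not None:
        meta["params_sha256"] = params.checksum()
    frame = pd.DataFrame(
        {"time_h": curve.times, "value": curve.values, "dose_nM": curve.dose}
    )
    buf = _io.StringIO()
    frame.to_csv(buf, index=False)
    Path(path).write_text(_header(meta) + buf.getvalue())


def read_growth_curve(path: str | Path) -> GrowthCurve:
    meta = _read_meta(path)
    frame = pd.read_csv(path, comment="#")
    for col in ("time_h", "value"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dose = float(meta.get("dose_nM", frame.get("dose_nM", pd.Series([0.0])).iloc[0]))
    return GrowthCurve(
        times=frame["time_h"].to_numpy(float),
        values=frame["value"].to_numpy(float),
        dose=dose,
        seed=int(meta.get("seed", -1)),
    )


def write_trajectory_long(
    traj: Trajectory,
    path: str | Path,
    params: ProcessParameters | None = None,
    seed: int | None = None,
) -> None:
    """Long-format density trajectory: time_h, class, x_center, density."""
    grid = traj.states[0].grid
    meta: dict[str, object] = {"seed": seed if seed is not None else -1}
    if params is not None:
        meta["params_sha256"] = params.checksum()
    chunks = []
    for t, state in zip(traj.times, traj.states):
        for idx, u in ((1, state.u1.values), (2, state.u2.values)):
            chunks.append(
                pd.DataFrame(
                    {
                        "time_h": t,
                        "class": idx,
                        "x_center": grid.centers,
                        "density": u,
                    }
                )
            )
    buf = _io.StringIO()
    pd.concat(chunks, ignore_index=True).to_csv(buf, index=False)
    Path(path).write_text(_header(meta) + buf.getvalue())


def write_trajectory_summary(
    traj: Trajectory,
    path: str | Path,
    params: ProcessParameters | None = None,
    seed: int | None = None,
) -> None:
    """Summary trajectory: time_h, N1, N2, M."""
    meta: dict[str, object] = {"seed": seed if seed is not None else -1}
    if params is not None:
        meta["params_sha256"] = params.checksum()
    frame = pd.DataFrame(
        {
            "time_h": traj.times,
            "N1": traj.totals[0],
            "N2": traj.totals[1],
            "M": traj.M_series,
        }
    )
    buf = _io.StringIO()
    frame.to_csv(buf, index=False)
    Path(path).write_text(_header(meta) + buf.getvalue())
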