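"""File I/O: TIFF stacks, CSV traces, JSON fits and schedules."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import CompartmentTrace, LightSchedule
from .result import FitResult
from .segment import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "write_fit",
    "read_flip_trace",
    "write_flip_trace",
]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-dimensional TIFF with OME-style metadata."""
    meta = {
        "axes": "TCYX",
        "channel_roles": stack.channel_roles,
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
    }
    tifffile.imwrite(
        str(path),
        np.asarray(stack.data, dtype=np.float32),
        metadata=meta,
    )


def read_stack(
    path: str | Path,
    role_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a (frames, channels, rows, cols) TIFF stack.

    Channel roles and physical metadata are taken from the embedded metadata
    when present; explicit arguments override.  Missing pixel size or frame
    interval with no override is an error.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 3:  # single channel
        data = data[:, None]
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D (TCYX) stack, got shape {data.shape}")
    roles = role_map or meta.get("channel_roles")
    if roles is None:
        raise ValueError("channel roles missing: supply role_map")
    roles = {k: int(v) for k, v in roles.items()}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = (
        frame_interval_s
        if frame_interval_s is not None
        else meta.get("frame_interval_s")
    )
    if px is None:
        raise ValueError("pixel size missing from metadata and no override given")
    if dt is None:
        raise ValueError("frame interval missing from metadata and no override given")
    return ImageStack(data, roles, float(px), float(dt))


def write_trace(path: str | Path, trace: CompartmentTrace) -> None:
    """CSV with columns time_s, lit, M, C, N, normalized (0/1)."""
    df = pd.DataFrame(
        {
            "time_s": trace.schedule.frame_times,
            "lit": trace.schedule.lit.astype(int),
            "M": trace.M,
            "C": trace.C,
            "N": trace.N,
            "normalized": int(trace.normalized),
        }
    )
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> CompartmentTrace:
    df = pd.read_csv(path)
    schedule = LightSchedule(
        df["time_s"].to_numpy(float), df["lit"].to_numpy(bool)
    )
    return CompartmentTrace(
        schedule,
        df["M"].to_numpy(float),
        df["C"].to_numpy(float),
        df["N"].to_numpy(float),
        normalized=bool(df["normalized"].iloc[0]),
    )


def write_flip_trace(path: str | Path, trace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "n": trace.n,
            "c": trace.c,
            "site": trace.bleach_site,
            "t_bleach_start_s": trace.t_bleach_start,
        }
    ).to_csv(path, index=False)


def read_flip_trace(path: str | Path):
    from .flip import FLIPTrace

    df = pd.read_csv(path)
    tb = (
        float(df["t_bleach_start_s"].iloc[0])
        if "t_bleach_start_s" in df.columns
        else float(df["time_s"].iloc[0])
    )
    return FLIPTrace(
        df["time_s"].to_numpy(float),
        df["n"].to_numpy(float),
        df["c"].to_numpy(float),
        str(df["site"].iloc[0]),
        t_bleach_start=tb,
    )


def write_fit(path: str | Path, fit: FitResult) -> None:
    Path(path).write_text(fit.to_json())


def cohort_table(fits: list[FitResult]) -> pd.DataFrame:
    """One row per cell: parameters, CI bounds, AIC and weight."""
    rows = []
    for i, f in enumerate(fits):
        row: dict[str, object] = {
            "cell": i,
            "variant": f.variant,
            "rss": f.rss,
            "aic": f.aic,
            "akaike_weight": f.akaike_weight,
            "converged": f.converged,
            "flags": ";".join(f.flags),
        }
        for name, v in f.params.items():
            row[name] = v
            lo, hi = f.conf_int[name]
            row[f"{name}_ci_lo"] = lo
            row[f"{name}_ci_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def write_schedule(path: str | Path, schedule: LightSchedule) -> None:
    Path(path).write_text(schedule.to_json())


def read_schedule(path: str | Path) -> LightSchedule:
    return LightSchedule.from_json(Path(path).read_text())
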