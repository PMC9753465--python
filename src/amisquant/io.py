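"""Calibrated TIFF/OME-TIFF reading and writing, plus CSV result export.

Stacks are written as OME-TIFF with the physical calibration
(PhysicalSizeX/Y/Z in μm, TimeIncrement in s) embedded in the metadata;
reading parses that metadata back, with explicit overrides taking
precedence.  A TIFF without any usable calibration and no override is a
format error — measurements in μm cannot proceed on uncalibrated
pixels.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .frap import FRAPTrace
from .stacks import CalibratedStack


def write_calibrated_tiff(stack: CalibratedStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with calibration metadata.

    Voxels are written bit-exactly in their current dtype; the axis
    order recorded is the stack's own (CZYX / CTYX / CTZYX).
    """
    metadata: dict = {
        "axes": stack.axes,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.z_step_um is not None:
        metadata["PhysicalSizeZ"] = stack.z_step_um
        metadata["PhysicalSizeZUnit"] = "µm"
    if stack.frame_interval_s is not None:
        metadata["TimeIncrement"] = stack.frame_interval_s
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(str(path), stack.voxels, ome=True, metadata=metadata)


def _parse_ome_calibration(ome_xml: str) -> dict:
    """Pull PhysicalSize/TimeIncrement attributes out of OME-XML."""
    out: dict = {}
    for key in ("PhysicalSizeX", "PhysicalSizeZ", "TimeIncrement"):
        m = re.search(rf'{key}="([0-9eE+.\-]+)"', ome_xml)
        if m:
            out[key] = float(m.group(1))
    names = re.findall(r'<Channel[^>]*\bName="([^"]*)"', ome_xml)
    if names:
        out["channel_names"] = tuple(names)
    return out


def read_calibrated_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> CalibratedStack:
    """Read a TIFF/OME-TIFF into a :class:`CalibratedStack`.

    Calibration is taken from the OME metadata when present; the keyword
    overrides win when given.  Missing in-plane calibration with no
    override raises :class:`~amisquant.errors.FormatError`, as does an
    axis layout this package does not model.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C")
        meta = _parse_ome_calibration(tif.ome_metadata) if tif.ome_metadata else {}

    # unlabelled axes (plain TIFF): a single extra dim is a z stack, two
    # are channel + z (channel first)
    if axes == "QYX":
        axes = "ZYX"
    elif axes == "QQYX":
        axes = "CZYX"

    px = pixel_size_um if pixel_size_um is not None else meta.get("PhysicalSizeX")
    if px is None:
        raise FormatError(
            f"{path.name}: no pixel-size calibration in metadata and no "
            "--pixel-size-um override given"
        )
    zs = z_step_um if z_step_um is not None else meta.get("PhysicalSizeZ")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("TimeIncrement")
    names = channel_names if channel_names is not None else meta.get("channel_names", ())

    # normalise the axis layout to one this package models
    if axes in ("YX",):
        data, axes = data[None, None], "CZYX"
    elif axes in ("ZYX",):
        data, axes = data[None], "CZYX"
    elif axes == "CYX":
        data, axes = data[:, None], "CZYX"
    elif axes == "ZCYX":
        data, axes = np.swapaxes(data, 0, 1), "CZYX"
    elif axes == "TYX":
        data, axes = data[None], "CTYX"
    elif axes == "TCYX":
        data, axes = np.swapaxes(data, 0, 1), "CTYX"
    elif axes == "TCZYX":
        data, axes = np.swapaxes(data, 0, 1), "CTZYX"
    elif axes in ("CZYX", "CTYX", "CTZYX"):
        pass
    else:
        raise FormatError(f"{path.name}: ambiguous or unsupported axes {axes!r}")

    return CalibratedStack(
        data,
        pixel_size_um=float(px),
        z_step_um=None if zs is None else float(zs),
        channel_names=tuple(names) if names else (),
        axes=axes,
        frame_interval_s=None if dt is None else float(dt),
    )


# ---------------------------------------------------------------------------
# FRAP trace CSV dialect: columns time_s, intensity, phase (pre|post),
# optional trace_id for files holding several traces.


def write_frap_traces_csv(traces: list[FRAPTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, (t, f) in enumerate(zip(tr.times_s, tr.intensities)):
            rows.append(
                {
                    "trace_id": tr.trace_id,
                    "time_s": t,
                    "intensity": f,
                    "phase": "pre" if i < tr.n_pre else "post",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frap_traces_csv(path: str | Path) -> list[FRAPTrace]:
    """Read one or many FRAP traces from CSV.

    Required columns: ``time_s``, ``intensity``, ``phase`` with values
    ``pre``/``post``; an optional ``trace_id`` column separates traces.
    """
    df = pd.read_csv(path)
    required = {"time_s", "intensity", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"FRAP CSV is missing columns: {sorted(missing)}")
    if "trace_id" not in df.columns:
        df = df.assign(trace_id="trace")
    bad = set(df["phase"].unique()) - {"pre", "post"}
    if bad:
        raise FormatError(f"FRAP CSV has unknown phase values: {sorted(bad)}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("time_s")
        n_pre = int((grp["phase"] == "pre").sum())
        if n_pre < 1 or n_pre >= len(grp):
            raise FormatError(f"trace {tid!r}: need pre frames followed by post frames")
        traces.append(
            FRAPTrace(
                grp["time_s"].to_numpy(float),
                grp["intensity"].to_numpy(float),
                n_pre=n_pre,
                trace_id=str(tid),
            )
        )
    return traces
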