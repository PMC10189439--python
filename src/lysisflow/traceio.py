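"""Trace and image file I/O.

Fluorometer traces travel as two-column CSV (``time_min`` or ``time_s``
plus ``rfu``); pressure traces as three-column CSV (``time_s``,
``pressure_a_mmHg``, ``pressure_b_mmHg``).  Unit suffixes in the header
are authoritative: times are converted to the package-internal
conventions (minutes for fluorescence, seconds/Pa for pressure) on
read.  Rendered histology images are written as PNG with a grayscale
side-car PNG carrying the ground-truth class map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .composition_analysis import LabelImage, render_color
from .errors import TraceFormatError
from .loop_simulator import PressureTrace
from .trace_kinetics import FluorescenceTrace
from .units import MMHG_PA

__all__ = [
    "parse_trace_csv",
    "write_fluorescence_csv",
    "write_pressure_csv",
    "write_label_image",
    "read_label_image",
    "write_report",
]


def _check_monotonic(t: np.ndarray, column: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        # +2: one for diff offset, one for the header line
        raise TraceFormatError(
            f"column {column!r} not strictly increasing at data row {int(bad[0]) + 2}"
        )


def parse_trace_csv(path: str | Path) -> FluorescenceTrace | PressureTrace:
    """Read a trace CSV, dispatching on its header.

    Returns a :class:`FluorescenceTrace` (time in min) or a
    :class:`PressureTrace` (time in s, pressures in Pa).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    cols = list(df.columns)
    if any(c.strip().replace(".", "", 1).lstrip("-").isdigit() for c in cols):
        raise TraceFormatError(f"{path} has no header row (numeric column names)")

    if "rfu" in cols:
        if "time_min" in cols:
            t = df["time_min"].to_numpy(dtype=float)
        elif "time_s" in cols:
            t = df["time_s"].to_numpy(dtype=float) / 60.0
        else:
            raise TraceFormatError(f"{path}: need a time_min or time_s column")
        _check_monotonic(t, "time")
        return FluorescenceTrace(time=t, rfu=df["rfu"].to_numpy(dtype=float))

    if {"time_s", "pressure_a_mmHg", "pressure_b_mmHg"} <= set(cols):
        t = df["time_s"].to_numpy(dtype=float)
        _check_monotonic(t, "time_s")
        return PressureTrace(
            time=t,
            pressure_a=df["pressure_a_mmHg"].to_numpy(dtype=float) * MMHG_PA,
            pressure_b=df["pressure_b_mmHg"].to_numpy(dtype=float) * MMHG_PA,
        )
    raise TraceFormatError(
        f"{path}: unrecognised header {cols}; expected time_min/time_s+rfu "
        "or time_s+pressure_a_mmHg+pressure_b_mmHg"
    )


def write_fluorescence_csv(trace: FluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.time, "rfu": trace.rfu}).to_csv(path, index=False)


def write_pressure_csv(trace: PressureTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "pressure_a_mmHg": trace.pressure_a / MMHG_PA,
            "pressure_b_mmHg": trace.pressure_b / MMHG_PA,
        }
    ).to_csv(path, index=False)


def write_label_image(image: LabelImage, path: str | Path) -> None:
    """Write rendered PNG plus ``<stem>.labels.png`` class-map side-car."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(render_color(image), mode="RGB").save(path)
    side = path.with_suffix(".labels.png")
    Image.fromarray(image.classes.astype(np.uint8), mode="L").save(side)
    meta = path.with_suffix(".meta.json")
    meta.write_text(json.dumps({"pixel_size_um": image.pixel_size}))


def read_label_image(path: str | Path) -> LabelImage:
    """Read a label image written by :func:`write_label_image`."""
    from PIL import Image

    path = Path(path)
    side = path.with_suffix(".labels.png")
    meta = path.with_suffix(".meta.json")
    if not side.exists():
        raise TraceFormatError(f"missing class-map side-car {side}")
    classes = np.asarray(Image.open(side))
    pixel_size = 20.0
    if meta.exists():
        pixel_size = float(json.loads(meta.read_text())["pixel_size_um"])
    return LabelImage(classes=classes, pixel_size=pixel_size)


def write_report(report: dict, path: str | Path | None) -> str:
    """Serialise an analysis report to JSON (file or returned string)."""
    text = json.dumps(report, indent=2, sort_keys=True, default=float)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
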