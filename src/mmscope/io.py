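"""Frame loading, batch-folder indexing and measurement output.

Batch acquisitions follow a naming protocol: a free-form area prefix, then
an underscore-separated YYMMDD date and HHMMSS time, e.g.
``Area01_171016_123301.tiff`` for area 1 imaged at 12:33:01 on
2017-10-16.  The timestamp orders frames chronologically within each
area.

Coordinate convention throughout the package: row-major, 0-based,
(row, col); masks are boolean pixel sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: area prefix may itself contain underscores; only the two trailing
#: fields are fixed by the protocol
_FILENAME_RE = re.compile(r"^(?P<area>.+)_(?P<date>\d{6})_(?P<time>\d{6})$")


class FilenameError(ValueError):
    """Raised for a filename that does not follow the naming protocol."""


@dataclass
class FrameStack:
    """One time point: the detection plane plus its fluorescence planes."""

    primary: np.ndarray
    fluorescence: List[np.ndarray] = field(default_factory=list)
    area_id: str = ""
    timestamp: datetime | None = None
    path: str = ""

    def __post_init__(self) -> None:
        if self.primary.ndim != 2:
            raise ValueError("primary plane must be 2-D")
        for plane in self.fluorescence:
            if plane.shape != self.primary.shape:
                raise ValueError("fluorescence planes must match the primary shape")


@dataclass
class BatchIndex:
    """area_id -> chronologically ordered frames of that area."""

    areas: Dict[str, List[FrameStack]]

    def __iter__(self):
        return iter(self.areas.items())


def parse_filename(name: str) -> tuple[str, datetime]:
    """Decode ``<area>_YYMMDD_HHMMSS[.ext]`` into (area_id, timestamp).

    The century pivot for YY is 2000-2099.
    """
    stem = Path(name).stem
    match = _FILENAME_RE.match(stem)
    if match is None:
        raise FilenameError(
            f"filename {name!r} does not follow the <area>_YYMMDD_HHMMSS naming protocol"
        )
    try:
        timestamp = datetime.strptime(match["date"] + match["time"], "%y%m%d%H%M%S")
    except ValueError as exc:
        raise FilenameError(f"filename {name!r} has malformed date/time fields: {exc}") from exc
    return match["area"], timestamp


def load_frame(path: str | Path, n_fluo: int = 0) -> FrameStack:
    """Load a TIFF as a FrameStack with ``n_fluo`` fluorescence planes.

    A multi-page TIFF holds the detection plane first, then the
    fluorescence planes in acquisition order.  The plane count must equal
    1 + n_fluo exactly.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        planes = [data]
    elif data.ndim == 3:
        planes = [data[i] for i in range(data.shape[0])]
    else:
        raise ValueError(f"{path.name}: expected a 2-D image or a stack of planes, got shape {data.shape}")
    if len(planes) != 1 + n_fluo:
        raise ValueError(
            f"{path.name}: expected {1 + n_fluo} plane(s) (1 detection + {n_fluo} fluorescence), "
            f"found {len(planes)}"
        )
    try:
        area_id, timestamp = parse_filename(path.name)
    except FilenameError:
        area_id, timestamp = "", None
    return FrameStack(
        primary=planes[0],
        fluorescence=planes[1:],
        area_id=area_id,
        timestamp=timestamp,
        path=str(path),
    )


def index_folder(folder: str | Path, n_fluo: int = 0, pattern: str = "*.tif*") -> BatchIndex:
    """Index every protocol-named TIFF in ``folder`` by area and time.

    Files are grouped by area id and ordered by timestamp; enumeration
    order of the directory never affects the result.
    """
    folder = Path(folder)
    entries: Dict[str, List[tuple[datetime, Path]]] = {}
    for path in sorted(folder.glob(pattern)):
        if _FILENAME_RE.match(path.stem) is None:
            logger.warning("skipping %s: not named by the protocol", path.name)
            continue
        area_id, timestamp = parse_filename(path.name)  # raises on malformed timestamps
        entries.setdefault(area_id, []).append((timestamp, path))
    areas: Dict[str, List[FrameStack]] = {}
    for area_id in sorted(entries):
        ordered = sorted(entries[area_id], key=lambda item: item[0])
        stamps = [t for t, _ in ordered]
        if any(b <= a for a, b in zip(stamps, stamps[1:])):
            raise FilenameError(f"area {area_id!r}: timestamps are not strictly increasing")
        areas[area_id] = [load_frame(p, n_fluo=n_fluo) for _, p in ordered]
    return BatchIndex(areas=areas)


#: fixed leading columns of the measurement CSV; fluo columns are appended
#: per configured fluorophore
CSV_BASE_COLUMNS = [
    "area_id",
    "timestamp",
    "frame_index",
    "channel_id",
    "bacterium_id",
    "parent_id",
    "event",
    "length_px",
    "width_px",
    "area_px",
]


def measurement_columns(n_fluo: int) -> List[str]:
    cols = list(CSV_BASE_COLUMNS)
    for k in range(n_fluo):
        cols += [f"fluo{k}_mean", f"fluo{k}_background"]
    return cols


def write_measurements(
    records: Sequence,
    path: str | Path,
    n_fluo: int = 0,
    um_per_px: float | None = None,
) -> None:
    """Write MeasurementRecords to CSV, one row per bacterium per frame.

    With ``um_per_px`` the pixel columns are supplemented by calibrated
    length_um / width_um / area_um2 columns.
    """
    rows = []
    for rec in records:
        row = {
            "area_id": rec.area_id,
            "timestamp": rec.timestamp,
            "frame_index": rec.frame_index,
            "channel_id": rec.channel_id,
            "bacterium_id": rec.bacterium_id,
            "parent_id": rec.parent_id if rec.parent_id is not None else "",
            "event": rec.event,
            "length_px": rec.length_px,
            "width_px": rec.width_px,
            "area_px": rec.area_px,
        }
        if um_per_px is not None:
            row["length_um"] = rec.length_px * um_per_px
            row["width_um"] = rec.width_px * um_per_px
            row["area_um2"] = rec.area_px * um_per_px**2
        for k, (mean, background) in enumerate(rec.fluorescence):
            row[f"fluo{k}_mean"] = mean
            row[f"fluo{k}_background"] = background
        rows.append(row)
    columns = measurement_columns(n_fluo)
    if um_per_px is not None:
        at = columns.index("area_px") + 1
        columns[at:at] = ["length_um", "width_um", "area_um2"]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False, float_format="%.6g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back into a DataFrame."""
    return pd.read_csv(path)
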