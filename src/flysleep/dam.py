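"""Reading and writing TriKinetics-style activity-monitor files.

A Drosophila Activity Monitor (DAM) reports, once per minute, the number of
infrared beam breaks for each of 32 activity tubes ("channels").  The de
facto file dialect handled here is tab-separated text with one row per
minute and columns::

    index  date  time  status  c1 c2 ... c32

where ``date`` is like ``4 Jan 16``, ``time`` is ``HH:MM:SS``, ``status``
is an integer reading code (1 = valid) and ``c1..c32`` are non-negative
per-channel counts.  Rows with a non-valid status are dropped with a logged
warning; gaps or non-monotone timestamps in the remaining rows are
rejected.

The in-memory representation is :class:`ActivityTrace`: one animal's
contiguous per-minute counts annotated with zeitgeber time (minutes since
lights-on; ZT 0-719 is day, ZT 720-1439 is night under the 12:12 cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CapacityError, DamFormatError, DamOrderingError

logger = logging.getLogger(__name__)

N_CHANNELS = 32
MINUTES_PER_DAY = 1440
DAY_MINUTES = 720  # lights-on half of the 12:12 cycle

_DATE_FORMAT = "%d %b %y"
_TIME_FORMAT = "%H:%M:%S"
VALID_STATUS = 1


@dataclass
class ActivityTrace:
    """One animal's contiguous per-minute activity counts.

    Attributes
    ----------
    animal_id : str
        Identifier; for file input this is ``<file stem>#<channel:02d>``.
    counts : numpy.ndarray of int
        Beam-break counts, one entry per minute, contiguous at 1-minute step.
    start_day : int
        1-based experiment day of the first minute (days roll over at ZT 0).
    start_zt : int
        Zeitgeber minute (0..1439) of the first sample.
    """

    animal_id: str
    counts: np.ndarray
    start_day: int = 1
    start_zt: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("activity counts must be non-negative")
        if not 0 <= self.start_zt < MINUTES_PER_DAY:
            raise ValueError("start_zt must be in [0, 1439]")

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ActivityTrace):
            return NotImplemented
        return (
            self.animal_id == other.animal_id
            and self.start_day == other.start_day
            and self.start_zt == other.start_zt
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def zt_minute(self) -> np.ndarray:
        """Zeitgeber minute (0..1439) of every sample."""
        return (self.start_zt + np.arange(len(self.counts))) % MINUTES_PER_DAY

    @property
    def day_index(self) -> np.ndarray:
        """Experiment day of every sample; increments when ZT wraps to 0."""
        return self.start_day + (self.start_zt + np.arange(len(self.counts))) // MINUTES_PER_DAY

    @property
    def lights_on(self) -> np.ndarray:
        """True for day minutes (ZT 0-719)."""
        return self.zt_minute < DAY_MINUTES

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: animal_id, day_index, zt_minute, lights_on, count."""
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "day_index": self.day_index,
                "zt_minute": self.zt_minute,
                "lights_on": self.lights_on,
                "count": self.counts,
            }
        )


def traces_to_frame(traces: Iterable[ActivityTrace]) -> pd.DataFrame:
    """Concatenate traces into one long-format DataFrame (CSV-exportable)."""
    frames = [t.to_frame() for t in traces]
    if not frames:
        return pd.DataFrame(
            columns=["animal_id", "day_index", "zt_minute", "lights_on", "count"]
        )
    return pd.concat(frames, ignore_index=True)


def _parse_timestamp(date_field: str, time_field: str, line_number: int) -> datetime:
    try:
        return datetime.strptime(f"{date_field} {time_field}", f"{_DATE_FORMAT} {_TIME_FORMAT}")
    except ValueError as exc:
        raise DamFormatError(f"unparseable timestamp {date_field!r} {time_field!r}", line_number) from exc


def read_dam_file(
    path,
    lights_on_clock_time: time = time(8, 0),
    channels: str | Sequence[int] = "nonempty",
) -> list[ActivityTrace]:
    """Read a monitor file into per-channel activity traces.

    Parameters
    ----------
    path : path-like
        Tab-separated monitor file (layout described in the module docstring).
    lights_on_clock_time : datetime.time
        Wall-clock time of lights-on; zeitgeber minute 0 is aligned to it.
        Monitors record wall-clock time only, so the caller must supply this.
    channels : "nonempty" | "all" | sequence of int
        Which channels (1-based) to return.  The default skips channels whose
        counts are zero throughout, the usual signature of an empty tube.

    Returns
    -------
    list of ActivityTrace
        One trace per selected channel; the first row is experiment day 1.

    Raises
    ------
    DamFormatError
        Malformed row (wrong column count, bad integer, bad timestamp).
    DamOrderingError
        Valid-row timestamps that are not strictly increasing at 1-minute
        cadence (gaps and duplicates both fail).
    """
    path = Path(path)
    timestamps: list[datetime] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 + N_CHANNELS:
                raise DamFormatError(
                    f"expected {4 + N_CHANNELS} tab-separated fields, found {len(fields)}",
                    line_number,
                )
            ts = _parse_timestamp(fields[1], fields[2], line_number)
            try:
                int(fields[0])  # reading index, unused but must be numeric
                status = int(fields[3])
                counts = [int(v) for v in fields[4:]]
            except ValueError as exc:
                raise DamFormatError(f"non-integer field: {exc}", line_number) from exc
            if any(c < 0 for c in counts):
                raise DamFormatError("negative activity count", line_number)
            if status != VALID_STATUS:
                logger.warning(
                    "%s line %d: dropping row with status %d", path.name, line_number, status
                )
                continue
            timestamps.append(ts)
            rows.append(counts)

    if not rows:
        raise DamFormatError(f"{path.name}: no valid rows")

    for prev, cur in zip(timestamps, timestamps[1:]):
        if cur - prev != timedelta(minutes=1):
            raise DamOrderingError(
                f"{path.name}: timestamps must advance by exactly 1 minute "
                f"({prev.isoformat()} -> {cur.isoformat()})"
            )

    counts = np.asarray(rows, dtype=np.int64)  # (n_minutes, 32)

    lights_on_minute = lights_on_clock_time.hour * 60 + lights_on_clock_time.minute
    first = timestamps[0]
    start_zt = (first.hour * 60 + first.minute - lights_on_minute) % MINUTES_PER_DAY

    if isinstance(channels, str):
        if channels == "all":
            selected = range(1, N_CHANNELS + 1)
        elif channels == "nonempty":
            selected = [ch for ch in range(1, N_CHANNELS + 1) if counts[:, ch - 1].any()]
        else:
            raise ValueError("channels must be 'nonempty', 'all' or a sequence of ints")
    else:
        selected = list(channels)
        for ch in selected:
            if not 1 <= ch <= N_CHANNELS:
                raise ValueError(f"channel {ch} out of range 1..{N_CHANNELS}")

    return [
        ActivityTrace(
            animal_id=f"{path.stem}#{ch:02d}",
            counts=counts[:, ch - 1],
            start_day=1,
            start_zt=start_zt,
        )
        for ch in selected
    ]


def write_dam_file(
    traces: Sequence[ActivityTrace],
    path,
    lights_on_clock_time: time = time(8, 0),
    start_date: datetime | None = None,
) -> None:
    """Write traces as a monitor file readable by :func:`read_dam_file`.

    Traces are placed on channels 1..k in order; unused channels are filled
    with zeros.  All traces must share length and zeitgeber alignment.
    Timestamps are synthesized so that re-reading with the same
    ``lights_on_clock_time`` restores each trace's ZT alignment, with the
    first row on experiment day 1.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("cannot write an empty trace list")
    if len(traces) > N_CHANNELS:
        raise CapacityError(f"{len(traces)} traces exceed the {N_CHANNELS}-channel capacity")
    n = len(traces[0])
    if n == 0:
        raise ValueError("traces must be non-empty")
    for t in traces[1:]:
        if len(t) != n or t.start_zt != traces[0].start_zt or t.start_day != traces[0].start_day:
            raise ValueError("all traces must share length and alignment")

    if start_date is None:
        start_date = datetime(2016, 1, 4)
    lights_on_dt = datetime.combine(start_date.date(), lights_on_clock_time)
    first_ts = lights_on_dt + timedelta(minutes=traces[0].start_zt)

    matrix = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for j, t in enumerate(traces):
        matrix[:, j] = t.counts

    with open(path, "w") as fh:
        for i in range(n):
            ts = first_ts + timedelta(minutes=i)
            fields = [
                str(i + 1),
                ts.strftime(_DATE_FORMAT).lstrip("0"),
                ts.strftime(_TIME_FORMAT),
                str(VALID_STATUS),
            ] + [str(v) for v in matrix[i]]
            fh.write("\t".join(fields) + "\n")
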