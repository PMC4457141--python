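"""Reading TriKinetics DAM2-style monitor files and extracting eclosion events.

A DAM2 monitor records infrared beam crossings per channel in fixed time bins.
In an eclosion-logger setup each channel holds a single pupa, so the first
nonzero count on a channel marks the moment the newly emerged adult crossed the
beam.  Clock times are converted to Zeitgeber time (ZT), hours elapsed since
lights-on, with ZT 0 = lights-on.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "DamDialect",
    "MonitorReading",
    "EclosionEvent",
    "parse_dam_monitor",
    "extract_eclosion_events",
    "to_zt",
    "write_events_tsv",
    "read_events_tsv",
    "format_monitor_lines",
]


class MonitorParseError(ValueError):
    """Raised when a monitor line cannot be parsed; message names the line."""


@dataclass(frozen=True)
class DamDialect:
    """Column layout of a tab-separated DAM monitor file.

    The canonical DAM2 export has a reading index, date (``"d mmm yy"``),
    time (``"HH:MM:SS"``), seven status/metadata columns and then 32
    channel-count columns; every offset is configurable because TriKinetics
    dialects vary between firmware versions.
    """

    index_col: int = 0
    date_col: int = 1
    time_col: int = 2
    first_count_col: int = 10
    n_channels: int = 32
    date_format: str = "%d %b %y"
    time_format: str = "%H:%M:%S"

    @property
    def n_columns(self) -> int:
        return self.first_count_col + self.n_channels


@dataclass(frozen=True)
class MonitorReading:
    """One (time bin, channel) cell of a monitor file."""

    reading_index: int
    date: dt.date
    clock_time: dt.time
    channel: int
    count: int

    @property
    def datetime(self) -> dt.datetime:
        return dt.datetime.combine(self.date, self.clock_time)


@dataclass(frozen=True)
class EclosionEvent:
    """First beam crossing on a channel, i.e. the fly's emergence time."""

    channel: int
    event_datetime: dt.datetime
    zt_hours: float


def to_zt(clock_time: dt.time, lights_on: dt.time) -> float:
    """Hours elapsed from lights-on to *clock_time*, modulo 24.

    ZT 0 coincides with lights-on; values lie in ``[0, 24)``.
    """
    seconds = (
        (clock_time.hour - lights_on.hour) * 3600
        + (clock_time.minute - lights_on.minute) * 60
        + (clock_time.second - lights_on.second)
        + (clock_time.microsecond - lights_on.microsecond) / 1e6
    )
    return (seconds / 3600.0) % 24.0


def parse_dam_monitor(
    source: TextIO | Iterable[str], dialect: DamDialect | None = None
) -> list[MonitorReading]:
    """Parse a DAM monitor text stream into per-(line, channel) readings.

    Returns one :class:`MonitorReading` per channel column per line, in file
    order.  Malformed lines (wrong column count, unparseable date/time/count)
    raise :class:`MonitorParseError` naming the 1-based line number.
    """
    dialect = dialect or DamDialect()
    readings: list[MonitorReading] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < dialect.n_columns:
            raise MonitorParseError(
                f"line {lineno}: expected at least {dialect.n_columns} "
                f"tab-separated columns, got {len(fields)}"
            )
        try:
            idx = int(fields[dialect.index_col])
            date = dt.datetime.strptime(
                fields[dialect.date_col].strip(), dialect.date_format
            ).date()
            clock = dt.datetime.strptime(
                fields[dialect.time_col].strip(), dialect.time_format
            ).time()
        except ValueError as exc:
            raise MonitorParseError(f"line {lineno}: {exc}") from exc
        for ch in range(dialect.n_channels):
            cell = fields[dialect.first_count_col + ch]
            try:
                count = int(cell)
            except ValueError as exc:
                raise MonitorParseError(
                    f"line {lineno}: channel {ch + 1} count {cell!r} is not an integer"
                ) from exc
            if count < 0:
                raise MonitorParseError(
                    f"line {lineno}: channel {ch + 1} count {count} is negative"
                )
            readings.append(
                MonitorReading(
                    reading_index=idx,
                    date=date,
                    clock_time=clock,
                    channel=ch + 1,
                    count=count,
                )
            )
    return readings


def extract_eclosion_events(
    readings: Iterable[MonitorReading], lights_on: dt.time
) -> list[EclosionEvent]:
    """First nonzero count per channel, as that channel's eclosion event.

    Channels whose counts are all zero are omitted (the pupa may have died);
    later crossings on an already-fired channel are ignored, so the operation
    is idempotent under duplicated or extended recordings.  Events are
    returned sorted by channel.
    """
    first: dict[int, MonitorReading] = {}
    for r in readings:
        if r.count > 0:
            prev = first.get(r.channel)
            if prev is None or r.datetime < prev.datetime:
                first[r.channel] = r
    return [
        EclosionEvent(
            channel=ch,
            event_datetime=first[ch].datetime,
            zt_hours=to_zt(first[ch].clock_time, lights_on),
        )
        for ch in sorted(first)
    ]


def write_events_tsv(events: Iterable[EclosionEvent], sink: TextIO) -> None:
    """Write events as TSV with columns channel, datetime (ISO 8601), zt_hours."""
    sink.write("channel\tdatetime\tzt_hours\n")
    for e in events:
        sink.write(f"{e.channel}\t{e.event_datetime.isoformat()}\t{e.zt_hours:.6f}\n")


def read_events_tsv(source: TextIO) -> list[EclosionEvent]:
    """Read back an event TSV written by :func:`write_events_tsv`."""
    header = source.readline().rstrip("\n").split("\t")
    if header != ["channel", "datetime", "zt_hours"]:
        raise ValueError(f"unexpected event-table header: {header}")
    events = []
    for line in source:
        if not line.strip():
            continue
        ch, iso, zt = line.rstrip("\n").split("\t")
        events.append(
            EclosionEvent(
                channel=int(ch),
                event_datetime=dt.datetime.fromisoformat(iso),
                zt_hours=float(zt),
            )
        )
    return events


def format_monitor_lines(
    readings: list[MonitorReading], dialect: DamDialect | None = None
) -> list[str]:
    """Serialise readings back into monitor-file lines (inverse of parsing).

    Readings must cover every channel for each time bin, as produced by
    :func:`parse_dam_monitor`.  Metadata columns the dialect skips are filled
    with zeros.
    """
    dialect = dialect or DamDialect()
    by_bin: dict[tuple[int, dt.date, dt.time], dict[int, int]] = {}
    for r in readings:
        by_bin.setdefault((r.reading_index, r.date, r.clock_time), {})[r.channel] = r.count
    lines = []
    for (idx, date, clock), counts in by_bin.items():
        fields = ["0"] * dialect.n_columns
        fields[dialect.index_col] = str(idx)
        fields[dialect.date_col] = date.strftime(dialect.date_format)
        fields[dialect.time_col] = clock.strftime(dialect.time_format)
        for ch in range(dialect.n_channels):
            fields[dialect.first_count_col + ch] = str(counts.get(ch + 1, 0))
        lines.append("\t".join(fields))
    return lines
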