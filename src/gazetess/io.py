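"""Reading and writing delimited gaze-sample logs.

Vendor export schemas vary, so the column layout is declared in a
:class:`LogDialect` (a declarative column mapping + delimiter) rather than
hard-coded.  The writer emits the same dialect it reads, so synthetic data
can be round-tripped through the reader bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .geometry import ScreenGeometry
from .trace import GazeTrace

__all__ = ["LogDialect", "read_gaze_log", "write_gaze_log"]

#: canonical field names a dialect must map
_REQUIRED = (
    "participant",
    "group",
    "stimulus",
    "time",
    "l_x",
    "l_y",
    "r_x",
    "r_y",
    "l_valid",
    "r_valid",
)

_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no", ""}


@dataclass(frozen=True)
class LogDialect:
    """Declarative description of a gaze-log text format.

    ``columns`` maps canonical field names (``time``, ``l_x`` ... ``r_valid``,
    ``participant``, ``group``, ``stimulus``) to the column headers used in
    the file.  Missing coordinates are written as ``missing_token``.
    """

    delimiter: str = "\t"
    columns: dict = field(
        default_factory=lambda: {name: name for name in _REQUIRED}
    )
    missing_token: str = ""

    def __post_init__(self) -> None:
        absent = [k for k in _REQUIRED if k not in self.columns]
        if absent:
            raise ValueError(f"dialect is missing column mappings for {absent}")


def _parse_bool(token: str, path: str, lineno: int) -> bool:
    token = token.strip()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValueError(f"{path}:{lineno}: unparseable validity flag {token!r}")


def _parse_coord(token: str, missing_token: str, path: str, lineno: int) -> float:
    token = token.strip()
    if token == missing_token or token.lower() in ("nan", "na"):
        return np.nan
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: unparseable coordinate {token!r}") from exc


def read_gaze_log(
    path, geometry: ScreenGeometry, dialect: LogDialect | None = None, nominal_rate: float = 250.0
) -> list[GazeTrace]:
    """Parse a delimited gaze log into one :class:`GazeTrace` per
    participant x stimulus segment.

    Samples are kept in file order; traces whose timestamps are not strictly
    increasing raise a ``ValueError`` naming the trace.  Missing coordinates
    are preserved as NaN, never zero-filled.
    """
    dialect = dialect or LogDialect()
    path = Path(path)
    cols = dialect.columns
    segments: dict[tuple[str, str, str], dict[str, list]] = {}
    order: list[tuple[str, str, str]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty gaze log")
        missing_headers = [c for c in cols.values() if c not in reader.fieldnames]
        if missing_headers:
            raise ValueError(f"{path}: header lacks columns {missing_headers}")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (
                    row[cols["participant"]],
                    row[cols["group"]],
                    row[cols["stimulus"]],
                )
                t = float(row[cols["time"]])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row") from exc
            lv = _parse_bool(row[cols["l_valid"]], str(path), lineno)
            rv = _parse_bool(row[cols["r_valid"]], str(path), lineno)
            lx = _parse_coord(row[cols["l_x"]], dialect.missing_token, str(path), lineno)
            ly = _parse_coord(row[cols["l_y"]], dialect.missing_token, str(path), lineno)
            rx = _parse_coord(row[cols["r_x"]], dialect.missing_token, str(path), lineno)
            ry = _parse_coord(row[cols["r_y"]], dialect.missing_token, str(path), lineno)
            if lv != (not np.isnan(lx) and not np.isnan(ly)):
                raise ValueError(
                    f"{path}:{lineno}: left validity flag inconsistent with coordinates"
                )
            if rv != (not np.isnan(rx) and not np.isnan(ry)):
                raise ValueError(
                    f"{path}:{lineno}: right validity flag inconsistent with coordinates"
                )
            if key not in segments:
                segments[key] = {k: [] for k in ("t", "lx", "ly", "rx", "ry", "lv", "rv")}
                order.append(key)
            seg = segments[key]
            seg["t"].append(t)
            seg["lx"].append(lx)
            seg["ly"].append(ly)
            seg["rx"].append(rx)
            seg["ry"].append(ry)
            seg["lv"].append(lv)
            seg["rv"].append(rv)
    traces = []
    for key in order:
        participant, grp, stim = key
        seg = segments[key]
        traces.append(
            GazeTrace(
                participant_id=participant,
                group=grp,
                stimulus_id=stim,
                t=np.array(seg["t"]),
                left_x=np.array(seg["lx"]),
                left_y=np.array(seg["ly"]),
                right_x=np.array(seg["rx"]),
                right_y=np.array(seg["ry"]),
                valid_left=np.array(seg["lv"]),
                valid_right=np.array(seg["rv"]),
                geometry=geometry,
                nominal_rate=nominal_rate,
            )
        )
    return traces


def _fmt(value: float, missing_token: str) -> str:
    # repr round-trips float64 exactly through text
    return missing_token if np.isnan(value) else repr(float(value))


def write_gaze_log(path, traces: Iterable[GazeTrace], dialect: LogDialect | None = None) -> None:
    """Write traces in the given dialect; inverse of :func:`read_gaze_log`."""
    dialect = dialect or LogDialect()
    cols = dialect.columns
    header = [cols[k] for k in _REQUIRED]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for tr in traces:
            for i in range(len(tr)):
                writer.writerow(
                    [
                        tr.participant_id,
                        tr.group,
                        tr.stimulus_id,
                        repr(float(tr.t[i])),
                        _fmt(tr.left_x[i], dialect.missing_token),
                        _fmt(tr.left_y[i], dialect.missing_token),
                        _fmt(tr.right_x[i], dialect.missing_token),
                        _fmt(tr.right_y[i], dialect.missing_token),
                        int(tr.valid_left[i]),
                        int(tr.valid_right[i]),
                    ]
                )
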