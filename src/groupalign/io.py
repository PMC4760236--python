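"""Readers and writers for the delimited text formats the tool touches.

Peak lists are delimited text (TSV by default, comma accepted) with a
mandatory header naming at least id, mz, rt and intensity columns; the
column mapping is configurable so exports from common feature-extraction
tools can be ingested without conversion. Chromatographic shape traces,
when available, live in a sidecar table (``id  rt_scan  signal``).
Ground truth is a two-column ``id_a  id_b`` table; matchings are written
as ``id_a  id_b  score``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Union

from .errors import FormatError, PeakParseError, ValidationError
from .peaks import GroundTruth, Matching, Peak, PeakList

PathLike = Union[str, Path]

DEFAULT_COLUMNS = {"id": "id", "mz": "mz", "rt": "rt", "intensity": "intensity"}


def _sniff_delimiter(header_line: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if ("," in header_line and "\t" not in header_line) else "\t"


def read_shape_traces(path: PathLike, delimiter: Optional[str] = None):
    """Read a sidecar trace table ``id  rt_scan  signal`` into a dict of traces."""
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            return {}
        delim = _sniff_delimiter(first, delimiter)
        header = [c.strip() for c in first.rstrip("\n").split(delim)]
        for col in ("id", "rt_scan", "signal"):
            if col not in header:
                raise FormatError(f"{path}: shape sidecar missing column {col!r}")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)
        traces: dict[str, list[tuple[float, float]]] = {}
        for row_no, row in enumerate(reader, start=2):
            try:
                t, s = float(row["rt_scan"]), float(row["signal"])
            except (TypeError, ValueError):
                raise PeakParseError(f"{path}: non-numeric trace sample at row {row_no}")
            traces.setdefault(row["id"], []).append((t, s))
    return {k: tuple(v) for k, v in traces.items()}


def read_peaklist(
    path: PathLike,
    run_id: Optional[str] = None,
    delimiter: Optional[str] = None,
    columns: Optional[Mapping[str, str]] = None,
    rt_in_minutes: bool = False,
    shape_path: Optional[PathLike] = None,
) -> PeakList:
    """Read a peak table into a :class:`PeakList`, preserving row order.

    Parameters
    ----------
    path : path
        Delimited text file with a header row.
    run_id : str, optional
        Label for the run; defaults to the file stem.
    delimiter : str, optional
        Field delimiter; sniffed between tab and comma when omitted.
    columns : mapping, optional
        Maps the canonical names ``id``/``mz``/``rt``/``intensity`` to the
        column names actually present in the file.
    rt_in_minutes : bool
        Convert RT from minutes to seconds on input. Internally RT is
        always seconds.
    shape_path : path, optional
        Sidecar trace table to attach chromatographic shapes.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    traces = read_shape_traces(shape_path, delimiter) if shape_path else {}

    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            return PeakList(run_id or path.stem, [])
        delim = _sniff_delimiter(first, delimiter)
        header = [c.strip() for c in first.rstrip("\n").split(delim)]
        for canon, col in colmap.items():
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r} (for {canon!r})")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)
        peaks = []
        for row_no, row in enumerate(reader, start=2):
            pid = row[colmap["id"]]
            if pid is None:
                raise PeakParseError(f"{path}: short row at line {row_no}")
            try:
                mz = float(row[colmap["mz"]])
                rt = float(row[colmap["rt"]])
                intensity = float(row[colmap["intensity"]])
            except (TypeError, ValueError):
                raise PeakParseError(
                    f"{path}: non-numeric mz/rt/intensity at row {row_no}"
                ) from None
            if rt_in_minutes:
                rt *= 60.0
            peaks.append(Peak(pid, mz, rt, intensity, shape=traces.get(pid)))
    return PeakList(run_id or path.stem, peaks)


def write_peaklist(run: PeakList, path: PathLike, shape_path: Optional[PathLike] = None) -> None:
    """Write a peak table (and optionally a shape sidecar); round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "mz", "rt", "intensity"])
        for p in run:
            writer.writerow([p.id, repr(p.mz), repr(p.rt), repr(p.intensity)])
    if shape_path is not None:
        with Path(shape_path).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "rt_scan", "signal"])
            for p in run:
                for t, s in p.shape or ():
                    writer.writerow([p.id, repr(t), repr(s)])


def read_ground_truth(
    path: PathLike,
    run_a: Optional[PeakList] = None,
    run_b: Optional[PeakList] = None,
    delimiter: Optional[str] = None,
) -> GroundTruth:
    """Read a two-column ``id_a  id_b`` pair table, validated against both runs."""
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            return GroundTruth([], run_a, run_b)
        delim = _sniff_delimiter(first, delimiter)
        header = [c.strip() for c in first.rstrip("\n").split(delim)]
        for col in ("id_a", "id_b"):
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)
        pairs = []
        for row in reader:
            a, b = row["id_a"], row["id_b"]
            if a is None or b is None:
                raise FormatError(f"{path}: short row in ground truth")
            pairs.append((a, b))
    return GroundTruth(pairs, run_a, run_b)


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id_a", "id_b"])
        for a, b in sorted(truth.pairs):
            writer.writerow([a, b])


def write_matching(matching: Matching, path: PathLike) -> None:
    """Write ``id_a  id_b  score`` rows; read-back reproduces the matching."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id_a", "id_b", "score"])
        for a, b, s in matching.scored_pairs:
            writer.writerow([a, b, repr(s)])


def read_matching(path: PathLike, delimiter: Optional[str] = None) -> Matching:
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            return Matching([])
        delim = _sniff_delimiter(first, delimiter)
        header = [c.strip() for c in first.rstrip("\n").split(delim)]
        for col in ("id_a", "id_b", "score"):
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)
        rows = []
        for row_no, row in enumerate(reader, start=2):
            try:
                rows.append((row["id_a"], row["id_b"], float(row["score"])))
            except (TypeError, ValueError):
                raise PeakParseError(f"{path}: non-numeric score at row {row_no}") from None
    return Matching(rows)
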