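"""Plain-text ROI time-series I/O.

A subject's data is a T x N numeric matrix (rows = time points, columns =
regions of interest), stored as delimited text with an optional single header
row of ROI labels. A cohort is a set of such files listed in order by a
manifest file (one path per line, relative to the manifest's directory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SubjectTimeSeries:
    """One subject's ROI time series: a T x N matrix plus labels."""

    values: np.ndarray
    subject_id: str = ""
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix (time x ROI)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing or non-finite values")
        if self.roi_labels is not None and len(self.roi_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.values.shape[1]} columns"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_timeseries(path: str | Path, subject_id: str | None = None) -> SubjectTimeSeries:
    """Read a delimited-text time-series matrix (comma or tab, auto-detected).

    A first row that fails numeric parsing is taken as the ROI-label header.
    Raises ``ValueError`` locating the offending row/column on ragged rows,
    non-numeric cells, or fewer than 3 time points.
    """
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(raw[0])
    labels: list[str] | None = None
    first = raw[0].split(delim)
    try:
        [float(c) for c in first]
    except ValueError:
        labels = [c.strip() for c in first]
        raw = raw[1:]
    rows: list[list[float]] = []
    width: int | None = None
    for i, ln in enumerate(raw):
        cells = ln.split(delim)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: row {i + 1} has {len(cells)} cells, expected {width}"
            )
        parsed = []
        for j, c in enumerate(cells):
            try:
                parsed.append(float(c))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {c!r}"
                ) from None
        rows.append(parsed)
    if len(rows) < 3:
        raise ValueError(f"{path}: need at least 3 time points, found {len(rows)}")
    if labels is not None and width is not None and len(labels) != width:
        raise ValueError(f"{path}: header has {len(labels)} labels for {width} columns")
    return SubjectTimeSeries(
        values=np.array(rows, dtype=float),
        subject_id=subject_id if subject_id is not None else path.stem,
        roi_labels=labels,
    )


def write_timeseries(ts: SubjectTimeSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a time-series matrix as delimited text at 10 significant digits."""
    path = Path(path)
    lines = []
    if ts.roi_labels is not None:
        lines.append(delimiter.join(ts.roi_labels))
    for row in ts.values:
        lines.append(delimiter.join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> list[SubjectTimeSeries]:
    """Read a cohort manifest: one subject file path per line, in order."""
    path = Path(path)
    cohort = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cohort.append(read_timeseries(path.parent / ln))
    if not cohort:
        raise ValueError(f"{path}: manifest lists no subjects")
    return cohort


def write_manifest(cohort: list[SubjectTimeSeries], directory: str | Path) -> Path:
    """Write each subject's matrix and a manifest listing them in order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, ts in enumerate(cohort):
        name = f"{ts.subject_id or f'subject{i:03d}'}.csv"
        write_timeseries(ts, directory / name)
        names.append(name)
    manifest = directory / "manifest.txt"
    manifest.write_text("\n".join(names) + "\n")
    return manifest


def write_matrix(
    m: np.ndarray, path: str | Path, labels: list[str] | None = None, delimiter: str = "\t"
) -> None:
    """Write a square labelled matrix as delimited text (header row + column)."""
    m = np.asarray(m)
    n = m.shape[0]
    if labels is None:
        labels = [f"ROI{i + 1}" for i in range(n)]
    lines = [delimiter.join([""] + list(labels))]
    for lab, row in zip(labels, m):
        lines.append(delimiter.join([lab] + [f"{v:.10g}" for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path: str | Path, delimiter: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Read a square labelled matrix written by :func:`write_matrix`."""
    raw = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    labels = raw[0].split(delimiter)[1:]
    rows = []
    for ln in raw[1:]:
        cells = ln.split(delimiter)
        rows.append([float(c) for c in cells[1:]])
    m = np.array(rows, dtype=float)
    if m.shape != (len(labels), len(labels)):
        raise ValueError(f"{path}: matrix shape {m.shape} does not match header")
    return m, labels
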