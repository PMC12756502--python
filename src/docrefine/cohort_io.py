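"""Cohort manifests, clinical tables and ROI time-series I/O.

A cohort is a list of subjects, each carrying a clinical label (HC, UWS or
MCS), an optional CRS-R total score (0-23), and a pointer to a preprocessed
ROI time-series file. Two table dialects are supported:

``delimited``
    The package's own manifest: a header row with at least
    ``subject_id,label,crsr_total,timeseries_path`` (comma-separated by
    default); optional ``months_since_onset`` and ``etiology`` columns are
    preserved on round-trip.

``clinical_table``
    The published clinical-characteristics layout (columns ``Patient ID``,
    ``Gender``, ``Age``, ``Months since onset``, ``Etiology``, ``Lesion
    information``, ``CRS-R score (1st)``, ``Diagnosis``), tab- or
    comma-separated. The historical diagnosis label ``VS`` (vegetative
    state) is normalized to ``UWS``.

The literal token ``n/a`` (case-insensitive) and empty cells denote missing
values; anything else unparseable is an error — inputs are assumed curated,
so silent coercion would hide corruption.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (
    InsufficientDataError,
    ParseError,
    SchemaError,
    SeedSelectionError,
)

VALID_LABELS = ("HC", "UWS", "MCS")

#: Columns required in the package's own manifest dialect.
MANIFEST_REQUIRED = ("subject_id", "label", "crsr_total", "timeseries_path")
MANIFEST_OPTIONAL = ("months_since_onset", "etiology")

#: Columns required in the published clinical-table dialect.
CLINICAL_REQUIRED = ("Patient ID", "Diagnosis", "CRS-R score (1st)")

_MISSING_TOKENS = {"", "n/a", "na", "nan", "none"}

CRSR_MIN, CRSR_MAX = 0, 23


@dataclass(frozen=True)
class Subject:
    """One cohort member.

    ``crsr_total`` is the Coma Recovery Scale-Revised total score (0-23);
    it may be missing (``None``), in which case the subject still
    participates in connectivity analyses but never in CRS-R seeding.
    """

    subject_id: str
    clinical_label: str
    crsr_total: Optional[int] = None
    months_since_onset: Optional[float] = None
    etiology: Optional[str] = None
    timeseries_path: Optional[str] = None

    def __post_init__(self):
        if self.clinical_label not in VALID_LABELS:
            raise SchemaError(
                f"subject {self.subject_id!r}: unknown label "
                f"{self.clinical_label!r} (expected one of {VALID_LABELS})"
            )
        if self.crsr_total is not None and not (
            CRSR_MIN <= self.crsr_total <= CRSR_MAX
        ):
            raise SchemaError(
                f"subject {self.subject_id!r}: CRS-R total "
                f"{self.crsr_total} outside [{CRSR_MIN}, {CRSR_MAX}]"
            )


@dataclass
class Cohort:
    """An ordered collection of subjects with stable iteration order."""

    subjects: list[Subject] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate subject ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def ids(self, label: Optional[str] = None) -> list[str]:
        """Subject ids in cohort order, optionally restricted to one label."""
        return [
            s.subject_id
            for s in self.subjects
            if label is None or s.clinical_label == label
        ]

    def by_label(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.clinical_label == label]

    def get(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass(frozen=True)
class ROITimeSeries:
    """A subject's preprocessed BOLD signal matrix, time points x regions."""

    data: np.ndarray
    subject_id: str = ""

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in _MISSING_TOKENS


def _parse_int(cell: str, what: str, row: int) -> Optional[int]:
    if _is_missing(cell):
        return None
    try:
        return int(cell.strip())
    except ValueError:
        raise ParseError(
            f"row {row}: unparseable {what} value {cell.strip()!r}"
        ) from None


def _parse_float(cell: str, what: str, row: int) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(cell.strip())
    except ValueError:
        raise ParseError(
            f"row {row}: unparseable {what} value {cell.strip()!r}"
        ) from None


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_rows(text: str) -> tuple[list[str], list[list[str]], str]:
    lines = text.splitlines()
    if not lines:
        raise SchemaError("empty file: no header row")
    delim = _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = [row for row in reader if any(c.strip() for c in row)]
    return rows[0], rows[1:], delim


def load_manifest(path, format: str = "delimited") -> Cohort:
    """Read a cohort from a manifest or clinical table.

    Parameters
    ----------
    path : path-like
        Delimited text file with a mandatory header row.
    format : {"delimited", "clinical_table"}
        Which dialect to expect (see module docstring).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return parse_manifest(text, format=format, provenance=str(path))


def parse_manifest(
    text: str, format: str = "delimited", provenance: str = ""
) -> Cohort:
    """Parse manifest text already in memory (see :func:`load_manifest`)."""
    if format not in ("delimited", "clinical_table"):
        raise ValueError(f"unknown manifest format {format!r}")
    header, rows, _ = _read_rows(text)
    header = [h.strip() for h in header]
    required = (
        MANIFEST_REQUIRED if format == "delimited" else CLINICAL_REQUIRED
    )
    for col in required:
        if col not in header:
            raise SchemaError(f"missing required column {col!r}")
    idx = {name: header.index(name) for name in header}

    def cell(row: list[str], col: str) -> str:
        j = idx.get(col)
        if j is None or j >= len(row):
            return ""
        return row[j]

    subjects = []
    for r, row in enumerate(rows, start=2):  # 1-based file row of data
        if format == "clinical_table":
            label = cell(row, "Diagnosis").strip()
            if label == "VS":
                label = "UWS"
            subjects.append(
                Subject(
                    subject_id=cell(row, "Patient ID").strip(),
                    clinical_label=label,
                    crsr_total=_parse_int(
                        cell(row, "CRS-R score (1st)"), "CRS-R", r
                    ),
                    months_since_onset=_parse_float(
                        cell(row, "Months since onset"), "months", r
                    ),
                    etiology=(
                        None
                        if _is_missing(cell(row, "Etiology"))
                        else cell(row, "Etiology").strip()
                    ),
                )
            )
        else:
            ts = cell(row, "timeseries_path").strip()
            subjects.append(
                Subject(
                    subject_id=cell(row, "subject_id").strip(),
                    clinical_label=cell(row, "label").strip(),
                    crsr_total=_parse_int(cell(row, "crsr_total"), "CRS-R", r),
                    months_since_onset=_parse_float(
                        cell(row, "months_since_onset"), "months", r
                    ),
                    etiology=(
                        None
                        if _is_missing(cell(row, "etiology"))
                        else cell(row, "etiology").strip()
                    ),
                    timeseries_path=ts if ts else None,
                )
            )
    return Cohort(subjects=subjects, provenance=provenance)


def save_manifest(cohort: Cohort, path) -> None:
    """Write a cohort in the ``delimited`` manifest dialect (UTF-8, comma).

    Emits the four required columns plus ``months_since_onset`` and
    ``etiology`` so that a load/save cycle preserves every field.
    """
    path = Path(path)
    cols = list(MANIFEST_REQUIRED) + list(MANIFEST_OPTIONAL)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for s in cohort:
            w.writerow(
                [
                    s.subject_id,
                    s.clinical_label,
                    "" if s.crsr_total is None else s.crsr_total,
                    "" if s.timeseries_path is None else s.timeseries_path,
                    ""
                    if s.months_since_onset is None
                    else repr(s.months_since_onset),
                    "" if s.etiology is None else s.etiology,
                ]
            )


def load_clinical_table() -> Cohort:
    """The packaged clinical-characteristics table (88 patients: 58 UWS
    printed as "VS", 30 MCS; patient 85 has a missing CRS-R total)."""
    text = (
        resources.files("docrefine.data")
        .joinpath("clinical_characteristics.tsv")
        .read_text(encoding="utf-8")
    )
    return parse_manifest(
        text, format="clinical_table", provenance="packaged clinical table"
    )


def select_seed_uws(cohort: Cohort, max_crsr: int = 5) -> set[str]:
    """UWS subjects with CRS-R total <= ``max_crsr``: the high-confidence
    seed of the refinement (misdiagnosis is unlikely at very low scores).

    Subjects with a missing CRS-R total are never selected. Raises
    :class:`SeedSelectionError` if the result is empty, since the
    refinement cannot start without a seed.
    """
    seed = {
        s.subject_id
        for s in cohort.by_label("UWS")
        if s.crsr_total is not None and s.crsr_total <= max_crsr
    }
    if not seed:
        raise SeedSelectionError(
            f"no UWS subject with CRS-R total <= {max_crsr}; "
            "the refinement has no seed"
        )
    return seed


def load_timeseries(path, subject_id: str = "") -> ROITimeSeries:
    """Read a plain delimited numeric time-series file (rows = time points,
    columns = regions). Comma, tab or whitespace separated.

    Raises :class:`ParseError` with a 1-based (row, column) location on a
    ragged or non-numeric cell, and :class:`InsufficientDataError` when the
    table has fewer than 3 time points or fewer than 2 regions.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise InsufficientDataError(f"{path}: empty time-series file")
    first = lines[0]
    if "," in first:
        split = lambda s: s.split(",")  # noqa: E731
    elif "\t" in first:
        split = lambda s: s.split("\t")  # noqa: E731
    else:
        split = str.split
    rows: list[list[float]] = []
    width = None
    for i, line in enumerate(lines, start=1):
        parts = split(line)
        if width is None:
            width = len(parts)
        elif len(parts) != width:
            raise ParseError(
                f"{path}: ragged row {i} (expected {width} columns, "
                f"found {len(parts)})"
            )
        vals = []
        for j, cell in enumerate(parts, start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {i}, column {j}: "
                    f"{cell.strip()!r}"
                ) from None
        rows.append(vals)
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < 2:
        raise InsufficientDataError(
            f"{path}: need at least 2 regions, found {data.shape[1]}"
        )
    if data.shape[0] < 3:
        raise InsufficientDataError(
            f"{path}: need at least 3 time points, found {data.shape[0]}"
        )
    return ROITimeSeries(data=data, subject_id=subject_id or path.stem)


def load_cohort_timeseries(cohort: Cohort, root=None) -> dict[str, ROITimeSeries]:
    """Load every subject's time series referenced by a cohort manifest.

    Relative ``timeseries_path`` entries are resolved against ``root``
    (default: current directory). Subjects without a path are skipped.
    """
    root = Path(root) if root is not None else Path(".")
    out = {}
    for s in cohort:
        if s.timeseries_path is None:
            continue
        p = Path(s.timeseries_path)
        if not p.is_absolute():
            p = root / p
        out[s.subject_id] = load_timeseries(p, subject_id=s.subject_id)
    return out


def with_timeseries_paths(cohort: Cohort, paths: dict[str, str]) -> Cohort:
    """Return a copy of the cohort with ``timeseries_path`` filled in."""
    return Cohort(
        subjects=[
            replace(s, timeseries_path=paths.get(s.subject_id, s.timeseries_path))
            for s in cohort
        ],
        provenance=cohort.provenance,
    )
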