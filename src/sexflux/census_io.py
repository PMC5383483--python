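"""Data model and I/O for longitudinal sex-expression censuses.

A census is a long-format table with one row per individual x year.  Each
individual of a subdioecious population is scored every flowering season into
one of six expressed sexual categories -- female (``F``), male (``M``),
hermaphrodite with only perfect flowers (``H``), and hermaphrodites mixing
perfect flowers with pistillate (``HF``), staminate (``HM``) or both (``HFM``)
flower types -- or recorded as non-flowering (``NF``) / not observed (``NA``).
Optional covariates per row: stem diameter at breast height (DBH, cm) and the
relative photosynthetic photon flux density above the crown in the leafless
(``rppfd_winter``) and leafy (``rppfd_summer``) seasons, both fractions of the
open-site flux.

The CSV dialect is fixed (comma-separated, UTF-8, header
``plot_id,individual_id,year,sex,dbh_cm,rppfd_winter,rppfd_summer``; blank
cells for missing numerics) so that fixtures round-trip bit-identically.
Lines starting with ``#`` are comments and are skipped on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Expressed sexual categories, in canonical order.
EXPRESSED_STATES: tuple[str, ...] = ("F", "M", "H", "HF", "HM", "HFM")

#: States that never enter transition counts.
UNEXPRESSED_STATES: tuple[str, ...] = ("NF", "NA")

#: Valid census codes: the six categories, the pooled hermaphrodite code
#: (used by censuses recorded directly on the 3-state space, e.g. synthetic
#: pooled-mode censuses), and the two unexpressed codes.
ALL_STATES: tuple[str, ...] = EXPRESSED_STATES + ("HALL",) + UNEXPRESSED_STATES

#: Pooled 3-state space used for the Markov analysis.
POOLED_STATES: tuple[str, ...] = ("F", "M", "HALL")

#: Total, surjective map from expressed states onto the pooled space
#: (every hermaphrodite category collapses to ``HALL``; idempotent on
#: already-pooled records).
POOL_TO_HALL: Mapping[str, str] = {
    "F": "F",
    "M": "M",
    "H": "HALL",
    "HF": "HALL",
    "HM": "HALL",
    "HFM": "HALL",
    "HALL": "HALL",
}

CENSUS_COLUMNS: tuple[str, ...] = (
    "plot_id",
    "individual_id",
    "year",
    "sex",
    "dbh_cm",
    "rppfd_winter",
    "rppfd_summer",
)

#: Fixed float format for all deterministic writers.
FLOAT_FORMAT = "%.6f"


class CensusValidationError(ValueError):
    """A census file or record violates the data model."""


def is_expressed(state: str) -> bool:
    """True for expressed sexual categories (incl. pooled HALL), False for NF/NA."""
    return state in ALL_STATES and state not in UNEXPRESSED_STATES


@dataclass(frozen=True)
class CensusRecord:
    """One individual-year observation."""

    plot_id: str
    individual_id: str
    year: int
    state: str
    dbh: float | None = None
    rppfd_winter: float | None = None
    rppfd_summer: float | None = None

    def __post_init__(self) -> None:
        if self.state not in ALL_STATES:
            raise CensusValidationError(
                f"unknown sex code {self.state!r} for individual "
                f"{self.individual_id!r}, year {self.year}"
            )
        if self.dbh is not None and self.dbh < 0:
            raise CensusValidationError(
                f"negative DBH for individual {self.individual_id!r}, year {self.year}"
            )
        for name in ("rppfd_winter", "rppfd_summer"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise CensusValidationError(
                    f"{name}={value} outside [0, 1] for individual "
                    f"{self.individual_id!r}, year {self.year}"
                )


@dataclass(frozen=True)
class Trajectory:
    """Year-ordered sex-expression history of one individual.

    NF/NA observations are retained; downstream stages decide whether a
    non-flowering year breaks a transition pair or is skipped for pattern
    classification.
    """

    individual_id: str
    plot_id: str
    observations: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        years = [y for y, _ in self.observations]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise CensusValidationError(
                f"years not strictly increasing for individual {self.individual_id!r}"
            )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(y for y, _ in self.observations)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.observations)

    def expressed_observations(self) -> tuple[tuple[int, str], ...]:
        return tuple((y, s) for y, s in self.observations if is_expressed(s))


def _parse_optional_float(text: str, column: str, row_num: int) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise CensusValidationError(
            f"row {row_num}: cannot parse {column}={text!r} as a number"
        ) from exc


def read_census(path: str | Path) -> list[CensusRecord]:
    """Read and validate a census CSV.

    Raises :class:`CensusValidationError` naming the offending row for unknown
    sex codes, duplicate (individual, year) keys, rPPFD values outside [0, 1]
    or a malformed header.
    """
    path = Path(path)
    records: list[CensusRecord] = []
    seen: set[tuple[str, int]] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        rows = csv.reader(handle)
        header: Sequence[str] | None = None
        for row_num, row in enumerate(rows, start=1):
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = tuple(cell.strip() for cell in row)
                if header != CENSUS_COLUMNS:
                    raise CensusValidationError(
                        f"{path.name}: header {header!r} does not match "
                        f"expected columns {CENSUS_COLUMNS!r}"
                    )
                continue
            if len(row) != len(CENSUS_COLUMNS):
                raise CensusValidationError(
                    f"{path.name} row {row_num}: expected "
                    f"{len(CENSUS_COLUMNS)} fields, got {len(row)}"
                )
            plot_id, individual_id, year_s, sex, dbh_s, rw_s, rs_s = (
                cell.strip() for cell in row
            )
            try:
                year = int(year_s)
            except ValueError as exc:
                raise CensusValidationError(
                    f"{path.name} row {row_num}: cannot parse year {year_s!r}"
                ) from exc
            try:
                record = CensusRecord(
                    plot_id=plot_id,
                    individual_id=individual_id,
                    year=year,
                    state=sex,
                    dbh=_parse_optional_float(dbh_s, "dbh_cm", row_num),
                    rppfd_winter=_parse_optional_float(rw_s, "rppfd_winter", row_num),
                    rppfd_summer=_parse_optional_float(rs_s, "rppfd_summer", row_num),
                )
            except CensusValidationError as exc:
                raise CensusValidationError(f"{path.name} row {row_num}: {exc}") from exc
            key = (individual_id, year)
            if key in seen:
                raise CensusValidationError(
                    f"{path.name} row {row_num}: duplicate observation for "
                    f"individual {individual_id!r}, year {year}"
                )
            seen.add(key)
            records.append(record)
    if header is None:
        raise CensusValidationError(f"{path.name}: empty file, no header")
    return records


def _format_optional(value: float | None) -> str:
    return "" if value is None else FLOAT_FORMAT % value


def write_census(
    records: Iterable[CensusRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a census CSV in the fixed dialect (deterministic output)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(CENSUS_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.plot_id,
                    rec.individual_id,
                    rec.year,
                    rec.state,
                    _format_optional(rec.dbh),
                    _format_optional(rec.rppfd_winter),
                    _format_optional(rec.rppfd_summer),
                ]
            )


def build_trajectories(records: Iterable[CensusRecord]) -> list[Trajectory]:
    """Group validated records into one year-sorted trajectory per individual.

    The multiset of observations is preserved: every record appears in exactly
    one trajectory.  Trajectories are returned sorted by individual id for
    deterministic downstream output.
    """
    by_individual: dict[str, list[CensusRecord]] = {}
    for rec in records:
        by_individual.setdefault(rec.individual_id, []).append(rec)
    trajectories = []
    for individual_id in sorted(by_individual):
        recs = sorted(by_individual[individual_id], key=lambda r: r.year)
        plot_ids = {r.plot_id for r in recs}
        if len(plot_ids) != 1:
            raise CensusValidationError(
                f"individual {individual_id!r} appears in multiple plots: "
                f"{sorted(plot_ids)}"
            )
        trajectories.append(
            Trajectory(
                individual_id=individual_id,
                plot_id=recs[0].plot_id,
                observations=tuple((r.year, r.state) for r in recs),
            )
        )
    return trajectories


def write_matrix(
    labels: Sequence[str],
    matrix: np.ndarray,
    path: str | Path,
    orientation: str = "rows-from",
) -> None:
    """Write a labelled square matrix as CSV.

    orientation="rows-from" stores the internal convention (rows = origin
    state).  orientation="paper" transposes on write so that *columns* are the
    origin ("previous year") state, the layout used in printed transition
    tables.
    """
    matrix = np.asarray(matrix)
    if orientation not in ("rows-from", "paper"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    out = matrix.T if orientation == "paper" else matrix
    integral = np.issubdtype(out.dtype, np.integer)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["state", *labels])
        for label, row in zip(labels, out):
            cells = [str(int(v)) if integral else FLOAT_FORMAT % v for v in row]
            writer.writerow([label, *cells])


def read_matrix(
    path: str | Path, orientation: str = "rows-from"
) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a labelled matrix CSV written by :func:`write_matrix`.

    The orientation argument states how the stored file is to be interpreted;
    reading a "paper"-oriented file with orientation="rows-from" therefore
    yields the transposed values.
    """
    if orientation not in ("rows-from", "paper"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        rows = [row for row in csv.reader(handle) if row and not row[0].startswith("#")]
    header = rows[0]
    labels = tuple(header[1:])
    values = np.array([[float(cell) for cell in row[1:]] for row in rows[1:]])
    if values.shape != (len(labels), len(labels)):
        raise CensusValidationError(f"{path.name}: matrix is not square")
    if np.allclose(values, np.round(values)):
        values = values.astype(int)
    if orientation == "paper":
        values = values.T
    return labels, values
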