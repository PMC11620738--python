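"""Data model and delimited-text I/O for cell-pair measurements and penetrance tables.

A *cell pair* is one mother cell's two daughters (proximal/distal) with their
nuclear fluorescence intensities and the signed focal-plane distance between
them.  A *penetrance record* is one (genotype, region) cell of a phenotype
table: the percentage of animals missing the structure and the sample size.

Files are plain UTF-8 delimited text (comma by default, tab accepted) with a
mandatory header row; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import RowValidationError, SchemaError

__all__ = [
    "LOG_BASE",
    "Cell",
    "Reporter",
    "Region",
    "CellPairMeasurement",
    "PhenotypeRecord",
    "log_ratio",
    "read_measurements",
    "write_measurements",
    "read_phenotypes",
    "write_phenotypes",
]

#: Default logarithm base for intensity ratios.  Any base works as long as the
#: same one is used for calibration, classification, and simulation; the
#: classification outcome is invariant to the choice.
LOG_BASE: float = 10.0

#: Max |pct - 100*count/n| (percentage points) tolerated between a printed
#: percentage and an explicit count: one-decimal rounding plus slack.
PCT_COUNT_TOLERANCE: float = 0.15


class Cell(str, Enum):
    """Which somatic gonadal precursor the pair descends from."""

    Z1 = "Z1"
    Z4 = "Z4"


class Reporter(str, Enum):
    """Fluorescent reporter identity.

    ``control_nls`` is the symmetric control used for depth calibration;
    ``pop1`` and ``sys1`` are polarity reporters.
    """

    control_nls = "control_nls"
    pop1 = "pop1"
    sys1 = "sys1"


class Region(str, Enum):
    anterior = "anterior"
    posterior = "posterior"


@dataclass(frozen=True)
class CellPairMeasurement:
    """One proximal/distal intensity pair with its focal-plane offset.

    ``z_distance_um`` is signed: proximal-daughter depth minus distal-daughter
    depth.  The unit is opaque but must be consistent between calibration and
    scoring.
    """

    animal_id: str
    genotype: str
    temperature_c: float
    cell: Cell
    reporter: Reporter
    intensity_proximal: float
    intensity_distal: float
    z_distance_um: float

    def __post_init__(self):
        object.__setattr__(self, "cell", Cell(self.cell))
        object.__setattr__(self, "reporter", Reporter(self.reporter))
        for name in ("intensity_proximal", "intensity_distal"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise RowValidationError(
                    f"{name} must be a finite positive number, got {v!r}"
                )
            object.__setattr__(self, name, v)
        object.__setattr__(self, "temperature_c", float(self.temperature_c))
        z = float(self.z_distance_um)
        if not math.isfinite(z):
            raise RowValidationError(f"z_distance_um must be finite, got {z!r}")
        object.__setattr__(self, "z_distance_um", z)

    def swapped(self) -> "CellPairMeasurement":
        """Return the measurement with proximal and distal roles exchanged."""
        return replace(
            self,
            intensity_proximal=self.intensity_distal,
            intensity_distal=self.intensity_proximal,
            z_distance_um=-self.z_distance_um,
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Penetrance of a missing-structure phenotype for one genotype and region."""

    genotype: str
    region: Region
    pct_missing: float
    n: int
    count_missing: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "region", Region(self.region))
        pct = float(self.pct_missing)
        if not 0.0 <= pct <= 100.0:
            raise RowValidationError(f"pct_missing must be in [0, 100], got {pct}")
        object.__setattr__(self, "pct_missing", pct)
        n = int(self.n)
        if n < 1:
            raise RowValidationError(f"n must be a positive integer, got {n}")
        object.__setattr__(self, "n", n)
        if self.count_missing is not None:
            c = int(self.count_missing)
            if not 0 <= c <= n:
                raise RowValidationError(
                    f"count_missing must be in [0, n={n}], got {c}"
                )
            object.__setattr__(self, "count_missing", c)
            # printed percent must be consistent with the explicit count
            if abs(pct - 100.0 * c / n) > PCT_COUNT_TOLERANCE:
                raise RowValidationError(
                    f"pct_missing {pct} inconsistent with count {c}/{n}"
                )


def log_ratio(m: CellPairMeasurement, base: float = LOG_BASE) -> float:
    """Observed log intensity ratio, proximal over distal.

    Antisymmetric under exchange of the two daughters:
    ``log_ratio(m.swapped()) == -log_ratio(m)``.
    """
    return math.log(m.intensity_proximal / m.intensity_distal, base)


MEASUREMENT_COLUMNS = (
    "animal_id",
    "genotype",
    "temperature_c",
    "cell",
    "reporter",
    "intensity_proximal",
    "intensity_distal",
    "z_distance_um",
)

PHENOTYPE_COLUMNS = ("genotype", "region", "pct_missing", "n")


def _open_rows(path: str | Path, delimiter: str | None):
    """Yield (line_number, row_dict) from a delimited file, skipping comments."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [
            (i, line)
            for i, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not lines:
        raise SchemaError(f"{path}: empty file (no header)")
    header_line = lines[0][1]
    if delimiter is None:
        delimiter = "\t" if "\t" in header_line else ","
    header = next(csv.reader([header_line], delimiter=delimiter))
    header = [h.strip() for h in header]
    for lineno, line in lines[1:]:
        values = next(csv.reader([line], delimiter=delimiter))
        yield lineno, header, dict(zip(header, (v.strip() for v in values)))


def _check_columns(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _read_header(path: str | Path, delimiter: str | None) -> list[str]:
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                delim = delimiter or ("\t" if "\t" in line else ",")
                return [h.strip() for h in next(csv.reader([line], delimiter=delim))]
    raise SchemaError(f"{path}: empty file (no header)")


def read_measurements(
    path: str | Path,
    delimiter: str | None = None,
    skip_invalid: bool = False,
) -> list[CellPairMeasurement]:
    """Read a measurement table, validating every row.

    Parameters
    ----------
    path
        Delimited text file with the measurement schema header.
    delimiter
        Explicit delimiter; auto-detected (tab vs comma) when ``None``.
    skip_invalid
        If True, rows violating invariants are dropped with a warning naming
        their line numbers instead of raising.

    Returns
    -------
    list of CellPairMeasurement in file order.
    """
    rows = list(_open_rows(path, delimiter))
    header = _read_header(path, delimiter) if not rows else rows[0][1]
    _check_columns(header, MEASUREMENT_COLUMNS, path)
    out: list[CellPairMeasurement] = []
    rejects: list[int] = []
    for lineno, _, row in rows:
        try:
            out.append(
                CellPairMeasurement(
                    animal_id=row["animal_id"],
                    genotype=row["genotype"],
                    temperature_c=float(row["temperature_c"]),
                    cell=row["cell"],
                    reporter=row["reporter"],
                    intensity_proximal=float(row["intensity_proximal"]),
                    intensity_distal=float(row["intensity_distal"]),
                    z_distance_um=float(row["z_distance_um"]),
                )
            )
        except (RowValidationError, ValueError) as exc:
            if skip_invalid:
                rejects.append(lineno)
            else:
                raise RowValidationError(
                    f"{path}: line {lineno}: {exc}", row_number=lineno
                ) from exc
    if rejects:
        warnings.warn(
            f"{path}: rejected {len(rejects)} invalid row(s) at line(s) "
            f"{', '.join(map(str, rejects))}",
            stacklevel=2,
        )
    return out


def write_measurements(
    records: Iterable[CellPairMeasurement],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write measurements in the canonical schema (round-trips with read)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(MEASUREMENT_COLUMNS)
        for m in records:
            writer.writerow(
                [
                    m.animal_id,
                    m.genotype,
                    repr(m.temperature_c),
                    m.cell.value,
                    m.reporter.value,
                    repr(m.intensity_proximal),
                    repr(m.intensity_distal),
                    repr(m.z_distance_um),
                ]
            )


def read_phenotypes(
    path: str | Path, delimiter: str | None = None
) -> list[PhenotypeRecord]:
    """Read a penetrance table (``genotype,region,pct_missing,n[,count_missing]``)."""
    rows = list(_open_rows(path, delimiter))
    header = _read_header(path, delimiter) if not rows else rows[0][1]
    _check_columns(header, PHENOTYPE_COLUMNS, path)
    out: list[PhenotypeRecord] = []
    for lineno, _, row in rows:
        try:
            count = row.get("count_missing", "")
            out.append(
                PhenotypeRecord(
                    genotype=row["genotype"],
                    region=row["region"],
                    pct_missing=float(row["pct_missing"]),
                    n=int(row["n"]),
                    count_missing=int(count) if count not in ("", None) else None,
                )
            )
        except (RowValidationError, ValueError) as exc:
            raise RowValidationError(
                f"{path}: line {lineno}: {exc}", row_number=lineno
            ) from exc
    return out


def write_phenotypes(
    records: Iterable[PhenotypeRecord],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(PHENOTYPE_COLUMNS + ("count_missing",))
        for r in records:
            writer.writerow(
                [
                    r.genotype,
                    r.region.value,
                    repr(r.pct_missing),
                    r.n,
                    "" if r.count_missing is None else r.count_missing,
                ]
            )
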