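"""Reading and writing the whitespace-delimited allele-count table.

The format is one row per sample with three (optionally four) columns:
sample identifier, reference-allele count, alternative-allele count, and an
optional ploidy (1 or 2, default 2).  Counts may be non-integer "effective"
counts, i.e. quality-weighted expected numbers of true observations.  Blank
lines and lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np

from .errors import ParseError, ValidationError

Source = Union[str, Path, IO[str]]

__all__ = ["CountRecord", "CountTable", "read_count_table", "write_count_table"]


@dataclass(frozen=True)
class CountRecord:
    """One sample's allele observations.

    Attributes
    ----------
    sample_id:
        Unique text label.
    ref_count:
        Number of reference-allele observations, ``l`` (non-negative real).
    alt_count:
        Number of alternative-allele observations, ``k - l``.
    ploidy:
        1 (hemizygous) or 2 (diploid).
    """

    sample_id: str
    ref_count: float
    alt_count: float
    ploidy: int = 2

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample identifier")
        if not (self.ref_count >= 0) or not (self.alt_count >= 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: counts must be non-negative, "
                f"got ref={self.ref_count}, alt={self.alt_count}"
            )
        if not (math.isfinite(self.ref_count) and math.isfinite(self.alt_count)):
            raise ValidationError(f"sample {self.sample_id!r}: counts must be finite")
        if self.ploidy not in (1, 2):
            raise ValidationError(
                f"sample {self.sample_id!r}: ploidy must be 1 or 2, got {self.ploidy}"
            )

    @property
    def total(self) -> float:
        """Total count ``k`` (derived, never stored separately)."""
        return self.ref_count + self.alt_count


@dataclass
class CountTable:
    """Ordered collection of :class:`CountRecord` with unique sample ids."""

    records: list[CountRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValidationError(f"duplicate sample identifier {rec.sample_id!r}")
            seen.add(rec.sample_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CountRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CountRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.records == other.records

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def ref_counts(self) -> np.ndarray:
        return np.array([r.ref_count for r in self.records], dtype=float)

    @property
    def alt_counts(self) -> np.ndarray:
        return np.array([r.alt_count for r in self.records], dtype=float)

    @property
    def totals(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def ploidies(self) -> np.ndarray:
        return np.array([r.ploidy for r in self.records], dtype=int)

    @classmethod
    def from_arrays(
        cls,
        sample_ids: Iterable[str],
        ref_counts: Iterable[float],
        alt_counts: Iterable[float],
        ploidies: Iterable[int] | int = 2,
    ) -> "CountTable":
        ids = list(sample_ids)
        if isinstance(ploidies, int):
            ploidies = [ploidies] * len(ids)
        recs = [
            CountRecord(s, float(l), float(a), int(m))
            for s, l, a, m in zip(ids, ref_counts, alt_counts, list(ploidies), strict=True)
        ]
        return cls(recs)


def concat_tables(a: CountTable, b: CountTable) -> CountTable:
    """Concatenate two tables, disambiguating colliding sample ids."""
    ids_a = set(a.sample_ids)
    recs = list(a.records)
    for rec in b.records:
        if rec.sample_id in ids_a:
            rec = CountRecord(rec.sample_id + "_b", rec.ref_count, rec.alt_count, rec.ploidy)
        recs.append(rec)
    return CountTable(recs)


def _parse_count(text: str, what: str, line_number: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"cannot parse {what} count {text!r}", line_number) from None
    return value


def read_count_table(source: Source) -> CountTable:
    """Parse a 3/4-column count table from a path or open text stream.

    Fields are separated by any run of whitespace; blank lines and ``#``
    comments are skipped.  Malformed or invalid lines raise with the
    offending line number.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return _read_lines(fh)
    return _read_lines(source)


def _read_lines(lines: Iterable[str]) -> CountTable:
    records: list[CountRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3 or len(fields) > 4:
            raise ParseError(
                f"expected 3 or 4 whitespace-separated fields, got {len(fields)}", lineno
            )
        sample_id = fields[0]
        if sample_id in seen:
            raise ValidationError(f"line {lineno}: duplicate sample identifier {sample_id!r}")
        ref = _parse_count(fields[1], "reference", lineno)
        alt = _parse_count(fields[2], "alternative", lineno)
        if len(fields) == 4:
            try:
                ploidy = int(fields[3])
            except ValueError:
                raise ParseError(f"cannot parse ploidy {fields[3]!r}", lineno) from None
        else:
            ploidy = 2
        try:
            rec = CountRecord(sample_id, ref, alt, ploidy)
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
        seen.add(sample_id)
        records.append(rec)
    return CountTable(records)


def _format_count(x: float) -> str:
    # 12 significant digits round-trips every count the program itself emits
    return format(x, ".12g")


def write_count_table(table: CountTable, sink: Source) -> None:
    """Write a table back to the tab-delimited 3/4-column text format.

    The ploidy column is emitted only when some record is not diploid, so the
    common all-diploid case keeps the minimal 3-column shape.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "wt", encoding="utf-8") as fh:
            write_count_table(table, fh)
        return
    four_cols = any(r.ploidy != 2 for r in table)
    for rec in table:
        cols = [rec.sample_id, _format_count(rec.ref_count), _format_count(rec.alt_count)]
        if four_cols:
            cols.append(str(rec.ploidy))
        sink.write("\t".join(cols) + "\n")
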