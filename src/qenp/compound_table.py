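"""GC-MS compound composition tables and Kovats retention indices.

A composition table is one row per chromatographic peak: a short stable
identifier, the compound name, an optional CAS registry string, the
retention time in minutes, and the peak's percent of total content.
Retention indices are computed against an n-alkane ladder by linear
interpolation between the bracketing alkanes:

    RI = 100*n + 100 * (tR(x) - tR(n)) / (tR(n+1) - tR(n))

for tR(n) <= tR(x) <= tR(n+1). An analyte eluting exactly at an alkane's
retention time gets RI = 100*n; retention times outside the ladder span are
an error (no extrapolation).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from qenp.errors import FormatError, OutOfRangeError, ValidationError

COMPOUND_COLUMNS = ("compound_id", "name", "cas", "retention_time_min", "pct_total")
LADDER_COLUMNS = ("carbon_number", "retention_time_min")

#: carbon-number range the ladder accepts (C8..C40 n-alkanes)
CARBON_MIN = 8
CARBON_MAX = 40

_PCT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Compound:
    """One GC-MS peak with identity, retention data, and relative content."""

    compound_id: str
    name: str
    cas: str
    retention_time: float  # minutes
    rel_content_pct: float  # percent of total (the R_i factor)
    retention_index: float | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not (self.retention_time > 0):
            raise ValidationError(
                f"compound {self.compound_id!r}: retention_time must be > 0, "
                f"got {self.retention_time}"
            )
        if not (0.0 <= self.rel_content_pct <= 100.0):
            raise ValidationError(
                f"compound {self.compound_id!r}: rel_content_pct must lie in "
                f"[0, 100], got {self.rel_content_pct}"
            )


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time) pairs.

    Carbon numbers and retention times must both be strictly increasing;
    carbon numbers are restricted to the C8-C40 range.
    """

    entries: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        entries = tuple((int(c), float(t)) for c, t in self.entries)
        object.__setattr__(self, "entries", entries)
        for carbon, _rt in entries:
            if not (CARBON_MIN <= carbon <= CARBON_MAX):
                raise ValidationError(
                    f"alkane carbon number {carbon} outside supported range "
                    f"[{CARBON_MIN}, {CARBON_MAX}]"
                )
        carbons = [c for c, _ in entries]
        rts = [t for _, t in entries]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValidationError("alkane carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError("alkane retention times must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        if len(self.entries) < 2:
            raise ValidationError("ladder needs at least 2 alkanes")
        return self.entries[0][1], self.entries[-1][1]


def _sniff_delimiter(path: Path, dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect == "auto":
        with open(path, newline="") as fh:
            header = fh.readline()
        return "\t" if "\t" in header else ","
    raise ValueError(f"unknown dialect {dialect!r}; expected tsv, csv, or auto")


def _read_rows(path: str | Path, dialect: str, required: Sequence[str]) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    delim = _sniff_delimiter(path, dialect)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        names = [n.strip() for n in reader.fieldnames]
        for col in required:
            if col not in names:
                raise FormatError(f"{path}: missing required column {col!r}")
        rows = []
        for row in reader:
            rows.append({(k.strip() if k else k): v for k, v in row.items()})
        return rows


def parse_compound_table(path: str | Path, dialect: str = "auto") -> list[Compound]:
    """Parse a composition table into ``Compound`` records, in file order.

    Parameters
    ----------
    path:
        TSV or CSV file with header columns ``compound_id, name, cas,
        retention_time_min, pct_total``. A blank CAS field is allowed.
    dialect:
        ``"tsv"``, ``"csv"``, or ``"auto"`` (sniff the header line).

    Raises
    ------
    FormatError
        Missing file or missing required column.
    ValidationError
        Duplicate compound_id, negative percent, or non-positive retention
        time. The combined percent total may not exceed 100 (small float
        tolerance).
    """
    rows = _read_rows(path, dialect, COMPOUND_COLUMNS)
    compounds: list[Compound] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        cid = (row["compound_id"] or "").strip()
        if cid in seen:
            raise ValidationError(f"{path}:{i}: duplicate compound_id {cid!r}")
        seen.add(cid)
        try:
            rt = float(row["retention_time_min"])
            pct = float(row["pct_total"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{i}: non-numeric field ({exc})") from exc
        compounds.append(
            Compound(
                compound_id=cid,
                name=(row["name"] or "").strip(),
                cas=(row["cas"] or "").strip(),
                retention_time=rt,
                rel_content_pct=pct,
            )
        )
    total = sum(c.rel_content_pct for c in compounds)
    if total > 100.0 + _PCT_SUM_TOL:
        raise ValidationError(
            f"{path}: pct_total column sums to {total:.6f} > 100"
        )
    return compounds


def parse_alkane_ladder(path: str | Path, dialect: str = "auto") -> AlkaneLadder:
    """Parse an n-alkane ladder TSV (``carbon_number, retention_time_min``)."""
    rows = _read_rows(path, dialect, LADDER_COLUMNS)
    entries = []
    for i, row in enumerate(rows, start=2):
        try:
            entries.append(
                (int(row["carbon_number"]), float(row["retention_time_min"]))
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{i}: non-numeric field ({exc})") from exc
    return AlkaneLadder(entries=tuple(entries))


def compute_retention_index(rt_x: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index of an analyte at retention time ``rt_x``.

    Linear interpolation between the bracketing alkanes C_n and C_{n+1}:
    ``100*n + 100 * (rt_x - tR(n)) / (tR(n+1) - tR(n))``. An exact match
    with an alkane retention time returns ``100 * carbon`` exactly.

    Raises
    ------
    OutOfRangeError
        ``rt_x`` outside the ladder's retention-time span.
    """
    lo, hi = ladder.span
    if not (lo <= rt_x <= hi):
        raise OutOfRangeError(
            f"retention time {rt_x} outside ladder span [{lo}, {hi}]"
        )
    entries = ladder.entries
    # exact alkane hit: return the fixed point without interpolating
    for carbon, rt in entries:
        if rt_x == rt:
            return 100.0 * carbon
    for (c_lo, t_lo), (c_hi, t_hi) in zip(entries, entries[1:]):
        if t_lo < rt_x < t_hi:
            frac = (rt_x - t_lo) / (t_hi - t_lo)
            # ladder carbons need not be consecutive; scale by the gap so
            # RI stays continuous across a C_n..C_m bracket
            return 100.0 * c_lo + 100.0 * (c_hi - c_lo) * frac
    raise OutOfRangeError(f"retention time {rt_x} not bracketed by ladder")  # pragma: no cover


def annotate_retention_indices(
    compounds: Iterable[Compound], ladder: AlkaneLadder
) -> list[Compound]:
    """Fill ``retention_index`` for each compound; order preserved.

    Raises ``OutOfRangeError`` naming the offending compound if any
    retention time falls outside the ladder span.
    """
    out = []
    for comp in compounds:
        try:
            ri = compute_retention_index(comp.retention_time, ladder)
        except OutOfRangeError as exc:
            raise OutOfRangeError(
                f"compound {comp.compound_id!r} ({comp.name}): {exc}"
            ) from exc
        out.append(replace(comp, retention_index=ri))
    return out


def builtin_composition_path() -> Path:
    """Path of the packaged 19-compound GC-MS composition table."""
    ref = resources.files("qenp.data").joinpath("compound_composition.tsv")
    return Path(str(ref))


def load_builtin_composition() -> list[Compound]:
    """Parse the packaged 19-compound composition table."""
    return parse_compound_table(builtin_composition_path(), dialect="tsv")


def write_compound_table(compounds: Sequence[Compound], path: str | Path) -> None:
    """Write compounds back out as TSV, including RI when present."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(COMPOUND_COLUMNS) + ["retention_index"])
        for c in compounds:
            ri = "" if c.retention_index is None else f"{c.retention_index:.4f}"
            writer.writerow(
                [c.compound_id, c.name, c.cas, c.retention_time,
                 c.rel_content_pct, ri]
            )


def total_content(compounds: Iterable[Compound]) -> float:
    return math.fsum(c.rel_content_pct for c in compounds)
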