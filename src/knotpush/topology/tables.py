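"""Bundled knot tables: identification, handedness and group membership.

Two TSV assets ship with the package (regenerable by
``scripts/build_knot_tables.py``):

* ``identify.tsv`` — one row per identifiable prime knot with its Jones
  polynomial.  Every polynomial is computed and verified by this package's
  own pipeline from constructions with provable knot type (rational 4-plats
  checked against determinant and Jones span, torus parametrisations); the
  stored form of each chiral knot is its positive-writhe ("right-handed")
  variant, so a mirror match means a left-handed knot.
* ``census.tsv`` — names and group flags (amphichiral / torus / twist) of
  all 801 prime knots up to 11 crossings; used for census statistics and
  group classification, it carries no polynomials.

Knots whose Jones polynomial is not in the identification table are
reported as "?" (the unidentified bucket), with the simplified diagram's
crossing count as a complexity lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .laurent import LaurentPoly

__all__ = [
    "KnotRecord",
    "KnotTables",
    "load_tables",
    "identify_knot",
    "handedness",
    "classify_groups",
    "census",
    "UNKNOT",
    "UNIDENTIFIED",
]

UNKNOT = "0_1"
UNIDENTIFIED = "?"

#: handedness is tabulated only up to this many crossings
MAX_HANDEDNESS_CROSSINGS = 9


@dataclass(frozen=True)
class KnotRecord:
    """One identifiable knot: table-diagram polynomial and chirality."""

    name: str
    crossing_number: int
    jones: LaurentPoly
    handedness: str          # "right" (stored form) or "amphichiral"
    determinant: int


@dataclass(frozen=True)
class CensusRow:
    name: str
    crossing_number: int
    amphichiral: bool
    torus: bool
    twist: bool


class KnotTables:
    """Loaded identification + census tables with lookup indices."""

    def __init__(self, records: list[KnotRecord], rows: list[CensusRow]):
        self.records = {r.name: r for r in records}
        self.census_rows = {r.name: r for r in rows}
        self._by_jones: dict[str, tuple[str, bool]] = {}
        for r in records:
            key = r.jones.key()
            mkey = r.jones.mirror().key()
            self._by_jones.setdefault(key, (r.name, False))
            if mkey != key:
                self._by_jones.setdefault(mkey, (r.name, True))

    def lookup(self, poly: LaurentPoly) -> tuple[str, bool] | None:
        return self._by_jones.get(poly.key())


def _read_tsv(filename: str) -> list[list[str]]:
    path = resources.files("knotpush.tables").joinpath(filename)
    lines = path.read_text().splitlines()
    rows = []
    for line in lines:
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    if not rows:
        raise RuntimeError(f"table asset {filename} is empty or missing")
    return rows[1:]  # drop header


@lru_cache(maxsize=1)
def load_tables() -> KnotTables:
    records = [
        KnotRecord(
            name=row[0],
            crossing_number=int(row[1]),
            jones=LaurentPoly.from_key(row[2]),
            handedness=row[3],
            determinant=int(row[4]),
        )
        for row in _read_tsv("identify.tsv")
    ]
    rows = [
        CensusRow(row[0], int(row[1]), row[2] == "1", row[3] == "1",
                  row[4] == "1")
        for row in _read_tsv("census.tsv")
    ]
    return KnotTables(records, rows)


def identify_knot(
    poly: LaurentPoly, tables: KnotTables | None = None
) -> tuple[str, bool]:
    """Match a Jones polynomial against the table.

    Returns (name, mirror flag); V = 1 gives the unknot, an exact match the
    table name with mirror False, a match of V(1/t) the name with mirror
    True, and anything else ("?", False).
    """
    tables = tables or load_tables()
    if poly == LaurentPoly.one():
        return UNKNOT, False
    hit = tables.lookup(poly)
    if hit is None:
        return UNIDENTIFIED, False
    return hit


def handedness(
    name: str, mirror: bool, tables: KnotTables | None = None
) -> str:
    """Chirality of an identified knot: left / right / amphichiral / undetermined.

    The stored table form of every chiral knot is the right-handed
    (positive-writhe) variant, so the mirror flag flips right to left.
    Handedness is tabulated only up to 9 crossings.
    """
    tables = tables or load_tables()
    if name == UNKNOT:
        return "amphichiral"
    rec = tables.records.get(name)
    if rec is None or rec.crossing_number > MAX_HANDEDNESS_CROSSINGS:
        return "undetermined"
    if rec.handedness == "amphichiral":
        return "amphichiral"
    return ("left" if mirror else "right")


def classify_groups(
    name: str, tables: KnotTables | None = None
) -> frozenset[str]:
    """Subset of {torus, twist, amphichiral} the named knot belongs to."""
    tables = tables or load_tables()
    row = tables.census_rows.get(name)
    if row is None:
        return frozenset()
    out = set()
    if row.amphichiral:
        out.add("amphichiral")
    if row.torus:
        out.add("torus")
    if row.twist:
        out.add("twist")
    return frozenset(out)


def census(tables: KnotTables | None = None) -> dict:
    """Totals per crossing number and per group over the bundled census."""
    tables = tables or load_tables()
    per_crossing: dict[int, int] = {}
    groups = {"amphichiral": 0, "torus": 0, "twist": 0}
    for row in tables.census_rows.values():
        per_crossing[row.crossing_number] = (
            per_crossing.get(row.crossing_number, 0) + 1
        )
        if row.amphichiral:
            groups["amphichiral"] += 1
        if row.torus:
            groups["torus"] += 1
        if row.twist:
            groups["twist"] += 1
    return {
        "total": sum(per_crossing.values()),
        "per_crossing_number": dict(sorted(per_crossing.items())),
        "groups": groups,
    }


def crossing_number_of(name: str, tables: KnotTables | None = None) -> int | None:
    """Crossing number parsed from the census (None for '?' or unknown)."""
    tables = tables or load_tables()
    if name == UNKNOT:
        return 0
    row = tables.census_rows.get(name)
    return row.crossing_number if row else None
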