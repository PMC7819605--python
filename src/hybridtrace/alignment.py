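"""Aligned sequence records and variable-site matrices.

This module is the data backbone of the package: it reads and validates
aligned nucleotide sequences (aligned FASTA), reads and writes the
variable-site table dialect used for published character matrices, and
extracts variable columns from an alignment.

Coordinates are 1-based alignment positions throughout the public
interface, matching the convention of published site tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import (
    AlignmentError,
    AlphabetError,
    FormatError,
    InsufficientDataError,
)

#: Unambiguous states (gap is a first-class fifth state downstream).
CANONICAL_STATES = "ACGT-"
#: IUPAC nucleotide ambiguity letters admitted for direct-sequenced samples.
IUPAC_AMBIGUITY = "RYSWKMBDHVN"
PERMITTED_ALPHABET = frozenset(CANONICAL_STATES + IUPAC_AMBIGUITY)

#: The published tables print a typographic minus for gaps; accept both.
_GAP_ALIASES = {"-", "−", "–"}


def _canonical_residues(raw: str, record_id: str) -> str:
    """Uppercase, normalise gap glyphs, and validate the alphabet."""
    out = []
    for col, ch in enumerate(raw, start=1):
        c = "-" if ch in _GAP_ALIASES else ch.upper()
        if c not in PERMITTED_ALPHABET:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {ch!r} at column {col}"
            )
        out.append(c)
    return "".join(out)


@dataclass(frozen=True)
class AlignedRecord:
    """One aligned sequence with an accession id and a taxon-group tag.

    Parameters
    ----------
    id
        Unique accession/sample label.
    group
        Taxon-group tag, e.g. ``parent_a``, ``parent_b``, ``hybrid``,
        ``mixture_control`` or any user label. May be empty.
    residues
        Aligned residues over {A,C,G,T,-} plus IUPAC ambiguity letters.
    """

    id: str
    group: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _canonical_residues(self.residues, self.id)
        )
        if not self.residues:
            raise AlignmentError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def state_at(self, position: int) -> str:
        """State at a 1-based alignment position."""
        return self.residues[position - 1]


def validate_alignment(records: Sequence[AlignedRecord]) -> None:
    """Check equal lengths and unique ids; raise :class:`AlignmentError`."""
    if not records:
        raise AlignmentError("empty alignment")
    length = len(records[0])
    for rec in records:
        if len(rec) != length:
            raise AlignmentError(
                f"ragged alignment: {rec.id!r} has length {len(rec)}, "
                f"expected {length}"
            )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate record ids: {dupes}")


def read_alignment(path: str | Path, groups: dict[str, str] | None = None) -> list[AlignedRecord]:
    """Read an aligned FASTA file into validated :class:`AlignedRecord` objects.

    The group tag is taken, in order of preference, from the *groups*
    mapping (id -> tag) or from the second whitespace-separated token of
    the FASTA description line; otherwise it is empty. File order is
    preserved.
    """
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        tokens = seq_rec.description.split()
        desc_group = tokens[1] if len(tokens) > 1 else ""
        group = (groups or {}).get(seq_rec.id, desc_group)
        records.append(AlignedRecord(seq_rec.id, group, str(seq_rec.seq)))
    validate_alignment(records)
    return records


def write_alignment(records: Sequence[AlignedRecord], path: str | Path) -> None:
    """Write aligned FASTA (wrapped at 80 characters; group in the description)."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.group) for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


@dataclass(frozen=True)
class SiteRow:
    """One row of a :class:`SiteMatrix`: an accession/haplotype and its states."""

    id: str
    group: str
    states: str
    count: int = 1


@dataclass
class SiteMatrix:
    """Taxa x labeled alignment positions with single-character states.

    The in-memory form of a published variable-site table: an ordered set
    of strictly increasing 1-based position labels and one row per
    accession or collapsed haplotype, optionally with a multiplicity
    (clone count).
    """

    positions: tuple[int, ...]
    rows: list[SiteRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = tuple(int(p) for p in self.positions)
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise FormatError(
                f"position labels must be strictly increasing: {self.positions}"
            )
        if any(p < 1 for p in self.positions):
            raise FormatError("position labels are 1-based (must be >= 1)")
        seen: set[str] = set()
        for row in self.rows:
            if row.id in seen:
                raise FormatError(f"duplicate row id {row.id!r}")
            seen.add(row.id)
            self._check_row(row)

    def _check_row(self, row: SiteRow) -> None:
        if len(row.states) != len(self.positions):
            raise FormatError(
                f"row {row.id!r}: {len(row.states)} states for "
                f"{len(self.positions)} positions"
            )
        if row.count < 1:
            raise FormatError(f"row {row.id!r}: multiplicity must be >= 1")
        _canonical_residues(row.states, row.id)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        positions: Iterable[int],
        rows: Iterable[tuple[str, str, str] | tuple[str, str, str, int]],
    ) -> "SiteMatrix":
        """Build from (id, group, states[, count]) tuples."""
        site_rows = []
        for tup in rows:
            if len(tup) == 3:
                rid, group, states = tup  # type: ignore[misc]
                count = 1
            else:
                rid, group, states, count = tup  # type: ignore[misc]
            site_rows.append(
                SiteRow(rid, group, _canonical_residues(states, rid), int(count))
            )
        return cls(tuple(positions), site_rows)

    # -- access ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[SiteRow]:
        return iter(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    @property
    def groups(self) -> list[str]:
        return sorted({r.group for r in self.rows})

    def row(self, rid: str) -> SiteRow:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def group_rows(self, tag: str) -> list[SiteRow]:
        return [r for r in self.rows if r.group == tag]

    def subset(self, ids: Sequence[str]) -> "SiteMatrix":
        """Rows restricted to *ids*, in the order given."""
        return SiteMatrix(self.positions, [self.row(i) for i in ids])

    def expand(self) -> "SiteMatrix":
        """Replicate each row by its multiplicity (ids suffixed ``.1``, ``.2``...)."""
        rows = []
        for r in self.rows:
            if r.count == 1:
                rows.append(r)
            else:
                rows.extend(
                    SiteRow(f"{r.id}.{k}", r.group, r.states, 1)
                    for k in range(1, r.count + 1)
                )
        return SiteMatrix(self.positions, rows)

    def column(self, position: int) -> list[str]:
        """States of one labeled column, one entry per row (multiplicity ignored)."""
        j = self.positions.index(position)
        return [r.states[j] for r in self.rows]


# -- TSV dialect ---------------------------------------------------------
#
# Header:  id <TAB> group <TAB> count <TAB> <pos1> <TAB> <pos2> ...
# The count column is optional; when the third header field parses as an
# integer it is taken to be the first position label instead.


def read_site_matrix(path: str | Path) -> SiteMatrix:
    """Read the site-matrix TSV dialect (see module docs)."""
    text = Path(path).read_text()
    return _parse_site_matrix(text, str(path))


def _parse_site_matrix(text: str, source: str) -> SiteMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{source}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "id" or header[1] != "group":
        raise FormatError(f"{source}: header must start with 'id\\tgroup'")
    has_count = header[2] == "count"
    pos_fields = header[3:] if has_count else header[2:]
    try:
        positions = tuple(int(p) for p in pos_fields)
    except ValueError as exc:
        raise FormatError(f"{source}: non-integer position label: {exc}") from exc
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise FormatError(f"{source}: position labels not strictly increasing")
    if len(lines) == 1:
        raise FormatError(f"{source}: no data rows")
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        expected = 3 + len(positions) if has_count else 2 + len(positions)
        if len(fields) != expected:
            raise FormatError(
                f"{source}: row {fields[0]!r} has {len(fields)} fields, "
                f"expected {expected}"
            )
        rid, group = fields[0], fields[1]
        count = int(fields[2]) if has_count else 1
        states = "".join(fields[3:] if has_count else fields[2:])
        rows.append(SiteRow(rid, group, _canonical_residues(states, rid), count))
    return SiteMatrix(positions, rows)


def write_site_matrix(matrix: SiteMatrix, path: str | Path) -> None:
    """Write the TSV dialect; round-trips bit-exactly through :func:`read_site_matrix`."""
    Path(path).write_text(format_site_matrix(matrix))


def format_site_matrix(matrix: SiteMatrix) -> str:
    buf = io.StringIO()
    buf.write("id\tgroup\tcount\t" + "\t".join(str(p) for p in matrix.positions) + "\n")
    for r in matrix.rows:
        buf.write(f"{r.id}\t{r.group}\t{r.count}\t" + "\t".join(r.states) + "\n")
    return buf.getvalue()


# -- variable-site extraction --------------------------------------------


def extract_variable_sites(
    records: Sequence[AlignedRecord], respect_iupac: bool = True
) -> SiteMatrix:
    """Columns of an alignment where at least two distinct states occur.

    With ``respect_iupac=True`` (default) every IUPAC ambiguity letter is
    its own state, so a direct-sequenced heterozygote makes a column
    variable. With ``respect_iupac=False`` ambiguity letters are ignored
    when counting distinct states (treated as missing), which restricts
    the scan to unambiguous variation.

    Position labels of the returned matrix are 1-based alignment
    coordinates.
    """
    if len(records) < 2:
        raise InsufficientDataError(
            "variable-site extraction needs at least two records"
        )
    validate_alignment(records)
    length = len(records[0])
    variable: list[int] = []
    for j in range(length):
        states = {rec.residues[j] for rec in records}
        if not respect_iupac:
            states -= set(IUPAC_AMBIGUITY)
        if len(states) >= 2:
            variable.append(j + 1)
    rows = [
        SiteRow(rec.id, rec.group, "".join(rec.residues[p - 1] for p in variable), 1)
        for rec in records
    ]
    return SiteMatrix(tuple(variable), rows)
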