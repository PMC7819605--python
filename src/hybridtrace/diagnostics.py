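"""Diagnostic fixed differences between parental species and hybrid additivity.

A *fixed difference* is an alignment column at which every sampled
accession of species A shares one state, every accession of species B
shares a different state, and the two states differ. Fixation is strict:
any within-group polymorphism, missing data, or ambiguity code excludes
the column. Columns where exactly one parent carries the gap are
single-base indel sites; each gap column is an independent indel (a
contiguous run of k gap columns counts as k single-base indel sites).

A direct-sequenced F1 hybrid is *additive* when it shows the IUPAC union
of the two parental bases at every diagnostic substitution site — the
symbolic counterpart of superimposed chromatogram peaks. Indel
heterozygosity frame-shifts a Sanger trace downstream of the gap, so
indel sites cannot be scored from a direct read and are reported
not-assessable rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import pandas as pd
from Bio.Data import IUPACData

from ._errors import DataQualityError, GroupingError
from .alignment import IUPAC_AMBIGUITY, AlignedRecord, SiteMatrix

Kind = Literal["substitution", "indel"]

#: base-set (frozenset) -> IUPAC letter, e.g. {A,G} -> R
_UNION_TO_IUPAC = {
    frozenset(bases): letter
    for letter, bases in IUPACData.ambiguous_dna_values.items()
    if len(bases) > 1
}

NOT_ASSESSABLE = None


def expected_additive_code(state_a: str, state_b: str) -> str | None:
    """IUPAC ambiguity letter for the union of two parental bases.

    Returns ``None`` (not assessable) if either state is a gap; returns
    the base itself if the two states are equal.
    """
    if state_a == "-" or state_b == "-":
        return NOT_ASSESSABLE
    if state_a in IUPAC_AMBIGUITY or state_b in IUPAC_AMBIGUITY:
        raise DataQualityError(
            f"expected_additive_code needs unambiguous bases, got "
            f"{state_a!r}/{state_b!r}"
        )
    if state_a == state_b:
        return state_a
    return _UNION_TO_IUPAC[frozenset((state_a, state_b))]


@dataclass(frozen=True)
class DiagnosticSite:
    """One fixed interspecific difference.

    ``expected_additive`` is the IUPAC union code for substitution sites
    and ``None`` for indel sites (not assessable from a direct read).
    """

    position: int
    state_a: str
    state_b: str
    kind: Kind
    expected_additive: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.state_a == self.state_b:
            raise ValueError("diagnostic site states must differ")
        is_indel = (self.state_a == "-") != (self.state_b == "-")
        if is_indel != (self.kind == "indel"):
            raise ValueError(
                f"kind {self.kind!r} inconsistent with states "
                f"{self.state_a}/{self.state_b} at {self.position}"
            )

    def swapped(self) -> "DiagnosticSite":
        return DiagnosticSite(
            self.position, self.state_b, self.state_a, self.kind,
            self.expected_additive,
        )


class DiagnosticSiteSet:
    """Ordered collection of diagnostic sites between two parental groups."""

    def __init__(self, sites: Sequence[DiagnosticSite], group_a: str, group_b: str):
        self.sites = list(sites)
        self.group_a = group_a
        self.group_b = group_b

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[DiagnosticSite]:
        return iter(self.sites)

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.sites]

    @property
    def substitutions(self) -> list[DiagnosticSite]:
        return [s for s in self.sites if s.kind == "substitution"]

    @property
    def indels(self) -> list[DiagnosticSite]:
        return [s for s in self.sites if s.kind == "indel"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [s.position for s in self.sites],
                "state_a": [s.state_a for s in self.sites],
                "state_b": [s.state_b for s in self.sites],
                "kind": [s.kind for s in self.sites],
                "expected_additive": [
                    s.expected_additive if s.expected_additive else "."
                    for s in self.sites
                ],
            }
        )


def fixed_differences(
    matrix: SiteMatrix, group_a: str, group_b: str
) -> DiagnosticSiteSet:
    """Positions fixed-different between *group_a* and *group_b* rows.

    Strict definition: all group-A rows uniform for one state, all
    group-B rows uniform for another, states distinct. Symmetric up to an
    A/B state swap. Ambiguity codes inside a parental row are a data
    quality error (parental accessions are expected to be homozygous).
    """
    rows_a = matrix.group_rows(group_a)
    rows_b = matrix.group_rows(group_b)
    if not rows_a:
        raise GroupingError(f"group {group_a!r} absent from matrix")
    if not rows_b:
        raise GroupingError(f"group {group_b!r} absent from matrix")
    for row in (*rows_a, *rows_b):
        for pos, st in zip(matrix.positions, row.states):
            if st in IUPAC_AMBIGUITY:
                raise DataQualityError(
                    f"ambiguity code {st!r} in parental row {row.id!r} "
                    f"at position {pos}"
                )
    sites = []
    for j, pos in enumerate(matrix.positions):
        states_a = {r.states[j] for r in rows_a}
        states_b = {r.states[j] for r in rows_b}
        if len(states_a) != 1 or len(states_b) != 1:
            continue
        (sa,) = states_a
        (sb,) = states_b
        if sa == sb:
            continue
        kind: Kind = "indel" if (sa == "-") != (sb == "-") else "substitution"
        code = expected_additive_code(sa, sb) if kind == "substitution" else None
        sites.append(DiagnosticSite(pos, sa, sb, kind, code))
    return DiagnosticSiteSet(sites, group_a, group_b)


Verdict = Literal[
    "additive", "matches_a_only", "matches_b_only", "other", "not_assessable"
]


@dataclass
class AdditivityReport:
    """Per-site additivity verdicts for one direct-sequenced sample.

    ``overall_additive`` is true iff every assessable (substitution)
    site shows the IUPAC union of the parental bases.
    """

    sample_id: str
    verdicts: dict[int, Verdict]

    @property
    def overall_additive(self) -> bool:
        assessable = [v for v in self.verdicts.values() if v != "not_assessable"]
        return bool(assessable) and all(v == "additive" for v in assessable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "position": list(self.verdicts),
                "verdict": list(self.verdicts.values()),
            }
        )


def check_additivity(
    sample: AlignedRecord, sites: DiagnosticSiteSet
) -> AdditivityReport:
    """Score a direct-sequenced sample at the diagnostic sites.

    *sample* must span all site positions (1-based coordinates index its
    residues). Indel sites are always not-assessable in direct mode.
    """
    verdicts: dict[int, Verdict] = {}
    for site in sites:
        if site.kind == "indel":
            verdicts[site.position] = "not_assessable"
            continue
        state = sample.state_at(site.position)
        if state == site.expected_additive:
            verdicts[site.position] = "additive"
        elif state == site.state_a:
            verdicts[site.position] = "matches_a_only"
        elif state == site.state_b:
            verdicts[site.position] = "matches_b_only"
        else:
            verdicts[site.position] = "other"
    return AdditivityReport(sample.id, verdicts)
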