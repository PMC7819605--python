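"""Chloroplast-based maternal-parent assignment.

Chloroplasts are maternally inherited in most angiosperms, so a
hybrid's cpDNA haplotype identifies its seed parent. Each hybrid is
compared against every sampled parental accession haplotype; an exact
match (distance zero over substitutions and indels) is the primary
criterion, mirroring strict sequence identity. When no parental
haplotype matches exactly, the nearest one is reported with its
distance and flagged as non-exact. A tie at minimal distance between
accessions of *different* species makes the assignment ambiguous.

Distances are simple site counts over a shared position set:
``all`` mode counts every differing position (substitutions + indels);
``substitutions`` mode skips positions where either haplotype has a gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from ._errors import GroupingError, InsufficientDataError, ShapeError
from .alignment import SiteMatrix

DistanceMode = Literal["substitutions", "all"]


def pairwise_distance(h1: str, h2: str, mode: DistanceMode = "all") -> int:
    """Number of differing positions between two state strings.

    ``substitutions`` mode skips positions where either state is a gap,
    so it never exceeds ``all`` mode.
    """
    if len(h1) != len(h2):
        raise ShapeError(f"length mismatch: {len(h1)} vs {len(h2)}")
    if mode == "substitutions":
        return sum(1 for a, b in zip(h1, h2) if a != b and a != "-" and b != "-")
    return sum(1 for a, b in zip(h1, h2) if a != b)


def distance_matrix(matrix: SiteMatrix, mode: DistanceMode = "all") -> pd.DataFrame:
    """All pairwise distances between rows; symmetric, zero diagonal."""
    if len(matrix.rows) < 2:
        raise InsufficientDataError("distance matrix needs at least two rows")
    ids = matrix.ids
    data = [
        [pairwise_distance(a.states, b.states, mode) for b in matrix.rows]
        for a in matrix.rows
    ]
    return pd.DataFrame(data, index=ids, columns=ids)


def min_conspecific_distance(
    matrix: SiteMatrix, accession: str, mode: DistanceMode = "substitutions"
) -> int:
    """Minimum distance from one accession to any other of its group.

    Operationalizes divergence statements of the form "accession X
    differed by k substitutions from the other conspecific accessions".
    """
    row = matrix.row(accession)
    others = [r for r in matrix.group_rows(row.group) if r.id != accession]
    if not others:
        raise GroupingError(f"no conspecific accessions for {accession!r}")
    return min(pairwise_distance(row.states, o.states, mode) for o in others)


@dataclass
class MaternalAssignment:
    """Per-hybrid maternal-parent verdict from cp haplotype matching."""

    hybrid_id: str
    species: str | None  # None when ambiguous
    matched_accessions: tuple[str, ...]
    distance: int  # substitutions + indels to nearest parental haplotype
    distance_substitutions: int
    exact_match: bool
    ambiguous: bool


def assign_maternal(
    hybrid_id: str,
    hybrid_states: str,
    parental: Mapping[str, Mapping[str, str]],
) -> MaternalAssignment:
    """Assign the maternal species of one hybrid cp haplotype.

    *parental* maps species tag -> {accession id -> states}, all on the
    same position set as *hybrid_states*. The nearest accession(s) by
    substitutions+indels distance determine the species; ties spanning
    two or more species are ambiguous.
    """
    if not parental or not any(parental.values()):
        raise GroupingError("empty parental haplotype set")
    scored = []
    for species, accessions in parental.items():
        for acc, states in accessions.items():
            scored.append(
                (
                    pairwise_distance(hybrid_states, states, "all"),
                    pairwise_distance(hybrid_states, states, "substitutions"),
                    species,
                    acc,
                )
            )
    dmin = min(s[0] for s in scored)
    nearest = [s for s in scored if s[0] == dmin]
    species_at_min = {s[2] for s in nearest}
    ambiguous = len(species_at_min) > 1
    return MaternalAssignment(
        hybrid_id=hybrid_id,
        species=None if ambiguous else next(iter(species_at_min)),
        matched_accessions=tuple(s[3] for s in nearest),
        distance=dmin,
        distance_substitutions=min(s[1] for s in nearest),
        exact_match=dmin == 0,
        ambiguous=ambiguous,
    )


def assign_all_maternal(
    matrix: SiteMatrix,
    hybrid_group: str,
    parent_groups: Sequence[str],
    extra_groups: Sequence[str] = (),
) -> list[MaternalAssignment]:
    """Assign every hybrid in *matrix* against the named parental groups.

    *extra_groups* (e.g. outgroup species) may be included as candidate
    maternal donors; an assignment landing on one of them warns that the
    parental hypothesis may be wrong, but is still reported.
    """
    hybrids = matrix.group_rows(hybrid_group)
    if not hybrids:
        raise GroupingError(f"hybrid group {hybrid_group!r} absent from matrix")
    parental: dict[str, dict[str, str]] = {}
    for tag in (*parent_groups, *extra_groups):
        rows = matrix.group_rows(tag)
        if not rows and tag in parent_groups:
            raise GroupingError(f"parental group {tag!r} absent from matrix")
        if rows:
            parental[tag] = {r.id: r.states for r in rows}
    out = []
    for row in hybrids:
        a = assign_maternal(row.id, row.states, parental)
        if a.species is not None and a.species not in parent_groups:
            warnings.warn(
                f"hybrid {row.id!r} matches non-parent group {a.species!r}; "
                "the parental hypothesis may be wrong",
                stacklevel=2,
            )
        out.append(a)
    return out


@dataclass
class DirectionSummary:
    """Hybridization directionality over a set of maternal assignments."""

    counts: dict[str, int]
    n_ambiguous: int

    @property
    def bidirectional(self) -> bool:
        return sum(1 for c in self.counts.values() if c >= 1) >= 2


def direction_summary(assignments: Sequence[MaternalAssignment]) -> DirectionSummary:
    """Per-species maternal counts; bidirectional iff at least one hybrid
    is assigned to each of two or more species."""
    counts: dict[str, int] = {}
    ambiguous = 0
    for a in assignments:
        if a.species is None:
            ambiguous += 1
        else:
            counts[a.species] = counts.get(a.species, 0) + 1
    return DirectionSummary(counts, ambiguous)


def assignments_frame(assignments: Sequence[MaternalAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hybrid": [a.hybrid_id for a in assignments],
            "species": [a.species or "ambiguous" for a in assignments],
            "matched_accessions": [
                ",".join(a.matched_accessions) for a in assignments
            ],
            "distance": [a.distance for a in assignments],
            "distance_substitutions": [
                a.distance_substitutions for a in assignments
            ],
            "exact_match": [a.exact_match for a in assignments],
        }
    )
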