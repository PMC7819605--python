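"""Cloned-amplicon haplotype collapse and chimera classification.

Cloning the ITS amplicon of an F1 hybrid recovers individual allele
copies, but PCR can also produce *chimeric* molecules: template switches
during amplification join stretches of the two parental alleles into a
recombinant read. Each distinct clone sequence (haplotype) is classified
against the two parental allele profiles:

* ``parental_a`` / ``parental_b`` — identical to one parent at every
  variable position;
* ``chimeric`` — carries parent-A states at some informative positions
  and parent-B states at others;
* ``parental_like_novel`` — matches a single parent at all informative
  positions but carries at least one state seen in neither parent
  (flagged separately rather than counted as chimeric, since a novel
  state may be polymerase error rather than recombination);
* ``ambiguous`` — indistinguishable (no informative or novel position).

The minimal breakpoint count — adjacent A<->B transitions along the
ordered informative positions — is the minimum number of template
switches explaining a chimeric clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import pandas as pd

from ._errors import InsufficientDataError, ShapeError
from .alignment import AlignedRecord

OriginLabel = Literal["A", "B", "shared", "novel"]
CloneVerdict = Literal[
    "parental_a", "parental_b", "chimeric", "parental_like_novel", "ambiguous"
]


@dataclass(frozen=True)
class HaplotypeProfile:
    """A distinct clone sequence restricted to variable-site positions."""

    name: str
    states: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("haplotype count must be >= 1")


def collapse_haplotypes(
    clones: Sequence[AlignedRecord],
    positions: Sequence[int] | None = None,
    names: Sequence[str] | None = None,
) -> list[HaplotypeProfile]:
    """Collapse clone records into distinct haplotypes with counts.

    With *positions* given, states are extracted at those 1-based
    coordinates of each (full-length) record; otherwise the record
    residues are taken to be site-level states already. Haplotypes are
    ordered by descending count, ties broken by first occurrence, and
    named H1, H2, ... unless *names* supplies labels in that order.
    """
    tally: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for idx, rec in enumerate(clones):
        if positions is None:
            states = rec.residues
        else:
            states = "".join(rec.state_at(p) for p in positions)
        tally[states] = tally.get(states, 0) + 1
        first_seen.setdefault(states, idx)
    ordered = sorted(tally, key=lambda s: (-tally[s], first_seen[s]))
    if names is not None and len(names) < len(ordered):
        raise ValueError("fewer names than distinct haplotypes")
    return [
        HaplotypeProfile(
            names[i] if names is not None else f"H{i + 1}", states, tally[states]
        )
        for i, states in enumerate(ordered)
    ]


@dataclass
class CloneClassification:
    """Verdict for one haplotype against the two parental profiles."""

    name: str
    verdict: CloneVerdict
    origin: tuple[OriginLabel, ...]
    breakpoints: int
    novel_positions: tuple[int, ...]
    count: int = 1

    @property
    def is_chimeric(self) -> bool:
        return self.verdict == "chimeric"


def origin_labels(
    states: str, parent_a: str, parent_b: str
) -> tuple[OriginLabel, ...]:
    """Per-position origin of a clone's states relative to two parents."""
    if not (len(states) == len(parent_a) == len(parent_b)):
        raise ShapeError(
            f"profile/parent length mismatch: {len(states)}, "
            f"{len(parent_a)}, {len(parent_b)}"
        )
    labels: list[OriginLabel] = []
    for s, a, b in zip(states, parent_a, parent_b):
        if s != a and s != b:
            labels.append("novel")
        elif a == b:
            labels.append("shared")
        elif s == a:
            labels.append("A")
        else:
            labels.append("B")
    return tuple(labels)


def min_breakpoints(origin: Sequence[OriginLabel]) -> int:
    """Minimal template-switch count: adjacent A<->B transitions among
    the informative labels (shared/novel positions are skipped)."""
    informative = [lab for lab in origin if lab in ("A", "B")]
    return sum(1 for x, y in zip(informative, informative[1:]) if x != y)


def classify_haplotype(
    profile: HaplotypeProfile,
    parent_a: str,
    parent_b: str,
    positions: Sequence[int] | None = None,
) -> CloneClassification:
    """Classify one haplotype; see the module docs for the verdict rules.

    *positions* (1-based labels aligned to the profile) is used only to
    report novel positions; indices are reported when omitted.
    """
    origin = origin_labels(profile.states, parent_a, parent_b)
    labels = positions if positions is not None else range(1, len(origin) + 1)
    novel = tuple(p for p, lab in zip(labels, origin) if lab == "novel")
    has_a = "A" in origin
    has_b = "B" in origin
    if has_a and has_b:
        verdict: CloneVerdict = "chimeric"
    elif novel:
        verdict = "parental_like_novel"
    elif has_a:
        verdict = "parental_a"
    elif has_b:
        verdict = "parental_b"
    else:
        verdict = "ambiguous"
    return CloneClassification(
        profile.name, verdict, origin, min_breakpoints(origin), novel, profile.count
    )


def classify_all(
    profiles: Sequence[HaplotypeProfile],
    parent_a: str,
    parent_b: str,
    positions: Sequence[int] | None = None,
) -> list[CloneClassification]:
    return [classify_haplotype(p, parent_a, parent_b, positions) for p in profiles]


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ChimeraSummary:
    """Clone totals, per-verdict counts and the chimeric percentage."""

    total: int
    by_verdict: dict[CloneVerdict, int]
    chimeric_percent: float
    table: pd.DataFrame

    @property
    def chimeric(self) -> int:
        return self.by_verdict.get("chimeric", 0)


def summarize_clones(classifications: Sequence[CloneClassification]) -> ChimeraSummary:
    """Summarize verdicts over clones (haplotype counts expanded).

    The chimeric percentage is 100 x chimeric/total, rounded half-up to
    one decimal.
    """
    if not classifications:
        raise InsufficientDataError("no clones to summarize")
    by_verdict: dict[CloneVerdict, int] = {}
    total = 0
    for c in classifications:
        total += c.count
        by_verdict[c.verdict] = by_verdict.get(c.verdict, 0) + c.count
    chimeric = by_verdict.get("chimeric", 0)
    percent = _round_half_up_1dp(100.0 * chimeric / total)
    table = pd.DataFrame(
        {
            "haplotype": [c.name for c in classifications],
            "count": [c.count for c in classifications],
            "verdict": [c.verdict for c in classifications],
            "breakpoints": [c.breakpoints for c in classifications],
            "origin": ["".join(_short(lab) for lab in c.origin) for c in classifications],
            "novel_positions": [
                ",".join(map(str, c.novel_positions)) or "." for c in classifications
            ],
        }
    )
    return ChimeraSummary(total, by_verdict, percent, table)


def _short(label: OriginLabel) -> str:
    return {"A": "A", "B": "B", "shared": ".", "novel": "*"}[label]
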