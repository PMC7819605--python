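"""Synthetic study-like datasets with known ground truth.

Emulates the molecular design of a two-parent hybrid study: two parental
species fixed-different at configurable substitution and single-base
indel positions, F1 hybrids carrying both nuclear alleles, clone
libraries subject to PCR-mediated recombination (polymerase template
switching), IUPAC-additive direct sequences, and maternally inherited
chloroplast haplotypes with a per-hybrid direction choice.

Template-switch model: each clone starts on a uniformly chosen parental
allele and, in each interval between adjacent variable sites, switches
template with probability ``r`` (at most one switch per interval,
independent across intervals). A clone is chimeric iff at least one
switch occurred, so the expected chimeric fraction over ``k`` variable
sites is ``1 - (1 - r)**(k - 1)`` exactly.

All randomness flows through one ``numpy`` generator seeded from
``SimConfig.seed``; the same seed reproduces the bundle byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._errors import ConfigError
from .alignment import AlignedRecord, write_alignment

Species = Literal["parent_a", "parent_b"]

#: Default per-interval template-switch probability. The closed form
#: above implies this rate when roughly half of the clones over a dozen
#: diagnostic sites are chimeric, which is the regime the package's
#: clone classifier is designed for.
DEFAULT_SWITCH_RATE = 0.065

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study design for the generator.

    Defaults mirror the real study's dimensions: a 736-bp nuclear
    alignment with 9 diagnostic substitutions + 3 single-base indels, a
    1980-bp chloroplast alignment with 4 substitutions + 6 single-base
    indels (one contiguous 6-bp gap), five accessions per parental
    species, seven hybrids (three with parent A as the maternal donor,
    four with parent B), and six clones per hybrid.
    """

    seed: int
    nuclear_length: int = 736
    cp_length: int = 1980
    nuclear_sub_positions: tuple[int, ...] = (43, 141, 230, 250, 422, 451, 479, 642, 688)
    nuclear_indel_positions: tuple[int, ...] = (44, 667, 668)
    cp_sub_positions: tuple[int, ...] = (263, 1089, 1182, 1239)
    cp_indel_positions: tuple[int, ...] = (164, 165, 166, 167, 168, 169)
    n_parent_a: int = 5
    n_parent_b: int = 5
    #: (hybrid id, maternal species) pairs.
    hybrids: tuple[tuple[str, Species], ...] = (
        ("HYB1", "parent_a"),
        ("HYB2", "parent_a"),
        ("HYB3", "parent_a"),
        ("HYB4", "parent_b"),
        ("HYB5", "parent_b"),
        ("HYB6", "parent_b"),
        ("HYB7", "parent_b"),
    )
    clones_per_hybrid: int = 6
    switch_rate: float = DEFAULT_SWITCH_RATE
    #: accession id -> number of private cp substitutions (intra-parental
    #: polymorphism, e.g. {"A3": 2}).
    cp_polymorphism: dict[str, int] = field(default_factory=dict)
    n_outgroup_species: int = 2
    n_outgroup_accessions: int = 2

    def __post_init__(self) -> None:
        for positions, length, tag in (
            (self.nuclear_sub_positions + self.nuclear_indel_positions,
             self.nuclear_length, "nuclear"),
            (self.cp_sub_positions + self.cp_indel_positions,
             self.cp_length, "cp"),
        ):
            if len(set(positions)) != len(positions):
                raise ConfigError(f"{tag}: diagnostic positions collide")
            if any(p < 1 or p > length for p in positions):
                raise ConfigError(f"{tag}: position outside 1..{length}")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ConfigError("switch_rate must be in [0, 1]")
        for hid, species in self.hybrids:
            if species not in ("parent_a", "parent_b"):
                raise ConfigError(f"hybrid {hid!r}: unknown maternal {species!r}")


@dataclass
class ParentalAlleles:
    """Ground-truth parental sequences for one simulated study."""

    nuclear_a: str
    nuclear_b: str
    cp_a: dict[str, str]  # accession id -> haplotype
    cp_b: dict[str, str]


def _random_background(rng: np.random.Generator, length: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=length)]


def _diverge(
    rng: np.random.Generator,
    background: list[str],
    sub_positions: Sequence[int],
    indel_positions: Sequence[int],
) -> tuple[str, str]:
    """Two alleles identical except at the configured diagnostic sites."""
    a = list(background)
    b = list(background)
    for p in sub_positions:
        x = _BASES[rng.integers(0, 4)]
        y = _BASES[(_BASES.index(x) + 1 + rng.integers(0, 3)) % 4]
        a[p - 1], b[p - 1] = x, y
    for p in indel_positions:
        # the gap lands in one parent, chosen at random per site
        if rng.integers(0, 2):
            a[p - 1] = "-"
        else:
            b[p - 1] = "-"
    return "".join(a), "".join(b)


def make_parents(config: SimConfig, rng: np.random.Generator | None = None) -> ParentalAlleles:
    """Generate parental nuclear alleles and cp accession haplotypes.

    Conspecific accessions are identical unless ``cp_polymorphism``
    grants an accession private substitutions at non-diagnostic sites.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nuc_a, nuc_b = _diverge(
        rng,
        _random_background(rng, config.nuclear_length),
        config.nuclear_sub_positions,
        config.nuclear_indel_positions,
    )
    cp_base_a, cp_base_b = _diverge(
        rng,
        _random_background(rng, config.cp_length),
        config.cp_sub_positions,
        config.cp_indel_positions,
    )
    diagnostic = set(config.cp_sub_positions) | set(config.cp_indel_positions)
    cp_a, cp_b = {}, {}
    for k in range(1, config.n_parent_a + 1):
        cp_a[f"A{k}"] = _with_private_subs(
            rng, cp_base_a, config.cp_polymorphism.get(f"A{k}", 0), diagnostic
        )
    for k in range(1, config.n_parent_b + 1):
        cp_b[f"B{k}"] = _with_private_subs(
            rng, cp_base_b, config.cp_polymorphism.get(f"B{k}", 0), diagnostic
        )
    return ParentalAlleles(nuc_a, nuc_b, cp_a, cp_b)


def _with_private_subs(
    rng: np.random.Generator, base: str, n: int, forbidden: set[int]
) -> str:
    if n == 0:
        return base
    seq = list(base)
    free = [p for p in range(1, len(base) + 1) if p not in forbidden and seq[p - 1] != "-"]
    for p in rng.choice(free, size=n, replace=False):
        old = seq[p - 1]
        seq[p - 1] = _BASES[(_BASES.index(old) + 1 + rng.integers(0, 3)) % 4]
    return "".join(seq)


@dataclass
class CloneTruth:
    """Ground truth for one simulated clone."""

    clone_id: str
    start_template: Species
    origins: str  # per variable site: 'a' or 'b'
    switch_intervals: tuple[int, ...]  # 0-based interval indices with a switch

    @property
    def chimeric(self) -> bool:
        return len(set(self.origins)) > 1


def simulate_clone_library(
    hybrid_id: str,
    allele_a: str,
    allele_b: str,
    r: float,
    n_clones: int,
    rng: np.random.Generator,
) -> tuple[list[AlignedRecord], list[CloneTruth]]:
    """Clone library under the per-interval template-switching model."""
    variable = [
        p for p in range(1, len(allele_a) + 1) if allele_a[p - 1] != allele_b[p - 1]
    ]
    clones: list[AlignedRecord] = []
    truths: list[CloneTruth] = []
    for c in range(1, n_clones + 1):
        template: Species = "parent_a" if rng.integers(0, 2) == 0 else "parent_b"
        origins = []
        switches = []
        seq = list(allele_a)  # non-variable positions agree between alleles
        current = template
        for i, p in enumerate(variable):
            if i > 0 and rng.random() < r:
                switches.append(i - 1)
                current = "parent_b" if current == "parent_a" else "parent_a"
            origins.append("a" if current == "parent_a" else "b")
            seq[p - 1] = (allele_a if current == "parent_a" else allele_b)[p - 1]
        clone_id = f"{hybrid_id}_c{c}"
        clones.append(AlignedRecord(clone_id, hybrid_id, "".join(seq)))
        truths.append(
            CloneTruth(clone_id, template, "".join(origins), tuple(switches))
        )
    return clones, truths


def expected_chimera_fraction(r: float, k: int) -> float:
    """Closed-form chimeric fraction: 1 - (1-r)**(k-1) for k variable sites."""
    if k < 2:
        return 0.0
    return 1.0 - (1.0 - r) ** (k - 1)


def fit_switch_rate(observed_fraction: float, k: int) -> float:
    """Invert the closed form: the per-interval switch rate implied by an
    observed chimeric fraction over k variable sites."""
    if not 0.0 <= observed_fraction < 1.0:
        raise ConfigError("observed fraction must be in [0, 1)")
    if k < 2:
        raise ConfigError("need at least two variable sites")
    return 1.0 - (1.0 - observed_fraction) ** (1.0 / (k - 1))


#: IUPAC union codes for unordered base pairs.
_PAIR_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def simulate_direct_sequence(
    hybrid_id: str, allele_a: str, allele_b: str, indel_placeholder: str = "N"
) -> tuple[AlignedRecord, list[int]]:
    """Direct-sequencing consensus of a heterozygous hybrid.

    Heterozygous substitution sites emit the IUPAC union code (the
    symbolic analogue of superimposed chromatogram peaks); sites where
    one allele has a gap emit *indel_placeholder* and are returned as
    flagged positions (a real trace is frame-shifted there).
    """
    seq = []
    flagged = []
    for p, (x, y) in enumerate(zip(allele_a, allele_b), start=1):
        if x == y:
            seq.append(x)
        elif x == "-" or y == "-":
            seq.append(indel_placeholder)
            flagged.append(p)
        else:
            seq.append(_PAIR_CODE[frozenset((x, y))])
    return AlignedRecord(hybrid_id, "hybrid", "".join(seq)), flagged


def simulate_cp(
    maternal_species: Species,
    parents: ParentalAlleles,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Hybrid cp haplotype: an exact copy of one maternal-species
    accession haplotype. Returns (accession id, sequence)."""
    if maternal_species == "parent_a":
        pool = parents.cp_a
    elif maternal_species == "parent_b":
        pool = parents.cp_b
    else:  # pragma: no cover - guarded by SimConfig
        raise ConfigError(f"unknown maternal species {maternal_species!r}")
    acc = sorted(pool)[rng.integers(0, len(pool))]
    return acc, pool[acc]


@dataclass
class StudyBundle:
    """Everything one simulated study emits, plus its ground truth."""

    config: SimConfig
    parents: ParentalAlleles
    nuclear_records: list[AlignedRecord]  # parents + hybrid direct + outgroups
    clone_records: list[AlignedRecord]  # grouped by hybrid id
    clone_truth: list[CloneTruth]
    cp_records: list[AlignedRecord]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write FASTA/TSV/JSON files; byte-identical for a given seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.nuclear_records, outdir / "nuclear_direct.fasta")
        write_alignment(self.clone_records, outdir / "nuclear_clones.fasta")
        write_alignment(self.cp_records, outdir / "cp.fasta")
        groups = "\n".join(
            f"{r.id}\t{r.group}"
            for r in (*self.nuclear_records, *self.clone_records, *self.cp_records)
        )
        (outdir / "groups.tsv").write_text(groups + "\n")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True) + "\n"
        )


def generate_study_like_dataset(
    seed: int, config: SimConfig | None = None
) -> StudyBundle:
    """Generate a full study-like bundle (see module docs)."""
    if config is None:
        config = SimConfig(seed=seed)
    rng = np.random.default_rng(config.seed)
    parents = make_parents(config, rng)

    nuclear_records = []
    for k in range(1, config.n_parent_a + 1):
        nuclear_records.append(AlignedRecord(f"A{k}", "parent_a", parents.nuclear_a))
    for k in range(1, config.n_parent_b + 1):
        nuclear_records.append(AlignedRecord(f"B{k}", "parent_b", parents.nuclear_b))

    truth: dict = {
        "seed": config.seed,
        "nuclear_diagnostics": {
            "substitutions": list(config.nuclear_sub_positions),
            "indels": list(config.nuclear_indel_positions),
        },
        "cp_diagnostics": {
            "substitutions": list(config.cp_sub_positions),
            "indels": list(config.cp_indel_positions),
        },
        "parent_alleles": {"nuclear_a": parents.nuclear_a, "nuclear_b": parents.nuclear_b},
        "maternal": {},
        "maternal_accession": {},
        "clones": {},
    }

    clone_records: list[AlignedRecord] = []
    clone_truth: list[CloneTruth] = []
    cp_records: list[AlignedRecord] = []
    for acc, seq in sorted(parents.cp_a.items()):
        cp_records.append(AlignedRecord(acc, "parent_a", seq))
    for acc, seq in sorted(parents.cp_b.items()):
        cp_records.append(AlignedRecord(acc, "parent_b", seq))

    for hid, maternal in config.hybrids:
        direct, _flagged = simulate_direct_sequence(
            hid, parents.nuclear_a, parents.nuclear_b
        )
        nuclear_records.append(direct)
        clones, truths = simulate_clone_library(
            hid,
            parents.nuclear_a,
            parents.nuclear_b,
            config.switch_rate,
            config.clones_per_hybrid,
            rng,
        )
        clone_records.extend(clones)
        clone_truth.extend(truths)
        acc, cp_seq = simulate_cp(maternal, parents, rng)
        cp_records.append(AlignedRecord(hid, "hybrid", cp_seq))
        truth["maternal"][hid] = maternal
        truth["maternal_accession"][hid] = acc
        for t in truths:
            truth["clones"][t.clone_id] = {
                "start_template": t.start_template,
                "origins": t.origins,
                "switch_intervals": list(t.switch_intervals),
                "chimeric": t.chimeric,
            }

    # additional species: diverged from both parents at private positions,
    # mirroring the role of non-parent controls in the study design
    nuc_diag = set(config.nuclear_sub_positions) | set(config.nuclear_indel_positions)
    cp_diag = set(config.cp_sub_positions) | set(config.cp_indel_positions)
    for s in range(1, config.n_outgroup_species + 1):
        out_nuc = _with_private_subs(rng, parents.nuclear_a, 4, nuc_diag)
        out_cp = _with_private_subs(rng, parents.cp_a["A1"], 3, cp_diag)
        for k in range(1, config.n_outgroup_accessions + 1):
            acc = f"OUT{s}_{k}"
            nuclear_records.append(AlignedRecord(acc, f"outgroup{s}", out_nuc))
            cp_records.append(AlignedRecord(acc, f"outgroup{s}", out_cp))

    return StudyBundle(
        config, parents, nuclear_records, clone_records, clone_truth,
        cp_records, truth,
    )
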