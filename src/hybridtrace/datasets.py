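"""Packaged reference matrices for the Cryptocoryne ×purpurea system.

Two variable-site matrices ship with the package, transcribed from the
published character tables for the putative hybrid *Cryptocoryne*
×*purpurea* nothovar. *purpurea* and its candidate parents *C. cordata*
var. *cordata* and *C. griffithii* from Peninsular Malaysia:

* **ITS** (nuclear ribosomal internal transcribed spacer): the 18
  variable sites of the 736-bp alignment — one consensus row per
  parental species (no intraspecific polymorphism was detected), the
  seven cloned hybrid haplotypes H1-H7 with clone counts (42 clones
  total), the three haplotypes recovered from the 1:1 parental
  DNA-mixture PCR control (6 clones), and the two additional species
  *C. schulzei* and *C. nurii* var. *nurii*.
* **trnK-matK** (chloroplast): the 20 variable sites of the 1980-bp
  alignment across all 21 accessions (7 hybrids, 5 accessions per
  parental species, 2 accessions each of the two additional species).

Position labels are 1-based coordinates in the respective alignment.
"""

from __future__ import annotations

from importlib import resources

from .alignment import SiteMatrix, SiteRow, _parse_site_matrix

ITS_PARENT_A = "cordata"  # C. cordata var. cordata
ITS_PARENT_B = "griffithii"  # C. griffithii


def _load(name: str) -> SiteMatrix:
    text = resources.files("hybridtrace.data").joinpath(name).read_text()
    return _parse_site_matrix(text, name)


def its_variable_sites() -> SiteMatrix:
    """The full ITS variable-site matrix (parents, clone haplotypes,
    mixture control, additional species)."""
    return _load("cryptocoryne_its_sites.tsv")


def cp_variable_sites() -> SiteMatrix:
    """The 21-accession trnK-matK variable-site matrix."""
    return _load("cryptocoryne_trnk_matk_sites.tsv")


def its_parental_matrix(n_per_species: int = 5) -> SiteMatrix:
    """Accession-level parental ITS matrix.

    The published table prints one consensus row per parental species
    because all conspecific accessions were identical; this expands each
    to *n_per_species* accession rows (the study sampled five per
    species), which is the input on which tree statistics such as the
    retention index are defined.
    """
    its = its_variable_sites()
    rows = []
    for row in (its.row("CORDATA"), its.row("GRIFFITHII")):
        rows.extend(
            SiteRow(f"{row.id}_{k}", row.group, row.states, 1)
            for k in range(1, n_per_species + 1)
        )
    return SiteMatrix(its.positions, rows)


def its_clone_matrix() -> SiteMatrix:
    """The seven hybrid clone haplotypes H1-H7 with clone counts."""
    its = its_variable_sites()
    return SiteMatrix(its.positions, its.group_rows("hybrid_clone"))


def its_mixture_matrix() -> SiteMatrix:
    """The three DNA-mixture control haplotypes with clone counts."""
    its = its_variable_sites()
    return SiteMatrix(its.positions, its.group_rows("mixture_control"))
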