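# Methods

## Problem setting

The package addresses molecular verification of a putative natural
interspecific hybrid. Two markers carry complementary signals: a
biparentally inherited nuclear marker (nrDNA ITS) can show *both*
parental alleles inside one hybrid individual, and a maternally
inherited chloroplast marker (trnK-matK) identifies the seed parent.
The worked system is *Cryptocoryne* ×*purpurea* nothovar. *purpurea*
with candidate parents *C. cordata* var. *cordata* and *C. griffithii*;
the packaged fixtures are the published variable-site matrices for that
system (18 ITS sites of a 736-bp alignment; 20 cp sites of a 1980-bp
alignment over 21 accessions).

## Diagnostic fixed differences

A fixed difference is an alignment column where all accessions of
species A share one state, all accessions of species B share another,
and the two differ. The definition is strict: any within-group
polymorphism, missing data, or IUPAC ambiguity code excludes the
column, and no tolerance parameter exists. This matters in practice —
with the polymorphic griffithii accession BIN included, the cp marker
has exactly 4 fixed substitutions plus 6 single-base indels; dropping
BIN would admit one more site (550). Contiguous gap columns are *not*
merged into a single indel event: each gap column is an independent
single-base indel site, so the 6-column cp gap counts as six indels.

Additivity of a direct-sequenced hybrid is assessed symbolically: at
each diagnostic substitution site the expected observation is the IUPAC
union of the two parental bases (A+G→R, C+T→Y, ...), the sequence-level
analogue of superimposed chromatogram peaks. Indel sites are reported
`not_assessable` in direct mode: a heterozygous indel frame-shifts a
Sanger trace downstream of the gap, which is precisely why such
amplicons are cloned rather than read directly. No quantitative
peak-height model is attempted.

## Clone classification and breakpoints

Cloned amplicons are collapsed to distinct haplotypes with counts and
classified against the full variable-site profiles of the parents (not
only the fixed diagnostic subset): per position the clone's state is
labeled `A`, `B`, `shared` (parents agree) or `novel` (matches
neither). A clone is *chimeric* iff it carries both `A` and `B`
labels. The minimal breakpoint count is the number of adjacent A↔B
transitions in the informative-label subsequence; under a template-
switching model of PCR-mediated recombination it is the minimum number
of switches explaining the clone.

Design choice: a `novel` state alone does not make a clone chimeric; it
yields the distinct verdict `parental_like_novel`. The published
haplotypes contain no novel states, so the behaviour is unconstrained
by data; flagging rather than counting avoids inflating the chimera
fraction with what may be polymerase error. The chimeric percentage is
rounded half-up to one decimal (22/42 → 52.4).

## Parsimony engine

Scoring is Fitch (unordered, equal-weight) parsimony with the gap as a
fifth character state by default. Fifth-state treatment is what makes
indel columns contribute steps like substitutions and is required to
reproduce tree lengths that count indel characters; a `missing` mode
(gap compatible with every state) is provided for sensitivity analysis.

Search is exact rather than heuristic: the matrices this package
targets collapse to ≤ 7 distinct haplotypes, so all (2n−5)!! unrooted
binary topologies can be enumerated outright (done for n ≤ 9), and a
branch-and-bound search — partial-tree length is a valid lower bound;
the initial upper bound comes from deterministic greedy stepwise
addition — covers larger inputs up to a hard cap of 16 haplotypes. All
optimal trees are returned, in a deterministic enumeration order fixed
by input haplotype order. Binary resolutions of a polytomy differ only
by zero-change branches; `collapse_zero_change_branches` contracts
them, and `distinct_mp_trees` reports the distinct collapsed trees
(both packaged matrices yield exactly one).

Indices over the scored characters, with per-character minimum
`m_i = (observed states) − 1` and star-tree steps
`g_i = (taxa) − (count of the most frequent state)` computed over
*taxa* (haplotype multiplicities expanded), not distinct haplotypes:

* CI = Σm_i / Σs_i (undefined and raised on a zero-length tree);
* RI = (Σg_i − Σs_i) / (Σg_i − Σm_i); when Σg = Σm (autapomorphy-only
  data) the conventional value 1 is reported with a `degenerate` flag.

Branch mapping uses the classic Fitch backtrace: the tree is rooted at
its first leaf, the down-pass state sets are refined top-down taking
the parent's state when available and otherwise the lowest state in a
fixed A<C<G<T<- order, making the mapping deterministic; per-branch
change counts always sum to the tree length (asserted in tests). On
homoplasy-free data the counts are assignment-invariant.

`is_perfectly_compatible` applies the four-gamete test to every pair of
state-subsets of every pair of characters; compatibility of the whole
matrix explains CI = RI = 1 (MP length = Σm_i).

Newick output is written in-house (unrooted trifurcation at the
internal node adjacent to the first leaf); parsing is delegated to
dendropy, with rooted-binary seed nodes suppressed so write→read is an
identity on topologies.

## Maternal assignment

The primary criterion is exact identity: a hybrid's cp haplotype equal
(substitutions + indels distance 0) to one or more accessions of a
single parental species assigns that species as the maternal parent.
When no exact match exists the nearest haplotype is reported with its
distance and `exact_match=False`; a minimal-distance tie across species
is `ambiguous` rather than resolved arbitrarily. Distances are plain
differing-site counts; `substitutions` mode skips any position where
either sequence has a gap, so it never exceeds `all` mode. "Divergence
of accession X from its conspecifics" is operationalized as the minimum
substitutions-only distance from X to any other accession of its group.
Candidate donors from non-parent groups may be included; matching one
triggers a warning (wrong-parental-hypothesis guard), not an error.

## Synthetic data generator

The generator emulates the study design with known ground truth:

* Two parental species differ at configurable diagnostic positions
  (defaults: the real ITS/cp diagnostic layout — 9 + 3 nuclear, 4 + 6
  cp — in alignments of 736 and 1980 bp); the background is identical
  across parents so every difference is interpretable. Conspecific
  accessions are identical unless an explicit cp polymorphism spec
  grants an accession private substitutions.
* Study shape: 5 + 5 parental accessions, 7 hybrids (3 with parent A
  maternal, 4 with parent B, mirroring the observed split), 6 clones
  per hybrid, two 2-accession non-parent species.
* Clone libraries follow the simplest model consistent with polymerase
  template switching: a clone starts on a uniformly chosen allele and
  switches template with probability `r` independently in each interval
  between adjacent variable sites (at most one switch per interval).
  A clone is chimeric iff ≥ 1 switch occurred, so the expected chimeric
  fraction is exactly `1 − (1−r)^(k−1)` for `k` variable sites — used
  as a closed-form test oracle. The default `r = 0.065` puts the
  chimeric fraction near one half at k = 12, the regime of interest;
  `fit_switch_rate` inverts the closed form for any observed fraction.
* Direct sequences take the IUPAC union at heterozygous substitution
  sites and a placeholder (`N`) at indel-heterozygous sites, which are
  returned as flagged positions.
* A hybrid's cp sequence is an exact copy of one randomly chosen
  accession haplotype of its configured maternal species.

All randomness flows through a single seeded `numpy` generator;
identical seeds give byte-identical output bundles. The generator does
*not* model coalescence, concerted evolution, sequencing error, or
alignment uncertainty — passing recovery tests therefore shows the
pipeline is correct under its own assumptions (clean alignments, strict
fixation, F1 hybrids), not that those assumptions hold for arbitrary
real data.

## Problem sizes and numerical choices

Everything runs on one CPU in seconds: exhaustive search at ≤ 7
haplotypes scores at most 945 topologies; property tests use 4-8-leaf
random matrices against a brute-force internal-labeling oracle;
simulation checks use 5 000 clones against the closed form at a 99%
binomial interval, and shortened (120/150 bp) alignments that keep the
full diagnostic structure. Percentages are rounded half-up via decimal
arithmetic to avoid binary-float rounding surprises at `.x5`
boundaries.

## Known limitations

* No heuristic tree search (TBR/NNI) beyond the stepwise-addition seed;
  inputs that do not collapse below 16 haplotypes are rejected.
* No statistical test separating in vitro PCR recombination from
  biological recombination; like the underlying study design, the
  mixture-control comparison is qualitative.
* Clone-to-hybrid attribution is supported (clones carry their source
  hybrid as a group tag) but only exercised on synthetic data, since
  published clone tables aggregate clones across hybrids.
* Direct-sequence additivity is symbolic; chromatogram traces and peak
  heights are out of scope.
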