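"""Exact maximum-parsimony engine for small haplotype matrices.

Fitch (unordered, equal-weight) parsimony with the alignment gap as a
fifth character state, exact search over unrooted binary topologies
(exhaustive enumeration for small leaf counts, branch-and-bound seeded
by stepwise addition above that), consistency and retention indices,
and a deterministic Fitch backtrace that maps character changes onto
branches.

Datasets of the kind this package targets collapse to a handful of
distinct haplotypes, so exact search is cheap and returns *all*
most-parsimonious trees with no heuristic nondeterminism. The number of
unrooted binary topologies on n leaves is (2n-5)!! — 3, 15, 105, 945,
10395, 135135 for n = 4..9.

Gap handling: ``fifth_state`` (default) treats "-" as an ordinary state,
so an indel column can contribute steps exactly like a substitution;
``missing`` treats "-" as missing data (a gap leaf is compatible with
any state and never forces a change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple, Sequence

import dendropy

from ._errors import (
    CapacityError,
    InsufficientDataError,
    ShapeError,
    UndefinedStatisticError,
)
from .alignment import SiteMatrix

GapMode = Literal["fifth_state", "missing"]

#: Fixed alphabet order used for deterministic tie-breaking.
_STATE_ORDER = "ACGT-"


def _state_rank(s: str) -> tuple[int, str]:
    i = _STATE_ORDER.find(s)
    return (i if i >= 0 else len(_STATE_ORDER), s)


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Distinct haplotypes x variable characters, with taxon membership.

    ``taxon_counts`` records how many sampled taxa carry each haplotype
    (row multiplicities included); the retention index depends on these
    counts, not just on the distinct haplotypes.
    """

    positions: tuple[int, ...]
    haplotype_names: tuple[str, ...]
    haplotype_states: tuple[str, ...]
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    taxon_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, states in zip(self.haplotype_names, self.haplotype_states):
            if len(states) != len(self.positions):
                raise ShapeError(
                    f"haplotype {name!r}: {len(states)} states for "
                    f"{len(self.positions)} characters"
                )
        for name in self.haplotype_names:
            self.taxon_counts.setdefault(name, 1)
            self.members.setdefault(name, (name,))

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_names)

    @property
    def n_characters(self) -> int:
        return len(self.positions)

    @property
    def n_taxa(self) -> int:
        return sum(self.taxon_counts[h] for h in self.haplotype_names)

    def state_counts(self, j: int) -> dict[str, int]:
        """Taxon-level state tally for character *j* (0-based index)."""
        counts: dict[str, int] = {}
        for name, states in zip(self.haplotype_names, self.haplotype_states):
            s = states[j]
            counts[s] = counts.get(s, 0) + self.taxon_counts[name]
        return counts

    def column_states(self, j: int) -> list[str]:
        return [states[j] for states in self.haplotype_states]


def dedupe(matrix: SiteMatrix) -> CharacterMatrix:
    """Collapse identical rows of a site matrix into distinct haplotypes.

    The haplotype is named after its first member row; the character set
    is the variable columns of the collapsed matrix (identical to the
    variable columns of the input). Row multiplicities contribute to the
    haplotype's taxon count.
    """
    if len(matrix.rows) < 2:
        raise InsufficientDataError("dedupe needs at least two rows")
    order: list[str] = []
    groups: dict[str, list] = {}
    for row in matrix.rows:
        if row.states not in groups:
            groups[row.states] = []
            order.append(row.states)
        groups[row.states].append(row)
    names = tuple(groups[s][0].id for s in order)
    members = {
        groups[s][0].id: tuple(r.id for r in groups[s]) for s in order
    }
    taxon_counts = {
        groups[s][0].id: sum(r.count for r in groups[s]) for s in order
    }
    variable = [
        j
        for j in range(len(matrix.positions))
        if len({s[j] for s in order}) >= 2
    ]
    states = tuple("".join(s[j] for j in variable) for s in order)
    return CharacterMatrix(
        tuple(matrix.positions[j] for j in variable),
        names,
        states,
        members,
        taxon_counts,
    )


def informative_characters(chars: CharacterMatrix) -> list[int]:
    """0-based indices of parsimony-informative characters: at least two
    states each carried by at least two taxa."""
    out = []
    for j in range(chars.n_characters):
        counts = chars.state_counts(j)
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# Unrooted trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class UnrootedTree:
    """Unrooted binary topology over labeled leaves.

    Nodes ``0 .. n_leaves-1`` are the leaves (in ``leaf_labels`` order);
    higher ids are internal (degree-3) nodes. Equality and hashing
    compare the leaf set and the induced split set, so two trees are
    equal iff they are the same unrooted topology regardless of node
    numbering.
    """

    leaf_labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}
        for u, v in self.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        return adj

    def split_for_edge(self, edge: tuple[int, int]) -> frozenset[str]:
        """Leaf labels on the second-node side of *edge* (edge removed)."""
        u, v = edge
        adj = self.neighbors()
        seen = {u, v}
        stack = [v]
        labels = []
        while stack:
            w = stack.pop()
            if w < self.n_leaves:
                labels.append(self.leaf_labels[w])
            for x in adj.get(w, ()):
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(labels)

    def splits(self) -> frozenset[frozenset[str]]:
        """Canonical nontrivial splits: for each internal edge, the side
        not containing the first leaf label."""
        all_labels = set(self.leaf_labels)
        first = self.leaf_labels[0]
        out = set()
        for edge in self.edges:
            side = self.split_for_edge(edge)
            if first in side:
                side = frozenset(all_labels - side)
            if 2 <= len(side) <= self.n_leaves - 2:
                out.add(side)
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnrootedTree):
            return NotImplemented
        return (
            set(self.leaf_labels) == set(other.leaf_labels)
            and self.splits() == other.splits()
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.leaf_labels), self.splits()))


def enumerate_topologies(labels: Sequence[str]) -> Iterator[UnrootedTree]:
    """All unrooted binary topologies over *labels*, in deterministic
    stepwise-insertion order; (2n-5)!! trees for n >= 3 leaves."""
    labels = tuple(labels)
    n = len(labels)
    if n < 2:
        raise InsufficientDataError("need at least two leaves")
    if n == 2:
        yield UnrootedTree(labels, ((0, 1),))
        return

    def recurse(edges: list[tuple[int, int]], next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield UnrootedTree(labels, tuple(edges))
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = (
                edges[:i]
                + edges[i + 1:]
                + [(u, w), (v, w), (next_leaf, w)]
            )
            yield from recurse(new_edges, next_leaf + 1, next_internal + 1)

    yield from recurse([(0, n), (1, n), (2, n)], 3, n + 1)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def _char_alphabets(chars: CharacterMatrix) -> list[list[str]]:
    """Per-character observed states in deterministic A<C<G<T<- order."""
    return [
        sorted({s[j] for s in chars.haplotype_states}, key=_state_rank)
        for j in range(chars.n_characters)
    ]


def _leaf_masks(
    chars: CharacterMatrix, gap_mode: GapMode
) -> tuple[list[list[int]], list[list[str]]]:
    """Bitmask encoding, character-major: masks[j][leaf]."""
    alphabets = _char_alphabets(chars)
    masks: list[list[int]] = []
    for j, alphabet in enumerate(alphabets):
        index = {s: 1 << k for k, s in enumerate(alphabet)}
        if gap_mode == "missing":
            nongap = [s for s in alphabet if s != "-"]
            full = sum(1 << alphabet.index(s) for s in nongap) or index.get("-", 1)
            col = [
                full if states[j] == "-" else index[states[j]]
                for states in chars.haplotype_states
            ]
        else:
            col = [index[states[j]] for states in chars.haplotype_states]
        masks.append(col)
    return masks, alphabets


def _postorder(edges: Sequence[tuple[int, int]], root: int):
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w != parent[u]:
                parent[w] = u
                order.append(w)
                stack.append(w)
    order.reverse()  # children before parents
    children = {u: [w for w in adj[u] if w != parent[u]] for u in order}
    return order, parent, children


def _score_edges(
    edges: Sequence[tuple[int, int]], masks: Sequence[Sequence[int]]
) -> tuple[int, list[int]]:
    """Fitch length of a tree given per-character leaf masks.

    The tree is rooted at leaf 0 for traversal; the score is rooting-
    invariant. Leaves are the nodes with ids < len(masks[j]).
    """
    order, _parent, children = _postorder(edges, 0)
    n_leaves_present = sum(1 for u in order if not children[u])
    per_char = []
    for col in masks:
        node_mask: dict[int, int] = {}
        steps = 0
        for u in order:
            kids = children[u]
            if not kids:
                node_mask[u] = col[u]
                continue
            m = node_mask[kids[0]]
            for k in kids[1:]:
                inter = m & node_mask[k]
                if inter:
                    m = inter
                else:
                    m |= node_mask[k]
                    steps += 1
            if u < len(col):  # rooted at a leaf: combine its own state
                inter = m & col[u]
                if inter:
                    m = inter
                else:
                    m |= col[u]
                    steps += 1
            node_mask[u] = m
        per_char.append(steps)
    del n_leaves_present
    return sum(per_char), per_char


def fitch_length(
    tree: UnrootedTree, chars: CharacterMatrix, gap_mode: GapMode = "fifth_state"
) -> tuple[int, tuple[int, ...]]:
    """Minimum number of state changes on *tree* under Fitch parsimony.

    Returns ``(total, per_character)``. Tree leaves must be exactly the
    matrix haplotypes (any order).
    """
    if set(tree.leaf_labels) != set(chars.haplotype_names):
        raise ShapeError("tree leaves do not match matrix haplotypes")
    masks, _ = _leaf_masks(chars, gap_mode)
    # reorder leaf masks to the tree's leaf numbering
    hap_index = {h: i for i, h in enumerate(chars.haplotype_names)}
    perm = [hap_index[lab] for lab in tree.leaf_labels]
    masks = [[col[p] for p in perm] for col in masks]
    total, per_char = _score_edges(tree.edges, masks)
    return total, tuple(per_char)


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------


def character_extremes(
    chars: CharacterMatrix, gap_mode: GapMode = "fifth_state"
) -> tuple[list[int], list[int]]:
    """Per-character (m_i, g_i): the minimum conceivable steps on any
    tree (observed states - 1) and the steps on the star tree (taxa
    minus the most frequent state's count)."""
    m_list, g_list = [], []
    for j in range(chars.n_characters):
        counts = chars.state_counts(j)
        if gap_mode == "missing":
            counts = {s: c for s, c in counts.items() if s != "-"}
        if not counts:
            m_list.append(0)
            g_list.append(0)
            continue
        m_list.append(len(counts) - 1)
        g_list.append(sum(counts.values()) - max(counts.values()))
    return m_list, g_list


def consistency_index(
    per_character_steps: Sequence[int],
    chars: CharacterMatrix,
    gap_mode: GapMode = "fifth_state",
) -> float:
    """CI = sum(m_i) / sum(s_i); 1 means homoplasy-free."""
    m_list, _ = character_extremes(chars, gap_mode)
    total_steps = sum(per_character_steps)
    if total_steps == 0:
        raise UndefinedStatisticError("CI undefined on a zero-length tree")
    return sum(m_list) / total_steps


class RetentionIndexResult(NamedTuple):
    value: float
    degenerate: bool


def retention_index(
    per_character_steps: Sequence[int],
    chars: CharacterMatrix,
    gap_mode: GapMode = "fifth_state",
) -> RetentionIndexResult:
    """RI = (sum g_i - sum s_i) / (sum g_i - sum m_i).

    When every character is an autapomorphy (g == m for all), the ratio
    is 0/0; the conventional value 1 is reported with ``degenerate``
    set.
    """
    m_list, g_list = character_extremes(chars, gap_mode)
    g, m, s = sum(g_list), sum(m_list), sum(per_character_steps)
    if g == m:
        return RetentionIndexResult(1.0, True)
    return RetentionIndexResult((g - s) / (g - m), False)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


@dataclass
class ParsimonyResult:
    """All most-parsimonious trees plus scores and indices."""

    trees: list[UnrootedTree]
    length: int
    per_character_steps: tuple[int, ...]
    ci: float
    ri: float
    ri_degenerate: bool
    informative_character_count: int
    chars: CharacterMatrix
    gap_mode: GapMode = "fifth_state"

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _stepwise_addition_tree(
    labels: tuple[str, ...], masks: Sequence[Sequence[int]]
) -> tuple[list[tuple[int, int]], int]:
    """Greedy stepwise-addition tree (deterministic; seeds the bound)."""
    n = len(labels)
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for leaf in range(3, n):
        best_edges = None
        best_score = None
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            cand = edges[:i] + edges[i + 1:] + [(u, w), (v, w), (leaf, w)]
            score, _ = _score_edges(cand, masks)
            if best_score is None or score < best_score:
                best_score = score
                best_edges = cand
        edges = best_edges  # type: ignore[assignment]
        next_internal += 1
    score, _ = _score_edges(edges, masks)
    return edges, score


def mp_search(
    chars: CharacterMatrix,
    mode: Literal["auto", "exhaustive", "branch_and_bound"] = "auto",
    gap_mode: GapMode = "fifth_state",
    cap: int = 16,
) -> ParsimonyResult:
    """Exact maximum-parsimony search returning ALL optimal trees.

    ``auto`` enumerates exhaustively for up to 9 haplotypes and uses
    branch-and-bound (bound seeded by stepwise addition) above that.
    Haplotype counts beyond *cap* raise :class:`CapacityError` — dedupe
    or subset the matrix instead.
    """
    n = chars.n_haplotypes
    if n < 2:
        raise InsufficientDataError("parsimony needs at least two haplotypes")
    if n > cap:
        raise CapacityError(
            f"{n} haplotypes exceeds the exact-search cap ({cap}); "
            "deduplicate or subset the matrix"
        )
    labels = chars.haplotype_names
    masks, _ = _leaf_masks(chars, gap_mode)

    if mode == "auto":
        mode = "exhaustive" if n <= 9 else "branch_and_bound"

    best_trees: list[tuple[tuple[int, int], ...]] = []
    best_score: int | None = None

    if n == 2:
        best_trees = [((0, 1),)]
        best_score, _ = _score_edges(best_trees[0], masks)
    elif mode == "exhaustive":
        def recurse(edges: list[tuple[int, int]], next_leaf: int, nxt: int):
            nonlocal best_score, best_trees
            if next_leaf == n:
                score, _ = _score_edges(edges, masks)
                if best_score is None or score < best_score:
                    best_score = score
                    best_trees = [tuple(edges)]
                elif score == best_score:
                    best_trees.append(tuple(edges))
                return
            for i in range(len(edges)):
                u, v = edges[i]
                cand = edges[:i] + edges[i + 1:] + [(u, nxt), (v, nxt), (next_leaf, nxt)]
                recurse(cand, next_leaf + 1, nxt + 1)

        recurse([(0, n), (1, n), (2, n)], 3, n + 1)
    else:  # branch and bound
        _seed_edges, seed_score = _stepwise_addition_tree(labels, masks)
        best_score = None
        upper = seed_score

        def recurse_bb(edges: list[tuple[int, int]], next_leaf: int, nxt: int):
            nonlocal best_score, best_trees, upper
            score, _ = _score_edges(edges, masks)
            if score > upper:
                return  # adding leaves never decreases the length
            if next_leaf == n:
                if best_score is None or score < best_score:
                    best_score = score
                    upper = score
                    best_trees = [tuple(edges)]
                elif score == best_score:
                    best_trees.append(tuple(edges))
                return
            for i in range(len(edges)):
                u, v = edges[i]
                cand = edges[:i] + edges[i + 1:] + [(u, nxt), (v, nxt), (next_leaf, nxt)]
                recurse_bb(cand, next_leaf + 1, nxt + 1)

        recurse_bb([(0, n), (1, n), (2, n)], 3, n + 1)

    assert best_score is not None
    trees = [UnrootedTree(labels, e) for e in best_trees]
    _, per_char = _score_edges(best_trees[0], masks)
    ci = consistency_index(per_char, chars, gap_mode) if best_score else float("nan")
    ri = retention_index(per_char, chars, gap_mode)
    return ParsimonyResult(
        trees,
        best_score,
        tuple(per_char),
        ci,
        ri.value,
        ri.degenerate,
        len(informative_characters(chars)),
        chars,
        gap_mode,
    )


# ---------------------------------------------------------------------------
# Branch mapping
# ---------------------------------------------------------------------------


def map_changes_to_branches(
    tree: UnrootedTree, chars: CharacterMatrix, gap_mode: GapMode = "fifth_state"
) -> dict[tuple[int, int], list[tuple[int, str, str]]]:
    """One minimal Fitch assignment; per-branch ``(position, from, to)``.

    Ambiguities in the backtrace are broken toward the parent's state
    when available, else the lowest state in A<C<G<T<- order, so the
    mapping is deterministic. The per-branch change counts sum to the
    tree length. Keys are node-id edges of *tree* (leaf ids index
    ``tree.leaf_labels``).
    """
    if set(tree.leaf_labels) != set(chars.haplotype_names):
        raise ShapeError("tree leaves do not match matrix haplotypes")
    masks, alphabets = _leaf_masks(chars, gap_mode)
    hap_index = {h: i for i, h in enumerate(chars.haplotype_names)}
    perm = [hap_index[lab] for lab in tree.leaf_labels]
    masks = [[col[p] for p in perm] for col in masks]

    order, parent, children = _postorder(tree.edges, 0)
    changes: dict[tuple[int, int], list[tuple[int, str, str]]] = {
        tuple(sorted(e)): [] for e in tree.edges
    }
    for j, col in enumerate(masks):
        alphabet = alphabets[j]
        node_mask: dict[int, int] = {}
        for u in order:
            kids = children[u]
            if not kids:
                node_mask[u] = col[u]
                continue
            m = node_mask[kids[0]]
            for k in kids[1:]:
                inter = m & node_mask[k]
                m = inter if inter else (m | node_mask[k])
            if u < len(col):
                inter = m & col[u]
                m = inter if inter else (m | col[u])
            node_mask[u] = m
        # top-down assignment from the root leaf
        state: dict[int, int] = {}
        root = order[-1]  # a leaf: its assignment is its own observed state
        root_inter = node_mask[root] & col[root]
        state[root] = _lowest_bit(root_inter if root_inter else col[root])
        for u in reversed(order[:-1]):
            p = parent[u]
            if state[p] & node_mask[u]:
                state[u] = state[p]
            else:
                state[u] = _lowest_bit(node_mask[u])
            if state[u] != state[p]:
                edge = tuple(sorted((p, u)))
                changes[edge].append(
                    (
                        chars.positions[j],
                        alphabet[state[p].bit_length() - 1],
                        alphabet[state[u].bit_length() - 1],
                    )
                )
    return changes


def _lowest_bit(mask: int) -> int:
    return mask & -mask


def collapse_zero_change_branches(
    tree: UnrootedTree, chars: CharacterMatrix, gap_mode: GapMode = "fifth_state"
) -> UnrootedTree:
    """Contract internal branches carrying no character changes.

    Binary resolutions of a polytomy are equally parsimonious and differ
    only by zero-change branches; after contraction they yield the same
    (possibly multifurcating) tree, which is the tree a parsimony
    program reports once zero-length branches are collapsed.
    """
    changes = map_changes_to_branches(tree, chars, gap_mode)
    n = tree.n_leaves
    # union-find over nodes joined by zero-change internal branches
    rep = {u: u for e in tree.edges for u in e}

    def find(x: int) -> int:
        while rep[x] != x:
            rep[x] = rep[rep[x]]
            x = rep[x]
        return x

    for (u, v), ch in changes.items():
        if not ch and u >= n and v >= n:  # keep leaf edges
            rep[find(u)] = find(v)
    internal = sorted({find(x) for x in rep} - set(range(n)))
    remap = {x: x for x in range(n)}
    remap.update({x: n + i for i, x in enumerate(internal)})
    edges = sorted(
        {
            (a, b)
            for u, v in tree.edges
            for a, b in [tuple(sorted((remap[find(u)], remap[find(v)])))]
            if a != b
        }
    )
    return UnrootedTree(tree.leaf_labels, tuple(edges))


def distinct_mp_trees(result: "ParsimonyResult") -> list[UnrootedTree]:
    """MP trees after contracting zero-change branches, deduplicated."""
    seen: list[UnrootedTree] = []
    for t in result.trees:
        c = collapse_zero_change_branches(t, result.chars, result.gap_mode)
        if c not in seen:
            seen.append(c)
    return seen


# ---------------------------------------------------------------------------
# Compatibility
# ---------------------------------------------------------------------------


def is_perfectly_compatible(chars: CharacterMatrix) -> bool:
    """True iff all characters are pairwise compatible (four-gamete test
    on every pair of state-subsets). A perfectly compatible matrix admits
    a tree on which every character changes exactly (states-1) times, so
    the MP length equals sum(m_i) and CI = RI = 1."""
    n = chars.n_haplotypes
    partitions: list[list[frozenset[int]]] = []
    for j in range(chars.n_characters):
        by_state: dict[str, set[int]] = {}
        for i, states in enumerate(chars.haplotype_states):
            by_state.setdefault(states[j], set()).add(i)
        partitions.append([frozenset(v) for v in by_state.values()])
    universe = frozenset(range(n))
    for a in range(len(partitions)):
        for b in range(a + 1, len(partitions)):
            for S in partitions[a]:
                for T in partitions[b]:
                    if (
                        S & T
                        and S - T
                        and T - S
                        and universe - (S | T)
                    ):
                        return False
    return True


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def to_newick(
    tree: UnrootedTree,
    members: dict[str, Sequence[str]] | None = None,
    sep: str = "|",
) -> str:
    """Newick string for an unrooted tree (trifurcation at the internal
    node adjacent to the first leaf; ``(A,B);`` for two leaves).

    With *members*, each haplotype label is expanded to its member
    accessions joined by *sep*.
    """
    def label(leaf: int) -> str:
        name = tree.leaf_labels[leaf]
        if members is not None and name in members:
            return sep.join(members[name])
        return name

    adj = tree.neighbors()
    if tree.n_leaves == 2:
        return f"({label(0)},{label(1)});"

    def write(node: int, parent: int) -> str:
        if node < tree.n_leaves:
            return label(node)
        parts = [write(w, node) for w in adj[node] if w != parent]
        return "(" + ",".join(parts) + ")"

    root = adj[0][0]  # internal node next to leaf 0
    parts = [write(w, root) for w in adj[root]]
    return "(" + ",".join(parts) + ");"


def from_newick(newick: str) -> UnrootedTree:
    """Parse a Newick string into an :class:`UnrootedTree`.

    A rooted-binary root (two children) is suppressed so that
    ``from_newick(to_newick(t)) == t`` for any tree produced here.
    """
    dt = dendropy.Tree.get(data=newick, schema="newick")
    dt.is_rooted = False
    leaves = [lf.taxon.label for lf in dt.leaf_node_iter()]
    leaf_id = {lab: i for i, lab in enumerate(leaves)}
    n = len(leaves)
    if n == 2:
        return UnrootedTree(tuple(leaves), ((0, 1),))
    next_internal = n
    node_id: dict = {}
    edges: list[tuple[int, int]] = []
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            node_id[node] = leaf_id[node.taxon.label]
        else:
            node_id[node] = next_internal
            next_internal += 1
        if node.parent_node is not None:
            edges.append((node_id[node.parent_node], node_id[node]))
    # suppress degree-2 nodes (e.g. a rooted-binary seed node)
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for node in [u for u in adj if u >= n and len(adj[u]) == 2]:
        a, b = sorted(adj[node])
        adj[a].discard(node)
        adj[b].discard(node)
        adj[a].add(b)
        adj[b].add(a)
        del adj[node]
    # renumber internal nodes compactly
    internal = sorted(u for u in adj if u >= n)
    remap = {u: u for u in range(n)}
    remap.update({u: n + i for i, u in enumerate(internal)})
    final_edges = sorted(
        tuple(sorted((remap[u], remap[v])))
        for u in adj
        for v in adj[u]
        if remap[u] < remap[v]
    )
    return UnrootedTree(tuple(leaves), tuple(final_edges))
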