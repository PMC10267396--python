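"""Presence/absence marker matrices and maximum-parsimony lineage trees.

Each de novo insertion locus is a binary, effectively irreversible clade
marker: it is present in every region descended from the cell in which the
retrotransposition occurred and absent elsewhere. The union of all
regions' event intervals (merged across regions) defines the reference
loci; the regions x loci presence/absence matrix is the character matrix
for an exhaustive maximum-parsimony search (Fitch small parsimony,
unordered binary characters), rooted on a declared outgroup for reporting.
Branch lengths are reported in steps and branch support by non-parametric
bootstrap over loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genomic_core import (
    GenomicInterval,
    IntervalSet,
    ValidationError,
    merge_overlapping,
)

__all__ = [
    "MarkerMatrix",
    "ParsimonyResult",
    "build_reference_positions",
    "presence_absence_matrix",
    "shared_set_counts",
    "SharedSetCounts",
    "enumerate_topologies",
    "fitch_length",
    "mp_search",
    "bootstrap_support",
    "count_informative_positions",
    "matrix_to_sequences",
    "sequences_to_matrix",
    "to_newick",
    "write_phylip",
    "write_character_fasta",
]

Topology = Tuple  # nested tuples of leaf-name strings

PRESENT_CHAR = "A"
ABSENT_CHAR = "T"


@dataclass
class MarkerMatrix:
    """Binary presence/absence characters: regions x reference loci."""

    regions: List[str]
    loci: List[GenomicInterval]
    states: np.ndarray  # shape (R, L), dtype uint8, values {0, 1}

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.shape != (len(self.regions), len(self.loci)):
            raise ValidationError("states shape does not match regions x loci")
        if self.states.size and not np.isin(self.states, (0, 1)).all():
            raise ValidationError("states must be binary")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, region: str) -> np.ndarray:
        return self.states[self.regions.index(region)]


def build_reference_positions(
    event_sets: Dict[str, IntervalSet]
) -> IntervalSet:
    """Union of all regions' event intervals, merged into reference loci."""
    if len(event_sets) < 2:
        raise ValidationError("need events from at least two regions")
    all_ivs = [
        GenomicInterval(iv.chrom, iv.start, iv.end)
        for ivs in event_sets.values()
        for iv in ivs
    ]
    return merge_overlapping(IntervalSet(all_ivs))


def presence_absence_matrix(
    reference: IntervalSet, event_sets: Dict[str, IntervalSet]
) -> MarkerMatrix:
    """state(region, locus) = 1 iff any of the region's events overlaps it."""
    regions = sorted(event_sets)
    loci = list(reference)
    states = np.zeros((len(regions), len(loci)), dtype=np.uint8)
    for ri, region in enumerate(regions):
        evs = event_sets[region]
        for li, locus in enumerate(loci):
            if evs.overlaps_any(locus):
                states[ri, li] = 1
    if len(loci) and (states.sum(axis=0) == 0).any():
        raise ValidationError(
            "reference locus with no supporting region contradicts construction"
        )
    return MarkerMatrix(regions, loci, states)


@dataclass
class SharedSetCounts:
    exact: Dict[FrozenSet[str], int]
    n_all_regions: int
    n_shared_multi: int  # loci present in >1 region


def shared_set_counts(matrix: MarkerMatrix) -> SharedSetCounts:
    """Venn-style counts: loci present in exactly each region subset."""
    exact: Dict[FrozenSet[str], int] = {}
    R = len(matrix.regions)
    for col in matrix.states.T:
        subset = frozenset(
            r for r, s in zip(matrix.regions, col) if s
        )
        exact[subset] = exact.get(subset, 0) + 1
    n_all = exact.get(frozenset(matrix.regions), 0)
    n_multi = sum(v for k, v in exact.items() if len(k) > 1)
    return SharedSetCounts(exact, n_all, n_multi)


# ---------------------------------------------------------------------------
# Topology enumeration and Fitch parsimony
# ---------------------------------------------------------------------------

MAX_EXHAUSTIVE_TAXA = 10  # 2,027,025 topologies; beyond this is unsupported


def _rooted_trees(leaves: Sequence[str]):
    """All rooted binary trees over ``leaves`` by stepwise insertion."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in _rooted_trees(leaves[:-1]):
        yield from _insertions(sub, leaves[-1])


def _insertions(tree, taxon):
    yield (taxon, tree)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, taxon):
            yield (t, right)
        for t in _insertions(right, taxon):
            yield (left, t)


def enumerate_topologies(leaves: Sequence[str], anchor: Optional[str] = None):
    """All unrooted topologies, represented rooted at ``anchor``'s edge.

    An unrooted binary tree over n taxa corresponds bijectively to a rooted
    binary tree over the remaining n-1 taxa once one taxon is fixed as the
    attachment point; each yielded topology is the pair
    ``(anchor, rooted_tree_over_rest)``.
    """
    leaves = list(leaves)
    if len(set(leaves)) != len(leaves):
        raise ValidationError("duplicate leaf labels")
    if len(leaves) < 4:
        raise ValidationError("need at least 4 taxa")
    if len(leaves) > MAX_EXHAUSTIVE_TAXA:
        raise ValidationError(
            f"exhaustive search unsupported beyond {MAX_EXHAUSTIVE_TAXA} taxa"
        )
    if anchor is None:
        anchor = leaves[0]
    if anchor not in leaves:
        raise ValidationError(f"anchor {anchor!r} is not a leaf")
    rest = sorted(l for l in leaves if l != anchor)
    for t in _rooted_trees(rest):
        yield (anchor, t)


def _leaf_masks(matrix: MarkerMatrix) -> Dict[str, np.ndarray]:
    # bitmask per character: 1 -> absent (state 0), 2 -> present (state 1)
    return {
        r: (matrix.states[i] + 1).astype(np.uint8)
        for i, r in enumerate(matrix.regions)
    }


def _fitch_down(node, masks: Dict[str, np.ndarray], steps: np.ndarray) -> np.ndarray:
    if isinstance(node, str):
        return masks[node]
    left = _fitch_down(node[0], masks, steps)
    right = _fitch_down(node[1], masks, steps)
    inter = left & right
    empty = inter == 0
    steps += empty
    return np.where(empty, left | right, inter)


def fitch_length(
    topology: Topology, matrix: MarkerMatrix
) -> Tuple[int, np.ndarray]:
    """Minimum number of state changes on ``topology``.

    Returns (total steps, per-character steps). The topology's leaves must
    be exactly the matrix regions.
    """
    if _leafset(topology) != frozenset(matrix.regions):
        raise ValidationError("topology leaves do not match matrix regions")
    steps = np.zeros(matrix.n_loci, dtype=np.int64)
    _fitch_down(topology, _leaf_masks(matrix), steps)
    return int(steps.sum()), steps


def _leafset(node) -> FrozenSet[str]:
    if isinstance(node, str):
        return frozenset((node,))
    return _leafset(node[0]) | _leafset(node[1])


def _clades(node, out: List[FrozenSet[str]]) -> FrozenSet[str]:
    if isinstance(node, str):
        c = frozenset((node,))
    else:
        c = _clades(node[0], out) | _clades(node[1], out)
    out.append(c)
    return c


def internal_bipartitions(topology: Topology) -> List[FrozenSet[str]]:
    """Non-trivial bipartitions of an unrooted topology ``(anchor, rest)``,
    each named by the leaf side not containing the anchor taxon."""
    anchor, rest = topology
    n = len(_leafset(topology))
    clades: List[FrozenSet[str]] = []
    _clades(rest, clades)
    return [c for c in clades if 1 < len(c) < n - 1]


def _branch_steps(
    topology: Topology, matrix: MarkerMatrix
) -> Dict[FrozenSet[str], int]:
    """Per-branch steps from a deterministic minimum-length refinement.

    Top-down pass over the Fitch state sets: each node takes its parent's
    state whenever compatible (the root takes the outgroup/anchor state,
    fixing character polarity); changes are charged to the branch above the
    node where the state differs from the parent.
    """
    anchor, rest = topology
    masks = _leaf_masks(matrix)
    sets: Dict[int, np.ndarray] = {}
    kids: Dict[int, Tuple] = {}
    clade_of: Dict[int, FrozenSet[str]] = {}
    counter = [0]

    def down(node) -> Tuple[int, np.ndarray]:
        nid = counter[0]
        counter[0] += 1
        if isinstance(node, str):
            s = masks[node]
            clade_of[nid] = frozenset((node,))
        else:
            lid, ls = down(node[0])
            rid, rs = down(node[1])
            inter = ls & rs
            s = np.where(inter == 0, ls | rs, inter)
            kids[nid] = (lid, rid)
            clade_of[nid] = clade_of[lid] | clade_of[rid]
        sets[nid] = s
        return nid, s

    top_id, top_set = down(rest)
    root_state = masks[anchor]  # anchor state is always in the root set
    branch: Dict[FrozenSet[str], int] = {frozenset((anchor,)): 0}

    def up(nid: int, parent_state: np.ndarray) -> None:
        s = sets[nid]
        compat = (parent_state & s) != 0
        state = np.where(compat, parent_state, s)
        branch[clade_of[nid]] = int((state != parent_state).sum())
        if nid in kids:
            lid, rid = kids[nid]
            up(lid, state)
            up(rid, state)

    up(top_id, root_state)
    return branch


@dataclass
class ParsimonyResult:
    """Outcome of an exhaustive maximum-parsimony search."""

    topology: Topology                      # rooted on the outgroup
    outgroup: str
    tree_length: int
    per_character_steps: np.ndarray
    branch_steps: Dict[FrozenSet[str], int]
    co_optimal: List[Topology]
    informative_sites: int                  # >=2 and <= R-1 regions present
    informative_sites_standard: int         # >=2 regions in each state
    bootstrap: Optional[Dict[FrozenSet[str], float]] = None

    def check_invariants(self) -> None:
        total = int(self.per_character_steps.sum())
        branch_sum = sum(self.branch_steps.values())
        if not (self.tree_length == total == branch_sum):
            raise AssertionError(
                f"tree length invariant violated: {self.tree_length}, "
                f"chars {total}, branches {branch_sum}"
            )


def _char_steps_all(
    matrix: MarkerMatrix, outgroup: str
) -> Tuple[List[Topology], np.ndarray]:
    """Per-character Fitch steps for every topology: (topologies, T x L)."""
    topologies = list(enumerate_topologies(matrix.regions, anchor=outgroup))
    masks = _leaf_masks(matrix)
    out = np.zeros((len(topologies), matrix.n_loci), dtype=np.int64)
    for i, topo in enumerate(topologies):
        steps = np.zeros(matrix.n_loci, dtype=np.int64)
        _fitch_down(topo, masks, steps)
        out[i] = steps
    return topologies, out


def mp_search(matrix: MarkerMatrix, outgroup: str) -> ParsimonyResult:
    """Exhaustive maximum-parsimony search over all unrooted topologies.

    The first minimal-length topology in the deterministic enumeration
    order is reported, rooted on the outgroup; all co-optimal topologies
    are retained.
    """
    if outgroup not in matrix.regions:
        raise ValidationError(f"outgroup {outgroup!r} is not a region")
    topologies, char_steps = _char_steps_all(matrix, outgroup)
    lengths = char_steps.sum(axis=1)
    best_len = int(lengths.min())
    co_idx = np.flatnonzero(lengths == best_len)
    best_i = int(co_idx[0])
    paper_inf, std_inf = count_informative_positions(matrix)
    result = ParsimonyResult(
        topology=topologies[best_i],
        outgroup=outgroup,
        tree_length=best_len,
        per_character_steps=char_steps[best_i],
        branch_steps=_branch_steps(topologies[best_i], matrix),
        co_optimal=[topologies[i] for i in co_idx],
        informative_sites=paper_inf,
        informative_sites_standard=std_inf,
    )
    result.check_invariants()
    return result


def bootstrap_support(
    matrix: MarkerMatrix,
    outgroup: str,
    replicates: int = 1_000,
    seed: int = 0,
) -> Dict[FrozenSet[str], float]:
    """Bootstrap branch support: resample loci with replacement.

    Support of a bipartition is the percentage of replicates whose MP
    tree(s) contain it; when a replicate has k co-optimal trees, each
    contributes 1/k.
    """
    topologies, char_steps = _char_steps_all(matrix, outgroup)
    biparts = [internal_bipartitions(t) for t in topologies]
    L = matrix.n_loci
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=replicates)
    lengths = char_steps @ weights.T  # (T, B)
    mins = lengths.min(axis=0)
    support: Dict[FrozenSet[str], float] = {}
    for b in range(replicates):
        co = np.flatnonzero(lengths[:, b] == mins[b])
        w = 1.0 / len(co)
        for ti in co:
            for bp in biparts[ti]:
                support[bp] = support.get(bp, 0.0) + w
    return {bp: 100.0 * v / replicates for bp, v in support.items()}


def count_informative_positions(matrix: MarkerMatrix) -> Tuple[int, int]:
    """(lineage-informative count, standard parsimony-informative count).

    The lineage definition counts a locus informative when present in at
    least two but not all regions (singletons and fully shared loci carry
    no branching signal); the standard definition requires at least two
    regions in each character state.
    """
    ones = matrix.states.sum(axis=0)
    R = len(matrix.regions)
    paper = int(((ones >= 2) & (ones <= R - 1)).sum())
    standard = int(((ones >= 2) & (R - ones >= 2)).sum())
    return paper, standard


# ---------------------------------------------------------------------------
# Character-matrix encoding and tree export
# ---------------------------------------------------------------------------


def matrix_to_sequences(matrix: MarkerMatrix) -> Dict[str, str]:
    """Encode each region's presence/absence row as an A/T sequence."""
    lut = np.frombuffer(f"{ABSENT_CHAR}{PRESENT_CHAR}".encode(), dtype=np.uint8)
    return {
        r: lut[matrix.states[i]].tobytes().decode("ascii")
        for i, r in enumerate(matrix.regions)
    }


def sequences_to_matrix(
    seqs: Dict[str, str], loci: Optional[List[GenomicInterval]] = None
) -> MarkerMatrix:
    regions = sorted(seqs)
    L = len(next(iter(seqs.values())))
    if any(len(s) != L for s in seqs.values()):
        raise ValidationError("sequences must have equal length")
    states = np.zeros((len(regions), L), dtype=np.uint8)
    for i, r in enumerate(regions):
        row = np.frombuffer(seqs[r].encode(), dtype=np.uint8)
        states[i] = (row == ord(PRESENT_CHAR)).astype(np.uint8)
    if loci is None:
        loci = [GenomicInterval("locus", i, i + 1) for i in range(L)]
    return MarkerMatrix(regions, loci, states)


def write_phylip(matrix: MarkerMatrix, path) -> None:
    seqs = matrix_to_sequences(matrix)
    lines = [f" {len(matrix.regions)} {matrix.n_loci}"]
    for r in matrix.regions:
        lines.append(f"{r}  {seqs[r]}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def write_character_fasta(matrix: MarkerMatrix, path) -> None:
    seqs = matrix_to_sequences(matrix)
    from pathlib import Path

    Path(path).write_text(
        "".join(f">{r}\n{seqs[r]}\n" for r in matrix.regions)
    )


def to_newick(result: ParsimonyResult) -> str:
    """Newick string, branch lengths in steps, bootstrap as internal labels."""
    branch = result.branch_steps
    supports = result.bootstrap or {}
    n = len(_leafset(result.topology))

    def fmt(node) -> str:
        if isinstance(node, str):
            return f"{node}:{branch.get(frozenset((node,)), 0)}"
        clade = _leafset(node)
        label = ""
        if 1 < len(clade) < n - 1 and clade in supports:
            label = f"{supports[clade]:.0f}"
        children = ",".join(fmt(c) for c in node)
        length = branch.get(clade, 0)
        return f"({children}){label}:{length}"

    anchor, rest = result.topology
    return f"({fmt(anchor)},{fmt(rest)});"
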