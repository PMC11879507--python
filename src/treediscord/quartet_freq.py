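"""Per-branch quartet topology frequencies computed from gene trees.

Each internal branch of a rooted species tree induces a quadripartition of
the taxa: the branch's two child clades (L, R), the sister clade (S), and
everything else (O).  Sampling one taxon per class from a gene tree yields
an unrooted quartet whose topology either matches the species tree
(``LR | S.``) or one of the two alternatives; tallying these over all gene
trees gives the (q1, q2, q3) frequencies consumed by the ILS/IH estimator.
This is the same quantity ASTRAL annotates its species trees with, computed
here directly so no external scoring run is needed.

For a branch whose parent is the root the fourth class is empty and the
rooted-triplet equivalent (one taxon from each of L, R, S on a rooted gene
tree) is scored instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .astral_io import AnnotatedSpeciesTree, GeneTreeSet
from .indices import TopologyFrequencies, canonicalize

__all__ = [
    "Quadripartition",
    "branch_quadripartition",
    "induced_quartet_topology",
    "induced_triplet_topology",
    "count_branch_frequencies",
    "attach_frequencies",
]


@dataclass(frozen=True)
class Quadripartition:
    """The four disjoint taxon sets induced by an internal branch."""

    left: FrozenSet[str]
    right: FrozenSet[str]
    sister: FrozenSet[str]
    rest: FrozenSet[str]

    def __post_init__(self) -> None:
        sets = (self.left, self.right, self.sister, self.rest)
        if not (self.left and self.right and self.sister):
            raise ValueError("left, right and sister classes must be non-empty")
        total = sum(len(s) for s in sets)
        if len(self.left | self.right | self.sister | self.rest) != total:
            raise ValueError("quadripartition classes must be disjoint")


def _leaf_labels(node: dendropy.Node) -> FrozenSet[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def branch_quadripartition(ast: AnnotatedSpeciesTree,
                           node: dendropy.Node) -> Quadripartition:
    """Quadripartition induced by the branch above ``node``.

    L and R are the node's first child clade and the union of the others;
    S is the sister clade; O is everything left (possibly empty when the
    parent is the root of the tree).
    """
    if node.is_leaf():
        raise ValueError("terminal branches induce no quadripartition")
    parent = node.parent_node
    if parent is None:
        raise ValueError("the root has no branch above it")
    children = node.child_nodes()
    left = _leaf_labels(children[0])
    right = frozenset().union(*(_leaf_labels(c) for c in children[1:]))
    sister = frozenset().union(
        *(_leaf_labels(sib) for sib in parent.child_nodes() if sib is not node)
    )
    all_taxa = ast.taxa()
    rest = frozenset(all_taxa - left - right - sister)
    return Quadripartition(left=left, right=right, sister=sister, rest=rest)


def _clade_masks(tree: dendropy.Tree) -> Tuple[Dict[str, int], List[int]]:
    """Bitmask of the leaf set below every node, cached on the tree."""
    cached = getattr(tree, "_td_clade_masks", None)
    if cached is not None:
        return cached
    bit: Dict[str, int] = {}
    masks: List[int] = []
    node_mask: Dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in bit:
                bit[label] = 1 << len(bit)
            node_mask[id(node)] = bit[label]
        else:
            m = 0
            for child in node.child_nodes():
                m |= node_mask[id(child)]
            node_mask[id(node)] = m
            masks.append(m)
    tree._td_clade_masks = (bit, masks)
    return bit, masks


def _quartet_bits(tree: dendropy.Tree, labels: Sequence[str]) -> List[int]:
    bit, _ = _clade_masks(tree)
    try:
        return [bit[label] for label in labels]
    except KeyError as exc:
        raise ValueError(f"taxon {exc.args[0]!r} missing from gene tree") from exc


def induced_quartet_topology(gene_tree: dendropy.Tree,
                             a: str, b: str, c: str, d: str) -> Optional[int]:
    """Topology of the quartet {a, b, c, d} induced by a gene tree.

    Returns 1 for ``ab|cd``, 2 for ``ac|bd``, 3 for ``ad|bc``, or None when
    a polytomy leaves the quartet unresolved.  Works on rooted and unrooted
    gene trees alike (only bipartitions are consulted).
    """
    A, B, C, D = _quartet_bits(gene_tree, (a, b, c, d))
    pair_code = {A | B: 1, C | D: 1, A | C: 2, B | D: 2, A | D: 3, B | C: 3}
    four = A | B | C | D
    _, masks = _clade_masks(gene_tree)
    for mask in masks:
        code = pair_code.get(mask & four)
        if code is not None:
            return code
    return None


def induced_triplet_topology(gene_tree: dendropy.Tree,
                             x: str, y: str, z: str) -> Optional[int]:
    """Rooted-triplet topology: 1 for ``(xy)z``, 2 for ``(xz)y``, 3 for ``(yz)x``.

    The gene tree must be rooted; the cherry is the pair that coalesces
    below the triplet's overall ancestor.  None when a polytomy leaves the
    triplet unresolved.
    """
    X, Y, Z = _quartet_bits(gene_tree, (x, y, z))
    pair_code = {X | Y: 1, X | Z: 2, Y | Z: 3}
    three = X | Y | Z
    _, masks = _clade_masks(gene_tree)
    for mask in masks:
        code = pair_code.get(mask & three)
        if code is not None:
            return code
    return None


def _present_by_class(tree: dendropy.Tree, classes: Sequence[FrozenSet[str]],
                      taxon_map: Optional[Dict[str, str]]) -> List[List[str]]:
    present: List[List[str]] = [[] for _ in classes]
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        species = taxon_map.get(label, label) if taxon_map else label
        for i, cls in enumerate(classes):
            if species in cls:
                present[i].append(label)
                break
    return [sorted(p) for p in present]


def count_branch_frequencies(genes: Iterable[dendropy.Tree],
                             quad: Quadripartition,
                             max_exact: int = 10_000,
                             sample_size: int = 1_000,
                             seed: int = 0,
                             mode: str = "per_gene",
                             taxon_map: Optional[Dict[str, str]] = None,
                             ) -> TopologyFrequencies:
    """Tally the three quartet topologies for one branch over gene trees.

    Every gene tree containing at least one taxon from each class
    contributes; all one-per-class combinations are enumerated exactly when
    their number is at most ``max_exact``, otherwise ``sample_size``
    combinations are drawn uniformly (seeded).  In ``per_gene`` mode each
    gene tree casts one vote, the majority topology of its combinations
    (ties are treated as unresolved); in ``per_quartet`` mode every resolved
    combination counts, ASTRAL-style.  ``n`` is the number of votes cast.
    """
    if mode not in ("per_gene", "per_quartet"):
        raise ValueError(f"unknown counting mode: {mode!r}")
    rng = np.random.default_rng(seed)
    use_triplets = not quad.rest
    classes = ([quad.left, quad.right, quad.sister] if use_triplets
               else [quad.left, quad.right, quad.sister, quad.rest])

    totals = [0, 0, 0]
    for tree in genes:
        present = _present_by_class(tree, classes, taxon_map)
        if any(not p for p in present):
            continue
        sizes = [len(p) for p in present]
        n_combos = int(np.prod(sizes))
        if n_combos <= max_exact:
            combos = itertools.product(*present)
        else:
            idx = [rng.integers(0, s, size=sample_size) for s in sizes]
            combos = (tuple(present[k][idx[k][j]] for k in range(len(present)))
                      for j in range(sample_size))
        tally = [0, 0, 0]
        for combo in combos:
            if use_triplets:
                topo = induced_triplet_topology(tree, *combo)
            else:
                topo = induced_quartet_topology(tree, *combo)
            if topo is not None:
                tally[topo - 1] += 1
        if sum(tally) == 0:
            continue
        if mode == "per_gene":
            best = max(tally)
            winners = [i for i, t in enumerate(tally) if t == best]
            if len(winners) != 1:
                continue  # majority tie: gene tree counted as unresolved
            totals[winners[0]] += 1
        else:
            for i in range(3):
                totals[i] += tally[i]

    if sum(totals) == 0:
        raise ValueError("branch uninformative: no gene tree covers all classes")
    return canonicalize(totals, n=sum(totals))


def attach_frequencies(ast: AnnotatedSpeciesTree,
                       genes: Iterable[dendropy.Tree],
                       max_exact: int = 10_000,
                       sample_size: int = 1_000,
                       seed: int = 0,
                       mode: str = "per_gene",
                       taxon_map: Optional[Dict[str, str]] = None) -> int:
    """Compute and attach frequencies to every internal non-root branch.

    Returns the number of branches annotated; branches no gene tree informs
    are left bare.  Replaces any frequencies parsed from annotations.
    """
    genes = list(genes)
    annotated = 0
    for node in ast.internal_nodes(exclude_root=True):
        quad = branch_quadripartition(ast, node)
        try:
            freqs = count_branch_frequencies(
                genes, quad, max_exact=max_exact, sample_size=sample_size,
                seed=seed, mode=mode, taxon_map=taxon_map,
            )
        except ValueError:
            continue
        ast.set_frequencies(node, freqs, source="counted")
        annotated += 1
    return annotated
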