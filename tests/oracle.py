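"""Independent brute-force oracles used by the test suite only.

The quartet-topology oracle uses the four-point condition on topological
path lengths (sums of pairwise distances), a different algorithm from the
bipartition scan in the package, so agreement between the two is a real
cross-check.
"""

from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np


def path_distance_matrix(tree: dendropy.Tree) -> Tuple[Dict[str, int], np.ndarray]:
    """Topological (edge-count) distances between all leaf pairs."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    index = {lf.taxon.label: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    dist = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix(is_store_path_edges=False)
    for i, li in enumerate(leaves):
        for j, lj in enumerate(leaves):
            if i < j:
                d = pdm.path_edge_count(li.taxon, lj.taxon)
                dist[i, j] = dist[j, i] = d
    return index, dist


def quartet_topology_fourpoint(index: Dict[str, int], dist: np.ndarray,
                               a: str, b: str, c: str, d: str) -> Optional[int]:
    """1 = ab|cd, 2 = ac|bd, 3 = ad|bc, None = unresolved (four-point ties)."""
    ia, ib, ic, id_ = index[a], index[b], index[c], index[d]
    s1 = dist[ia, ib] + dist[ic, id_]
    s2 = dist[ia, ic] + dist[ib, id_]
    s3 = dist[ia, id_] + dist[ib, ic]
    sums = [s1, s2, s3]
    best = min(sums)
    winners = [i for i, s in enumerate(sums) if s == best]
    if len(winners) != 1:
        return None
    return winners[0] + 1


def random_binary_tree(labels: List[str], rng: np.random.Generator) -> dendropy.Tree:
    """Rooted binary tree built by random sequential joins (pure topology)."""
    nodes = [f"{lab}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes[i] = merged
        nodes.pop(j)
    return dendropy.Tree.get(data=nodes[0] + ";", schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
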