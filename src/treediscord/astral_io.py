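"""Reading and writing species trees with ASTRAL-style branch annotations.

ASTRAL/ASTER emit newick species trees whose internal branches carry quartet
supports as bracketed ``key=value`` blocks, either as bare comments
(``)[q1=0.6;q2=0.3;q3=0.1;EN=812.3]:0.2``) or as quoted node labels
(``)'[f1=6000;f2=3000;f3=1000]'``).  This module ingests both dialects into
an :class:`AnnotatedSpeciesTree` (a thin wrapper over a dendropy tree whose
edges carry :class:`~treediscord.indices.TopologyFrequencies`), supports
outgroup rooting, and writes per-branch TSV reports and re-annotated newick.
"""

from __future__ import annotations

import io
import re
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy

from .indices import (
    IndexResult,
    TopologyFrequencies,
    canonicalize,
    classify_node,
    estimate_indices,
    format_percent,
)

__all__ = [
    "AnnotatedSpeciesTree",
    "GeneTreeSet",
    "parse_annotated_newick",
    "read_species_tree",
    "read_gene_trees",
    "read_taxon_map",
    "root_with_outgroup",
    "compute_indices",
    "write_report",
    "REPORT_COLUMNS",
]

#: A set of gene trees; leaves may cover only a subset of the species taxa.
GeneTreeSet = dendropy.TreeList

_KV_RE = re.compile(r"([A-Za-z_][\w.]*)\s*=\s*([-+]?[0-9.][0-9.eE+-]*)")
_FREQ_KEYS = frozenset({"q1", "q2", "q3", "f1", "f2", "f3", "EN", "pp1", "pp"})

REPORT_COLUMNS = (
    "node_id", "q1", "q2", "q3", "n", "chi2", "P",
    "ILS_i", "IH_i", "ILS_e", "IH_e", "category",
)


class AnnotatedSpeciesTree:
    """Rooted species tree whose internal edges may carry quartet supports.

    Annotations live on dendropy ``Edge`` objects (``edge.freqs``,
    ``edge.posterior``, ``edge.extra``, ``edge.freqs_source``) so that they
    survive rerooting, which rewires nodes but keeps edges intact.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, dialect: str = "auto") -> "AnnotatedSpeciesTree":
        return parse_annotated_newick(text, dialect=dialect)

    @classmethod
    def read(cls, path: str, dialect: str = "auto") -> "AnnotatedSpeciesTree":
        with open(path) as fh:
            return parse_annotated_newick(fh.read(), dialect=dialect)

    # -- accessors -----------------------------------------------------

    def taxa(self) -> set:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def internal_nodes(self, exclude_root: bool = False):
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if exclude_root and node is root:
                continue
            yield node

    def annotated_nodes(self) -> List[dendropy.Node]:
        return [n for n in self.internal_nodes() if self.frequencies(n) is not None]

    @staticmethod
    def frequencies(node: dendropy.Node) -> Optional[TopologyFrequencies]:
        return getattr(node.edge, "freqs", None)

    @staticmethod
    def set_frequencies(node: dendropy.Node, freqs: TopologyFrequencies,
                        source: str = "counted") -> None:
        node.edge.freqs = freqs
        node.edge.freqs_source = source

    @staticmethod
    def posterior(node: dendropy.Node) -> Optional[float]:
        return getattr(node.edge, "posterior", None)

    def node_ids(self) -> Dict[dendropy.Node, str]:
        """Stable preorder ids N1, N2, ... for internal nodes."""
        return {node: f"N{i}" for i, node in enumerate(self.internal_nodes(), start=1)}

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True)


def _parse_kv(text: str) -> Dict[str, float]:
    pairs = _KV_RE.findall(text)
    out: Dict[str, float] = {}
    for key, value in pairs:
        try:
            out[key] = float(value)
        except ValueError:
            continue
    return out


def _annotate_node(node: dendropy.Node, dialect: str) -> None:
    candidates: List[str] = []
    candidates.extend(c for c in (node.comments or []))
    candidates.extend(c for c in (node.edge.comments or []))
    if node.label:
        candidates.append(node.label)

    data: Dict[str, float] = {}
    if dialect != "plain":
        for cand in candidates:
            data.update(_parse_kv(cand))

    if {"q1", "q2", "q3"} <= data.keys():
        raw = (data["q1"], data["q2"], data["q3"])
        total = sum(raw)
        if abs(total - 1.0) > 0.05:
            warnings.warn(
                f"q1+q2+q3 = {total:.4f} far from 1 at node; renormalizing",
                stacklevel=2,
            )
        if "EN" in data:
            n = data["EN"]
        elif {"f1", "f2", "f3"} <= data.keys():
            n = data["f1"] + data["f2"] + data["f3"]
        else:
            n = 0.0
        node.edge.freqs = canonicalize(raw, n=n)
        node.edge.freqs_source = "annotation"
    elif {"f1", "f2", "f3"} <= data.keys():
        node.edge.freqs = canonicalize((data["f1"], data["f2"], data["f3"]),
                                       n=data.get("EN"))
        node.edge.freqs_source = "annotation"

    if "pp1" in data:
        node.edge.posterior = data["pp1"]
    elif "pp" in data:
        node.edge.posterior = data["pp"]
    elif node.label and not data:
        try:
            node.edge.posterior = float(node.label)
        except ValueError:
            pass

    extra = {k: v for k, v in data.items() if k not in _FREQ_KEYS}
    if extra:
        node.edge.extra = extra


def parse_annotated_newick(text: str, dialect: str = "auto") -> AnnotatedSpeciesTree:
    """Parse a newick species tree, harvesting ASTRAL-style annotations.

    ``dialect`` is one of ``auto`` (try ``key=value`` blocks in comments and
    quoted labels, fall back to plain support labels), ``astral`` (same,
    but never treat labels as plain supports) or ``plain`` (labels are
    posterior/support values only).  Terminal branches are never annotated.
    """
    if dialect not in ("auto", "astral", "plain"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        _annotate_node(node, dialect)
    return AnnotatedSpeciesTree(tree)


def read_species_tree(path: str, dialect: str = "auto") -> AnnotatedSpeciesTree:
    return AnnotatedSpeciesTree.read(path, dialect=dialect)


def read_gene_trees(source: str, is_path: bool = True) -> GeneTreeSet:
    """Read newick gene trees (one per line); empty input is an error."""
    if is_path:
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    if not text.strip():
        raise ValueError("gene-tree set is empty")
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"gene-tree parse error: {exc}") from exc
    if len(trees) == 0:
        raise ValueError("gene-tree set is empty")
    return trees


def read_taxon_map(path: str) -> Dict[str, str]:
    """Two-column TSV mapping gene-tree tip labels to species-tree taxa."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"taxon map line {line_no}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def root_with_outgroup(ast: AnnotatedSpeciesTree,
                       outgroup: Iterable[str]) -> AnnotatedSpeciesTree:
    """Root the tree on the edge subtending a monophyletic outgroup.

    The input may be rooted or unrooted (trifurcating root); annotations
    ride on edges and are preserved.  A non-monophyletic outgroup is an
    error naming the intruding taxa.
    """
    labels = set(outgroup)
    taxa = ast.taxa()
    missing = labels - taxa
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if labels == taxa:
        raise ValueError("outgroup cannot contain every taxon")

    tree = ast.tree

    def clade_leaves(node):
        return {leaf.taxon.label for leaf in node.leaf_iter()}

    target = tree.mrca(taxon_labels=sorted(labels))
    if clade_leaves(target) != labels:
        complement = taxa - labels
        alt = tree.mrca(taxon_labels=sorted(complement))
        if clade_leaves(alt) == complement:
            target = alt
        else:
            intruders = sorted(clade_leaves(target) - labels)
            raise ValueError(
                f"outgroup {sorted(labels)} is not monophyletic; "
                f"smallest containing clade also holds {intruders}"
            )
    if target is tree.seed_node:
        raise ValueError("outgroup already spans the root; cannot reroot")
    tree.reroot_at_edge(target.edge, update_bipartitions=False)
    return ast


def compute_indices(ast: AnnotatedSpeciesTree, alpha: float = 0.05
                    ) -> Dict[dendropy.Node, IndexResult]:
    """Run the ILS/IH estimator on every annotated internal branch."""
    return {node: estimate_indices(ast.frequencies(node), alpha=alpha)
            for node in ast.annotated_nodes()}


def _fmt_p(p: float) -> str:
    if p != p:  # NaN: branch without an effective gene-tree count
        return "NA"
    return f"{p:.3g}"


def write_report(ast: AnnotatedSpeciesTree,
                 results: Mapping[dendropy.Node, IndexResult],
                 strict: bool = False) -> Tuple[str, str]:
    """Emit the per-node TSV report and an index-annotated newick.

    Returns ``(tsv_text, newick_text)``.  Output is byte-stable for
    identical inputs.  The newick embeds q1/q2/q3/EN (full precision, so a
    re-parse recovers identical indices) plus P, ILS_i and IH_i.
    """
    ids = ast.node_ids()
    buf = io.StringIO()
    buf.write("\t".join(REPORT_COLUMNS) + "\n")
    any_row = False
    for node in ast.internal_nodes():
        if node not in results:
            continue
        any_row = True
        freqs = ast.frequencies(node)
        res = results[node]
        call = classify_node(res, strict=strict)
        row = (
            ids[node],
            f"{freqs.q1:.6f}", f"{freqs.q2:.6f}", f"{freqs.q3:.6f}",
            f"{freqs.n:.6g}",
            f"{res.chi2_stat:.6g}",
            _fmt_p(res.p_value),
            format_percent(res.ils_index),
            format_percent(res.ih_index),
            format_percent(res.ils_explained),
            format_percent(res.ih_explained),
            call.category.value,
        )
        buf.write("\t".join(row) + "\n")
    if not any_row:
        warnings.warn("tree has no annotated branches; report is empty", stacklevel=2)

    saved_labels = {}
    for node in ast.internal_nodes():
        if node in results:
            freqs = ast.frequencies(node)
            res = results[node]
            saved_labels[node] = node.label
            node.label = (
                f"[q1={freqs.q1:.10g};q2={freqs.q2:.10g};q3={freqs.q3:.10g};"
                f"EN={freqs.n:.10g};P={_fmt_p(res.p_value)};"
                f"ILS_i={format_percent(res.ils_index)};"
                f"IH_i={format_percent(res.ih_index)}]"
            )
    newick = ast.as_newick()
    for node, label in saved_labels.items():
        node.label = label
    return buf.getvalue(), newick
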