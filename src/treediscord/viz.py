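"""Species-tree rendering with per-branch topology bar charts.

Each annotated internal node gets a three-bar inset (q1, q2, q3, with a
reference line at 1/3 — the expectation under maximal incomplete lineage
sorting) and a text block listing the effective gene-tree count n, the
symmetry-test P value, and the ILS/IH indices and explained fractions.
Bars are filled when the asymmetry test is significant (an introgression
signal) and hollow otherwise.  SVG output is byte-deterministic for
identical inputs.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import matplotlib

matplotlib.use("Agg")  # noqa: E402 -- headless, deterministic backend
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

import dendropy

from .astral_io import AnnotatedSpeciesTree
from .indices import IndexResult, Resolution, classify_node, format_percent

__all__ = ["render_tree", "PALETTE"]

#: Fixed colors for the species-tree topology (q1) and the two minor ones.
PALETTE = ("#4C72B0", "#DD8452", "#55A868")

_RC = {
    "svg.hashsalt": "treediscord",
    "svg.fonttype": "none",
    "font.family": "DejaVu Sans",
    "font.size": 8.0,
}


def _layout(tree: dendropy.Tree) -> Dict[dendropy.Node, tuple]:
    """Rectangular cladogram coordinates: x = depth, leaves right-aligned."""
    coords: Dict[dendropy.Node, list] = {}
    depth: Dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
    max_depth = max(depth.values())
    y = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            coords[node] = [float(max_depth), float(y)]
            y += 1
        else:
            ys = [coords[c][1] for c in node.child_nodes()]
            coords[node] = [float(depth[node]), sum(ys) / len(ys)]
    return {n: tuple(c) for n, c in coords.items()}


def _fmt_p(p: float) -> str:
    return "NA" if p != p else f"{p:.3g}"


def render_tree(ast: AnnotatedSpeciesTree,
                results: Mapping[dendropy.Node, IndexResult],
                path: str,
                collapse_resolved: bool = False,
                alpha: float = 0.05,
                strict: bool = False) -> str:
    """Render the annotated species tree to ``path`` (format by extension).

    ``collapse_resolved`` hides the bar chart and label block of nodes the
    resolution guideline calls well resolved, leaving bars only at
    conflicted nodes.  Nodes whose species-tree topology was demoted from
    the major slot are flagged with ``*``.  Raises ``ValueError`` when no
    node carries results.
    """
    if not results:
        raise ValueError("no annotated nodes: nothing to render")
    shown = {
        node: res for node, res in results.items()
        if not (collapse_resolved
                and classify_node(res, strict=strict).category
                is Resolution.WELL_RESOLVED)
    }
    tree = ast.tree
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    with matplotlib.rc_context(_RC):
        fig, ax = plt.subplots(
            figsize=(8.0, max(2.5, 0.85 * n_leaves)), dpi=100)
        coords = _layout(tree)
        for node in tree.preorder_node_iter():
            x, y = coords[node]
            if node.parent_node is not None:
                px, _ = coords[node.parent_node]
                ax.plot([px, x], [y, y], color="0.2", lw=1.0,
                        solid_capstyle="butt", zorder=1)
            if not node.is_leaf():
                ys = [coords[c][1] for c in node.child_nodes()]
                ax.plot([x, x], [min(ys), max(ys)], color="0.2", lw=1.0,
                        solid_capstyle="butt", zorder=1)
            else:
                ax.text(x + 0.06, y, node.taxon.label, va="center",
                        ha="left", fontsize=9)

        node_ids = ast.node_ids()
        box_w, box_h = 0.34, 0.85
        for node in ast.internal_nodes():
            if node not in shown:
                continue
            res = shown[node]
            freqs = ast.frequencies(node)
            x, y = coords[node]
            bx, by = x + 0.10, y - box_h / 2.0
            bar_w = box_w / 3.0
            for i, q in enumerate((freqs.q1, freqs.q2, freqs.q3)):
                face = PALETTE[i] if res.significant else "none"
                rect = Rectangle((bx + i * bar_w, by), bar_w * 0.82,
                                 q * box_h, facecolor=face,
                                 edgecolor=PALETTE[i], lw=0.9, zorder=3)
                rect.set_gid(f"bars-{node_ids[node]}-q{i + 1}")
                ax.add_patch(rect)
            # reference line at 1/3: the equal-frequency expectation
            ax.plot([bx - 0.02, bx + box_w], [by + box_h / 3.0] * 2,
                    color="0.5", lw=0.7, ls="--", zorder=2)
            flag = "*" if freqs.demoted else ""
            label = (
                f"n={freqs.n:.6g}{flag}\n"
                f"P={_fmt_p(res.p_value)}\n"
                f"ILS-i={format_percent(res.ils_index)}% "
                f"IH-i={format_percent(res.ih_index)}%\n"
                f"ILS-e={format_percent(res.ils_explained)}% "
                f"IH-e={format_percent(res.ih_explained)}%"
            )
            ax.text(bx + box_w + 0.06, y, label, va="center", ha="left",
                    fontsize=6.5, zorder=3)

        ax.set_axis_off()
        ax.set_xlim(-0.3, max(c[0] for c in coords.values()) + 1.6)
        ax.set_ylim(-1.0, n_leaves)
        ax.invert_yaxis()
        fig.subplots_adjust(left=0.02, right=0.98, top=0.98, bottom=0.02)
        metadata: Optional[dict] = None
        if str(path).endswith(".svg"):
            metadata = {"Date": None, "Creator": "treediscord"}
        fig.savefig(path, metadata=metadata)
        plt.close(fig)
    return str(path)
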