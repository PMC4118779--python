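"""Dendrogram row order and rectangular (right-angle) layout.

The tree controls display order: rows follow the depth-first, child-order
preserving leaf sequence, overriding FASTA order.  Layout places leaf i at
y = i * row_height + row_height/2, internal nodes at the mean of their
children's y, and draws one vertical + one horizontal segment per edge
(the classic cladogram elbow).  Horizontal scaling is uniform by depth by
default; cumulative branch length is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import TreeNode

#: A line segment in panel pixel coordinates: (x1, y1, x2, y2).
Segment = tuple[float, float, float, float]


@dataclass(frozen=True)
class DendrogramLayout:
    leaf_order: tuple[str, ...]
    segments: tuple[Segment, ...]
    panel_width_px: int
    row_height_px: int


def leaf_order(tree: TreeNode) -> list[str]:
    """Depth-first, child-order preserving leaf labels (top to bottom)."""
    return tree.leaf_names()


def _depth(node: TreeNode) -> int:
    if node.is_leaf:
        return 0
    return 1 + max(_depth(c) for c in node.children)


def _max_path_length(node: TreeNode, acc: float = 0.0) -> float:
    acc += node.branch_length or 0.0
    if node.is_leaf:
        return acc
    return max(_max_path_length(c, acc) for c in node.children)


def layout(
    tree: TreeNode,
    row_height_px: int,
    panel_width_px: int,
    use_branch_lengths: bool = False,
) -> DendrogramLayout:
    """Compute the dendrogram geometry for the left-hand panel.

    Leaves sit at x = panel_width_px; internal-node x is scaled uniformly by
    depth (root at 0), or, with ``use_branch_lengths``, by cumulative branch
    length normalised to the panel width (every branch length must then be
    present).
    """
    if row_height_px < 1 or panel_width_px < 1:
        raise ValueError("dimensions must be positive")

    order = leaf_order(tree)
    leaf_y = {name: i * row_height_px + row_height_px / 2
              for i, name in enumerate(order)}

    if use_branch_lengths:
        def missing(node: TreeNode) -> bool:
            if node is not tree and node.branch_length is None:
                return True
            return any(missing(c) for c in node.children)
        if missing(tree):
            raise ValueError("use_branch_lengths requires every branch length")
        total = _max_path_length(tree) - (tree.branch_length or 0.0)
        scale = panel_width_px / total if total > 0 else 0.0
    else:
        max_depth = _depth(tree)

    segments: list[Segment] = []

    def place(node: TreeNode, depth: int, dist: float) -> tuple[float, float]:
        """Return (x, y) of node; emit elbow segments for its child edges."""
        if node.is_leaf:
            return float(panel_width_px), leaf_y[node.name]
        child_xy = []
        for c in node.children:
            child_xy.append(
                place(c, depth + 1, dist + (c.branch_length or 0.0))
            )
        y = sum(xy[1] for xy in child_xy) / len(child_xy)
        if use_branch_lengths:
            x = min(dist * scale, float(panel_width_px))
        else:
            x = depth / max_depth * panel_width_px if max_depth else 0.0
        for cx, cy in child_xy:
            segments.append((x, y, x, cy))   # vertical to child's row
            segments.append((x, cy, cx, cy))  # horizontal out to child
        return x, y

    if tree.is_leaf:
        # single-sequence tree: one horizontal stub into the row
        y = leaf_y[tree.name]
        segments.append((0.0, y, float(panel_width_px), y))
    else:
        place(tree, 0, 0.0)

    return DendrogramLayout(tuple(order), tuple(segments),
                            panel_width_px, row_height_px)
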