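"""Labeling of trained maps and extraction of class-specific clusters.

After training, every measurement is assigned to its best matching node.
Nodes are then labeled by the majority class of their content; a node
containing measurements of two or more classes is *mixed*.  A class
cluster is either

* two or more hex-adjacent nodes that contain measurements of one class
  only, or
* a single pure node holding at least 80% (>= 12 of a nominal 15) of the
  measurements of one mouse.

Mixed nodes never belong to clusters.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import hexgrid, som as _som
from .classes import MouseClass


@dataclass
class NodeAssignment:
    """Per-node content of a labeled map."""

    side: int
    indices: list[list[int]]                      # measurement rows per node
    class_counts: list[Counter]                   # class code -> count per node
    mouse_counts: list[Counter]                   # mouse id -> count per node

    @property
    def n_measurements(self) -> int:
        return sum(len(ix) for ix in self.indices)


@dataclass
class LabeledMap:
    assignment: NodeAssignment
    majority_class: list[str | None]              # per node; None when empty
    is_mixed: np.ndarray                          # bool per node
    total_count: np.ndarray                       # int per node
    ties: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)

    @property
    def side(self) -> int:
        return self.assignment.side


@dataclass
class ClassCluster:
    mouse_class: MouseClass
    nodes: frozenset[tuple[int, int]]
    n_measurements: int


def assign_measurements(som: _som.SOMap, data: np.ndarray,
                        labels: Sequence[str],
                        mouse_ids: Sequence[str] | None = None) -> NodeAssignment:
    """Map every measurement row to its best matching node."""
    data = np.asarray(data, dtype=float)
    labels = list(labels)
    if len(labels) != data.shape[0]:
        raise ValueError("labels length mismatch")
    if mouse_ids is not None and len(mouse_ids) != data.shape[0]:
        raise ValueError("mouse_ids length mismatch")
    bmu = _som.bmu_indices(som, data)
    n = som.n_nodes
    indices: list[list[int]] = [[] for _ in range(n)]
    class_counts = [Counter() for _ in range(n)]
    mouse_counts = [Counter() for _ in range(n)]
    for i, node in enumerate(bmu):
        indices[node].append(i)
        class_counts[node][labels[i]] += 1
        if mouse_ids is not None:
            mouse_counts[node][str(mouse_ids[i])] += 1
    return NodeAssignment(som.side, indices, class_counts, mouse_counts)


def label_nodes(assignment: NodeAssignment) -> LabeledMap:
    """Label each node with its majority class.

    Majority ties break to the lexicographically first class code and are
    recorded in ``ties``.  Empty nodes stay unlabeled and are not mixed.
    """
    n = assignment.side ** 2
    majority: list[str | None] = [None] * n
    mixed = np.zeros(n, dtype=bool)
    totals = np.zeros(n, dtype=int)
    ties: list[tuple[int, tuple[str, ...]]] = []
    for node in range(n):
        counts = assignment.class_counts[node]
        totals[node] = sum(counts.values())
        if not counts:
            continue
        top = max(counts.values())
        winners = sorted(c for c, k in counts.items() if k == top)
        majority[node] = winners[0]
        if len(winners) > 1:
            ties.append((node, tuple(winners)))
        mixed[node] = len(counts) >= 2
    return LabeledMap(assignment, majority, mixed, totals, ties)


def mixed_node_stats(lmap: LabeledMap,
                     within_classes: Sequence[str | MouseClass] | None = None
                     ) -> tuple[int, int]:
    """(number of mixed nodes, number of measurements they contain).

    With ``within_classes``, mixing is evaluated only among those classes:
    a node qualifies if it contains measurements of at least two of them.
    Measurement counts are node totals (everything in qualifying nodes).
    """
    if within_classes is None:
        sel = None
    else:
        sel = {c.code if isinstance(c, MouseClass) else MouseClass.from_code(c).code
               for c in within_classes}
    n_mixed = 0
    n_meas = 0
    for node in range(lmap.side ** 2):
        counts = lmap.assignment.class_counts[node]
        present = set(counts) if sel is None else set(counts) & sel
        if len(present) >= 2:
            n_mixed += 1
            n_meas += int(lmap.total_count[node])
    return n_mixed, n_meas


def between_group_mixed(lmap: LabeledMap,
                        group_a: Sequence[str | MouseClass],
                        group_b: Sequence[str | MouseClass]) -> tuple[int, int]:
    """Nodes mixing measurements from two class *groups* (and their
    measurement totals), e.g. any context-shock class together with any
    shock-context class."""
    def codes(group):
        return {c.code if isinstance(c, MouseClass) else MouseClass.from_code(c).code
                for c in group}
    a, b = codes(group_a), codes(group_b)
    n_mixed = 0
    n_meas = 0
    for node in range(lmap.side ** 2):
        present = set(lmap.assignment.class_counts[node])
        if present & a and present & b:
            n_mixed += 1
            n_meas += int(lmap.total_count[node])
    return n_mixed, n_meas


def _singleton_threshold(purity_fraction: float, nominal_replicates: int) -> int:
    # ceil with a guard against float artifacts (0.8 * 15 -> 12, not 13)
    return int(np.ceil(purity_fraction * nominal_replicates - 1e-9))


def extract_clusters(lmap: LabeledMap, nominal_replicates: int = 15,
                     purity_fraction: float = 0.8) -> list[ClassCluster]:
    """Extract class-specific clusters from a labeled map.

    Mixed nodes are discarded; the remaining pure nodes are grouped into
    connected components under hex adjacency, per class.  Components of two
    or more nodes are accepted outright.  A pure singleton is accepted only
    if a single mouse contributes at least ``purity_fraction`` of a nominal
    replicate count to it (>= 12 of 15 by default); extra same-class
    measurements from other mice do not disqualify it.
    """
    side = lmap.side
    pure: dict[tuple[int, int], str] = {}
    for node in range(side ** 2):
        counts = lmap.assignment.class_counts[node]
        if len(counts) == 1:
            pure[hexgrid.node_coord(node, side)] = next(iter(counts))
    threshold = _singleton_threshold(purity_fraction, nominal_replicates)

    clusters: list[ClassCluster] = []
    seen: set[tuple[int, int]] = set()
    for start in sorted(pure):
        if start in seen:
            continue
        code = pure[start]
        comp = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nb in hexgrid.neighbors(cur, side):
                if nb in pure and pure[nb] == code and nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        n_meas = sum(int(lmap.total_count[hexgrid.node_index(c, side)]) for c in comp)
        if len(comp) >= 2:
            clusters.append(ClassCluster(MouseClass.from_code(code),
                                         frozenset(comp), n_meas))
        else:
            node = hexgrid.node_index(start, side)
            mice = lmap.assignment.mouse_counts[node]
            if mice and max(mice.values()) >= threshold:
                clusters.append(ClassCluster(MouseClass.from_code(code),
                                             frozenset(comp), n_meas))
    return clusters


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: Node colors by class code, following the usual presentation of these maps.
DEFAULT_CLASS_COLORS = {
    "c-SC-s": "#8B5A2B",   # brown
    "c-SC-m": "#FFA500",   # orange
    "c-CS-s": "#2E8B57",   # green
    "c-CS-m": "#FFD700",   # yellow
    "t-SC-s": "#ADD8E6",   # light blue
    "t-SC-m": "#00008B",   # dark blue
    "t-CS-s": "#FFB6C1",   # light pink
    "t-CS-m": "#C71585",   # dark pink
}


def render_text(lmap: LabeledMap) -> str:
    """Fixed-width text grid, one cell per node, ``code:count``.

    Mixed nodes list every class present (by decreasing count, ties by
    code); empty nodes render as ``.``.  Odd rows are indented half a cell
    to suggest the hexagonal layout.  Output is deterministic.
    """
    side = lmap.side
    cells = []
    for node in range(side ** 2):
        counts = lmap.assignment.class_counts[node]
        if not counts:
            cells.append(".")
        else:
            codes = sorted(counts, key=lambda c: (-counts[c], c))
            cells.append("+".join(codes) + f":{int(lmap.total_count[node])}")
    width = max(len(c) for c in cells) + 2
    lines = []
    for row in range(side):
        indent = " " * (width // 2) if row % 2 else ""
        lines.append(indent + "".join(
            cells[row * side + col].ljust(width) for col in range(side)).rstrip())
    return "\n".join(lines) + "\n"


def render_map(lmap: LabeledMap, clusters: Sequence[ClassCluster] = (),
               path: str | Path | None = None,
               class_colors: dict[str, str] | None = None) -> str:
    """Render a labeled map as text, and optionally as an image.

    Returns the text rendering.  If ``path`` is given, writes the text to
    ``path`` and a hexagon image (class colors, cluster outlines) next to
    it with a ``.png`` suffix.  Purely presentational.
    """
    text = render_text(lmap)
    if path is not None:
        path = Path(path)
        path.write_text(text)
        _render_image(lmap, clusters, path.with_suffix(".png"),
                      class_colors or DEFAULT_CLASS_COLORS)
    return text


def _render_image(lmap: LabeledMap, clusters: Sequence[ClassCluster],
                  path: Path, class_colors: dict[str, str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import RegularPolygon

    side = lmap.side
    pos = hexgrid.embedding(side)
    cluster_nodes = {c for cl in clusters for c in cl.nodes}
    fig, ax = plt.subplots(figsize=(1.0 + side, 1.0 + side))
    for node in range(side ** 2):
        coord = hexgrid.node_coord(node, side)
        code = lmap.majority_class[node]
        color = class_colors.get(code, "#CCCCCC") if code else "white"
        edge = "black" if coord in cluster_nodes else "#999999"
        lw = 2.5 if coord in cluster_nodes else 0.8
        ax.add_patch(RegularPolygon((pos[node, 0], pos[node, 1]),
                                    numVertices=6, radius=0.55,
                                    facecolor=color, edgecolor=edge,
                                    linewidth=lw))
        label = "" if code is None else f"{code}\n{int(lmap.total_count[node])}"
        if lmap.is_mixed[node]:
            label += "*"
        ax.text(pos[node, 0], pos[node, 1], label,
                ha="center", va="center", fontsize=7)
    ax.set_xlim(-1, side + 1)
    ax.set_ylim(-1, side)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
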