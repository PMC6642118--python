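"""Semantic similarity between MeSH descriptors and descriptor sets.

Six measures, each normalised to [0, 1].  Five are path-based over the
multi-placement hierarchy (shortest path, weighted link, Wu–Palmer,
Leacock–Chodorow, Li); the sixth (Lord) is information-content based,
driven by cumulative occurrence counts of each heading in a document
collection.  Notation: ``l`` = minimum edge count between placements,
``h`` = depth of the lowest common ancestor (0 at the virtual root),
``D`` = maximum depth of the vocabulary.

Normalisation forms:

* shortest path:      ``1 - l / 2D`` (floored at 0)
* weighted link:      ``1 - L / L_max`` with depth-halving edge weights
  ``2^-d`` and ``L_max = 2 * sum_{d=1..D} 2^-d``
* Wu–Palmer:          ``2h / (d_a + d_b)`` on the LCA-maximising pair
* Leacock–Chodorow:   ``-ln((l + 1) / 2D) / ln(2D)`` (node-counted path,
  clamped to [0, 1])
* Li:                 ``exp(-alpha * l) * tanh(beta * h)`` — note the
  self-similarity ``tanh(beta * depth) < 1`` is inherent to this measure
* Lord:               ``IC(MICA) / IC_max`` with ``IC = -ln(count/total)``

Scores of two term *sets* are combined by the best-match average, and a
score >= 0.5 is conventionally flagged as a significant match.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .mesh import MeshTree, tree_number_depth

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityConfig",
    "MEASURES",
    "similarity",
    "sim_shortest_path",
    "sim_weighted_link",
    "sim_wu_palmer",
    "sim_leacock_chodorow",
    "sim_li",
    "sim_lord",
    "set_similarity",
    "significance_flag",
]

MEASURES = (
    "shortest_path",
    "weighted_link",
    "wu_palmer",
    "leacock_chodorow",
    "li",
    "lord",
)


@dataclass
class SimilarityConfig:
    """Tunables for the parametric measures.

    ``li_alpha`` and ``li_beta`` are the exponential path-decay and
    depth-saturation constants of the Li measure (defaults 0.2 and 0.6,
    the values customary for this measure).  ``ic_table`` maps descriptor
    ui -> cumulative occurrence count (a node's count includes all of its
    descendants'), required by the Lord measure only.
    """

    li_alpha: float = 0.2
    li_beta: float = 0.6
    ic_table: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.li_alpha < 0:
            raise ValueError("li_alpha must be non-negative")
        if self.li_beta <= 0:
            raise ValueError("li_beta must be positive")
        if self.ic_table is not None and any(v < 0 for v in self.ic_table.values()):
            raise ValueError("ic_table counts must be non-negative")


def sim_shortest_path(tree: MeshTree, a: str, b: str) -> float:
    l = tree.shortest_path_edges(a, b)
    return max(0.0, 1.0 - l / (2 * tree.max_depth))


def sim_wu_palmer(tree: MeshTree, a: str, b: str) -> float:
    _, h, da, db = tree.lca_detail(a, b)
    if h == 0:
        return 0.0
    return 2.0 * h / (da + db)


def sim_leacock_chodorow(tree: MeshTree, a: str, b: str) -> float:
    two_d = 2 * tree.max_depth
    l_nodes = tree.shortest_path_edges(a, b) + 1
    raw = -math.log(l_nodes / two_d)
    return min(1.0, max(0.0, raw / math.log(two_d)))


def sim_li(tree: MeshTree, a: str, b: str, config: SimilarityConfig | None = None) -> float:
    config = config or SimilarityConfig()
    l = tree.shortest_path_edges(a, b)
    _, h = tree.lca(a, b)
    return math.exp(-config.li_alpha * l) * math.tanh(config.li_beta * h)


def _edge_weight_sum(d_from: int, d_to: int) -> float:
    """Sum of 2^-d over edges entering nodes at depths d_from+1 .. d_to."""
    return sum(2.0 ** -d for d in range(d_from + 1, d_to + 1))


def sim_weighted_link(tree: MeshTree, a: str, b: str) -> float:
    da, db = tree._get(a), tree._get(b)
    if a == b:
        return 1.0
    best = None
    for pa in da.tree_numbers:
        for pb in db.tree_numbers:
            anc = MeshTree._common_prefix(pa, pb)
            h = tree_number_depth(anc) if anc is not None else 0
            dist = _edge_weight_sum(h, tree_number_depth(pa)) + _edge_weight_sum(
                h, tree_number_depth(pb)
            )
            if best is None or dist < best:
                best = dist
    l_max = 2.0 * _edge_weight_sum(0, tree.max_depth)
    return max(0.0, 1.0 - best / l_max)


def _ic_context(tree: MeshTree, ic_table: Mapping[str, float]) -> tuple[float, float]:
    """Total occurrence mass (sum over category-level placements) and IC_max."""
    roots = {ui for pos, ui in tree.position_index.items() if "." not in pos}
    total = sum(float(ic_table.get(ui, 0.0)) for ui in roots)
    if total <= 0:
        raise ValueError("ic_table has zero total mass at category level")
    ic_max = 0.0
    for ui, count in ic_table.items():
        if count > 0:
            ic_max = max(ic_max, -math.log(count / total))
    if ic_max <= 0:
        raise ValueError("ic_table admits no positive information content")
    return total, ic_max


def sim_lord(tree: MeshTree, a: str, b: str, config: SimilarityConfig) -> float:
    """Information-content similarity: IC of the most informative common
    ancestor over the largest attainable IC in the table."""
    if config is None or config.ic_table is None:
        raise ValueError("lord measure requires an ic_table")
    total, ic_max = _ic_context(tree, config.ic_table)
    common = tree.ancestor_uis(a) & tree.ancestor_uis(b)
    best_ic = 0.0
    for ui in common:
        count = config.ic_table.get(ui)
        if count is None or count <= 0:
            continue
        best_ic = max(best_ic, -math.log(count / total))
    return min(1.0, best_ic / ic_max)


def similarity(
    tree: MeshTree,
    a: str,
    b: str,
    measure: str,
    config: SimilarityConfig | None = None,
) -> float:
    """Dispatch to one of the six measures; *a*, *b* are descriptor uis."""
    if measure == "shortest_path":
        return sim_shortest_path(tree, a, b)
    if measure == "weighted_link":
        return sim_weighted_link(tree, a, b)
    if measure == "wu_palmer":
        return sim_wu_palmer(tree, a, b)
    if measure == "leacock_chodorow":
        return sim_leacock_chodorow(tree, a, b)
    if measure == "li":
        return sim_li(tree, a, b, config)
    if measure == "lord":
        return sim_lord(tree, a, b, config or SimilarityConfig())
    raise ValueError(f"unknown measure {measure!r}")


def set_similarity(
    tree: MeshTree,
    set_a: Iterable[str],
    set_b: Iterable[str],
    measure: str = "shortest_path",
    config: SimilarityConfig | None = None,
) -> float:
    """Best-match-average similarity between two term sets.

    Terms may be descriptor uis or preferred names; unresolvable terms
    are excluded with a warning.  Score =
    ``(sum_a max_b s(a,b) + sum_b max_a s(a,b)) / (|A| + |B|)``.
    """
    def _resolve(terms: Iterable[str]) -> list[str]:
        out = []
        for t in terms:
            ui = tree.resolve(t)
            if ui is None:
                logger.warning("term %r not in vocabulary; excluded", t)
            else:
                out.append(ui)
        return out

    A, B = _resolve(set_a), _resolve(set_b)
    if not A or not B:
        raise ValueError("both term sets must be non-empty after resolution")
    forward = sum(max(similarity(tree, a, b, measure, config) for b in B) for a in A)
    backward = sum(max(similarity(tree, a, b, measure, config) for a in A) for b in B)
    return (forward + backward) / (len(A) + len(B))


def significance_flag(score: float, threshold: float = 0.5) -> bool:
    """True when a [0, 1] similarity reaches the significance threshold
    (inclusive at 0.5 by convention)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score {score} outside [0, 1]")
    return score >= threshold
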