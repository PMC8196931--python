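"""Operational monophyly of a labeled group via the maximum F measure.

A group is *operationally monophyletic* when some tree node (or, for
unrooted trees, some side of some bipartition) achieves

    F = 2 * (precision * recall) / (precision + recall) >= 0.95

where precision is the fraction of tips under the node carrying the group
label and recall the fraction of all labeled tips captured by the node.
Both sides of every bipartition are scanned so the result does not depend
on where the input tree happens to be rooted.
"""

from __future__ import annotations

from psychromark.types import FResult, LabeledTree

F_THRESHOLD = 0.95


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when either is 0."""
    if precision <= 0.0 or recall <= 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def is_operationally_monophyletic(f: float, threshold: float = F_THRESHOLD) -> bool:
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"F measure must be in [0, 1], got {f}")
    return f >= threshold


def _candidate_tip_sets(labeled: LabeledTree) -> list[frozenset[str]]:
    """Tip sets of every bipartition side, in pre-order of the defining node."""
    all_tips = frozenset(labeled.tip_names)
    sets: list[frozenset[str]] = []
    for node in labeled.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sets.append(below)
        other = all_tips - below
        if other:
            sets.append(other)
    if not sets:  # single-tip tree
        sets.append(all_tips)
    return sets


def max_f_measure(
    labeled: LabeledTree, target_label: str, threshold: float = F_THRESHOLD
) -> FResult:
    """Scan all bipartition sides and return the one maximizing F.

    Ties are broken toward the smaller tip set (the most specific clade
    claim), then toward the earlier pre-order position.
    """
    labeled_tips = {t for t in labeled.tip_names if labeled.labels.get(t) == target_label}
    if not labeled_tips:
        raise ValueError(f"no tip carries label {target_label!r}")
    n_labeled = len(labeled_tips)

    best: tuple[float, int] | None = None  # (-f, size) for min-comparison
    best_result: FResult | None = None
    for tips in _candidate_tip_sets(labeled):
        inside = len(labeled_tips & tips)
        precision = inside / len(tips)
        recall = inside / n_labeled
        f = f_measure(precision, recall)
        key = (-f, len(tips))
        if best is None or key < best:
            best = key
            best_result = FResult(
                best_tips=tips,
                precision=precision,
                recall=recall,
                f=f,
                monophyletic=is_operationally_monophyletic(f, threshold),
            )
    assert best_result is not None
    return best_result
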