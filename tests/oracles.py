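"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the F-measure
oracle scans bipartitions of a nested-tuple topology, the marker oracle
evaluates the presence/absence predicate family by family, and the
alignment oracle is a plain Gotoh dynamic program.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def random_tuple_tree(rng, n_tips, prefix="t"):
    """Random binary topology as nested tuples plus its newick string."""
    structs = [f"{prefix}{i}" for i in range(n_tips)]
    while len(structs) > 1:
        i, j = sorted(rng.choice(len(structs), 2, replace=False))
        b = structs.pop(j)
        a = structs.pop(i)
        structs.append((a, b))
    root = structs[0]

    def to_newick(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return root, to_newick(root) + ";"


def max_f_oracle(root, labels, target):
    """Exhaustive F-measure scan over both sides of every bipartition."""

    def tips(node):
        if isinstance(node, str):
            return frozenset([node])
        return frozenset().union(*(tips(c) for c in node))

    all_tips = tips(root)
    labeled = {t for t in all_tips if labels.get(t) == target}
    candidates = set()

    def collect(node):
        s = tips(node)
        if s != all_tips:
            candidates.add(s)
            candidates.add(all_tips - s)
        if not isinstance(node, str):
            for c in node:
                collect(c)

    collect(root)
    best = 0.0
    for s in candidates:
        inside = len(labeled & s)
        if inside == 0:
            continue
        p, r = inside / len(s), inside / len(labeled)
        best = max(best, 2 * p * r / (p + r))
    return best


def group_specific_oracle(counts, groups, presence_min=0.95, absence_max=0.05):
    """Family-by-family predicate evaluation; returns {group: set of families}."""
    out = {}
    levels = sorted(set(groups.values))
    for grp in levels:
        fams = set()
        inside = [g for g in counts.columns if groups[g] == grp]
        for fam in counts.index:
            pres_in = sum(counts.loc[fam, g] >= 1 for g in inside) / len(inside)
            ok = pres_in >= presence_min
            for other in levels:
                if other == grp or not ok:
                    continue
                out_cols = [g for g in counts.columns if groups[g] == other]
                pres_out = sum(counts.loc[fam, g] >= 1 for g in out_cols) / len(out_cols)
                ok = ok and pres_out <= absence_max
            if ok:
                fams.add(fam)
        out[grp] = fams
    return out


def sw_score_oracle(query, subject, open_cost=12.0, extend_cost=1.0):
    """Quadratic Gotoh DP for the optimal Smith-Waterman score.

    Affine convention: a gap of length L costs open_cost + (L-1)*extend_cost.
    """
    n, m = len(query), len(subject)
    neg = -1e9
    scores = [[float(_B62[a, b]) for b in subject] for a in query]
    h_prev = [0.0] * (m + 1)
    f_prev = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h_row = [0.0] * (m + 1)
        f_row = [neg] * (m + 1)
        e = neg
        srow = scores[i - 1]
        for j in range(1, m + 1):
            e = max(h_row[j - 1] - open_cost, e - extend_cost)
            f_row[j] = max(h_prev[j] - open_cost, f_prev[j] - extend_cost)
            h = h_prev[j - 1] + srow[j - 1]
            if e > h:
                h = e
            if f_row[j] > h:
                h = f_row[j]
            if h < 0.0:
                h = 0.0
            h_row[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_row, f_row
    return best
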