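"""Group-specific gene families (the 95/95 rule), the pan genome, and
copy-number comparisons between groups.

A family is specific to group G when it is present (copy count >= 1) in
at least 95 % of G's genomes and present in at most 5 % of the genomes of
*each* other group, evaluated separately.  Threshold comparisons use
>= / <= at the exact boundary; fractions are not rounded.  Marker-set
sizes are additionally reported as families per genome to account for
unequal group sizes.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from psychromark.types import GeneFamilyMatrix, MarkerSet

PRESENCE_MIN = 0.95
ABSENCE_MAX = 0.05


def _group_members(
    matrix: GeneFamilyMatrix, groups: pd.Series
) -> dict[str, list[str]]:
    groups = groups.loc[[g for g in matrix.genome_ids if g in groups.index]]
    unassigned = [g for g in matrix.genome_ids if groups.get(g, "unassigned") == "unassigned"]
    if unassigned:
        warnings.warn(f"{len(unassigned)} unassigned genomes excluded: {unassigned[:5]}")
    members: dict[str, list[str]] = {}
    for gid in matrix.genome_ids:
        grp = groups.get(gid, "unassigned")
        if grp != "unassigned":
            members.setdefault(grp, []).append(gid)
    if not members:
        raise ValueError("no labeled genomes")
    return members


def group_specific_genes(
    matrix: GeneFamilyMatrix,
    groups: pd.Series,
    presence_min: float = PRESENCE_MIN,
    absence_max: float = ABSENCE_MAX,
) -> dict[str, MarkerSet]:
    """Marker families per group under the presence/absence rule."""
    members = _group_members(matrix, groups)
    presence = matrix.counts >= 1
    frac = {
        grp: presence[cols].sum(axis=1) / len(cols) for grp, cols in members.items()
    }
    out: dict[str, MarkerSet] = {}
    for grp, cols in members.items():
        mask = frac[grp] >= presence_min
        for other, other_cols in members.items():
            if other == grp:
                continue
            mask &= frac[other] <= absence_max
        fams = list(matrix.counts.index[mask])
        out[grp] = MarkerSet(
            group=grp,
            families=fams,
            proteins={f: matrix.representatives[f] for f in fams},
            n_genomes=len(cols),
        )
    return out


def pan_genome(matrix: GeneFamilyMatrix) -> MarkerSet:
    """Union of all families observed in at least one genome."""
    if matrix.counts.empty:
        raise ValueError("empty gene-family matrix")
    observed = matrix.counts.index[(matrix.counts >= 1).any(axis=1)]
    fams = list(observed)
    return MarkerSet(
        group="pan",
        families=fams,
        proteins={f: matrix.representatives[f] for f in fams},
        n_genomes=len(matrix.genome_ids),
    )


def copy_number_compare(
    matrix: GeneFamilyMatrix,
    groups: pd.Series,
    group_a: str = "A",
    group_c: str = "C",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family mean copy number in two groups with a one-way ANOVA.

    Status is ``higher``/``lower`` (group C vs group A) when p < alpha,
    ``absent_in_C`` when the family never occurs in group C but does in
    group A, otherwise ``ns``.  Families absent from both groups are
    excluded.
    """
    members = _group_members(matrix, groups)
    for grp in (group_a, group_c):
        if grp not in members or len(members[grp]) < 2:
            raise ValueError(f"group {grp!r} needs >= 2 genomes")
    cols_a, cols_c = members[group_a], members[group_c]
    rows = []
    for fam in matrix.counts.index:
        xa = matrix.counts.loc[fam, cols_a].to_numpy(dtype=float)
        xc = matrix.counts.loc[fam, cols_c].to_numpy(dtype=float)
        if xa.sum() == 0 and xc.sum() == 0:
            continue
        mean_a, mean_c = float(xa.mean()), float(xc.mean())
        if np.ptp(np.concatenate([xa, xc])) == 0:
            p = 1.0
        else:
            p = float(stats.f_oneway(xa, xc).pvalue)
            if np.isnan(p):
                p = 1.0
        if xc.sum() == 0 and xa.sum() > 0:
            status = "absent_in_C"
        elif p < alpha:
            status = "higher" if mean_c > mean_a else "lower"
        else:
            status = "ns"
        rows.append(
            {
                "family_id": fam,
                f"mean_{group_a}": mean_a,
                f"mean_{group_c}": mean_c,
                "p": p,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("family_id")


def normalize_marker_counts(marker_sets: dict[str, MarkerSet]) -> pd.DataFrame:
    """Raw and per-genome marker-set sizes for each group."""
    rows = []
    for grp, ms in sorted(marker_sets.items()):
        rows.append(
            {
                "group": grp,
                "n_families": len(ms.families),
                "n_genomes": ms.n_genomes,
                "families_per_genome": ms.normalized_size,
            }
        )
    return pd.DataFrame(rows).set_index("group")
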