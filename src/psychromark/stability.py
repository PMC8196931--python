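"""Protein stability from two-state Gibbs-Helmholtz curves.

The folding free energy at temperature T (kelvin) is

    dG(T) = -dHm * (1 - T/Tm) + dCp * (Tm - T + T * ln(T/Tm))

with dHm the (positive) unfolding enthalpy at the melting temperature Tm
and dCp the unfolding heat-capacity change.  This is the two-state
Gibbs-Helmholtz unfolding free energy with the folding sign convention:
dG(Tm) = 0 by construction, dG is negative between cold and heat
denaturation, and more-negative dG means a more stable fold.  A
cold-adapted group with *higher* (less negative) dG at -1 degC therefore
carries destabilized proteins.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from psychromark.types import StabilityCurve

#: -1 degC, the evaluation temperature for cold-environment comparisons
T_MINUS_1C = 272.15
T_STANDARD = 298.15


def delta_g(curve: StabilityCurve, t: float) -> float:
    """Folding free energy (kcal/mol) at temperature ``t`` kelvin."""
    if t <= 0:
        raise ValueError(f"temperature must be positive kelvin, got {t}")
    tm, dhm, dcp = curve.tm, curve.dhm, curve.dcp
    return -dhm * (1.0 - t / tm) + dcp * (tm - t + t * math.log(t / tm))


def robust_curve_filter(
    curves: Sequence[StabilityCurve],
    tm_range: tuple[float, float] = (273.15, 400.0),
    max_abs_dg_standard: float = 50.0,
) -> list[StabilityCurve]:
    """Parameter-sanity filter for physically plausible folded proteins.

    Keeps curves with Tm inside ``tm_range``, positive dHm and dCp, and
    |dG(298.15 K)| <= ``max_abs_dg_standard`` kcal/mol.  The thresholds
    are configuration, not physics: they separate usable two-state fits
    from degenerate ones.
    """
    kept = []
    for c in curves:
        if not (tm_range[0] <= c.tm <= tm_range[1]):
            continue
        if c.dhm <= 0 or c.dcp <= 0:
            continue
        if abs(delta_g(c, T_STANDARD)) > max_abs_dg_standard:
            continue
        kept.append(c)
    return kept


def group_stability_compare(
    curves: Sequence[StabilityCurve],
    groups: pd.Series,
    t: float = T_MINUS_1C,
) -> dict:
    """Per-group mean dG at ``t`` with a one-way ANOVA across groups.

    Also flags, per protein family present in both groups, whether group
    C's dG exceeds group A's (i.e. the protein is predicted less stable
    in the cold-adapted group).  Groups with no curves are excluded;
    fewer than two groups with >= 2 curves is an error.
    """
    by_group: dict[str, list[float]] = {}
    by_group_protein: dict[str, dict[str, list[float]]] = {}
    for c in curves:
        grp = groups.get(c.genome_id, "unassigned")
        if grp == "unassigned":
            continue
        val = delta_g(c, t)
        by_group.setdefault(grp, []).append(val)
        by_group_protein.setdefault(grp, {}).setdefault(c.protein_id, []).append(val)
    usable = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 robust curves each")
    means = {g: float(np.mean(v)) for g, v in usable.items()}
    pooled = np.concatenate(list(usable.values()))
    if np.ptp(pooled) == 0:
        p = 1.0
    else:
        p = float(stats.f_oneway(*usable.values()).pvalue)
        if math.isnan(p):
            p = 1.0

    flags = {}
    if "A" in by_group_protein and "C" in by_group_protein:
        shared = set(by_group_protein["A"]) & set(by_group_protein["C"])
        for prot in sorted(shared):
            flags[prot] = float(np.mean(by_group_protein["C"][prot])) > float(
                np.mean(by_group_protein["A"][prot])
            )
    return {
        "t": t,
        "group_means": means,
        "p": p,
        "c_less_stable_flags": flags,
    }


def curves_from_table(df: pd.DataFrame) -> list[StabilityCurve]:
    """Build curves from a table with protein_id, genome_id, tm, dhm, dcp."""
    return [
        StabilityCurve(
            protein_id=str(r.protein_id),
            genome_id=str(r.genome_id),
            tm=float(r.tm),
            dhm=float(r.dhm),
            dcp=float(r.dcp),
        )
        for r in df.itertuples(index=False)
    ]
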