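"""Genome-wide compositional statistics distinguishing groups.

G+C content, amino-acid usage, per-residue group tests (one-way ANOVA),
OLS of residue frequency on G+C, Bray-Curtis amino-acid bias per
functional category, and Kruskal-Wallis enrichment of functional-category
content ("non-parametric one-way ANOVA").  Raw p-values are reported with
significance at p < 0.05; an optional Benjamini-Hochberg flag is provided
for users who want FDR control.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from psychromark.types import AMINO_ACIDS

ALPHA = 0.05


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T) of a nucleotide sequence; N is excluded.

    Returns NaN for an empty or all-N sequence.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    counts = Counter(seq)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def aa_composition(proteome: Sequence[tuple[str, str]]) -> pd.Series:
    """Residue frequencies over all proteins of a genome; X is ignored.

    Returns a length-20 Series indexed by residue, summing to 1.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    counts = Counter()
    for _, seq in proteome:
        counts.update(seq)
    counts.pop("X", None)
    total = sum(counts[a] for a in AMINO_ACIDS)
    if total == 0:
        raise ValueError("proteome contains no canonical residues")
    return pd.Series({a: counts[a] / total for a in AMINO_ACIDS}, name="freq")


def composition_table(
    proteomes: dict[str, Sequence[tuple[str, str]]]
) -> pd.DataFrame:
    """Genome × residue frequency table."""
    return pd.DataFrame({g: aa_composition(p) for g, p in proteomes.items()}).T


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def aa_group_test(
    compositions: pd.DataFrame,
    groups: pd.Series,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-residue one-way ANOVA for a group effect on usage frequency.

    ``compositions`` is genome × residue; ``groups`` maps genome -> group
    label.  ``delta`` is mean(C) - mean(A) when both groups are present
    (else the difference between the last and first group).  Residues are
    flagged significant at p < alpha (BH-adjusted if ``fdr``).
    """
    groups = groups.loc[compositions.index]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 genomes")
    lo, hi = ("A", "C") if {"A", "C"} <= set(levels) else (levels[0], levels[-1])
    rows = []
    for res in compositions.columns:
        samples = [compositions.loc[groups == lv, res].to_numpy() for lv in levels]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            p = 1.0
        else:
            p = float(stats.f_oneway(*samples).pvalue)
            if np.isnan(p):
                p = 1.0
        delta = float(
            compositions.loc[groups == hi, res].mean()
            - compositions.loc[groups == lo, res].mean()
        )
        rows.append({"residue": res, "delta": delta, "p": p})
    out = pd.DataFrame(rows).set_index("residue")
    padj = _bh_adjust(out["p"].to_numpy()) if fdr else out["p"].to_numpy()
    out["significant"] = padj < alpha
    return out


def aa_gc_regression(
    compositions: pd.DataFrame, gc: pd.Series
) -> pd.DataFrame:
    """Per-residue OLS of usage frequency on genomic G+C content.

    Returns slope, r2 and p per residue.  With zero variance in G+C all
    entries are NaN; two-point fits are flagged ``underdetermined``.
    """
    gc = gc.loc[compositions.index].astype(float)
    n = len(gc)
    if n < 3:
        raise ValueError("need at least 3 genomes")
    out = []
    degenerate = float(np.ptp(gc.to_numpy())) == 0.0
    for res in compositions.columns:
        if degenerate:
            out.append({"residue": res, "slope": np.nan, "r2": np.nan, "p": np.nan})
            continue
        fit = stats.linregress(gc.to_numpy(), compositions[res].to_numpy())
        out.append(
            {
                "residue": res,
                "slope": float(fit.slope),
                "r2": float(fit.rvalue**2),
                "p": float(fit.pvalue),
            }
        )
    df = pd.DataFrame(out).set_index("residue")
    df["underdetermined"] = n <= 2
    return df


def pooled_category_composition(
    proteomes: dict[str, Sequence[tuple[str, str]]],
    assignments: pd.DataFrame,
    genome_ids: Sequence[str],
) -> dict[str, pd.Series]:
    """Pool all proteins of each functional category across a set of genomes.

    ``assignments`` has columns (protein_id, category).  Returns
    category -> 20-residue frequency vector of the concatenated proteins.
    """
    cat_of = dict(zip(assignments["protein_id"], assignments["category"]))
    counts: dict[str, Counter] = {}
    for gid in genome_ids:
        for pid, seq in proteomes[gid]:
            cat = cat_of.get(pid)
            if cat is None:
                continue
            counts.setdefault(cat, Counter()).update(seq)
    out = {}
    for cat, c in counts.items():
        c.pop("X", None)
        total = sum(c[a] for a in AMINO_ACIDS)
        if total:
            out[cat] = pd.Series({a: c[a] / total for a in AMINO_ACIDS})
    return out


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """BC = sum|x_i - y_i| / sum(x_i + y_i); larger = stronger bias."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float(np.sum(x + y))
    if denom == 0:
        return 0.0
    return float(np.sum(np.abs(x - y)) / denom)


def category_bias(
    comp_a: dict[str, pd.Series], comp_c: dict[str, pd.Series]
) -> pd.DataFrame:
    """Bray-Curtis amino-acid bias per functional category, ranked.

    Compares the pooled composition of each category between two groups;
    categories absent from either side are skipped with a warning.
    """
    rows = []
    for cat in sorted(set(comp_a) | set(comp_c)):
        if cat not in comp_a or cat not in comp_c:
            warnings.warn(f"category {cat!r} absent from one group; skipped")
            continue
        rows.append(
            {"category": cat, "bc_distance": bray_curtis(comp_a[cat], comp_c[cat])}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("bc_distance", ascending=False).reset_index(drop=True)
    return df


def ko_enrichment(
    content: pd.DataFrame,
    groups: pd.Series,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis test of per-genome category content between groups.

    ``content`` is category × genome (0/1 presence or counts).  Constant
    categories get p = 1.  ``direction`` is the group with the larger
    median ('C'-ward positive when C and A are compared).
    """
    groups = groups.loc[content.columns]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 genomes")
    lo, hi = ("A", "C") if {"A", "C"} <= set(levels) else (levels[0], levels[-1])
    rows = []
    for cat in content.index:
        samples = [
            content.loc[cat, groups[groups == lv].index].to_numpy(dtype=float)
            for lv in levels
        ]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            stat, p = 0.0, 1.0
        else:
            res = stats.kruskal(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
        med_diff = float(
            np.median(content.loc[cat, groups[groups == hi].index])
            - np.median(content.loc[cat, groups[groups == lo].index])
        )
        direction = hi if med_diff > 0 else (lo if med_diff < 0 else "ns")
        rows.append({"category": cat, "statistic": stat, "p": p, "direction": direction})
    out = pd.DataFrame(rows).set_index("category")
    padj = _bh_adjust(out["p"].to_numpy()) if fdr else out["p"].to_numpy()
    out["significant"] = padj < alpha
    return out
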