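"""Genome quality filtering, AAI dereplication and gene-family clustering.

QC removal rules use the strict inequalities of the source protocol:
a genome is removed iff contigs > 300, N50 < 20 kb, completeness < 95 %
or contamination > 5 % (boundary values pass).  AAI is the mean percent
identity over reciprocal-best-hit protein pairs passing an e <= 1e-5,
identity >= 30 %, coverage >= 70 %-of-the-shorter-protein screen.
Gene families are connected components of the alignment graph at the
1e-5 / 70 % identity / 70 % bidirectional-coverage cutoffs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from psychromark import metascreen
from psychromark.types import GeneFamilyMatrix, GenomeRecord

logger = logging.getLogger(__name__)

#: sentinel for genome pairs with no reciprocal best hits
UNDEFINED_AAI = float("nan")


@dataclass
class QcThresholds:
    max_contigs: int = 300
    min_n50: int = 20_000
    min_completeness: float = 95.0
    max_contamination: float = 5.0
    aai_derep: float = 99.5


def qc_filter(
    genomes: Sequence[GenomeRecord], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[GenomeRecord], list[tuple[GenomeRecord, list[str]]]]:
    """Split genomes into (kept, removed-with-reason-codes)."""
    kept: list[GenomeRecord] = []
    removed: list[tuple[GenomeRecord, list[str]]] = []
    for g in genomes:
        for field in ("n_contigs", "n50", "completeness", "contamination"):
            if getattr(g, field) is None:
                raise ValueError(f"genome {g.genome_id}: missing QC metric {field!r}")
        reasons = []
        if g.n_contigs > thresholds.max_contigs:
            reasons.append("contigs")
        if g.n50 < thresholds.min_n50:
            reasons.append("n50")
        if g.completeness < thresholds.min_completeness:
            reasons.append("completeness")
        if g.contamination > thresholds.max_contamination:
            reasons.append("contamination")
        if reasons:
            removed.append((g, reasons))
        else:
            kept.append(g)
    return kept, removed


def _best_hits(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    e_max: float,
    id_min: float,
    cov_min: float,
    prefilter: bool,
) -> dict[str, tuple[str, float]]:
    """Best accepted hit per query: query_id -> (subject_id, identity)."""
    db_residues = sum(len(s) for _, s in subjects)
    index = metascreen.KmerIndex(subjects, k=4) if prefilter else None
    best: dict[str, tuple[str, float, float]] = {}
    for qid, qseq in queries:
        cand = index.candidates(qseq) if index is not None else range(len(subjects))
        for si in cand:
            sid, sseq = subjects[si]
            hit = metascreen.local_align(qseq, sseq, qid, sid)
            if hit is None:
                continue
            cov_shorter = (
                hit.query_coverage if len(qseq) <= len(sseq) else hit.subject_coverage
            )
            if hit.identity < id_min or cov_shorter < cov_min:
                continue
            if metascreen.estimate_evalue(hit.bits, len(qseq), db_residues) > e_max:
                continue
            prev = best.get(qid)
            if prev is None or hit.score > prev[2]:
                best[qid] = (sid, hit.identity, hit.score)
    return {q: (s, ident) for q, (s, ident, _) in best.items()}


def pairwise_aai(
    proteome_a: Sequence[tuple[str, str]],
    proteome_b: Sequence[tuple[str, str]],
    e_max: float = 1e-5,
    id_min: float = 30.0,
    cov_min: float = 70.0,
    prefilter: bool = True,
) -> float:
    """Average amino-acid identity between two proteomes.

    Mean percent identity over reciprocal-best-hit pairs passing the
    screen; NaN (with a log message) when no RBH pair exists.  Symmetric
    by construction of the reciprocal requirement.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    fwd = _best_hits(proteome_a, proteome_b, e_max, id_min, cov_min, prefilter)
    rev = _best_hits(proteome_b, proteome_a, e_max, id_min, cov_min, prefilter)
    identities = []
    for qid, (sid, ident_fwd) in fwd.items():
        back = rev.get(sid)
        if back is not None and back[0] == qid:
            identities.append(0.5 * (ident_fwd + back[1]))
    if not identities:
        logger.warning("no reciprocal best hits; AAI undefined")
        return UNDEFINED_AAI
    return float(np.mean(identities))


def dereplicate(
    genomes: Sequence[GenomeRecord],
    aai_threshold: float = 99.5,
    aai_fn: Optional[Callable[[GenomeRecord, GenomeRecord], float]] = None,
) -> list[GenomeRecord]:
    """Collapse genomes into single-linkage clusters at AAI >= threshold.

    One representative survives per cluster: highest completeness, ties
    broken by lowest contamination, then lexicographic genome id.
    ``aai_fn`` may supply precomputed AAI values; by default AAI is
    computed from the proteomes.
    """
    if aai_fn is None:
        cache: dict[tuple[str, str], float] = {}

        def aai_fn(a: GenomeRecord, b: GenomeRecord) -> float:
            key = tuple(sorted((a.genome_id, b.genome_id)))
            if key not in cache:
                cache[key] = pairwise_aai(a.proteome, b.proteome)
            return cache[key]

    # sort for input-order invariance
    ordered = sorted(genomes, key=lambda g: g.genome_id)
    n = len(ordered)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            aai = aai_fn(ordered[i], ordered[j])
            if not math.isnan(aai) and aai >= aai_threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[GenomeRecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(ordered[i])

    reps = []
    for members in clusters.values():
        members.sort(
            key=lambda g: (
                -(g.completeness if g.completeness is not None else 0.0),
                g.contamination if g.contamination is not None else math.inf,
                g.genome_id,
            )
        )
        reps.append(members[0])
    reps.sort(key=lambda g: g.genome_id)
    return reps


def cluster_gene_families(
    proteomes: dict[str, Sequence[tuple[str, str]]],
    e_max: float = 1e-5,
    id_min: float = 70.0,
    cov_min: float = 70.0,
    prefilter: bool = True,
) -> GeneFamilyMatrix:
    """Cluster all proteins into gene families by single-linkage.

    An edge joins two proteins when their local alignment passes all
    three cutoffs with coverage required on both query and subject;
    families are the connected components.  Every protein is assigned to
    exactly one family; the longest member sequence represents each
    family.  Family ids ``fam_00000...`` are assigned in order of first
    (genome, protein) appearance.
    """
    if not proteomes:
        raise ValueError("at least one proteome is required")
    all_prots: list[tuple[str, str, str]] = []  # (genome_id, protein_id, seq)
    for gid, prots in proteomes.items():
        for pid, seq in prots:
            all_prots.append((gid, pid, seq))
    n = len(all_prots)
    db_residues = sum(len(s) for _, _, s in all_prots)

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    seqs = [(f"{g}:{p}", s) for g, p, s in all_prots]
    index = metascreen.KmerIndex(seqs, k=4) if prefilter else None
    for i in range(n):
        qseq = all_prots[i][2]
        cand = index.candidates(qseq) if index is not None else range(n)
        for j in cand:
            if j <= i or find(i) == find(j):
                continue
            sseq = all_prots[j][2]
            hit = metascreen.local_align(qseq, sseq)
            if hit is None:
                continue
            if (
                hit.identity < id_min
                or hit.query_coverage < cov_min
                or hit.subject_coverage < cov_min
            ):
                continue
            if metascreen.estimate_evalue(hit.bits, len(qseq), db_residues) > e_max:
                continue
            union(i, j)

    roots: dict[int, str] = {}
    fam_members: dict[str, list[int]] = {}
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = f"fam_{len(roots):05d}"
        fam_members.setdefault(roots[r], []).append(i)

    genome_ids = list(proteomes.keys())
    fam_ids = sorted(fam_members)
    counts = pd.DataFrame(
        0, index=fam_ids, columns=genome_ids, dtype=int
    )
    representatives: dict[str, tuple[str, str]] = {}
    for fam, members in fam_members.items():
        for i in members:
            counts.loc[fam, all_prots[i][0]] += 1
        longest = max(members, key=lambda i: (len(all_prots[i][2]), -i))
        representatives[fam] = (all_prots[longest][1], all_prots[longest][2])
    return GeneFamilyMatrix(counts=counts, representatives=representatives)
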