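"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure the analysis chain is built to
detect: a genome collection whose cold-adapted group C forms an exclusive
clade, carries group-specific gene families satisfying the 95/95 rule by
construction, and shows lower G+C and shifted amino-acid usage; metagenome
gene catalogs containing point-mutated copies of pan-genome genes with a
planted group-C enrichment in a designated sample cohort; Gibbs-Helmholtz
stability parameters with a planted group-C destabilization at -1 degC;
and compositional OTU count matrices with planted basis correlations.

All randomness flows through one integer seed per call; identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from psychromark.types import (
    AMINO_ACIDS,
    GeneFamilyMatrix,
    GenomeRecord,
    LabeledTree,
    MarkerSet,
    SampleMetadata,
    StabilityCurve,
)

GROUPS = ("A", "B", "C")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults define the study conditions the pipeline targets: group
    sizes 74/22/10 genomes, 95/95-compatible presence probabilities,
    metagenome cohorts with a planted cold-soil enrichment, a group-C
    destabilization of +0.7 kcal/mol at -1 degC (cold-adapted proteomes
    trade stability for flexibility), and 76 samples for co-occurrence;
    family and protein counts are desk-scale.
    """

    seed: int = 0
    # genome collection
    n_genomes_per_group: tuple[int, int, int] = (74, 22, 10)  # A, B, C
    n_families_core: int = 120
    n_families_group_specific: int = 30  # per group
    n_families_accessory: int = 60
    accessory_presence_prob: float = 0.3
    presence_prob_in_group: float = 1.0
    presence_prob_out_group: float = 0.0
    gc_mean_per_group: dict = field(
        default_factory=lambda: {"A": 0.655, "B": 0.645, "C": 0.605}
    )
    gc_sd: float = 0.008
    genome_seq_len: int = 20_000
    aa_shift: dict = field(
        default_factory=lambda: {
            "N": 0.006, "K": 0.006, "I": 0.004, "S": 0.004,
            "A": -0.010, "E": -0.005, "R": -0.005,
        }
    )
    protein_len_mean: int = 150
    protein_len_sd: int = 30
    protein_len_min: int = 60
    # metagenome catalogs
    n_metagenomes: int = 30
    enriched_sample_count: int = 3
    enrichment_factor: float = 4.0
    mutation_identity: float = 90.0
    # markers are a small fraction of the pan-genome signal, as in real
    # surveys where pan hits dwarf group-specific hits; background
    # families therefore carry higher per-family catalog rates
    marker_rate_range: tuple[float, float] = (0.1, 0.5)
    family_rate_range: tuple[float, float] = (0.5, 2.0)
    depth_sigma: float = 0.5
    # cores from a single enriched site share comparable depth, so the
    # cohort forms a tight cluster and its excess shows as an intercept
    # shift rather than a slope change
    enriched_depth_sigma: float = 0.05
    enriched_cohort: str = "permafrost_cohort"
    # stability curves
    n_stability_proteins: int = 80
    stability_offset: float = 0.7  # kcal/mol added to group C dG(-1 degC)
    tm_range: tuple[float, float] = (310.0, 350.0)
    dg_mean: float = -8.0  # baseline folding dG at -1 degC, kcal/mol
    dg_sd: float = 1.5  # spread across proteins
    dg_noise_sd: float = 0.3  # per-curve noise within a protein
    # OTU counts
    n_otus: int = 50
    n_otu_samples: int = 76
    otu_depth: int = 10_000
    planted_corr: float = 0.8
    planted_pairs: tuple = ((0, 1, 1.0), (2, 3, -1.0))

    def validate(self) -> None:
        for p in (
            self.presence_prob_in_group,
            self.presence_prob_out_group,
            self.accessory_presence_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if min(self.n_genomes_per_group) < 1:
            raise ConfigError("every group needs at least one genome")
        if self.enrichment_factor < 1.0:
            raise ConfigError("enrichment_factor must be >= 1")
        if not -1.0 <= self.planted_corr <= 1.0:
            raise ConfigError("planted_corr must be in [-1, 1]")


@dataclass
class GenomeCollectionTruth:
    marker_families: dict[str, list[str]]
    group_aa_freqs: dict[str, np.ndarray]
    gc_targets: dict[str, float]
    genome_groups: pd.Series


@dataclass
class CatalogTruth:
    copy_counts: pd.DataFrame  # sample x {hits_pan, hits_A, hits_B, hits_C}
    enriched_samples: list[str]
    source_families: dict[str, list[str]]  # sample -> family of each gene


@dataclass
class StabilityTruth:
    offset: float
    baseline: pd.DataFrame


@dataclass
class OtuTruth:
    basis_correlation: pd.DataFrame
    planted: list[tuple[str, str, float]]


def _group_freqs(cfg: SimConfig) -> dict[str, np.ndarray]:
    base = np.full(20, 1.0 / 20.0)
    freqs = {"A": base.copy(), "B": base.copy()}
    shifted = base.copy()
    for res, delta in cfg.aa_shift.items():
        shifted[AMINO_ACIDS.index(res)] += delta
    if (shifted <= 0).any():
        raise ConfigError("aa_shift drives a residue frequency below zero")
    freqs["C"] = shifted / shifted.sum()
    return freqs


def _draw_protein(rng: np.random.Generator, freq: np.ndarray, cfg: SimConfig) -> str:
    length = max(
        cfg.protein_len_min,
        int(round(rng.normal(cfg.protein_len_mean, cfg.protein_len_sd))),
    )
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=freq))


def _presence_vector(
    rng: np.random.Generator, n_in: int, n_out: tuple[int, ...], cfg: SimConfig
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Presence flags for one group-specific family, enforcing 95/95.

    Sampled from the configured probabilities, then resampled until the
    family is present in >= 95 % of the target group and <= 5 % of each
    other group, so planted markers satisfy the rule by construction.
    """
    for _ in range(1000):
        inside = rng.random(n_in) < cfg.presence_prob_in_group
        outside = [rng.random(n) < cfg.presence_prob_out_group for n in n_out]
        if inside.mean() >= 0.95 and all(
            (o.mean() <= 0.05 if len(o) else True) for o in outside
        ):
            return inside, outside
    raise ConfigError(
        "could not realize a 95/95-compatible presence vector; "
        "presence probabilities too far from 1/0"
    )


def _random_nucleotide(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]  # A, T, G, C
    return "".join(rng.choice(list("ATGC"), size=length, p=p))


def _caterpillar_newick(tips: Sequence[str], rng: np.random.Generator) -> str:
    sub = f"{tips[0]}:{rng.uniform(0.01, 0.1):.4f}"
    for t in tips[1:]:
        sub = f"({sub},{t}:{rng.uniform(0.01, 0.1):.4f}):{rng.uniform(0.01, 0.1):.4f}"
    return sub


def simulate_genome_collection(
    cfg: SimConfig,
) -> tuple[list[GenomeRecord], GeneFamilyMatrix, LabeledTree, GenomeCollectionTruth]:
    """Genome records, gene-family matrix, group-clade tree and ground truth.

    Proteome residues are drawn i.i.d. from per-group frequency vectors;
    family membership is assigned by construction (the matrix is emitted
    directly, so marker discovery is tested independently of sequence
    clustering).  Each group forms an exclusive clade on the tree.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    freqs = _group_freqs(cfg)
    n_a, n_b, n_c = cfg.n_genomes_per_group
    genome_ids: list[str] = (
        [f"A{i:03d}" for i in range(n_a)]
        + [f"B{i:03d}" for i in range(n_b)]
        + [f"C{i:03d}" for i in range(n_c)]
    )
    genome_group = {g: g[0] for g in genome_ids}
    members = {grp: [g for g in genome_ids if genome_group[g] == grp] for grp in GROUPS}

    fam_ids: list[str] = []
    fam_owner: dict[str, Optional[str]] = {}
    presence = pd.DataFrame(False, index=[], columns=genome_ids)
    rows = {}
    for i in range(cfg.n_families_core):
        fam = f"core_{i:04d}"
        fam_ids.append(fam)
        fam_owner[fam] = None
        rows[fam] = {g: True for g in genome_ids}
    marker_truth: dict[str, list[str]] = {g: [] for g in GROUPS}
    for grp in GROUPS:
        others = [h for h in GROUPS if h != grp]
        for i in range(cfg.n_families_group_specific):
            fam = f"spec{grp}_{i:04d}"
            fam_ids.append(fam)
            fam_owner[fam] = grp
            marker_truth[grp].append(fam)
            inside, outside = _presence_vector(
                rng, len(members[grp]), tuple(len(members[h]) for h in others), cfg
            )
            row = {}
            for g, flag in zip(members[grp], inside):
                row[g] = bool(flag)
            for h, flags in zip(others, outside):
                for g, flag in zip(members[h], flags):
                    row[g] = bool(flag)
            rows[fam] = row
    for i in range(cfg.n_families_accessory):
        fam = f"acc_{i:04d}"
        fam_ids.append(fam)
        fam_owner[fam] = None
        keep = rng.random(len(genome_ids)) < cfg.accessory_presence_prob
        if not keep.any():
            keep[int(rng.integers(len(genome_ids)))] = True
        rows[fam] = {g: bool(k) for g, k in zip(genome_ids, keep)}
    presence = pd.DataFrame.from_dict(rows, orient="index").loc[fam_ids, genome_ids]
    counts = presence.astype(int)

    # proteomes: one protein per present family, drawn from the genome
    # group's residue frequencies; representative = first carrier's copy
    proteomes: dict[str, list[tuple[str, str]]] = {g: [] for g in genome_ids}
    representatives: dict[str, tuple[str, str]] = {}
    for fam in fam_ids:
        carriers = [g for g in genome_ids if presence.loc[fam, g]]
        for g in carriers:
            pid = f"{g}|{fam}"
            seq = _draw_protein(rng, freqs[genome_group[g]], cfg)
            proteomes[g].append((pid, seq))
            if fam not in representatives:
                representatives[fam] = (pid, seq)
        if fam not in representatives:  # family present nowhere (possible only
            pid = f"ref|{fam}"  # for out-group-only probabilistic draws)
            representatives[fam] = (pid, _draw_protein(rng, freqs["A"], cfg))

    gc_targets = dict(cfg.gc_mean_per_group)
    records = []
    for g in genome_ids:
        grp = genome_group[g]
        gc = float(np.clip(rng.normal(gc_targets[grp], cfg.gc_sd), 0.25, 0.75))
        nuc = _random_nucleotide(rng, cfg.genome_seq_len, gc)
        records.append(
            GenomeRecord(
                genome_id=g,
                group=grp,
                environment="PA" if grp in ("B", "C") else "NPA",
                proteome=proteomes[g],
                genome_seq_gc=(nuc.count("G") + nuc.count("C")) / len(nuc),
                completeness=float(rng.uniform(95.0, 100.0)),
                contamination=float(rng.uniform(0.0, 3.0)),
                n_contigs=int(rng.integers(20, 200)),
                n50=int(rng.integers(50_000, 2_000_000)),
            )
        )

    newick = (
        "("
        + ",".join(_caterpillar_newick(members[grp], rng) for grp in GROUPS)
        + ");"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labeled = LabeledTree(tree=tree, labels=dict(genome_group))

    matrix = GeneFamilyMatrix(counts=counts, representatives=representatives)
    truth = GenomeCollectionTruth(
        marker_families=marker_truth,
        group_aa_freqs=freqs,
        gc_targets=gc_targets,
        genome_groups=pd.Series(genome_group),
    )
    return records, matrix, labeled, truth


_BLOSUM = substitution_matrices.load("BLOSUM62")
_SUBSTITUTION_P = {}
for _a in AMINO_ACIDS:
    _w = np.array(
        [math.exp(_BLOSUM[_a, _b]) if _b != _a else 0.0 for _b in AMINO_ACIDS]
    )
    _SUBSTITUTION_P[_a] = _w / _w.sum()


def mutate_protein(
    rng: np.random.Generator, seq: str, target_identity: float
) -> str:
    """Point-mutate at per-residue rate 1 - identity/100 with
    BLOSUM62-favored replacements, keeping realized identity near target
    under local alignment."""
    rate = 1.0 - target_identity / 100.0
    out = []
    for ch in seq:
        if ch in _SUBSTITUTION_P and rng.random() < rate:
            out.append(rng.choice(list(AMINO_ACIDS), p=_SUBSTITUTION_P[ch]))
        else:
            out.append(ch)
    return "".join(out)


def _simulate_copy_counts(
    cfg: SimConfig,
    matrix: GeneFamilyMatrix,
    marker_sets: dict[str, MarkerSet],
) -> tuple[dict[str, list[tuple[str, int]]], list[SampleMetadata], CatalogTruth]:
    """Per-sample (family, copy-number) draws plus metadata and truth.

    The copy-count process: each pan family f gets a per-family rate
    lambda_f; sample s draws Poisson(d_s * lambda_f) copies where d_s is
    a log-normal depth factor.  Enrichment is site-level and uniform:
    every enriched sample carries the same additional group-C marker
    copies, apportioned across marker families so the cohort total is
    (enrichment_factor - 1) times the expected baseline.  The cohort
    therefore averages enrichment_factor-times more group-C copies while
    staying parallel to the background regression line (an intercept
    offset, the signature a single enriched site leaves in hit counts).
    """
    cfg.validate()
    for grp, ms in marker_sets.items():
        if not ms.families:
            raise ConfigError(f"marker set for group {grp!r} is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    fam_ids = matrix.family_ids
    all_markers = set().union(*(ms.families for ms in marker_sets.values()))
    fam_rate = {
        f: rng.uniform(
            *(cfg.marker_rate_range if f in all_markers else cfg.family_rate_range)
        )
        for f in fam_ids
    }
    c_markers = set(marker_sets.get("C", MarkerSet("C", [], {}, 0)).families)
    set_of_family = {grp: set(ms.families) for grp, ms in marker_sets.items()}

    # uniform site-level extra copies for the enriched cohort, apportioned
    # by largest remainder so the total is (factor - 1) * sum(lambda_C)
    extra: dict[str, int] = {f: 0 for f in fam_ids}
    if cfg.enrichment_factor > 1.0 and c_markers:
        lams = {f: fam_rate[f] for f in fam_ids if f in c_markers}
        total = (cfg.enrichment_factor - 1.0) * sum(lams.values())
        n_extra = int(round(total))
        shares = {f: n_extra * lam / sum(lams.values()) for f, lam in lams.items()}
        for f, s in shares.items():
            extra[f] = int(s)
        remainder = n_extra - sum(extra[f] for f in lams)
        for f, _ in sorted(
            lams.items(), key=lambda kv: (shares[kv[0]] - int(shares[kv[0]]), kv[0]),
            reverse=True,
        )[:remainder]:
            extra[f] += 1

    sample_ids = [f"mg{i:03d}" for i in range(cfg.n_metagenomes)]
    enriched = sorted(
        rng.choice(cfg.n_metagenomes, size=cfg.enriched_sample_count, replace=False)
    )
    enriched_ids = [sample_ids[i] for i in enriched]

    copies: dict[str, list[tuple[str, int]]] = {}
    metadata: list[SampleMetadata] = []
    truth_rows = {}
    source_families: dict[str, list[str]] = {}
    for sid in sample_ids:
        sigma = cfg.enriched_depth_sigma if sid in enriched_ids else cfg.depth_sigma
        depth = float(np.exp(rng.normal(0.0, sigma)))
        counts = {"hits_pan": 0, **{f"hits_{g}": 0 for g in marker_sets}}
        fam_copies: list[tuple[str, int]] = []
        sources: list[str] = []
        for fam in fam_ids:
            lam = depth * fam_rate[fam]
            n_copies = int(rng.poisson(lam))
            if sid in enriched_ids:
                n_copies += extra[fam]
            if n_copies:
                fam_copies.append((fam, n_copies))
                sources.extend([fam] * n_copies)
                counts["hits_pan"] += n_copies
                for grp, fams in set_of_family.items():
                    if fam in fams:
                        counts[f"hits_{grp}"] += n_copies
        copies[sid] = fam_copies
        source_families[sid] = sources
        truth_rows[sid] = counts
        if sid in enriched_ids:
            mat = float(rng.uniform(-20.0, -5.0))
            cohort = cfg.enriched_cohort
        else:
            mat = float(rng.uniform(-24.0, 28.0))
            cohort = "background"
        lat = float(np.clip(66.0 - 1.6 * mat + rng.normal(0.0, 4.0), -90.0, 90.0))
        metadata.append(
            SampleMetadata(sample_id=sid, mat=mat, latitude=lat, cohort=cohort)
        )
    truth = CatalogTruth(
        copy_counts=pd.DataFrame.from_dict(truth_rows, orient="index").rename_axis(
            "sample_id"
        ),
        enriched_samples=enriched_ids,
        source_families=source_families,
    )
    return copies, metadata, truth


def simulate_hit_counts(
    cfg: SimConfig,
    matrix: GeneFamilyMatrix,
    marker_sets: dict[str, MarkerSet],
) -> tuple[pd.DataFrame, list[SampleMetadata], CatalogTruth]:
    """Ground-truth per-sample copy counts without sequence generation.

    Runs the identical copy-count process as
    :func:`simulate_metagenome_catalogs` (same seed, same draws) but
    skips the point-mutated sequences; useful for repeated-seed power
    studies of the downstream regression/ANCOVA stage.
    """
    copies, metadata, truth = _simulate_copy_counts(cfg, matrix, marker_sets)
    return truth.copy_counts.copy(), metadata, truth


def simulate_metagenome_catalogs(
    cfg: SimConfig,
    matrix: GeneFamilyMatrix,
    marker_sets: dict[str, MarkerSet],
) -> tuple[dict[str, list[tuple[str, str]]], list[SampleMetadata], CatalogTruth]:
    """Metagenome gene catalogs with a planted group-C enrichment.

    Every catalog gene is a point-mutated copy of a pan-genome family
    representative; per-sample copy numbers are Poisson with a log-normal
    sample depth factor, so regressions of group hits on pan hits have
    realistic leverage.  Exactly ``enriched_sample_count`` samples carry
    ``enrichment_factor``-times more copies of group-C marker families
    and are flagged as the enriched cohort in the metadata.
    """
    if cfg.mutation_identity < 40.0:
        raise ConfigError("mutation_identity below 40 % is undetectable by the screen")
    copies, metadata, truth = _simulate_copy_counts(cfg, matrix, marker_sets)
    seq_rng = np.random.default_rng(cfg.seed + 4)
    catalogs: dict[str, list[tuple[str, str]]] = {}
    for sid, fam_copies in copies.items():
        genes: list[tuple[str, str]] = []
        gi = 0
        for fam, n_copies in fam_copies:
            rep_seq = matrix.representatives[fam][1]
            for _ in range(n_copies):
                genes.append(
                    (
                        f"{sid}_g{gi:05d}",
                        mutate_protein(seq_rng, rep_seq, cfg.mutation_identity),
                    )
                )
                gi += 1
        catalogs[sid] = genes
    return catalogs, metadata, truth


def hit_table_from_truth(truth: CatalogTruth) -> pd.DataFrame:
    """Ground-truth copy counts in hit-table form (sample x hits_*)."""
    return truth.copy_counts.copy()


def simulate_stability_params(
    cfg: SimConfig, protein_ids: Optional[Sequence[str]] = None
) -> tuple[list[StabilityCurve], pd.Series, StabilityTruth]:
    """Gibbs-Helmholtz parameters with a planted group-C offset at -1 degC.

    For each protein a baseline curve is drawn once and shared across
    groups: Tm and dCp are sampled, a target folding dG(-1 degC) is drawn
    from N(dg_mean, dg_sd), and dHm is solved so the curve passes through
    that target.  The group-C copy has its enthalpy adjusted so that its
    dG(-1 degC) sits exactly ``stability_offset`` kcal/mol above the
    baseline, then per-curve noise is added.  Returns (curves, genome ->
    group labels, truth).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    if protein_ids is None:
        protein_ids = [f"prot_{i:04d}" for i in range(cfg.n_stability_proteins)]
    t_eval = 272.15
    curves: list[StabilityCurve] = []
    baseline_rows = []
    genome_of_group = {g: f"sim{g}" for g in GROUPS}
    for pid in protein_ids:
        tm = float(rng.uniform(*cfg.tm_range))
        dcp = float(abs(rng.normal(2.0, 0.3)) + 0.2)
        dg0 = float(rng.normal(cfg.dg_mean, cfg.dg_sd))
        c1 = 1.0 - t_eval / tm
        c2 = tm - t_eval + t_eval * math.log(t_eval / tm)
        # dG(t_eval) = -dHm*c1 + dCp*c2 == dg0
        dhm = (dcp * c2 - dg0) / c1
        baseline_rows.append(
            {"protein_id": pid, "tm": tm, "dhm": dhm, "dcp": dcp, "dg0": dg0}
        )
        coeff = -c1  # d(dG)/d(dHm) at the evaluation temperature
        for grp in GROUPS:
            noise = float(rng.normal(0.0, cfg.dg_noise_sd))
            offset = cfg.stability_offset if grp == "C" else 0.0
            curves.append(
                StabilityCurve(
                    protein_id=pid,
                    genome_id=genome_of_group[grp],
                    tm=tm,
                    dhm=dhm + (offset + noise) / coeff,
                    dcp=dcp,
                )
            )
    groups = pd.Series({genome_of_group[g]: g for g in GROUPS})
    truth = StabilityTruth(
        offset=cfg.stability_offset, baseline=pd.DataFrame(baseline_rows)
    )
    return curves, groups, truth


def simulate_otu_counts(cfg: SimConfig) -> tuple[pd.DataFrame, OtuTruth]:
    """Compositional OTU counts from correlated log-normal basis abundances.

    The log-basis covariance is the identity except for the planted pairs,
    which get correlation ``planted_corr`` times the pair's sign.  Counts
    are multinomial draws at fixed depth, so every sample row sums to the
    sequencing depth exactly.
    """
    cfg.validate()
    if cfg.n_otus < 10:
        raise ConfigError("SparCC assumptions need at least 10 OTUs")
    rng = np.random.default_rng(cfg.seed + 3)
    d = cfg.n_otus
    corr = np.eye(d)
    otu_ids = [f"otu_{i:03d}" for i in range(d)]
    planted: list[tuple[str, str, float]] = []
    for i, j, sign in cfg.planted_pairs:
        rho = cfg.planted_corr * sign
        corr[i, j] = corr[j, i] = rho
        planted.append((otu_ids[i], otu_ids[j], rho))
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(d))
    mu = rng.normal(0.0, 1.0, size=d)  # uneven mean abundances
    # planted OTUs are pinned to above-average abundance: correlations
    # planted in rare taxa are attenuated by multinomial sampling noise,
    # which the abundance/prevalence filter exists to exclude
    for i, j, _ in cfg.planted_pairs:
        mu[i] = mu[j] = 0.5
    z = rng.standard_normal((cfg.n_otu_samples, d)) @ chol.T
    basis = np.exp(mu[None, :] + z)
    counts = np.empty((cfg.n_otu_samples, d), dtype=int)
    for s in range(cfg.n_otu_samples):
        counts[s] = rng.multinomial(cfg.otu_depth, basis[s] / basis[s].sum())
    df = pd.DataFrame(
        counts,
        index=[f"sample_{s:03d}" for s in range(cfg.n_otu_samples)],
        columns=otu_ids,
    )
    truth = OtuTruth(
        basis_correlation=pd.DataFrame(corr, index=otu_ids, columns=otu_ids),
        planted=planted,
    )
    return df, truth
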