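"""Shared domain types for the pipeline.

Conventions used throughout the package:

* group labels are ``"A"`` (non-polar/alpine), ``"B"`` (polar/alpine but
  paraphyletic), ``"C"`` (the operationally monophyletic cold-adapted
  clade) or ``"unassigned"``;
* environments are ``"PA"`` (polar and alpine), ``"NPA"`` or ``"unknown"``;
* temperatures are kelvin internally; free energies kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd

VALID_GROUPS = ("A", "B", "C", "unassigned")
VALID_ENVIRONMENTS = ("PA", "NPA", "unknown")

#: the 20 canonical residues, alphabetical
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_AA_SET = frozenset(AMINO_ACIDS) | {"X"}


@dataclass
class GenomeRecord:
    """One genome: identity, labels, proteome and assembly quality metrics."""

    genome_id: str
    group: str = "unassigned"
    environment: str = "unknown"
    proteome: list[tuple[str, str]] = field(default_factory=list)
    genome_seq_gc: Optional[float] = None
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    n_contigs: Optional[int] = None
    n50: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"genome {self.genome_id}: invalid group {self.group!r}")
        if self.environment not in VALID_ENVIRONMENTS:
            raise ValueError(
                f"genome {self.genome_id}: invalid environment {self.environment!r}"
            )
        for pid, seq in self.proteome:
            bad = set(seq) - _AA_SET
            if bad:
                raise ValueError(
                    f"genome {self.genome_id}, protein {pid}: "
                    f"non-canonical residues {sorted(bad)}"
                )
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"genome {self.genome_id}: {name}={v} outside [0, 100]"
                )


@dataclass
class LabeledTree:
    """A phylogeny over genome tips plus a genome→group label map."""

    tree: dendropy.Tree
    labels: dict[str, str]

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __post_init__(self) -> None:
        tips = self.tip_names
        if len(tips) != len(set(tips)):
            raise ValueError("tree has duplicate tip labels")
        for node in self.tree.preorder_internal_node_iter():
            n_children = len(node.child_nodes())
            if n_children == 1 and node is not self.tree.seed_node:
                raise ValueError("tree has an internal node with a single child")


@dataclass
class SampleMetadata:
    """Per-metagenome metadata used for climate binning and cohort tests."""

    sample_id: str
    mat: Optional[float] = None  # mean annual temperature, °C
    latitude: Optional[float] = None
    climate: str = "unassigned"  # PA | temperate | tropical | unassigned
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.mat is not None and not (-90.0 <= self.mat <= 60.0):
            raise ValueError(f"sample {self.sample_id}: MAT {self.mat} outside [-90, 60]")
        if self.latitude is not None and not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(
                f"sample {self.sample_id}: latitude {self.latitude} outside [-90, 90]"
            )


@dataclass
class GeneFamilyMatrix:
    """Gene-family × genome copy-count matrix with one representative per family.

    ``counts`` is a DataFrame indexed by family id with one column per
    genome; entries are non-negative integer copy counts.
    ``representatives`` maps family id → (protein_id, sequence).
    """

    counts: pd.DataFrame
    representatives: dict[str, tuple[str, str]]

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("copy counts must be non-negative")
        missing = set(self.counts.index) - set(self.representatives)
        if missing:
            raise ValueError(f"families without representative: {sorted(missing)[:5]}")


@dataclass
class MarkerSet:
    """Gene families specific to one group under the 95/95 rule."""

    group: str
    families: list[str]
    proteins: dict[str, tuple[str, str]]
    n_genomes: int

    @property
    def normalized_size(self) -> float:
        """Marker families per genome of the group."""
        return len(self.families) / self.n_genomes if self.n_genomes else 0.0


@dataclass
class FResult:
    """Best-node F measure for a labeled group on a tree."""

    best_tips: frozenset[str]
    precision: float
    recall: float
    f: float
    monophyletic: bool


@dataclass
class AlignmentHit:
    """One accepted (or candidate) local protein alignment."""

    query_id: str
    subject_id: str
    score: float  # raw Smith-Waterman score
    bits: float
    identity: float  # percent of alignment columns that match
    query_coverage: float  # percent of query length spanned
    subject_coverage: float = 0.0  # percent of subject length spanned
    evalue: Optional[float] = None


@dataclass
class StabilityCurve:
    """Two-state Gibbs–Helmholtz stability parameters for one protein.

    ``tm`` in kelvin; ``dhm`` (unfolding enthalpy at Tm) in kcal/mol;
    ``dcp`` (heat-capacity change) in kcal/(mol·K).  ΔG(Tm) = 0 by
    construction of the model.
    """

    protein_id: str
    genome_id: str
    tm: float
    dhm: float
    dcp: float

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError(f"{self.protein_id}: Tm must be positive, got {self.tm}")


@dataclass
class RegressionFit:
    """OLS fit of group-specific hits on pan-genome hits."""

    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class AncovaResult:
    """One-way ANCOVA (k = 2) comparing two regression lines.

    When the slopes are not homogeneous (interaction p < 0.05) the
    intercept comparison is not valid and ``valid`` is False.
    """

    slope_homogeneity_p: float
    intercept_diff_p: Optional[float]
    adjusted_means: dict[str, float]
    valid: bool
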