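"""Readers/writers for the standard formats the pipeline touches.

FASTA is parsed with Biopython; ids are the header token before the first
whitespace.  Trees are newick via dendropy.  Tables are TSV with a header
row.  Parsers reject malformed input rather than silently truncating.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from psychromark.types import LabeledTree, SampleMetadata


class ParseError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """Table missing mandatory columns."""


def read_proteome_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into an ordered list of (protein_id, sequence).

    Sequences are upper-cased and terminal ``*`` stop characters stripped.
    Duplicate ids and empty sequences raise :class:`ParseError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        seq = str(rec.seq).upper().strip("*")
        if not pid:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: record {pid!r} has an empty sequence")
        if pid in seen:
            raise ParseError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        records.append((pid, seq))
    return records


def write_proteome_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tree_newick(path: str | Path, labels: dict[str, str]) -> LabeledTree:
    """Read a newick tree and attach group labels to its tips.

    Tips absent from ``labels`` are labeled ``"unassigned"`` with a warning.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"{path}: unparseable newick ({exc})") from exc
    attached: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in labels:
            attached[name] = labels[name]
        else:
            warnings.warn(f"tip {name!r} missing from label map; labeled unassigned")
            attached[name] = "unassigned"
    return LabeledTree(tree=tree, labels=attached)


def write_tree_newick(path: str | Path, labeled: LabeledTree) -> None:
    labeled.tree.write(
        path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True
    )


def read_metadata_table(
    path: str | Path, mandatory: Sequence[str] = ("sample_id",)
) -> pd.DataFrame:
    """Read a TSV metadata table; unknown columns are preserved as strings.

    Numeric columns among {mat, latitude, completeness, contamination,
    n_contigs, n50} are coerced; missing mandatory columns raise
    :class:`SchemaError` listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    # tolerate unicode minus from spreadsheet exports
    numeric = ("mat", "latitude", "completeness", "contamination", "n_contigs", "n50")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    for col in numeric:
        if col in df.columns:
            cleaned = df[col].str.replace("−", "-", regex=False)
            df[col] = pd.to_numeric(cleaned)
    return df


def write_metadata_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def sample_metadata_from_table(df: pd.DataFrame) -> list[SampleMetadata]:
    """Convert a metadata DataFrame into typed :class:`SampleMetadata` rows."""
    rows = []
    for _, r in df.iterrows():
        rows.append(
            SampleMetadata(
                sample_id=str(r["sample_id"]),
                mat=None if "mat" not in df.columns or pd.isna(r.get("mat")) else float(r["mat"]),
                latitude=None
                if "latitude" not in df.columns or pd.isna(r.get("latitude"))
                else float(r["latitude"]),
                climate=str(r["climate"]) if "climate" in df.columns and not pd.isna(r.get("climate")) else "unassigned",
                cohort=str(r["cohort"]) if "cohort" in df.columns and not pd.isna(r.get("cohort")) else "",
            )
        )
    return rows


def read_family_matrix(path: str | Path) -> pd.DataFrame:
    """Read a families × genomes copy-count TSV (family ids in column 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative copy counts")
    return df


def write_family_matrix(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t")


def read_stability_table(path: str | Path) -> pd.DataFrame:
    """Read a curve-parameter TSV with columns protein_id, genome_id, tm, dhm, dcp."""
    df = pd.read_csv(path, sep="\t")
    needed = {"protein_id", "genome_id", "tm", "dhm", "dcp"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def validate_bundle(directory: str | Path) -> dict[str, list[str]]:
    """Check a data-bundle directory; returns {filename: [problems]}.

    Recognizes ``*.faa`` proteomes, ``*.nwk`` trees and ``*.tsv`` tables.
    """
    directory = Path(directory)
    report: dict[str, list[str]] = {}
    for f in sorted(directory.iterdir()):
        problems: list[str] = []
        try:
            if f.suffix in (".faa", ".fasta", ".fa"):
                read_proteome_fasta(f)
            elif f.suffix in (".nwk", ".newick", ".tre"):
                read_tree_newick(f, labels={})
            elif f.suffix == ".tsv":
                read_metadata_table(f, mandatory=())
            else:
                continue
        except (ParseError, SchemaError) as exc:
            problems.append(str(exc))
        report[f.name] = problems
    return report
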