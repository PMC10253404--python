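"""Readers, writers and validation for the pipeline's plain-text formats.

All tables are tab-separated UTF-8 with a header row; missing values are
written as "NA" and accessions are opaque strings. Sequences travel as FASTA.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import SchemaError, ValidationError

PEPTIDE_COLUMNS = ["peptide_id", "peptide_sequence", "protein_accession", "sample_id", "intensity"]
DESIGN_COLUMNS = ["species", "probe", "method", "replicate", "sample_id"]
ANNOTATION_COLUMNS = ["accession", "description", "go_terms", "ipr_terms"]
HOMOLOGUE_COLUMNS = ["local_accession", "reference_accession"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_peptide_report(path: str | Path) -> pd.DataFrame:
    """Read a peptide-level LFQ report.

    Rows with several ";"-separated accessions are kept and flagged
    ``multi_mapped`` (the quantification stage excludes them from abundance
    sums). Negative intensities are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_accession": str, "sample_id": str})
    _require_columns(df, PEPTIDE_COLUMNS, f"peptide report {path}")
    if df.empty:
        warnings.warn(f"peptide report {path} contains a header but no rows")
        df["multi_mapped"] = pd.Series(dtype=bool)
        return df
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = df.index[intensity.isna() | (intensity < 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header and 1-based lines
        raise ValidationError(f"peptide report {path}: non-numeric or negative intensity at line(s) {lines}")
    df["intensity"] = intensity
    df["multi_mapped"] = df["protein_accession"].str.contains(";", regex=False)
    return df


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-design table.

    Hard errors: missing columns, duplicate sample ids, a species without a
    probe-less control (the capture-vs-control classification is undefined
    without one). Incomplete triplicates only warn.
    """
    _require_columns(design, DESIGN_COLUMNS, "design table")
    dup = design["sample_id"][design["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id(s) in design: {sorted(set(dup))}")
    for species, sub in design.groupby("species"):
        if not (sub["probe"] == "none").any():
            raise ValidationError(f"species {species!r} has no probe-less control samples")
    cell_sizes = design.groupby(["species", "probe", "method"])["replicate"].count()
    for cell, n in cell_sizes.items():
        if n < 2:
            warnings.warn(f"design cell {cell} has only {n} replicate(s); statistics need >= 2")
        elif n < 3:
            warnings.warn(f"design cell {cell} has {n} replicates (incomplete triplicate)")
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "probe": str, "method": str})
    return validate_design(design)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ANNOTATION_COLUMNS, f"annotation table {path}")
    return df


def read_homologue_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, HOMOLOGUE_COLUMNS, f"homologue map {path}")
    dup = df["local_accession"][df["local_accession"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"homologue map {path}: local accession(s) mapped more than once: {sorted(set(dup))[:5]}"
        )
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {accession: sequence} preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n{seq}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> int:
    """Write a TSV with 'NA' for missing cells; returns the row count."""
    df.to_csv(path, sep="\t", na_rep="NA", index=index)
    return len(df)
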