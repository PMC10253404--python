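"""Sequence-similarity shortlisting of captured candidate enzymes.

Candidates for an unknown flavonol hydroxylase are shortlisted by combining
two orthogonal signals: local-alignment similarity to known hydroxylase query
sequences, and capture significance from the probe experiments. Similarity
can come from an in-package Smith-Waterman search (BLOSUM62, affine gaps,
BLAST-like cost defaults) or be ingested from BLAST tabular output (outfmt
6), in which case the bit score is the similarity score and the tier cuts
(high > 500, low <= 300) mirror the scale BLAST reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, ValidationError
from .significance import CLASS_SEVERITY, CaptureClass

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap costs; a gap of length L costs
    gap_open + L * gap_extend (the BLAST convention, defaults 11/1)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigurationError("gap penalties must be > 0")


def _validate_sequence(seq: str, role: str) -> None:
    if not seq:
        raise ValidationError(f"{role} sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValidationError(f"invalid residue {ch!r} at position {i} of {role} sequence")


def _build_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    # PairwiseAligner charges open on the first gapped position and extend on
    # the rest; shift so a length-L gap costs gap_open + L * gap_extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def local_align(query: str, subject: str, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Optimal Smith-Waterman local alignment score with affine gaps.

    Symmetric in its arguments (the substitution matrix is symmetric) and
    never negative: the empty alignment scores 0.
    """
    _validate_sequence(query, "query")
    _validate_sequence(subject, "subject")
    aligner = _build_aligner(scheme)
    return max(0.0, float(aligner.score(query, subject)))


def search_database(
    queries: dict[str, str],
    database: dict[str, str],
    scheme: ScoringScheme = ScoringScheme(),
    report_floor: float = 50.0,
    high_cut: float = 500.0,
    low_cut: float = 300.0,
) -> pd.DataFrame:
    """All-vs-all local alignment of queries against a sequence database.

    Hits scoring at least ``report_floor`` are reported, ranked per query by
    descending score, and tiered: ``high`` above ``high_cut``, ``low`` at or
    below ``low_cut``, ``none`` in between. Cuts are configuration, not
    constants: raw Smith-Waterman scores are not calibrated to BLAST bit
    scores, so when BLAST output is available prefer
    :func:`parse_blast_tabular`.
    """
    if not database:
        raise ValidationError("sequence database is empty")
    aligner = _build_aligner(scheme)
    rows = []
    for q_acc, q_seq in queries.items():
        _validate_sequence(q_seq, f"query {q_acc}")
        for s_acc, s_seq in database.items():
            _validate_sequence(s_seq, f"subject {s_acc}")
            score = max(0.0, float(aligner.score(q_seq, s_seq)))
            if score >= report_floor:
                rows.append({"query": q_acc, "subject": s_acc, "score": score})
    cols = ["query", "subject", "score", "tier"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["tier"] = assign_tiers(out["score"], high_cut=high_cut, low_cut=low_cut)
    return (
        out.sort_values(["query", "score", "subject"], ascending=[True, False, True])
        .reset_index(drop=True)[cols]
    )


def assign_tiers(scores: pd.Series, high_cut: float = 500.0, low_cut: float = 300.0) -> pd.Series:
    """Tier similarity scores: high (> high_cut), low (<= low_cut), none."""
    tier = pd.Series("none", index=scores.index)
    tier[scores > high_cut] = "high"
    tier[scores <= low_cut] = "low"
    return tier


def parse_blast_tabular(path: str | Path, high_cut: float = 500.0, low_cut: float = 300.0) -> pd.DataFrame:
    """Read BLAST tabular output (-outfmt 6) into an alignment-hit table.

    The bit score (column 12) becomes the similarity score; the e-value is
    carried through unchanged. Lines with the wrong column count are rejected
    with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                rows.append(
                    {
                        "query": parts[0],
                        "subject": parts[1],
                        "pident": float(parts[2]),
                        "length": int(parts[3]),
                        "evalue": float(parts[10]),
                        "score": float(parts[11]),
                    }
                )
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    cols = ["query", "subject", "pident", "length", "evalue", "score", "tier"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["tier"] = assign_tiers(out["score"], high_cut=high_cut, low_cut=low_cut)
    return out[cols]


def write_blast_tabular(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits back out in the 12-column tabular layout (fields the table
    does not carry are filled with zeros), for round-tripping."""
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            pident = getattr(row, "pident", 0.0)
            length = getattr(row, "length", 0)
            evalue = getattr(row, "evalue", 0.0)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (row.query, row.subject, pident, length, 0, 0, 0, 0, 0, 0,
                              evalue, row.score)
                )
                + "\n"
            )


def crossref_shortlist(
    hits: pd.DataFrame,
    capture: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Join alignment hits with capture classifications into a ranked shortlist.

    ``capture`` is a classified statistics table indexed by accession (in the
    same namespace as the hit subjects; apply the homologue map upstream if
    needed). Each subject keeps its best-scoring hit. Rank order: capture
    class severity (absent-from-control first, then enriched, then
    significant...), then alignment score descending, then accession — a
    total order with deterministic tie-breaks. Returns (shortlist,
    hits_without_capture, captures_without_hit); subjects classified
    not_detected go to the side table.
    """
    best = (
        hits.sort_values(["subject", "score", "query"], ascending=[True, False, True])
        .drop_duplicates(subset="subject", keep="first")
        .set_index("subject")
    )
    captured = capture[capture["capture_class"] != CaptureClass.NOT_DETECTED.value]
    common = best.index.intersection(captured.index)
    shortlist = best.loc[common, ["query", "score", "tier"]].copy()
    shortlist["capture_class"] = captured.loc[common, "capture_class"]
    shortlist["severity"] = shortlist["capture_class"].map(CLASS_SEVERITY)
    shortlist.index.name = "subject"
    shortlist = shortlist.reset_index().sort_values(
        ["severity", "score", "subject"], ascending=[False, False, True]
    ).reset_index(drop=True)
    shortlist["rank"] = range(1, len(shortlist) + 1)
    shortlist = shortlist.drop(columns="severity")

    hits_only = best.loc[best.index.difference(captured.index)]
    hits_only.index.name = "subject"
    hits_only = hits_only.reset_index()
    capture_only = captured.loc[captured.index.difference(best.index)]
    return shortlist, hits_only, capture_only
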