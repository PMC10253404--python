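"""Annotation-based candidate screening, cross-assay tables and GO enrichment.

Captured proteins are sorted into candidate classes for the flavonoid-pathway
enzyme hunt — oxidases (A), methyltransferases (B), glycosyltransferases (C),
everything else or unannotated (D) — by case-insensitive keyword matching
against protein descriptions and GO/InterPro term names. Assays run against
different species' databases are made comparable through a homologue map onto
a common reference proteome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .significance import HIGHLY_SIGNIFICANT

#: keyword vocabulary of the A/B/C candidate classes, matched as
#: case-insensitive substrings; priority A > B > C on multiple matches
DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "A_oxidase": (
        "oxidase", "oxidoreductase", "hydroxylase", "monooxygenase",
        "cytochrome p450", "peroxidase", "dioxygenase",
    ),
    "B_methyltransferase": ("methyltransferase", "o-methyltransferase", "methyl transferase"),
    "C_glycosyltransferase": (
        "glycosyltransferase", "glucosyltransferase", "glcnac transferase", "udp-glycosyl",
    ),
}

CATEGORY_PRIORITY = ("A_oxidase", "B_methyltransferase", "C_glycosyltransferase")

_GO_RE = re.compile(r"^GO:\d{7}$")
_IPR_RE = re.compile(r"^IPR\d{6}$")


def _split_terms(cell: str) -> list[tuple[str, str]]:
    """Parse ';'-separated 'ID|name' annotation terms; name may be absent."""
    if not isinstance(cell, str) or not cell.strip():
        return []
    out = []
    for chunk in cell.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        ident, _, name = chunk.partition("|")
        out.append((ident.strip(), name.strip()))
    return out


def categorize_candidates(
    annotations: pd.DataFrame,
    keywords: dict[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """Map each accession to its screen category.

    ``annotations`` needs accession, description, go_terms and ipr_terms
    columns. Keywords are searched in the description and in the GO/IPR term
    names; assignment is deterministic and independent of row order.
    """
    keywords = keywords or DEFAULT_KEYWORDS
    for cat in CATEGORY_PRIORITY:
        if not keywords.get(cat):
            raise ConfigurationError(f"keyword list for {cat} must be non-empty")

    def one(row) -> str:
        text = str(row.description or "").lower()
        for cell in (row.go_terms, row.ipr_terms):
            for _, name in _split_terms(cell):
                text += " " + name.lower()
        for cat in CATEGORY_PRIORITY:
            if any(kw.lower() in text for kw in keywords[cat]):
                return cat
        return "D_other"

    out = pd.Series(
        [one(row) for row in annotations.itertuples(index=False)],
        index=annotations["accession"].to_numpy(),
        name="category",
    )
    out.index.name = "accession"
    return out


def apply_homologue_map(accessions: pd.Index | pd.Series, homologue_map: pd.DataFrame) -> pd.Series:
    """Translate local accessions to reference accessions; unmapped entries
    keep their local accession (flagged by the caller where relevant)."""
    lut = dict(zip(homologue_map["local_accession"], homologue_map["reference_accession"]))
    return pd.Series([lut.get(a, a) for a in accessions], index=list(accessions))


def build_heatmap_table(
    classified_by_assay: dict[tuple[str, str, str], pd.DataFrame],
    categories: pd.Series,
    homologue_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format cross-assay capture table (the tabular heatmap).

    Keys of ``classified_by_assay`` are (species, probe, method); each value
    is a classified statistics table indexed by local accession. One output
    row per (reference accession, assay) with any detection, carrying the
    capture class, the fold change r when defined, and the screen category.
    Many-to-one homologue collisions are resolved per assay by keeping the
    cell with the lower p (ties: lower accession). Proteins highly
    significant under exactly one of the two quercetin probes (Q8/Q6) are
    flagged ``exclusive_quercetin_probe``.
    """
    rows = []
    for (species, probe, method), table in classified_by_assay.items():
        det = table[table["capture_class"] != "not_detected"]
        if homologue_map is not None:
            ref = apply_homologue_map(det.index, homologue_map)
            mapped = ref.to_numpy()
        else:
            mapped = np.asarray(det.index)
        for local_acc, ref_acc, row in zip(det.index, mapped, det.itertuples(index=False)):
            rows.append(
                {
                    "reference_accession": ref_acc,
                    "local_accession": local_acc,
                    "species": species,
                    "probe": probe,
                    "method": method,
                    "capture_class": row.capture_class,
                    "r": row.r,
                    "p": row.p,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["reference_accession", "local_accession", "species", "probe",
                     "method", "capture_class", "r", "p", "category",
                     "exclusive_quercetin_probe"]
        )
    long = pd.DataFrame(rows)
    # collapse homologue collisions: best (lowest p, NaN last) per assay cell
    long["_p_order"] = long["p"].fillna(np.inf)
    long = (
        long.sort_values(["_p_order", "local_accession"])
        .drop_duplicates(subset=["reference_accession", "species", "probe", "method"], keep="first")
        .drop(columns="_p_order")
    )

    cat_lut = categories.to_dict()
    long["category"] = [cat_lut.get(a, cat_lut.get(r, "D_other"))
                        for a, r in zip(long["local_accession"], long["reference_accession"])]

    hs = long["capture_class"].isin(HIGHLY_SIGNIFICANT)
    q_probes = long.loc[hs & long["probe"].isin(["Q8", "Q6"])]
    probes_per_ref = q_probes.groupby("reference_accession")["probe"].nunique()
    exclusive = set(probes_per_ref.index[probes_per_ref == 1])
    long["exclusive_quercetin_probe"] = long["reference_accession"].isin(exclusive)
    return long.sort_values(["reference_accession", "species", "probe", "method"]).reset_index(drop=True)


def cross_species_coherence(
    results_species1: dict[tuple, pd.DataFrame],
    results_species2: dict[tuple, pd.DataFrame],
    homologue_map1: pd.DataFrame,
    homologue_map2: pd.DataFrame,
) -> set[str]:
    """Reference accessions highly significant in at least one assay of each
    species — capture confirmed from both proteomes."""

    def hs_refs(results: dict[tuple, pd.DataFrame], hmap: pd.DataFrame) -> set[str]:
        refs: set[str] = set()
        for table in results.values():
            hs = table.index[table["capture_class"].isin(HIGHLY_SIGNIFICANT)]
            refs.update(apply_homologue_map(hs, hmap))
        return refs

    return hs_refs(results_species1, homologue_map1) & hs_refs(results_species2, homologue_map2)


@dataclass
class EnrichmentResult:
    """GO over-representation table with BH-adjusted p-values."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def go_enrichment(
    target: "set[str]",
    background: "set[str]",
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per GO term.

    ``background`` is the set of proteins detected in the total proteome and
    must contain ``target``. For a term annotated on K background proteins of
    N, with k hits among the n targets, p = P[X >= k] for X ~
    Hypergeom(N, K, n); Benjamini-Hochberg adjustment across the tested
    terms. Terms with zero target hits are skipped.
    """
    if not target <= background:
        raise ValidationError("target set must be a subset of the background set")
    ann = annotations[annotations["accession"].isin(background)]
    term_members: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for row in ann.itertuples(index=False):
        for ident, name in _split_terms(row.go_terms):
            if not _GO_RE.match(ident):
                raise ValidationError(f"malformed GO identifier {ident!r} on {row.accession}")
            term_members.setdefault(ident, set()).add(row.accession)
            if name:
                term_names.setdefault(ident, name)

    n_bg = len(background)
    n_target = len(target)
    rows = []
    for ident, members in term_members.items():
        k = len(members & target)
        if k == 0:
            continue
        big_k = len(members)
        p = stats.hypergeom.sf(k - 1, n_bg, big_k, n_target)
        rows.append(
            {
                "term": ident,
                "name": term_names.get(ident, ""),
                "target_count": k,
                "target_size": n_target,
                "background_count": big_k,
                "background_size": n_bg,
                "p": min(float(p), 1.0),
            }
        )
    cols = ["term", "name", "target_count", "target_size", "background_count",
            "background_size", "p", "p_adjusted"]
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p_adjusted", "p", "term"]).reset_index(drop=True)[cols]
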