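"""Peptide report -> normalized protein abundance matrix -> per-contrast statistics.

Processing rules, applied downstream of peptide identification:

* protein abundance = sum of intensities of peptides *unique* to that protein
  (peptides mapping to more than one accession contribute to none);
* normalization on total protein amounts: each sample column is rescaled so
  its total matches the grand mean of the column totals, preserving all
  within-sample ratios;
* proteins quantified by fewer than two peptides are dropped;
* ratios come from grouped (replicate-averaged) abundances, p-values from a
  one-way ANOVA on log2 abundances.

Missing values are genuinely missing (a protein not observed in a sample),
never zero, and are never imputed: absence propagates as flags because the
"absent from the negative control" state is meaningful downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance table plus per-cell unique-peptide counts.

    ``abundance`` uses NaN for "not observed" (a state distinct from zero);
    ``peptide_counts`` is integer-valued, 0 where nothing was observed.
    """

    abundance: pd.DataFrame
    peptide_counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.peptide_counts = self.peptide_counts.reindex(
            index=self.abundance.index, columns=self.abundance.columns, fill_value=0
        ).astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.index)

    def detection_counts(self, sample_ids: list[str]) -> pd.Series:
        """Number of the given samples in which each protein was observed."""
        return self.abundance[sample_ids].notna().sum(axis=1)


@dataclass
class Contrast:
    """A numerator-group vs denominator-group comparison (e.g. Q8 capture
    vs probe-less control)."""

    numerator: list[str]
    denominator: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ConfigurationError("contrast groups must be non-empty")
        if set(self.numerator) & set(self.denominator):
            raise ConfigurationError("contrast groups must be disjoint")

    def reversed(self) -> "Contrast":
        return Contrast(self.denominator, self.numerator, label=f"rev({self.label})")


def aggregate_abundance(peptides: pd.DataFrame, catalog: set[str]) -> AbundanceMatrix:
    """Sum unique-peptide intensities into a raw protein x sample matrix.

    ``peptides`` must carry peptide_id, protein_accession, sample_id and
    intensity columns; a protein_accession holding several ";"-separated
    accessions marks a shared peptide, which is excluded from every protein's
    sum. Accessions absent from ``catalog`` raise, listing the offenders.
    """
    required = {"peptide_id", "protein_accession", "sample_id", "intensity"}
    missing = required - set(peptides.columns)
    if missing:
        raise ValidationError(f"peptide report lacks columns: {sorted(missing)}")

    multi = peptides["protein_accession"].str.contains(";", regex=False)
    unique_rows = peptides.loc[~multi]

    referenced = set(unique_rows["protein_accession"].unique())
    for acc_field in peptides.loc[multi, "protein_accession"].unique():
        referenced.update(acc_field.split(";"))
    unknown = referenced - catalog
    if unknown:
        raise ValidationError(
            f"peptides reference accessions not in the catalog: {sorted(unknown)[:10]}"
        )

    abundance = unique_rows.pivot_table(
        index="protein_accession", columns="sample_id", values="intensity",
        aggfunc="sum", dropna=True,
    )
    counts = unique_rows.pivot_table(
        index="protein_accession", columns="sample_id", values="peptide_id",
        aggfunc="nunique",
    ).fillna(0)
    abundance.index.name = "accession"
    counts.index.name = "accession"
    return AbundanceMatrix(abundance=abundance, peptide_counts=counts)


def normalize_abundance(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Equalize column totals to their grand mean ("normalization on total
    protein amounts"). Idempotent; preserves within-sample ratios."""
    totals = matrix.abundance.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"samples with no observed abundance cannot be normalized: {bad}")
    scale = totals.mean() / totals
    return AbundanceMatrix(
        abundance=matrix.abundance * scale,
        peptide_counts=matrix.peptide_counts.copy(),
    )


def filter_min_peptides(matrix: AbundanceMatrix, k: int = 2) -> AbundanceMatrix:
    """Drop proteins whose best per-sample unique-peptide count is below ``k``
    (default: quantified by a minimum of two peptides)."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    keep = matrix.peptide_counts.max(axis=1) >= k
    return AbundanceMatrix(
        abundance=matrix.abundance.loc[keep],
        peptide_counts=matrix.peptide_counts.loc[keep],
    )


def group_ratio(
    matrix: AbundanceMatrix, contrast: Contrast, center: str = "mean"
) -> pd.DataFrame:
    """Per-protein fold change r between grouped abundances.

    r = center(observed numerator abundances) / center(observed denominator
    abundances). A protein observed in neither / only one side is flagged
    (``absent_in_numerator`` / ``absent_in_denominator``) instead of getting
    an infinite or undefined number; flagged rows carry NaN in ``r``.
    """
    if center not in ("mean", "median"):
        raise ConfigurationError("center must be 'mean' or 'median'")
    num = matrix.abundance[contrast.numerator]
    den = matrix.abundance[contrast.denominator]
    agg = "median" if center == "median" else "mean"
    num_c = getattr(num, agg)(axis=1, skipna=True)
    den_c = getattr(den, agg)(axis=1, skipna=True)
    absent_num = num.isna().all(axis=1)
    absent_den = den.isna().all(axis=1)
    r = num_c / den_c
    r[absent_num | absent_den] = np.nan
    return pd.DataFrame(
        {
            "r": r,
            "absent_in_numerator": absent_num,
            "absent_in_denominator": absent_den,
            "n_detected_numerator": num.notna().sum(axis=1),
            "n_detected_denominator": den.notna().sum(axis=1),
        }
    )


def anova_pvalue(
    matrix: AbundanceMatrix, groups: list[list[str]], log_transform: bool = True
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per protein across the sample groups.

    Computed on log2 abundances by default (LFQ intensities are
    multiplicative). Proteins with fewer than two observed values in any
    group, or with zero within- and between-group variance, get NaN with the
    reason in the ``flag`` column. Vectorized sum-of-squares decomposition;
    missing cells are simply absent from their group's sample.
    """
    if len(groups) < 2:
        raise ConfigurationError("ANOVA needs at least 2 groups")
    values = matrix.abundance
    if log_transform:
        values = np.log2(values)

    n_prot = len(values)
    group_n = np.zeros((len(groups), n_prot))
    group_sum = np.zeros((len(groups), n_prot))
    group_sumsq = np.zeros((len(groups), n_prot))
    for gi, sample_ids in enumerate(groups):
        block = values[list(sample_ids)].to_numpy(dtype=float)
        mask = ~np.isnan(block)
        group_n[gi] = mask.sum(axis=1)
        group_sum[gi] = np.nansum(np.where(mask, block, 0.0), axis=1)
        group_sumsq[gi] = np.nansum(np.where(mask, block ** 2, 0.0), axis=1)

    total_n = group_n.sum(axis=0)
    total_sum = group_sum.sum(axis=0)
    total_sumsq = group_sumsq.sum(axis=0)
    k = len(groups)

    with np.errstate(divide="ignore", invalid="ignore"):
        ss_total = total_sumsq - total_sum ** 2 / total_n
        ss_within = (group_sumsq - group_sum ** 2 / np.where(group_n > 0, group_n, np.nan)).sum(axis=0)
        ss_between = ss_total - ss_within
        df_between = float(k - 1)
        df_within = total_n - k
        f_stat = (ss_between / df_between) / (ss_within / df_within)

    enough = (group_n >= 2).all(axis=0)
    # zero within-group variance makes F undefined (0/0) or infinite
    degenerate = enough & ~np.isfinite(f_stat)
    valid = enough & np.isfinite(f_stat)
    p = np.full(n_prot, np.nan)
    p[valid] = stats.f.sf(f_stat[valid], df_between, df_within[valid])
    # survival function can return exactly 0 at extreme F; clamp into (0, 1]
    p[valid] = np.clip(p[valid], np.finfo(float).tiny, 1.0)

    flag = np.where(~enough, "insufficient_replicates", "")
    flag = np.where(degenerate, "zero_variance", flag)
    return pd.DataFrame(
        {"F": np.where(valid, f_stat, np.nan), "p": p, "flag": flag}, index=values.index
    )


def contrast_statistics(
    matrix: AbundanceMatrix,
    contrast: Contrast,
    center: str = "mean",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Combined per-protein statistics table for one capture-vs-control
    contrast: fold change r with absence flags, ANOVA p, derived log2(r) and
    -log10(p), detection counts and the best per-sample peptide count."""
    ratios = group_ratio(matrix, contrast, center=center)
    anova = anova_pvalue(matrix, [contrast.numerator, contrast.denominator],
                         log_transform=log_transform)
    out = ratios.join(anova[["p", "flag"]])
    out = out.rename(
        columns={
            "n_detected_numerator": "n_detected_capture",
            "n_detected_denominator": "n_detected_control",
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_r"] = np.where(out["r"] > 0, np.log2(out["r"]), np.nan)
        out["neg_log10_p"] = -np.log10(out["p"])
    out["contrast"] = contrast.label
    out["max_peptides"] = matrix.peptide_counts.max(axis=1)
    return out
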