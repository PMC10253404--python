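"""Probe/method set comparisons and the probe-vs-probe selectivity volcano.

When two probes both capture a protein and the negative control contains no
signal for it, the capture-vs-control ratio is undefined in both assays; the
remaining quantitative handle is the head-to-head abundance ratio between the
two capture samples. That is the selectivity volcano: lg2(r) of probe-A vs
probe-B capture abundance against -log10 of the two-group test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quantify import AbundanceMatrix, Contrast, anova_pvalue


@dataclass
class VennCounts:
    """Exact region cardinalities for 2 or 3 labeled sets.

    ``regions`` maps a membership signature — a tuple of booleans aligned
    with ``labels`` — to the number of accessions with exactly that
    membership pattern (the 2^k - 1 non-empty diagram regions).
    """

    labels: list[str]
    regions: dict[tuple[bool, ...], int]

    def count(self, *members: str) -> int:
        sig = tuple(lab in members for lab in self.labels)
        return self.regions.get(sig, 0)

    def set_size(self, label: str) -> int:
        i = self.labels.index(label)
        return sum(n for sig, n in self.regions.items() if sig[i])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(lab for lab, m in zip(self.labels, sig) if m), n)
            for sig, n in sorted(self.regions.items(), reverse=True)
        ]
        return pd.DataFrame(rows, columns=["region", "count"])


def set_overlap(sets: dict[str, "set[str] | list[str]"]) -> VennCounts:
    """Region counts of 2 or 3 labeled accession sets by set algebra.

    Inputs given as sequences must not contain duplicates (sets must be
    sets); every non-empty membership signature is reported, including
    zero-count regions.
    """
    if not 2 <= len(sets) <= 3:
        raise ValidationError("set_overlap supports 2 or 3 sets")
    clean: dict[str, set] = {}
    for label, members in sets.items():
        as_set = set(members)
        if not isinstance(members, (set, frozenset)) and len(as_set) != len(list(members)):
            raise ValidationError(f"set {label!r} contains duplicate accessions")
        clean[label] = as_set
    labels = list(clean)
    regions: dict[tuple[bool, ...], int] = {}
    for sig in product([True, False], repeat=len(labels)):
        if not any(sig):
            continue
        inside = set.intersection(*(clean[lab] for lab, m in zip(labels, sig) if m))
        outside = set.union(set(), *(clean[lab] for lab, m in zip(labels, sig) if not m))
        regions[sig] = len(inside - outside)
    return VennCounts(labels=labels, regions=regions)


def probe_selectivity(
    matrix: AbundanceMatrix,
    probe_a_samples: list[str],
    probe_b_samples: list[str],
    eligible: "set[str]",
    p_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Head-to-head selectivity statistics for the eligible proteins.

    ``eligible`` should hold proteins highly significantly captured by both
    probes and absent from the negative controls. Returns ``(records,
    excluded)``: records carry lg2_r (log2 mean probe-A / mean probe-B
    abundance), neg_log10_p from the two-group ANOVA on log2 abundances, and
    a ``significant`` flag at p < ``p_max``; proteins missing in all
    replicates of either probe go to the excluded table with a reason.
    """
    eligible_idx = [acc for acc in matrix.proteins if acc in eligible]
    sub = AbundanceMatrix(
        abundance=matrix.abundance.loc[eligible_idx],
        peptide_counts=matrix.peptide_counts.loc[eligible_idx],
    )
    a = sub.abundance[probe_a_samples]
    b = sub.abundance[probe_b_samples]
    absent_a = a.isna().all(axis=1)
    absent_b = b.isna().all(axis=1)
    excluded = pd.DataFrame(
        {
            "reason": np.select(
                [absent_a & absent_b, absent_a, absent_b],
                ["absent_in_both_probes", "absent_in_probe_a", "absent_in_probe_b"],
                default="",
            )
        },
        index=sub.abundance.index,
    )
    excluded = excluded[excluded["reason"] != ""]

    keep = ~(absent_a | absent_b)
    kept = AbundanceMatrix(
        abundance=sub.abundance.loc[keep], peptide_counts=sub.peptide_counts.loc[keep]
    )
    # difference of logs (not log of the quotient) so that swapping the
    # probes negates lg2_r exactly
    lg2_r = (np.log2(kept.abundance[probe_a_samples].mean(axis=1, skipna=True))
             - np.log2(kept.abundance[probe_b_samples].mean(axis=1, skipna=True)))
    anova = anova_pvalue(kept, [probe_a_samples, probe_b_samples], log_transform=True)
    records = pd.DataFrame(
        {
            "lg2_r": lg2_r,
            "p": anova["p"],
            "neg_log10_p": -np.log10(anova["p"]),
            "significant": anova["p"] < p_max,
        }
    )
    records.index.name = "accession"
    return records, excluded


def selectivity_partition(
    records: pd.DataFrame,
) -> tuple[set[str], set[str], set[str]]:
    """Split selectivity records into (probe-A-enriched, probe-B-enriched,
    nonsignificant) accession sets by the sign of lg2_r among significant
    records."""
    sig = records["significant"].fillna(False).astype(bool)
    a_enriched = set(records.index[sig & (records["lg2_r"] > 0)])
    b_enriched = set(records.index[sig & (records["lg2_r"] < 0)])
    nonsig = set(records.index) - a_enriched - b_enriched
    return a_enriched, b_enriched, nonsig


def plot_volcano(records: pd.DataFrame, path, label_a: str = "A", label_b: str = "B") -> None:
    """Convenience scatter of the selectivity volcano (lg2_r vs -log10 p)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = records["significant"].fillna(False).astype(bool)
    ax.scatter(records.loc[~sig, "lg2_r"], records.loc[~sig, "neg_log10_p"],
               c="grey", s=12, label="n.s.")
    ax.scatter(records.loc[sig, "lg2_r"], records.loc[sig, "neg_log10_p"],
               c="firebrick", s=14, label="p < 0.05")
    ax.axvline(0.0, lw=0.5, c="k")
    ax.set_xlabel(f"lg2(r)  [{label_a} vs {label_b}]")
    ax.set_ylabel("-log10(p)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
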