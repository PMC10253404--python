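"""Replicate-reproducibility filter and tiered capture-significance calls.

A protein's capture by a probe is classified against its probe-less negative
control into one of five exclusive tiers:

* ``not_detected`` — not reproducibly observed in the capture samples;
* ``detected`` — observed, but with no statistical support (or with r/p
  undefined);
* ``significant`` — ANOVA p < 0.05;
* ``highly_significant_enriched`` — strong enrichment, log2(r) > 2 AND
  -log10(p) > 2.5 (both strict);
* ``highly_significant_absent_control`` — detected in the capture but in
  none of the control replicates, the strongest qualitative signature an
  affinity-capture experiment can produce (no ratio is computable because
  there is nothing to divide by).

"Highly significant capture" is the union of the last two tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import ConfigurationError


class CaptureClass(str, Enum):
    NOT_DETECTED = "not_detected"
    DETECTED = "detected"
    SIGNIFICANT = "significant"
    HS_ENRICHED = "highly_significant_enriched"
    HS_ABSENT_CONTROL = "highly_significant_absent_control"


#: ordering used for rank comparisons (higher = stronger evidence)
CLASS_SEVERITY: dict[str, int] = {
    CaptureClass.NOT_DETECTED.value: 0,
    CaptureClass.DETECTED.value: 1,
    CaptureClass.SIGNIFICANT.value: 2,
    CaptureClass.HS_ENRICHED.value: 3,
    CaptureClass.HS_ABSENT_CONTROL.value: 4,
}

HIGHLY_SIGNIFICANT = frozenset(
    {CaptureClass.HS_ENRICHED.value, CaptureClass.HS_ABSENT_CONTROL.value}
)


@dataclass(frozen=True)
class SignificanceThresholds:
    """Cut-offs of the classification rule. Defaults: p < 0.05 for the
    significant tier; log2(r) > 2 with -log10(p) > 2.5 for strong enrichment;
    detection in at least 2 of 3 capture replicates to count as reproducible;
    zero detected control replicates to count as absent from the control."""

    p_max: float = 0.05
    log2_r_min: float = 2.0
    neg_log10_p_min: float = 2.5
    min_replicates_detected: int = 2
    max_control_detected: int = 0

    def __post_init__(self) -> None:
        if self.p_max <= 0 or self.log2_r_min <= 0 or self.neg_log10_p_min <= 0:
            raise ConfigurationError("all significance thresholds must be positive")
        if self.min_replicates_detected < 1:
            raise ConfigurationError("min_replicates_detected must be >= 1")


def reproducibility_filter(
    stats: pd.DataFrame, min_replicates_detected: int, n_replicates: int | None = None
) -> pd.Index:
    """Accessions detected in at least ``min_replicates_detected`` capture
    replicates; everything else is reclassified ``not_detected`` downstream."""
    if n_replicates is not None and min_replicates_detected > n_replicates:
        raise ConfigurationError(
            "min_replicates_detected exceeds the number of capture replicates"
        )
    keep = stats["n_detected_capture"] >= min_replicates_detected
    return stats.index[keep]


def classify_capture(
    r: float,
    p: float,
    n_detected_capture: int,
    n_detected_control: int,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> CaptureClass:
    """Classify one protein's capture evidence. Total over every (r, p,
    detection) combination; undefined r or p (NaN) falls through to the
    weaker tiers rather than erroring."""
    if n_detected_capture < thresholds.min_replicates_detected:
        return CaptureClass.NOT_DETECTED
    if n_detected_control <= thresholds.max_control_detected:
        return CaptureClass.HS_ABSENT_CONTROL
    r_def = r is not None and not math.isnan(r) and r > 0
    p_def = p is not None and not math.isnan(p)
    if r_def and p_def:
        if math.log2(r) > thresholds.log2_r_min and -math.log10(p) > thresholds.neg_log10_p_min:
            return CaptureClass.HS_ENRICHED
    if p_def and p < thresholds.p_max:
        return CaptureClass.SIGNIFICANT
    return CaptureClass.DETECTED


def classify_table(
    stats: pd.DataFrame, thresholds: SignificanceThresholds = SignificanceThresholds()
) -> pd.DataFrame:
    """Apply :func:`classify_capture` to a contrast-statistics table,
    returning it with a ``capture_class`` column appended."""
    out = stats.copy()
    out["capture_class"] = [
        classify_capture(row.r, row.p, row.n_detected_capture, row.n_detected_control,
                         thresholds).value
        for row in stats.itertuples(index=False)
    ]
    return out


def highly_significant_set(classified: pd.DataFrame) -> set[str]:
    """Accessions in either highly-significant branch."""
    mask = classified["capture_class"].isin(HIGHLY_SIGNIFICANT)
    return set(classified.index[mask])


def summarize_assay(classified_by_assay: dict[tuple, pd.DataFrame]) -> pd.DataFrame:
    """Per-assay counts of each capture class.

    Keys are assay identifiers (e.g. (species, probe, method) tuples); the
    summary adds a ``highly_significant`` column equal to the sum of the two
    highly-significant branches. Class counts partition the evaluated
    proteins: they sum to the number of classified rows of each assay.
    """
    class_order = [c.value for c in CaptureClass]
    rows = []
    for key, table in classified_by_assay.items():
        counts = table["capture_class"].value_counts()
        row = {"assay": "/".join(str(k) for k in key) if isinstance(key, tuple) else str(key)}
        for cls in class_order:
            row[cls] = int(counts.get(cls, 0))
        row["highly_significant"] = sum(row[c] for c in HIGHLY_SIGNIFICANT)
        row["total"] = int(len(table))
        rows.append(row)
    cols = ["assay", *class_order, "highly_significant", "total"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
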