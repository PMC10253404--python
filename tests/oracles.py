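"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity from first principles, deliberately
avoiding the code paths of the package under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb, log10, log2

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Quadratic Gotoh dynamic program for the optimal local alignment score
    with affine gaps costing gap_open + L * gap_extend for a length-L gap."""
    n, m = len(a), len(b)
    neg = float("-inf")
    first = gap_open + gap_extend  # cost of opening a length-1 gap
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def anova_f_and_p(groups: list[list[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from the raw sum-of-squares decomposition."""
    from scipy.stats import f as f_dist

    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b, df_w = k - 1, n - k
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    return f_stat, float(f_dist.sf(f_stat, df_b, df_w))


def hypergeom_upper_tail(k: int, n_bg: int, big_k: int, n_target: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N=n_bg, K=big_k, n=n_target), by exact
    summation of the pmf in rational arithmetic."""
    total = Fraction(0)
    denom = comb(n_bg, n_target)
    for j in range(k, min(big_k, n_target) + 1):
        total += Fraction(comb(big_k, j) * comb(n_bg - big_k, n_target - j), denom)
    return float(total)


def capture_class_rule(
    r: float | None,
    p: float | None,
    control_detected: bool,
    capture_reproducible: bool = True,
) -> str:
    """Literal transcription of the tiered capture-significance rule."""
    if not capture_reproducible:
        return "not_detected"
    if not control_detected:
        return "highly_significant_absent_control"
    if r is not None and r > 0 and p is not None:
        if log2(r) > 2 and -log10(p) > 2.5:
            return "highly_significant_enriched"
    if p is not None and p < 0.05:
        return "significant"
    return "detected"


def venn_regions(sets: dict[str, set]) -> dict[tuple[bool, ...], int]:
    """Region counts by per-element membership enumeration."""
    labels = list(sets)
    universe = set().union(*sets.values())
    counts: dict[tuple[bool, ...], int] = {
        sig: 0 for sig in product([True, False], repeat=len(labels)) if any(sig)
    }
    for el in universe:
        sig = tuple(el in sets[lab] for lab in labels)
        counts[sig] += 1
    return counts
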