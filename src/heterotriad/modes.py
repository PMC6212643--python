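"""Inheritance-mode classification of triad genes.

For each gene in a hybrid + two-parent triad, hybrid expression is compared
with the mid-parent value and with each parent using a two-tailed
pooled-variance (homoscedastic) t-test on summary statistics (mean, SD, n).
Five classes follow:

* additive             — hybrid equal to the mid-parent (p_mid > alpha)
* high_parent_dominance — equal to the higher parent, different from mid-parent
* low_parent_dominance  — equal to the lower parent, different from mid-parent
* overdominance        — significantly above the higher parent
* underdominance       — significantly below the lower parent

plus ``ambiguous`` for patterns the tree cannot place (e.g. different from
both parents but between them).  The mid-parent comparison group is a
pseudo-group with mean (P1+P2)/2, n = min(n1, n2), and
SD = sqrt((sd1^2 + sd2^2)/4) — the spread of the average of the two parent
means mapped back to a per-observation scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .model import ExpressionMatrix, FamilyDesign, SummaryStat

__all__ = [
    "MODES",
    "TriadGeneStats",
    "ModeCall",
    "ModeDistribution",
    "t_test_summary",
    "mid_parent_stat",
    "classify_triad",
    "classify_matrix",
    "summarize_modes",
]

MODES = (
    "additive",
    "high_parent_dominance",
    "low_parent_dominance",
    "overdominance",
    "underdominance",
    "ambiguous",
)


@dataclass(frozen=True)
class TriadGeneStats:
    """Summary stats for one gene across hybrid, high parent, low parent."""

    gene_id: str
    hybrid: SummaryStat
    parent_high: SummaryStat
    parent_low: SummaryStat

    def __post_init__(self) -> None:
        if self.parent_high.mean < self.parent_low.mean:
            raise ValueError("parent_high.mean must be >= parent_low.mean")

    @property
    def mid_parent_value(self) -> float:
        return (self.parent_high.mean + self.parent_low.mean) / 2.0

    @classmethod
    def from_parents(
        cls, gene_id: str, hybrid: SummaryStat, p1: SummaryStat, p2: SummaryStat
    ) -> "TriadGeneStats":
        """Order the two parents by mean; invariant to their input order."""
        hi, lo = (p1, p2) if p1.mean >= p2.mean else (p2, p1)
        return cls(gene_id=gene_id, hybrid=hybrid, parent_high=hi, parent_low=lo)


@dataclass(frozen=True)
class ModeCall:
    gene_id: str
    mode: str
    p_mid: float
    p_vs_high: float | None = None
    p_vs_low: float | None = None


@dataclass
class ModeDistribution:
    """Mode counts and percentages for one triad (denominator = all triad DEGs)."""

    triad: str
    counts: dict[str, int]
    n_total: int

    @property
    def percents(self) -> dict[str, float]:
        return {m: 100.0 * c / self.n_total for m, c in self.counts.items()}

    @property
    def nonadditive_count(self) -> int:
        return self.n_total - self.counts.get("additive", 0)

    @property
    def nonadditive_percent(self) -> float:
        return 100.0 * self.nonadditive_count / self.n_total


def t_test_summary(a: SummaryStat, b: SummaryStat) -> float:
    """Two-tailed pooled-variance t-test from summary statistics.

    Degenerate conventions: both SDs zero with equal means -> p = 1;
    both SDs zero with unequal means -> p = 0.
    """
    if a.sd == 0 and b.sd == 0:
        return 1.0 if a.mean == b.mean else 0.0
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    p = float(res.pvalue)
    if math.isnan(p):
        return 1.0 if a.mean == b.mean else 0.0
    return p


def mid_parent_stat(p1: SummaryStat, p2: SummaryStat) -> SummaryStat:
    """Pseudo-group representing the mid-parent value.

    Mean is the average of the parent means; the variance of that average is
    (var1/ (4) + var2/(4)) on the mean scale, carried back to a per-observation
    SD of sqrt((sd1^2 + sd2^2)/4); n is the smaller parental n.
    """
    return SummaryStat(
        mean=(p1.mean + p2.mean) / 2.0,
        sd=math.sqrt((p1.sd**2 + p2.sd**2) / 4.0),
        n=min(p1.n, p2.n),
    )


def classify_triad(stats: TriadGeneStats, alpha: float = 0.05) -> ModeCall:
    """Assign one inheritance mode to a triad gene.

    Decision tree: first test the hybrid against the mid-parent pseudo-group;
    p > alpha means additive.  Otherwise test against each parent: above the
    high parent and significant -> overdominance; below the low parent and
    significant -> underdominance; indistinguishable from exactly one parent
    -> dominance toward that parent; anything else -> ambiguous.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    mp = mid_parent_stat(stats.parent_high, stats.parent_low)
    p_mid = t_test_summary(stats.hybrid, mp)
    if p_mid > alpha:
        return ModeCall(stats.gene_id, "additive", p_mid)
    p_hi = t_test_summary(stats.hybrid, stats.parent_high)
    p_lo = t_test_summary(stats.hybrid, stats.parent_low)
    h = stats.hybrid.mean
    if h > stats.parent_high.mean and p_hi <= alpha:
        mode = "overdominance"
    elif h < stats.parent_low.mean and p_lo <= alpha:
        mode = "underdominance"
    elif p_hi > alpha and p_lo <= alpha:
        mode = "high_parent_dominance"
    elif p_lo > alpha and p_hi <= alpha:
        mode = "low_parent_dominance"
    else:
        mode = "ambiguous"
    return ModeCall(stats.gene_id, mode, p_mid, p_hi, p_lo)


def triad_gene_stats(
    matrix: ExpressionMatrix, gene: str, hybrid: str, design: FamilyDesign
) -> TriadGeneStats:
    """Collapse a gene's replicate values into triad summary statistics."""
    p1, p2 = design.parents_of(hybrid)
    row = matrix.values.loc[gene]
    hyb = SummaryStat.from_values(row[matrix.samples_of(hybrid)])
    s1 = SummaryStat.from_values(row[matrix.samples_of(p1)])
    s2 = SummaryStat.from_values(row[matrix.samples_of(p2)])
    return TriadGeneStats.from_parents(gene, hyb, s1, s2)


def classify_matrix(
    matrix: ExpressionMatrix,
    hybrid: str,
    design: FamilyDesign,
    genes: set[str] | list[str] | None = None,
    alpha: float = 0.05,
) -> list[ModeCall]:
    """Classify every gene (or a subset, e.g. the triad DEG set) in a triad."""
    gene_list = list(genes) if genes is not None else matrix.genes
    return [
        classify_triad(triad_gene_stats(matrix, g, hybrid, design), alpha=alpha)
        for g in gene_list
    ]


def summarize_modes(calls: list[ModeCall], triad: str) -> ModeDistribution:
    """Count calls per mode; percentages use the triad DEG total as denominator.

    The nonadditive fraction is everything except additive (ambiguous calls
    count as nonadditive but stay visible as their own category).
    """
    if not calls:
        raise ValueError("no mode calls to summarize")
    counts = {m: 0 for m in MODES}
    for call in calls:
        if call.mode not in counts:
            raise ValueError(f"unknown mode {call.mode!r}")
        counts[call.mode] += 1
    return ModeDistribution(triad=triad, counts=counts, n_total=len(calls))


def distribution_from_counts(counts: dict[str, int], triad: str) -> ModeDistribution:
    """Build a ModeDistribution directly from per-class counts."""
    full = {m: int(counts.get(m, 0)) for m in MODES}
    n_total = sum(full.values())
    if n_total == 0:
        raise ValueError("counts sum to zero")
    return ModeDistribution(triad=triad, counts=full, n_total=n_total)


def mode_table(calls: list[ModeCall]) -> pd.DataFrame:
    """Flat per-gene table of mode calls."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "mode": [c.mode for c in calls],
            "p_mid": [c.p_mid for c in calls],
            "p_vs_high": [c.p_vs_high for c in calls],
            "p_vs_low": [c.p_vs_low for c in calls],
        }
    )
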