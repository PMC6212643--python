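"""Growth-trait statistics: mid-parent heterosis, ANOVA/Tukey, letter display.

Mid-parent heterosis (MPH) quantifies hybrid vigor on the phenotype scale:

    MPH% = (F1 - MP) * 100 / MP

where F1 is the mean of the two reciprocal hybrid family means and
MP = (P1 + P2) / 2 is the mid-parent value, the mean of the two inbred
family means.  Family comparisons use one-way ANOVA followed by all-pairs
Tukey HSD, summarized as a compact letter display (families sharing a
letter do not differ at the chosen alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import FamilyDesign, FormatError, PhenotypeTable, SummaryStat

__all__ = [
    "MphReport",
    "mph_from_means",
    "compute_mph",
    "compare_families",
    "compact_letter_display",
]


@dataclass
class MphReport:
    """Per-trait heterosis summary for one 2x2 diallel."""

    trait: str
    f1_mean: float
    mid_parent: float
    mph_percent: float
    family_stats: dict[str, SummaryStat] = field(default_factory=dict)
    tukey_letters: dict[str, str] = field(default_factory=dict)
    anova_f: float | None = None
    anova_p: float | None = None


def mph_from_means(
    inbred1_mean: float, inbred2_mean: float, hybrid1_mean: float, hybrid2_mean: float
) -> tuple[float, float, float]:
    """MPH% from the four family means.

    Returns (F1, MP, MPH%).  Symmetric in the two inbreds and in the two
    hybrids; invariant to rescaling all means by a common positive factor.
    """
    f1 = (hybrid1_mean + hybrid2_mean) / 2.0
    mp = (inbred1_mean + inbred2_mean) / 2.0
    if mp == 0:
        raise ZeroDivisionError("mid-parent value is zero; heterosis undefined")
    return f1, mp, (f1 - mp) * 100.0 / mp


def compute_mph(pheno: PhenotypeTable, design: FamilyDesign, trait: str) -> MphReport:
    """Mid-parent heterosis of *trait* from individual-level data.

    Family means are plain means over individuals; F1 and MP are unweighted
    means of family means.
    """
    if trait not in pheno.traits:
        raise FormatError(f"trait {trait!r} not in phenotype table (has {pheno.traits})")
    means: dict[str, float] = {}
    stats_by_family: dict[str, SummaryStat] = {}
    for fam in design.families:
        vals = pheno.family_values(fam, trait)
        if vals.size == 0:
            raise FormatError(f"family {fam!r} has no individuals for trait {trait!r}")
        means[fam] = float(vals.mean())
        if vals.size >= 2:
            stats_by_family[fam] = SummaryStat.from_values(vals)
    f1, mp, mph = mph_from_means(
        means[design.inbred_1], means[design.inbred_2],
        means[design.hybrid_1], means[design.hybrid_2],
    )
    return MphReport(
        trait=trait, f1_mean=f1, mid_parent=mp, mph_percent=mph,
        family_stats=stats_by_family,
    )


def compare_families(
    pheno: PhenotypeTable, trait: str, alpha: float = 0.05
) -> tuple[float, float, pd.DataFrame, dict[str, str]]:
    """One-way ANOVA + all-pairs Tukey HSD across families for one trait.

    Returns ``(F, p, tukey_p_matrix, letters)`` where ``tukey_p_matrix`` is a
    symmetric DataFrame of adjusted p-values and ``letters`` is the compact
    letter display (same letter => not significantly different at *alpha*).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    fams = sorted(pheno.data["family"].unique())
    groups = [pheno.family_values(f, trait) for f in fams]
    for f, g in zip(fams, groups):
        if g.size < 2:
            raise FormatError(f"family {f!r} needs >= 2 individuals for ANOVA")
    if all(np.allclose(g, g[0]) for g in groups):
        raise FormatError("zero within-family variance everywhere; ANOVA degenerate")
    fstat, pval = stats.f_oneway(*groups)

    values = np.concatenate(groups)
    labels = np.concatenate([[f] * g.size for f, g in zip(fams, groups)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pmat = pd.DataFrame(np.ones((len(fams), len(fams))), index=fams, columns=fams)
    res = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    for _, row in res.iterrows():
        g1, g2, p = str(row["group1"]), str(row["group2"]), float(row["p-adj"])
        pmat.loc[g1, g2] = p
        pmat.loc[g2, g1] = p
    letters = compact_letter_display(pmat, alpha=alpha)
    return float(fstat), float(pval), pmat, letters


def compact_letter_display(p_matrix: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a pairwise p-value matrix.

    Groups sharing a letter are not significantly different (p > alpha).
    Deterministic: pairs are processed, and letters assigned, in alphabetical
    order of the group labels.
    """
    groups = sorted(str(g) for g in p_matrix.index)
    # start with one column containing every group
    columns: list[set[str]] = [set(groups)]
    sig_pairs = [
        (g1, g2)
        for g1, g2 in combinations(groups, 2)
        if float(p_matrix.loc[g1, g2]) <= alpha
    ]
    for g1, g2 in sig_pairs:
        new_cols: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb: drop columns that are subsets of another
        columns = []
        for col in new_cols:
            if not col:
                continue
            if any(col < other for other in new_cols if other is not col):
                continue
            if col in columns:
                continue
            columns.append(col)
    # deterministic letter order: sort columns by their alphabetically
    # earliest member, then by size (larger first)
    columns.sort(key=lambda c: (min(c), -len(c), tuple(sorted(c))))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for i, col in enumerate(columns):
        for g in sorted(col):
            letters[g].append(alphabet[i % len(alphabet)])
    return {g: "".join(ls) for g, ls in letters.items()}


def mph_table(
    pheno: PhenotypeTable,
    design: FamilyDesign,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    with_tukey: bool = True,
) -> pd.DataFrame:
    """All-trait MPH report as a flat table (one row per trait)."""
    traits = traits or pheno.traits
    rows = []
    for trait in traits:
        rep = compute_mph(pheno, design, trait)
        row: dict[str, object] = {
            "trait": trait,
            "f1_mean": rep.f1_mean,
            "mid_parent": rep.mid_parent,
            "mph_percent": rep.mph_percent,
        }
        for fam, st in rep.family_stats.items():
            row[f"mean_{fam}"] = st.mean
            row[f"sd_{fam}"] = st.sd
            row[f"n_{fam}"] = st.n
        if with_tukey:
            fstat, pval, _, letters = compare_families(pheno, trait, alpha=alpha)
            row["anova_F"] = fstat
            row["anova_p"] = pval
            for fam, let in letters.items():
                row[f"letters_{fam}"] = let
        rows.append(row)
    return pd.DataFrame(rows)
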