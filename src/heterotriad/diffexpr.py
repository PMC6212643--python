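"""Pairwise differential expression and hybrid-vs-both-parents triad sets.

A gene is differentially expressed (DEG) between two families when
|log2 ratio of family means| exceeds the fold-change threshold AND the
BH-adjusted p-value (FDR) falls at or below the FDR threshold; the study
convention is |log2 ratio| > 1 and FDR <= 0.001.  P-values come from a
two-sample t-test on log2(value + c) across replicates, pooled-variance by
default (Welch optional).  A triad DEG is a gene significant versus BOTH
parents of a hybrid with a concordant direction (up in both or down in
both); discordant genes are excluded and reported, not silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, FamilyDesign, FormatError

__all__ = [
    "DEFAULT_LFC",
    "DEFAULT_FDR",
    "TriadDegSet",
    "normalize_fpkm",
    "test_pairwise",
    "apply_thresholds",
    "triad_deg_set",
]

DEFAULT_LFC = 1.0
DEFAULT_FDR = 0.001

# pseudo-value added before taking logs, per unit
PSEUDO = {"FPKM": 0.25, "count": 0.5}


def normalize_fpkm(
    matrix: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert raw counts to FPKM.

    FPKM[g, s] = count[g, s] * 1e9 / (length[g] * total_counts[s]).
    """
    if matrix.unit != "count":
        raise FormatError(f"normalize_fpkm expects unit='count', got {matrix.unit!r}")
    missing = [g for g in matrix.genes if g not in gene_lengths]
    if missing:
        raise FormatError(f"missing gene length(s): {missing[:10]}")
    lengths = np.array([float(gene_lengths[g]) for g in matrix.genes])
    if (lengths <= 0).any():
        raise FormatError("gene lengths must be positive")
    totals = matrix.values.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise FormatError("sample(s) with zero total counts")
    fpkm = matrix.values.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=matrix.values.index, columns=matrix.values.columns),
        sample_meta=matrix.sample_meta.copy(),
        unit="FPKM",
    )


def test_pairwise(
    matrix: ExpressionMatrix,
    fam1: str,
    fam2: str,
    method: str = "pooled_log",
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression test between two families.

    Returns a DataFrame (one row per gene) with columns gene_id, log2_ratio,
    p_value, fdr, direction, is_deg.  log2_ratio is log2 of the ratio of
    pseudo-shifted family means (fam1 over fam2); p comes from a two-sided
    t-test on log2(value + c) over replicates, pooled ("pooled_log") or
    Welch ("welch_log"); FDR is Benjamini-Hochberg over all tested genes.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    if method not in ("pooled_log", "welch_log"):
        raise ValueError(f"unknown method {method!r}")
    c = PSEUDO[matrix.unit] if pseudo is None else float(pseudo)
    x1 = matrix.family_values(fam1).to_numpy(dtype=float)
    x2 = matrix.family_values(fam2).to_numpy(dtype=float)
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        raise FormatError("each family needs >= 2 replicates for the t-test")

    log2_ratio = np.log2(x1.mean(axis=1) + c) - np.log2(x2.mean(axis=1) + c)
    l1, l2 = np.log2(x1 + c), np.log2(x2 + c)
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision-loss warning;
        # those genes are handled by the zero-variance convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(l1, l2, axis=1, equal_var=(method == "pooled_log"))
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> p=1, unequal -> p=0
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(l1.mean(axis=1), l2.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    out = pd.DataFrame(
        {
            "gene_id": matrix.genes,
            "group1": fam1,
            "group2": fam2,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "fdr": fdr,
        }
    )
    return apply_thresholds(out)


def apply_thresholds(
    records: pd.DataFrame, lfc_threshold: float = DEFAULT_LFC, fdr_threshold: float = DEFAULT_FDR
) -> pd.DataFrame:
    """Set is_deg and direction: is_deg <=> |log2_ratio| > lfc AND fdr <= threshold."""
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = records.copy()
    out["direction"] = np.where(out["log2_ratio"] > 0, "up", "down")
    out["is_deg"] = (out["log2_ratio"].abs() > lfc_threshold) & (out["fdr"] <= fdr_threshold)
    return out


@dataclass
class TriadDegSet:
    """Genes differentially expressed in a hybrid versus both of its parents."""

    hybrid: str
    parents: tuple[str, str]
    genes: set[str]
    records: pd.DataFrame  # merged per-parent DEG records for triad genes
    discordant: list[str] = field(default_factory=list)  # up vs one parent, down vs other
    n_up: int = 0
    n_down: int = 0


def triad_deg_set(
    matrix: ExpressionMatrix,
    hybrid: str,
    design: FamilyDesign,
    lfc_threshold: float = DEFAULT_LFC,
    fdr_threshold: float = DEFAULT_FDR,
    method: str = "pooled_log",
) -> TriadDegSet:
    """Hybrid-vs-both-parents DEG set with direction concordance.

    A gene enters the triad set iff it is a DEG versus each parent separately
    (at the same thresholds) and moves the same way relative to both.
    """
    if not design.is_hybrid(hybrid):
        raise FormatError(f"{hybrid!r} is not a hybrid in the design")
    p1, p2 = sorted(design.parents_of(hybrid))
    r1 = apply_thresholds(test_pairwise(matrix, hybrid, p1, method=method),
                          lfc_threshold, fdr_threshold)
    r2 = apply_thresholds(test_pairwise(matrix, hybrid, p2, method=method),
                          lfc_threshold, fdr_threshold)
    merged = r1.merge(r2, on="gene_id", suffixes=(f"_{p1}", f"_{p2}"))
    both = merged[f"is_deg_{p1}"] & merged[f"is_deg_{p2}"]
    concordant = merged[f"direction_{p1}"] == merged[f"direction_{p2}"]
    keep = merged[both & concordant]
    discordant = merged.loc[both & ~concordant, "gene_id"].tolist()
    genes = set(keep["gene_id"])
    n_up = int((keep[f"direction_{p1}"] == "up").sum())
    n_down = int((keep[f"direction_{p1}"] == "down").sum())
    return TriadDegSet(
        hybrid=hybrid,
        parents=(p1, p2),
        genes=genes,
        records=keep.reset_index(drop=True),
        discordant=discordant,
        n_up=n_up,
        n_down=n_down,
    )
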