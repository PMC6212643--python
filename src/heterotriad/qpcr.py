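"""Relative quantification of qPCR data by the 2^-ddCt method.

Per replicate, dCt = Ct(target) - Ct(reference); ddCt subtracts the
calibrator family's mean dCt for the same gene; relative expression is
2^-ddCt, so the calibrator family's mean relative expression is 1 by
construction.  Amplification efficiency is fixed at 2 (no efficiency
correction).  Concordance with RNA-seq compares the direction of hybrid
vs parent fold changes across the two platforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CtTable, ExpressionMatrix, FamilyDesign

__all__ = ["ddct", "concordance"]


def ddct(ct: CtTable, calibrator: str) -> pd.DataFrame:
    """Per-(gene, family) 2^-ddCt relative expression with SD over replicates.

    The calibrator family must be present for every gene: its replicate-mean
    dCt anchors the scale gene by gene.
    """
    df = ct.data.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    rows = []
    for gene, sub in df.groupby("gene_id", sort=True):
        cal = sub.loc[sub["family"] == calibrator, "dct"]
        if cal.empty:
            raise ValueError(f"no calibrator ({calibrator!r}) rows for gene {gene!r}")
        cal_mean = float(cal.mean())
        for family, fam_sub in sub.groupby("family", sort=True):
            rel = np.power(2.0, -(fam_sub["dct"].to_numpy(dtype=float) - cal_mean))
            rows.append(
                {
                    "gene_id": gene,
                    "family": family,
                    "rel_expr": float(rel.mean()),
                    "sd": float(rel.std(ddof=1)) if rel.size > 1 else 0.0,
                    "n": int(rel.size),
                }
            )
    return pd.DataFrame(rows)


def concordance(
    qpcr: pd.DataFrame,
    rnaseq: ExpressionMatrix,
    gene_list: set[str] | list[str],
    design: FamilyDesign,
) -> dict:
    """Direction agreement between qPCR and RNA-seq hybrid-vs-parent folds.

    For every gene and every (hybrid, parent) pair of the diallel, compares
    sign(qPCR fold change) with sign(RNA-seq fold change).  Genes missing
    from either platform are skipped and listed in the report.
    """
    qpcr_means = qpcr.set_index(["gene_id", "family"])["rel_expr"]
    pairs = [
        (hyb, par) for hyb in design.hybrids for par in design.parents_of(hyb)
    ]
    rows, skipped = [], []
    for gene in sorted(set(gene_list)):
        in_q = gene in set(qpcr["gene_id"])
        in_r = gene in rnaseq.values.index
        if not (in_q and in_r):
            skipped.append(gene)
            continue
        for hyb, par in sorted(set(pairs)):
            try:
                q_fold = float(qpcr_means.loc[(gene, hyb)]) - float(qpcr_means.loc[(gene, par)])
            except KeyError:
                skipped.append(gene)
                break
            r_fold = float(rnaseq.values.loc[gene, rnaseq.samples_of(hyb)].mean()) - float(
                rnaseq.values.loc[gene, rnaseq.samples_of(par)].mean()
            )
            rows.append(
                {
                    "gene_id": gene,
                    "hybrid": hyb,
                    "parent": par,
                    "qpcr_sign": int(np.sign(q_fold)),
                    "rnaseq_sign": int(np.sign(r_fold)),
                    "concordant": bool(np.sign(q_fold) == np.sign(r_fold)),
                }
            )
    table = pd.DataFrame(rows)
    frac = float(table["concordant"].mean()) if len(table) else float("nan")
    return {"table": table, "fraction_concordant": frac, "skipped": sorted(set(skipped))}
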