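"""Over-representation analysis of a gene set against an annotation map.

A generic hypergeometric test: for each term, the upper-tail probability of
drawing at least k term-annotated genes when n genes are sampled from a
background of N genes of which K carry the term.  P-values are adjusted
with Benjamini-Hochberg across tested terms.  The ontology content (GO,
KEGG, custom) is supplied by the user as a flat gene -> term map; GO's
three namespaces are ordinary term metadata here.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AnnotationMap

__all__ = ["enrich"]

RESULT_COLUMNS = [
    "term_id", "term_name", "k", "K", "n", "N", "fold", "p_value", "fdr",
]


def enrich(
    gene_set: set[str],
    background: set[str],
    annot: AnnotationMap,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *gene_set* within *background*.

    Only genes present in the annotation map count toward N (background)
    and n (gene-set size); unannotated genes cannot contribute to any term.
    Terms with fewer than *min_term_size* annotated background genes are
    skipped.  Results are sorted by p-value.
    """
    gene_set = set(gene_set)
    background = set(background)
    offenders = sorted(gene_set - background)
    if offenders:
        raise ValueError(f"gene set not contained in background: {offenders[:10]}")
    if not annot.gene_to_terms:
        raise ValueError("annotation map is empty")

    annotated_bg = background & annot.genes
    annotated_set = gene_set & annot.genes
    N, n = len(annotated_bg), len(annotated_set)
    rows = []
    if n > 0:
        for term, term_genes in sorted(annot.term_to_genes().items()):
            K = len(term_genes & annotated_bg)
            if K < min_term_size:
                continue
            k = len(term_genes & annotated_set)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            fold = (k / n) / (K / N) if k else 0.0
            rows.append(
                {
                    "term_id": term,
                    "term_name": annot.name_of(term),
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "fold": fold,
                    "p_value": min(p, 1.0),
                }
            )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["fdr"] = fdr
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[RESULT_COLUMNS]
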