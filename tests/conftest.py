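import numpy as np
import pandas as pd
import pytest

from heterotriad import ExpressionMatrix, FamilyDesign, PhenotypeTable


@pytest.fixture
def design():
    return FamilyDesign()  # A, D inbreds; B, C reciprocal hybrids


@pytest.fixture
def small_phenotypes(design):
    """Four families x 5 individuals with distinct, noise-free-ish means."""
    rng = np.random.default_rng(7)
    rows = []
    means = {"A": 60.0, "B": 64.0, "C": 68.0, "D": 57.0}
    for fam, mu in means.items():
        for i in range(5):
            rows.append(
                {
                    "individual_id": f"{fam}_{i}",
                    "family": fam,
                    "shell_length": mu + rng.normal(0, 0.5),
                }
            )
    return PhenotypeTable(data=pd.DataFrame(rows), design=design)


def make_matrix(values: dict[str, list[float]], n_rep: int = 3, unit: str = "FPKM"):
    """Build an ExpressionMatrix from family -> per-gene replicate-constant means.

    ``values[fam]`` is a per-gene list; each family gets ``n_rep`` identical
    replicate columns unless a (gene x rep) array is given.
    """
    fams = list(values)
    samples, cols = [], []
    for fam in fams:
        arr = np.asarray(values[fam], dtype=float)
        if arr.ndim == 1:
            arr = np.repeat(arr[:, None], n_rep, axis=1)
        for r in range(arr.shape[1]):
            samples.append(f"{fam}_r{r + 1}")
            cols.append(arr[:, r])
    n_genes = len(cols[0])
    genes = [f"g{i}" for i in range(n_genes)]
    vals = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene_id"), columns=samples
    )
    meta = pd.DataFrame(
        {
            "family": [s.rsplit("_r", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values=vals, sample_meta=meta, unit=unit)


@pytest.fixture
def matrix_factory():
    return make_matrix
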