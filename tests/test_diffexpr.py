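"""Pairwise DEG calling, FDR control, FPKM normalization, triad sets."""

import numpy as np
import pandas as pd
import pytest

from heterotriad import FamilyDesign, FormatError
from heterotriad.diffexpr import (
    apply_thresholds,
    normalize_fpkm,
    test_pairwise as pairwise_deg,
    triad_deg_set,
)
from heterotriad.simulate import SimConfig, simulate_expression_triads


def brute_force_bh(p):
    """Step-up Benjamini-Hochberg, written from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def test_bh_hand_example():
    """p = (0.001, 0.01, 0.02, 0.9) adjusts to (0.004, 0.02, 0.0267, 0.9)."""
    adj = brute_force_bh([0.001, 0.01, 0.02, 0.9])
    np.testing.assert_allclose(adj, [0.004, 0.02, 0.02666667, 0.9], rtol=1e-6)
    # and the pipeline's BH agrees with the brute force on the same vector
    from statsmodels.stats.multitest import multipletests

    _, fdr, _, _ = multipletests([0.001, 0.01, 0.02, 0.9], method="fdr_bh")
    np.testing.assert_allclose(fdr, adj, rtol=1e-9)


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(11)
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 40))
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr, brute_force_bh(p), rtol=1e-10)


def test_fpkm_closed_form(matrix_factory):
    """Single gene, length 1 kb, 100 counts in a 1e6-fragment library -> FPKM 100."""
    m = matrix_factory({"A": [[100.0, 100.0]]}, unit="count")
    # pad the library to 1e6 total counts with a second gene
    vals = m.values.copy()
    vals.loc["filler"] = 1e6 - 100
    m2 = type(m)(values=vals, sample_meta=m.sample_meta, unit="count")
    out = normalize_fpkm(m2, {"g0": 1000, "filler": 1000})
    assert out.unit == "FPKM"
    np.testing.assert_allclose(out.values.loc["g0"], 100.0)


def test_fpkm_scale_invariance_and_brute_force():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 1000, size=(50, 4)).astype(float)
    samples = [f"s{i}" for i in range(4)]
    genes = [f"g{i}" for i in range(50)]
    from heterotriad.model import ExpressionMatrix

    meta = pd.DataFrame(
        {"family": ["A", "A", "D", "D"], "replicate": [1, 2, 1, 2]},
        index=pd.Index(samples, name="sample_id"),
    )
    lengths = {g: float(rng.integers(200, 5000)) for g in genes}
    m = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        sample_meta=meta, unit="count",
    )
    out = normalize_fpkm(m, lengths)
    # brute-force per cell
    for i, g in enumerate(genes[::7]):
        for j, s in enumerate(samples):
            expected = m.values.loc[g, s] * 1e9 / (lengths[g] * counts[:, j].sum())
            assert out.values.loc[g, s] == pytest.approx(expected)
    # doubling every count in one sample leaves that sample's FPKM unchanged
    doubled = counts.copy()
    doubled[:, 0] *= 2
    m2 = ExpressionMatrix(
        values=pd.DataFrame(doubled, index=genes, columns=samples),
        sample_meta=meta, unit="count",
    )
    out2 = normalize_fpkm(m2, lengths)
    np.testing.assert_allclose(out2.values.iloc[:, 0], out.values.iloc[:, 0])


def test_identical_values_not_deg(matrix_factory):
    m = matrix_factory({"A": [5.0, 8.0], "D": [5.0, 8.0]})
    rec = pairwise_deg(m, "A", "D")
    assert (rec["log2_ratio"] == 0).all()
    assert not rec["is_deg"].any()
    assert (rec["p_value"] == 1.0).all()  # zero variance, equal means


def test_planted_fold_change_detected(design):
    """A 4-fold planted change at low dispersion passes |lfc|>1, FDR<=0.001."""
    cfg = SimConfig(
        seed=9, n_genes=400, nb_dispersion=0.001, effect_log2fc=2.0,
        mode_fractions={"no_change": 0.5, "overdominance": 0.5},
        baseline_mean_range=(100.0, 500.0),
    )
    m, truth = simulate_expression_triads(cfg, design)
    rec = pairwise_deg(m, "B", "A")
    planted = {g for g, md in truth.gene_modes.items() if md == "overdominance"}
    hit = rec[rec["gene_id"].isin(planted)]["is_deg"]
    assert hit.mean() >= 0.95


def test_swap_groups_negates_ratio_preserves_significance(matrix_factory):
    rng = np.random.default_rng(5)
    vals_a = rng.gamma(5, 10, size=(30, 3))
    vals_d = rng.gamma(5, 10, size=(30, 3))
    m = matrix_factory({"A": vals_a, "D": vals_d})
    r1 = pairwise_deg(m, "A", "D")
    r2 = pairwise_deg(m, "D", "A")
    np.testing.assert_allclose(r1["log2_ratio"], -r2["log2_ratio"], rtol=1e-9)
    np.testing.assert_allclose(r1["p_value"], r2["p_value"], rtol=1e-9)
    np.testing.assert_allclose(r1["fdr"], r2["fdr"], rtol=1e-9)
    assert (r1["is_deg"] == r2["is_deg"]).all()


@pytest.mark.parametrize(
    "lfc,fdr,expect_deg,expect_dir",
    [
        (0.5, 1e-6, False, "up"),    # below fold threshold
        (2.0, 0.0005, True, "up"),   # passes both
        (-2.0, 0.002, False, "down"),  # above FDR threshold
    ],
)
def test_apply_thresholds_cases(lfc, fdr, expect_deg, expect_dir):
    rec = pd.DataFrame(
        {"gene_id": ["g"], "log2_ratio": [lfc], "p_value": [fdr], "fdr": [fdr]}
    )
    out = apply_thresholds(rec, 1.0, 0.001)
    assert bool(out["is_deg"][0]) is expect_deg
    assert out["direction"][0] == expect_dir


def test_triad_requires_both_parents_and_concordance(matrix_factory, design):
    # g0: up vs both parents -> in triad set
    # g1: DEG vs A only -> excluded
    # g2: up vs A, down vs D -> discordant, excluded but logged
    m = matrix_factory(
        {
            "A": [[10, 11, 10], [10, 11, 10], [10, 11, 10]],
            "D": [[10, 11, 12], [99, 100, 101], [400, 410, 420]],
            "B": [[100, 110, 105], [100, 110, 105], [100, 110, 105]],
            "C": [[10, 11, 12], [10, 11, 12], [10, 11, 12]],
        }
    )
    triad = triad_deg_set(m, "B", design, fdr_threshold=0.01)
    assert "g0" in triad.genes
    assert "g1" not in triad.genes
    assert "g2" not in triad.genes
    assert "g2" in triad.discordant


def test_triad_set_subset_of_pairwise_sets(design):
    cfg = SimConfig(seed=21, n_genes=300, nb_dispersion=0.05)
    m, _ = simulate_expression_triads(cfg, design)
    triad = triad_deg_set(m, "B", design)
    for parent in triad.parents:
        rec = pairwise_deg(m, "B", parent)
        pairwise = set(rec[rec["is_deg"]]["gene_id"])
        assert triad.genes <= pairwise


def test_triad_recovers_planted_overdominant_genes(design):
    """>= 45 of 50 strongly overdominant genes survive the triad intersection."""
    n_over = 50
    cfg = SimConfig(
        seed=17, n_genes=500, nb_dispersion=0.001, effect_log2fc=2.0,
        mode_fractions={"no_change": 0.9, "overdominance": 0.1},
        baseline_mean_range=(100.0, 500.0),
    )
    m, truth = simulate_expression_triads(cfg, design)
    planted = {g for g, md in truth.gene_modes.items() if md == "overdominance"}
    assert len(planted) == n_over
    triad = triad_deg_set(m, "B", design)
    assert len(planted & triad.genes) >= 45


def test_triad_rejects_inbred_label(matrix_factory, design):
    m = matrix_factory({"A": [1.0], "B": [1.0], "C": [1.0], "D": [1.0]})
    with pytest.raises(FormatError, match="hybrid"):
        triad_deg_set(m, "A", design)
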