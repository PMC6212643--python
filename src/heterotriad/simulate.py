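"""Synthetic diallel data with known ground truth.

Two generators mirror the study design — a 2x2 complete diallel cross with
two inbred families (A, D) and two reciprocal hybrids (B, C):

* ``simulate_phenotypes`` draws individual growth traits as
  Normal(family mean, cv * mean), with hybrid family means set to the
  mid-parent value inflated by a target mid-parent heterosis percentage.
  The two reciprocal hybrids are offset symmetrically (+- 1/4 of the
  heterosis increment) so their average hits the target F1 mean.
* ``simulate_expression_triads`` plants a per-gene inheritance mode
  (additive, dominance toward either parent, over-/underdominance, or
  no change), sets the four family expected means accordingly, and draws
  negative-binomial counts (variance = mu + dispersion * mu^2).  The same
  parental samples serve both hybrids' triads, as in the study.

Default trait means, heterosis targets and coefficients of variation match
the study's reported adult growth table (n = 50 per family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, FamilyDesign, PhenotypeTable

__all__ = ["TraitSpec", "SimConfig", "SyntheticTruth",
           "simulate_phenotypes", "simulate_expression_triads"]

MODE_LABELS = (
    "additive",
    "high_parent_dominance",
    "low_parent_dominance",
    "overdominance",
    "underdominance",
    "no_change",
)


@dataclass(frozen=True)
class TraitSpec:
    """One simulated growth trait: parental means, target MPH%, noise level."""

    inbred1_mean: float
    inbred2_mean: float
    target_mph_percent: float
    cv: float  # coefficient of variation of individual values

    def __post_init__(self) -> None:
        if self.inbred1_mean <= 0 or self.inbred2_mean <= 0:
            raise ValueError("trait means must be positive")
        if self.cv <= 0:
            raise ValueError(f"cv must be positive, got {self.cv}")


# Adult growth traits of the four families (shell dimensions in mm, weights
# in g); CVs approximate the reported SD/mean ratios.
DEFAULT_TRAITS: dict[str, TraitSpec] = {
    "shell_length": TraitSpec(59.84, 56.92, 12.9, 0.05),
    "shell_height": TraitSpec(60.78, 57.82, 14.9, 0.055),
    "shell_width": TraitSpec(19.42, 18.68, 18.2, 0.07),
    "shell_weight": TraitSpec(16.46, 15.57, 17.2, 0.10),
    "total_weight": TraitSpec(23.38, 21.34, 33.2, 0.17),
}

DEFAULT_MODE_FRACTIONS: dict[str, float] = {
    "no_change": 0.90,
    "additive": 0.02,
    "overdominance": 0.03,
    "underdominance": 0.02,
    "low_parent_dominance": 0.02,
    "high_parent_dominance": 0.01,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic diallel.

    ``nb_dispersion`` is the negative-binomial overdispersion alpha in
    var = mu + alpha * mu^2; ``effect_log2fc`` separates the expression
    groups that a planted mode requires to differ.
    """

    seed: int = 0
    n_individuals_per_family: int = 50
    trait_specs: Mapping[str, TraitSpec] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )
    n_genes: int = 1000
    n_replicates: int = 3
    mode_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_FRACTIONS)
    )
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)

    def __post_init__(self) -> None:
        total = sum(self.mode_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_fractions must sum to 1, got {total}")
        unknown = set(self.mode_fractions) - set(MODE_LABELS)
        if unknown:
            raise ValueError(f"unknown mode label(s): {sorted(unknown)}")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.baseline_mean_range
        if not 0 < lo <= hi:
            raise ValueError("baseline_mean_range must be positive and ordered")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for name, spec in self.trait_specs.items():
            if not isinstance(spec, TraitSpec):
                raise TypeError(f"trait {name!r}: expected TraitSpec")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SimConfig":
        d = dict(d)
        if "trait_specs" in d:
            d["trait_specs"] = {
                name: spec if isinstance(spec, TraitSpec) else TraitSpec(**spec)
                for name, spec in dict(d["trait_specs"]).items()
            }
        if "baseline_mean_range" in d:
            d["baseline_mean_range"] = tuple(d["baseline_mean_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene modes and per-trait realized MPH%."""

    gene_modes: dict[str, str] = field(default_factory=dict)
    trait_mph: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.gene_modes), "mode": list(self.gene_modes.values())}
        )


def _family_trait_means(spec: TraitSpec, design: FamilyDesign) -> dict[str, float]:
    mp = (spec.inbred1_mean + spec.inbred2_mean) / 2.0
    increment = mp * spec.target_mph_percent / 100.0
    return {
        design.inbred_1: spec.inbred1_mean,
        design.inbred_2: spec.inbred2_mean,
        # reciprocal hybrids straddle the target F1 mean symmetrically
        design.hybrid_1: mp + 0.75 * increment,
        design.hybrid_2: mp + 1.25 * increment,
    }


def simulate_phenotypes(
    cfg: SimConfig, design: FamilyDesign | None = None
) -> tuple[PhenotypeTable, SyntheticTruth]:
    """Draw individual-level growth traits for the four diallel families.

    Values are Normal(family mean, cv * family mean), truncated at zero by
    resampling.  The truth records the MPH% realized by the drawn values.
    """
    design = design or FamilyDesign()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals_per_family
    rows: dict[str, list] = {"individual_id": [], "family": []}
    for trait in cfg.trait_specs:
        rows[trait] = []
    for fam in design.families:
        rows["individual_id"].extend(f"{fam}_{i + 1:03d}" for i in range(n))
        rows["family"].extend([fam] * n)
    for trait, spec in cfg.trait_specs.items():
        means = _family_trait_means(spec, design)
        for fam in design.families:
            mu = means[fam]
            vals = rng.normal(mu, spec.cv * mu, size=n)
            while (vals <= 0).any():  # truncate at zero by resampling
                bad = vals <= 0
                vals[bad] = rng.normal(mu, spec.cv * mu, size=int(bad.sum()))
            rows[trait].extend(vals.tolist())
    table = PhenotypeTable(data=pd.DataFrame(rows), design=design)

    truth = SyntheticTruth()
    for trait in cfg.trait_specs:
        m = {fam: table.family_mean(fam, trait) for fam in design.families}
        f1 = (m[design.hybrid_1] + m[design.hybrid_2]) / 2.0
        mp = (m[design.inbred_1] + m[design.inbred_2]) / 2.0
        truth.trait_mph[trait] = (f1 - mp) * 100.0 / mp
    return table, truth


def _assign_modes(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic counts per mode (largest-remainder), shuffled once."""
    fracs = {m: cfg.mode_fractions.get(m, 0.0) for m in MODE_LABELS}
    counts = {m: int(np.floor(f * cfg.n_genes)) for m, f in fracs.items()}
    short = cfg.n_genes - sum(counts.values())
    remainders = sorted(
        fracs, key=lambda m: (fracs[m] * cfg.n_genes) % 1.0, reverse=True
    )
    for m in remainders[:short]:
        counts[m] += 1
    labels = [m for m in MODE_LABELS for _ in range(counts[m])]
    rng.shuffle(labels)
    return labels


def _mode_means(
    mode: str, mu: float, fc: float, high_is_parent1: bool
) -> tuple[float, float, float]:
    """(parent1, parent2, hybrid) expected means for one planted mode.

    Separation modes split the parents symmetrically on the log2 scale by
    *fc*; over/underdominance keep the parents equal and move the hybrid by
    *fc* relative to them.
    """
    up, dn = mu * 2.0 ** (fc / 2.0), mu * 2.0 ** (-fc / 2.0)
    p1, p2 = (up, dn) if high_is_parent1 else (dn, up)
    hi, lo = max(p1, p2), min(p1, p2)
    if mode == "no_change":
        return mu, mu, mu
    if mode == "additive":
        return p1, p2, (p1 + p2) / 2.0
    if mode == "high_parent_dominance":
        return p1, p2, hi
    if mode == "low_parent_dominance":
        return p1, p2, lo
    if mode == "overdominance":
        return mu, mu, mu * 2.0**fc
    if mode == "underdominance":
        return mu, mu, mu * 2.0**-fc
    raise ValueError(f"unknown mode {mode!r}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha * mu^2."""
    size = 1.0 / alpha
    p = size / (size + np.asarray(mu, dtype=float))
    return rng.negative_binomial(size, p)


def simulate_expression_triads(
    cfg: SimConfig, design: FamilyDesign | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Plant per-gene inheritance modes and draw NB counts for all families.

    Both hybrids share the planted mode of each gene and the same parental
    samples, so the two triads are directly comparable.
    """
    design = design or FamilyDesign()
    rng = np.random.default_rng(cfg.seed)
    modes = _assign_modes(cfg, rng)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    baselines = rng.uniform(*cfg.baseline_mean_range, size=cfg.n_genes)
    high_parent1 = rng.random(cfg.n_genes) < 0.5

    fam_order = list(design.families)
    samples = [f"{fam}_r{r + 1}" for fam in fam_order for r in range(cfg.n_replicates)]
    meta = pd.DataFrame(
        {
            "family": [s.rsplit("_r", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )

    mu = np.empty((cfg.n_genes, len(samples)))
    col_of = {s: j for j, s in enumerate(samples)}
    for i, (mode, base, hp1) in enumerate(zip(modes, baselines, high_parent1)):
        p1m, p2m, hybm = _mode_means(mode, float(base), cfg.effect_log2fc, bool(hp1))
        fam_mean = {
            design.inbred_1: p1m,
            design.inbred_2: p2m,
            design.hybrid_1: hybm,
            design.hybrid_2: hybm,
        }
        for s in samples:
            mu[i, col_of[s]] = fam_mean[meta.loc[s, "family"]]
    counts = _nb_draw(rng, mu, cfg.nb_dispersion).astype(float)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        sample_meta=meta,
        unit="count",
    )
    truth = SyntheticTruth(gene_modes=dict(zip(genes, modes)))
    return matrix, truth
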