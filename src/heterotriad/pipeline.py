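"""End-to-end orchestration: simulate -> phenotype -> DEG -> modes -> enrich -> qPCR.

All interchange between stages goes through files; a run is a pure function
of its YAML config (plus the seed inside it), so re-running with the same
config reproduces every output table byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import diffexpr, enrichment, io, modes, phenotype, qpcr
from .model import FamilyDesign
from .simulate import SimConfig, simulate_expression_triads, simulate_phenotypes

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("heterotriad")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    outdir: Path
    design: FamilyDesign = field(default_factory=FamilyDesign)
    seed: int = 0
    lfc: float = diffexpr.DEFAULT_LFC
    fdr: float = diffexpr.DEFAULT_FDR
    alpha: float = 0.05
    simulate: SimConfig | None = None
    phenotype_path: Path | None = None
    expression_path: Path | None = None
    sample_meta_path: Path | None = None
    expression_unit: str = "count"
    annotation_path: Path | None = None
    ct_path: Path | None = None
    calibrator: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh)
        thresholds = raw.get("thresholds", {})
        sim = raw.get("simulate")
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", raw.get("seed", 0))
            sim = SimConfig.from_dict(sim)
        design = FamilyDesign.from_dict(raw.get("design", {}))
        paths = {
            k: Path(v)
            for k, v in raw.items()
            if k.endswith("_path") and v is not None
        }
        return cls(
            outdir=Path(raw["outdir"]),
            design=design,
            seed=int(raw.get("seed", 0)),
            lfc=float(thresholds.get("lfc", diffexpr.DEFAULT_LFC)),
            fdr=float(thresholds.get("fdr", diffexpr.DEFAULT_FDR)),
            alpha=float(thresholds.get("alpha", 0.05)),
            simulate=sim,
            expression_unit=str(raw.get("expression_unit", "count")),
            calibrator=raw.get("calibrator"),
            **paths,
        )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in dependency order.

    Returns a run report (also written as ``report.json`` in the output
    directory) containing the MPH table, per-comparison DEG counts, triad
    DEG counts, and mode distributions for both triads.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict[str, Any] = {
        "seed": cfg.seed,
        "thresholds": {"lfc": cfg.lfc, "fdr": cfg.fdr, "alpha": cfg.alpha},
    }
    try:
        pheno_path, expr_path, meta_path = (
            cfg.phenotype_path, cfg.expression_path, cfg.sample_meta_path,
        )
        unit = cfg.expression_unit
        if cfg.simulate is not None:
            pheno_path, expr_path, meta_path, unit = _run_simulate(cfg, outdir)
            report["simulated"] = True

        if pheno_path is not None:
            report["mph"] = _run_phenotype(cfg, pheno_path, outdir)

        if expr_path is not None:
            matrix = _load_expression(expr_path, meta_path, unit)
            report["deg"] = _run_deg(cfg, matrix, outdir)
            report["modes"] = _run_modes(cfg, matrix, outdir)
            if cfg.annotation_path is not None:
                report["enrichment"] = _run_enrichment(cfg, matrix, outdir)
            if cfg.ct_path is not None:
                report["qpcr"] = _run_qpcr(cfg, matrix, outdir)
    finally:
        log.removeHandler(handler)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


@_stage("simulate")
def _run_simulate(cfg: RunConfig, outdir: Path):
    sim = cfg.simulate
    pheno, truth_p = simulate_phenotypes(sim, cfg.design)
    matrix, truth_e = simulate_expression_triads(sim, cfg.design)
    pheno_path = io.write_phenotype_table(pheno, outdir / "phenotypes.csv")
    expr_path, meta_path = io.write_expression_matrix(
        matrix, outdir / "expression.tsv", outdir / "sample_meta.tsv"
    )
    io.write_results(truth_e.to_frame(), outdir / "truth_modes.tsv")
    log.info("simulated %d individuals/family, %d genes",
             sim.n_individuals_per_family, sim.n_genes)
    return pheno_path, expr_path, meta_path, "count"


@_stage("phenotype")
def _run_phenotype(cfg: RunConfig, pheno_path: Path, outdir: Path):
    pheno = io.read_phenotype_table(pheno_path, cfg.design)
    table = phenotype.mph_table(pheno, cfg.design, alpha=cfg.alpha)
    io.write_results(table, outdir / "mph.tsv")
    log.info("phenotype: %d traits", len(table))
    return {
        row["trait"]: round(float(row["mph_percent"]), 1) for _, row in table.iterrows()
    }


@_stage("deg")
def _load_expression(expr_path, meta_path, unit):
    if meta_path is None:
        raise FileNotFoundError("sample_meta_path is required with expression_path")
    return io.read_expression_matrix(expr_path, meta_path, unit=unit)


@_stage("deg")
def _run_deg(cfg: RunConfig, matrix, outdir: Path):
    fams = matrix.families
    out: dict[str, Any] = {"pairwise": {}, "triads": {}}
    for i, f1 in enumerate(fams):
        for f2 in fams[i + 1:]:
            rec = diffexpr.apply_thresholds(
                diffexpr.test_pairwise(matrix, f1, f2), cfg.lfc, cfg.fdr
            )
            io.write_results(rec, outdir / f"deg_{f1}_vs_{f2}.tsv")
            sub = rec[rec["is_deg"]]
            out["pairwise"][f"{f1} vs {f2}"] = {
                "total": int(len(sub)),
                "up": int((sub["direction"] == "up").sum()),
                "down": int((sub["direction"] == "down").sum()),
            }
    for hyb in cfg.design.hybrids:
        triad = diffexpr.triad_deg_set(matrix, hyb, cfg.design, cfg.lfc, cfg.fdr)
        if len(triad.records):
            io.write_results(triad.records, outdir / f"triad_{hyb}.tsv")
        out["triads"][hyb] = {
            "total": len(triad.genes),
            "up": triad.n_up,
            "down": triad.n_down,
            "discordant": len(triad.discordant),
        }
    return out


@_stage("modes")
def _run_modes(cfg: RunConfig, matrix, outdir: Path):
    out: dict[str, Any] = {}
    for hyb in cfg.design.hybrids:
        triad = diffexpr.triad_deg_set(matrix, hyb, cfg.design, cfg.lfc, cfg.fdr)
        genes = sorted(triad.genes)
        if not genes:
            out[hyb] = {"n_total": 0}
            continue
        calls = modes.classify_matrix(matrix, hyb, cfg.design, genes, alpha=cfg.alpha)
        dist = modes.summarize_modes(calls, triad=hyb)
        io.write_results(modes.mode_table(calls), outdir / f"modes_{hyb}.tsv")
        out[hyb] = {
            "n_total": dist.n_total,
            "counts": dist.counts,
            "percents": {m: round(p, 1) for m, p in dist.percents.items()},
            "nonadditive_percent": round(dist.nonadditive_percent, 1),
        }
    return out


@_stage("enrichment")
def _run_enrichment(cfg: RunConfig, matrix, outdir: Path):
    annot = io.read_annotation(cfg.annotation_path)
    background = set(matrix.genes)
    out = {}
    for hyb in cfg.design.hybrids:
        triad = diffexpr.triad_deg_set(matrix, hyb, cfg.design, cfg.lfc, cfg.fdr)
        res = enrichment.enrich(triad.genes, background, annot)
        if len(res):
            io.write_results(res, outdir / f"enrichment_{hyb}.tsv")
        out[hyb] = int((res["fdr"] <= 0.05).sum()) if len(res) else 0
    return out


@_stage("qpcr")
def _run_qpcr(cfg: RunConfig, matrix, outdir: Path):
    ct = io.read_ct_table(cfg.ct_path)
    calibrator = cfg.calibrator or cfg.design.inbred_1
    rel = qpcr.ddct(ct, calibrator)
    io.write_results(rel, outdir / "qpcr_relative.tsv")
    conc = qpcr.concordance(rel, matrix, set(ct.data["gene_id"]), cfg.design)
    if len(conc["table"]):
        io.write_results(conc["table"], outdir / "qpcr_concordance.tsv")
    return {
        "fraction_concordant": conc["fraction_concordant"],
        "skipped": conc["skipped"],
    }
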