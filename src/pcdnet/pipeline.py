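"""File-based end-to-end driver.

Runs simulate -> de -> coexpress -> preserve -> enrich -> integrate ->
predict -> report inside a working directory; every stage reads its inputs
from files written by earlier stages (so any stage can be re-run or resumed)
and the run is recorded in a JSON manifest of input hashes, parameters and
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpnet, diffexpr, enrich, integrate, io, simulate
from .config import PipelineConfig, Thresholds

__all__ = ["RunManifest", "run_pipeline", "run_study_cascade",
           "PipelineError"]

log = logging.getLogger("pcdnet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclasses.dataclass
class RunManifest:
    stages: dict = dataclasses.field(default_factory=dict)
    version: str = "0.1.0"

    def record(self, stage: str, inputs: list[str], params: dict,
               outputs: list[str]) -> None:
        self.stages[stage] = {
            "inputs": {p: _sha256(p) for p in inputs},
            "parameters": params,
            "outputs": outputs,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"version": self.version, "stages": self.stages}, fh,
                      indent=1)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(work: Path, stage: str, *files: str) -> None:
    for f in files:
        if not (work / f).exists():
            raise PipelineError(
                f"stage {stage!r}: missing dependency {f!r}; run the "
                "producing stage first or enable it")


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the configured stages; returns the run manifest.

    Stage failures are re-raised as :class:`PipelineError` naming the stage.
    """
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    manifest = RunManifest()
    for stage in cfg.stages:
        log.info("stage %s starting", stage)
        try:
            _STAGES[stage](cfg, work, thr, manifest)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest.write(work / "manifest.json")
    return manifest


def death_treatment_expression(study: simulate.SyntheticStudy,
                               thr: Thresholds = Thresholds(),
                               center: bool = True) -> pd.DataFrame:
    """Filtered log2(RPKM+1) of death-experiment treatment samples.

    Applies the co-expression input filter and (by default) per-experiment
    centering so the network reflects within-experiment covariation.
    """
    death = study.design[study.design["experiment"].str.startswith("death")]
    samp = death.loc[death["condition"] == "treatment", "sample"].tolist()
    sub = study.counts.counts[samp]
    keep = coexpnet.wgcna_input_filter(sub, thr)
    expr = coexpnet.log_expression(sub.loc[keep],
                                   study.counts.library_sizes[samp],
                                   study.gene_lengths.reindex(keep))
    if center:
        groups = death.set_index("sample").loc[samp, "experiment"].values
        expr = coexpnet.center_within_groups(expr, groups)
    # centering can zero out degenerate genes; they carry no signal
    expr = expr[expr.std(axis=1) > 0]
    return expr


def run_study_cascade(study: simulate.SyntheticStudy,
                      thr: Thresholds = Thresholds(),
                      soft_power: int = 12, min_module_size: int = 30,
                      cut_height: float = 0.98, merge_height: float = 0.25
                      ) -> dict:
    """In-memory end-to-end analysis of a synthetic study.

    Runs per-experiment DE, co-expression module detection on death
    treatment samples, module over-representation against the catalog, and
    the full candidate cascade. Returns a dict with the DE profiles,
    modules, enriched module labels and the candidate table.
    """
    death_profiles, stress_profiles = [], []
    for exp in sorted(study.design["experiment"].unique()):
        _, prof = diffexpr.run_de(study.counts, study.design, exp, thr)
        (death_profiles if exp.startswith("death")
         else stress_profiles).append(prof)
    expr = death_treatment_expression(study, thr)
    adj = coexpnet.adjacency(expr, soft_power)
    modules = coexpnet.detect_modules(1.0 - coexpnet.tom(adj), expr,
                                      min_size=min_module_size,
                                      cut_height=cut_height,
                                      merge_height=merge_height,
                                      kme_rescue=0.5)
    enriched = []
    for mod in modules.modules():
        res = enrich.ora(modules.members(mod), modules.labels.index,
                         study.catalog, fdr_cut=thr.fdr_go)
        hit = res[res["significant"] &
                  res["name"].str.lower().str.contains(
                      "|".join(integrate.DEATH_KEYWORDS))]
        if len(hit):
            enriched.append(mod)
    table = integrate.candidate_cascade(
        death_profiles, stress_profiles, modules, enriched, study.catalog,
        study.census, study.orthologs, study.yeast_profiles)
    return {"death_profiles": death_profiles,
            "stress_profiles": stress_profiles, "modules": modules,
            "enriched_modules": enriched, "candidates": table,
            "expression": expr}


def _stage_simulate(cfg: PipelineConfig, work: Path, thr: Thresholds,
                    manifest: RunManifest) -> None:
    sim_cfg, conserved = simulate.planted_recovery_config(
        seed=cfg.seed, n_genes=cfg.sim_n_genes,
        n_conserved=cfg.sim_n_conserved, module_size=cfg.sim_module_size)
    study = simulate.simulate_study(sim_cfg, conserved=conserved)
    io.write_counts(study.counts, work / "counts.tsv")
    io.write_design(study.design, work / "design.tsv")
    io.write_series(study.gene_lengths, work / "gene_lengths.tsv",
                    value="length")
    io.write_annotation(study.catalog, work / "annotation.tsv")
    io.write_gmt(study.catalog, work / "catalog.gmt")
    io.write_gene_list(study.census, work / "census.txt")
    io.write_orthologs(study.orthologs, work / "orthologs.tsv")
    io.write_network(study.network, work / "network.tsv")
    io.write_disease(study.disease_annotation, work / "disease.tsv")
    io.write_truth(study.truth, work / "truth.json")
    for p in study.yeast_profiles:
        io.write_series(p.direction, work / f"yeast_de_{p.experiment}.tsv",
                        value="direction")
    manifest.record("simulate", [], {"seed": cfg.seed}, ["counts.tsv"])


def _counts_and_design(cfg: PipelineConfig, work: Path):
    counts_path = Path(cfg.counts) if cfg.counts else work / "counts.tsv"
    design_path = Path(cfg.design) if cfg.design else work / "design.tsv"
    if not counts_path.exists() or not design_path.exists():
        raise PipelineError("de: missing dependency counts/design; run "
                            "'simulate' or point the config at input files")
    return io.read_counts(counts_path), io.read_design(design_path), \
        [str(counts_path), str(design_path)]


def _stage_de(cfg: PipelineConfig, work: Path, thr: Thresholds,
              manifest: RunManifest) -> None:
    counts, design, inputs = _counts_and_design(cfg, work)
    (work / "de").mkdir(exist_ok=True)
    outputs = []
    for exp in sorted(design["experiment"].unique()):
        table, _ = diffexpr.run_de(counts, design, exp, thr)
        out = work / "de" / f"{exp}.tsv"
        io.write_de_table(table, out)
        log.info("de %s: %d DEGs (thresholds: |log2FC|>=%g, FDR<%g, CPM>=%g)",
                 exp, int((table["direction"] != "none").sum()),
                 thr.lfc_min, thr.fdr_deg, thr.cpm_min)
        outputs.append(str(out))
    manifest.record("de", inputs, {"lfc_min": thr.lfc_min,
                                   "fdr_deg": thr.fdr_deg,
                                   "cpm_min": thr.cpm_min}, outputs)


def _death_expression(cfg: PipelineConfig, work: Path, thr: Thresholds,
                      arm: str) -> pd.DataFrame:
    counts, design, _ = _counts_and_design(cfg, work)
    death = design[design["experiment"].str.startswith("death")]
    samples = death.loc[death["condition"] == arm, "sample"].tolist()
    sub = counts.counts[samples]
    keep = coexpnet.wgcna_input_filter(sub, thr)
    lengths = None
    lp = (Path(cfg.gene_lengths) if cfg.gene_lengths
          else work / "gene_lengths.tsv")
    if lp.exists():
        lengths = io.read_series(lp, value="length").reindex(keep)
    lib = counts.library_sizes[samples]
    expr = coexpnet.log_expression(sub.loc[keep], lib, lengths)
    groups = death.set_index("sample").loc[samples, "experiment"].values
    expr = coexpnet.center_within_groups(expr, groups)
    return expr[expr.std(axis=1) > 0]


def _stage_coexpress(cfg: PipelineConfig, work: Path, thr: Thresholds,
                     manifest: RunManifest) -> None:
    expr = _death_expression(cfg, work, thr, "treatment")
    adj = coexpnet.adjacency(expr, cfg.soft_power)
    dissim = 1.0 - coexpnet.tom(adj)
    modules = coexpnet.detect_modules(dissim, expr,
                                      min_size=cfg.min_module_size,
                                      cut_height=cfg.cut_height,
                                      merge_height=cfg.merge_height,
                                      kme_rescue=0.5)
    io.write_series(modules.labels, work / "modules.tsv", value="module")
    if modules.eigengenes is not None:
        modules.eigengenes.to_csv(work / "eigengenes.tsv", sep="\t",
                                  index_label="sample")
    expr.to_csv(work / "expr_treatment.tsv", sep="\t", index_label="gene")
    log.info("coexpress: %d modules over %d genes (power %d)",
             len(modules.modules()), len(expr), cfg.soft_power)
    manifest.record("coexpress", [], {"power": cfg.soft_power,
                                      "min_size": cfg.min_module_size},
                    ["modules.tsv"])


def _read_modules(work: Path) -> coexpnet.ModuleAssignment:
    labels = io.read_series(work / "modules.tsv", value="module")
    eig = None
    ep = work / "eigengenes.tsv"
    if ep.exists():
        eig = pd.read_csv(ep, sep="\t", index_col=0)
    return coexpnet.ModuleAssignment(labels=labels.astype(object),
                                     eigengenes=eig)


def _stage_preserve(cfg: PipelineConfig, work: Path, thr: Thresholds,
                    manifest: RunManifest) -> None:
    _need(work, "preserve", "modules.tsv")
    modules = _read_modules(work)
    ref = pd.read_csv(work / "expr_treatment.tsv", sep="\t", index_col=0)
    test = _death_expression(cfg, work, thr, "control")
    common = ref.index.intersection(test.index)
    report = coexpnet.module_preservation(
        ref.loc[common], test.loc[common], modules,
        n_perm=thr.n_perm, seed=cfg.seed, beta=cfg.soft_power)
    report.table.to_csv(work / "preservation.tsv", sep="\t")
    manifest.record("preserve", [str(work / "modules.tsv")],
                    {"n_perm": thr.n_perm}, ["preservation.tsv"])


def _load_de_tables(work: Path) -> dict[str, pd.DataFrame]:
    de_dir = work / "de"
    if not de_dir.exists():
        raise PipelineError("missing dependency: de tables; run 'de' first")
    return {p.stem: io.read_de_table(p) for p in sorted(de_dir.glob("*.tsv"))}


def _stage_enrich(cfg: PipelineConfig, work: Path, thr: Thresholds,
                  manifest: RunManifest) -> None:
    _need(work, "enrich", "modules.tsv", "annotation.tsv")
    modules = _read_modules(work)
    catalog = io.read_annotation(work / "annotation.tsv")
    background = modules.labels.index
    rows = []
    enriched = []
    for mod in modules.modules():
        res = enrich.ora(modules.members(mod), background, catalog,
                         fdr_cut=thr.fdr_go)
        res.insert(0, "module", mod)
        rows.append(res)
        hit = res[res["significant"] &
                  res["name"].str.lower().str.contains("|".join(
                      integrate.DEATH_KEYWORDS))]
        if len(hit):
            enriched.append(mod)
    all_res = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame())
    all_res.to_csv(work / "module_enrichment.tsv", sep="\t", index=False)
    io.write_gene_list(enriched, work / "death_modules.txt")

    tables = _load_de_tables(work)
    death_tables = {k: v for k, v in tables.items() if k.startswith("death")}
    pep = enrich.pep_analysis(death_tables, catalog, n_perm=cfg.es_n_perm,
                              seed=cfg.seed, fdr_cut=thr.fdr_pathway)
    pep.drop(columns=["per_experiment_es"]).to_csv(
        work / "dysregulated_pathways.tsv", sep="\t", index=False)
    manifest.record("enrich", [str(work / "modules.tsv")],
                    {"fdr_go": thr.fdr_go, "fdr_pathway": thr.fdr_pathway},
                    ["module_enrichment.tsv", "dysregulated_pathways.tsv"])


def _stage_integrate(cfg: PipelineConfig, work: Path, thr: Thresholds,
                     manifest: RunManifest) -> None:
    _need(work, "integrate", "modules.tsv", "death_modules.txt",
          "annotation.tsv", "census.txt", "orthologs.tsv")
    tables = _load_de_tables(work)
    death_profiles = [io.de_profile_from_table(v, k)
                      for k, v in tables.items() if k.startswith("death")]
    stress_profiles = [io.de_profile_from_table(v, k)
                       for k, v in tables.items() if k.startswith("stress")]
    modules = _read_modules(work)
    death_mods = io.read_gene_list(work / "death_modules.txt")
    catalog = io.read_annotation(work / "annotation.tsv")
    census = io.read_gene_list(work / "census.txt")
    omap = io.read_orthologs(work / "orthologs.tsv")
    yeast = [diffexpr.DEGProfile(p.stem.replace("yeast_de_", ""),
                                 io.read_series(p, value="direction"))
             for p in sorted(work.glob("yeast_de_*.tsv"))]
    table = integrate.candidate_cascade(
        death_profiles, stress_profiles, modules, death_mods, catalog,
        census, omap, yeast)
    table.to_csv(work / "candidates.tsv", sep="\t", index_label="gene")
    manifest.record("integrate", [str(work / "modules.tsv")],
                    {}, ["candidates.tsv"])


def _stage_predict(cfg: PipelineConfig, work: Path, thr: Thresholds,
                   manifest: RunManifest) -> None:
    _need(work, "predict", "candidates.tsv", "network.tsv", "disease.tsv")
    table = pd.read_csv(work / "candidates.tsv", sep="\t", index_col=0)
    conserved = table.index[table["conserved"]].astype(str)
    network = io.read_network(work / "network.tsv")
    disease = io.read_disease(work / "disease.tsv")
    pred = integrate.predict_disease(conserved, network, disease,
                                     fdr_cut=cfg.fdr_disease,
                                     min_weight=cfg.edge_weight_min)
    pred.to_csv(work / "predictions.tsv", sep="\t", index=False)
    manifest.record("predict", [str(work / "candidates.tsv")],
                    {"fdr": cfg.fdr_disease}, ["predictions.tsv"])


def _stage_report(cfg: PipelineConfig, work: Path, thr: Thresholds,
                  manifest: RunManifest) -> None:
    _need(work, "report", "candidates.tsv")
    table = pd.read_csv(work / "candidates.tsv", sep="\t", index_col=0)
    summary = integrate.occurrence_report(table)
    summary.to_csv(work / "occurrence_summary.tsv", sep="\t",
                   index_label="occurrence")
    hist = (table.groupby("occurrence").size().rename("n_genes"))
    hist.to_csv(work / "occurrence_histogram.tsv", sep="\t")
    manifest.record("report", [str(work / "candidates.tsv")], {},
                    ["occurrence_summary.tsv", "occurrence_histogram.tsv"])


_STAGES = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "coexpress": _stage_coexpress,
    "preserve": _stage_preserve,
    "enrich": _stage_enrich,
    "integrate": _stage_integrate,
    "predict": _stage_predict,
    "report": _stage_report,
}
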