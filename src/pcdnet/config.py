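"""Threshold and pipeline configuration objects.

All cutoffs applied anywhere in the pipeline live in :class:`Thresholds`
so that every analysis stage reads from a single audited source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

__all__ = ["Thresholds", "PipelineConfig"]


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs used across the pipeline.

    Attributes
    ----------
    cpm_min : float
        A gene is "expressed" in an experiment only if its CPM is at least
        this value in every replicate of both arms.
    lfc_min : float
        Absolute log2 fold-change required to call a DEG (inclusive bound).
    fdr_deg : float
        BH FDR required to call a DEG (strict upper bound).
    fdr_pathway, fdr_go, q_pathdb : float
        Significance cutoffs for pathway dysregulation, GO module enrichment
        and pathway-database module enrichment respectively.
    wgcna_min_reads, wgcna_min_rep_frac : float
        Co-expression input filter: at least ``wgcna_min_reads`` raw reads in
        at least ``wgcna_min_rep_frac`` of replicates.
    n_perm : int
        Permutations used by the module-preservation statistic.
    zsummary_strong : float
        Zsummary above which a module counts as strongly preserved.
    """

    cpm_min: float = 1.0
    lfc_min: float = 1.0
    fdr_deg: float = 0.05
    fdr_pathway: float = 0.01
    fdr_go: float = 0.01
    q_pathdb: float = 0.01
    wgcna_min_reads: float = 10.0
    wgcna_min_rep_frac: float = 0.8
    n_perm: int = 200
    zsummary_strong: float = 10.0
    dispersion_shrink_weight: float = 0.7
    lfc_prior_cpm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cpm_min", "lfc_min", "fdr_deg", "fdr_pathway", "fdr_go",
                     "q_pathdb", "wgcna_min_reads", "n_perm", "zsummary_strong"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fdr_deg", "fdr_pathway", "fdr_go", "q_pathdb",
                     "wgcna_min_rep_frac", "dispersion_shrink_weight"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


_KNOWN_PIPELINE_KEYS = {
    "workdir", "seed", "thresholds", "stages",
    "counts", "design", "catalog", "orthologs", "yeast_de", "census",
    "network", "disease", "gene_lengths",
    "soft_power", "min_module_size", "cut_height", "merge_height",
    "edge_weight_min", "fdr_disease", "es_n_perm",
    "sim_n_genes", "sim_module_size", "sim_n_conserved",
}

_ALL_STAGES = ("simulate", "de", "coexpress", "preserve", "enrich",
               "integrate", "predict", "report")


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end driver.

    Unknown keys in a config mapping are rejected rather than ignored so a
    typo cannot silently disable a threshold.
    """

    workdir: str = "pcdnet_run"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: tuple = _ALL_STAGES
    counts: str | None = None
    design: str | None = None
    catalog: str | None = None
    orthologs: str | None = None
    yeast_de: str | None = None
    census: str | None = None
    network: str | None = None
    disease: str | None = None
    gene_lengths: str | None = None
    soft_power: int = 12
    min_module_size: int = 30
    cut_height: float = 0.98
    merge_height: float = 0.25
    edge_weight_min: float = 0.0
    fdr_disease: float = 0.05
    es_n_perm: int = 200
    sim_n_genes: int = 2000
    sim_module_size: int = 100
    sim_n_conserved: int = 32

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "PipelineConfig":
        unknown = set(mapping) - _KNOWN_PIPELINE_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(mapping)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = Thresholds(**data["thresholds"])
        if "stages" in data:
            bad = set(data["stages"]) - set(_ALL_STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_mapping(self) -> dict[str, Any]:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
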