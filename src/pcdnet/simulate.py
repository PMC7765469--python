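"""Synthetic multi-experiment RNA-seq study generator with planted truth.

Emulates the structure of a comparative cell-death transcriptomics study:
negative-binomial count matrices for a panel of cell-death and stress
experiments (treatment vs control arms), latent-factor co-expression modules
present in treatments, annotation catalogs in which planted death modules
are enriched for apoptosis/autophagy terms, a cross-species ortholog map
with sign-concordant yeast DEG calls for a planted conserved gene set, and
a functional network with planted disease neighborhoods. Every generator is
deterministic given the configuration seed, and the planted ground truth is
returned alongside the data so downstream stages can be tested end to end.

Counts are drawn gamma-Poisson: Var = mu + phi * mu^2, with phi = 0 giving
the exact Poisson limit.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpnet import ModuleAssignment, UNASSIGNED
from .diffexpr import CountMatrix, DEGProfile
from .enrich import TermCatalog
from .integrate import OrthologMap

__all__ = [
    "PlantedDEG", "ModuleSpec", "SimConfig", "GroundTruth", "SyntheticStudy",
    "simulate_experiment", "plant_modules", "make_catalog", "make_orthologs",
    "make_network", "simulate_study", "default_study_config",
    "planted_recovery_config", "table2_like_candidates",
]


@dataclasses.dataclass(frozen=True)
class PlantedDEG:
    """A gene with a planted log2 fold-change in a subset of experiments.

    ``concordant`` keeps the sign identical across the subset; otherwise the
    sign alternates between the listed experiments.
    """

    gene: int
    log2fc: float
    experiments: tuple[str, ...]
    concordant: bool = True


@dataclasses.dataclass(frozen=True)
class ModuleSpec:
    """A planted latent-factor co-expression module.

    ``condition`` 'treatment-only' restricts the shared factor to treatment
    samples; 'both' applies it to all samples. ``scope`` 'death' restricts
    the module to cell-death experiments, 'all' extends it to stress ones.
    """

    module_id: str
    members: tuple[int, ...]
    factor_sd: float = 1.0
    loading_range: tuple[float, float] = (0.7, 1.0)
    condition: str = "treatment-only"
    scope: str = "death"


@dataclasses.dataclass
class SimConfig:
    """Full specification of a synthetic study.

    ``baseline_log_mean``/``baseline_log_sd`` parameterize the per-gene
    baseline on the log2 CPM scale; ``dispersion`` is the NB phi
    (Var = mu + phi mu^2, phi = 0 -> Poisson). Library sizes are drawn
    log-normally around ``lib_size_mean``.
    """

    n_genes: int = 2000
    n_experiments_death: int = 9
    n_experiments_stress: int = 27
    replicates_per_arm: int = 4
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    planted_degs: tuple[PlantedDEG, ...] = ()
    module_spec: tuple[ModuleSpec, ...] = ()
    seed: int = 0
    lib_size_mean: float = 1e7
    lib_size_log_sd: float = 0.15
    min_module_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        seen: set[int] = set()
        for m in self.module_spec:
            mem = set(m.members)
            if mem & seen:
                raise ValueError("module gene-member sets must be disjoint")
            if any(g < 0 or g >= self.n_genes for g in mem):
                raise ValueError("module member out of range")
            seen |= mem
        valid = set(self.experiments())
        for d in self.planted_degs:
            if not (0 <= d.gene < self.n_genes):
                raise ValueError(f"planted DEG gene {d.gene} out of range")
            if not set(d.experiments) <= valid:
                raise ValueError(f"unknown experiment in planted DEG {d.gene}")

    def gene_names(self) -> list[str]:
        width = max(5, len(str(self.n_genes - 1)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def death_experiments(self) -> list[str]:
        return [f"death{i + 1:02d}" for i in range(self.n_experiments_death)]

    def stress_experiments(self) -> list[str]:
        return [f"stress{i + 1:02d}" for i in range(self.n_experiments_stress)]

    def experiments(self) -> list[str]:
        return self.death_experiments() + self.stress_experiments()

    def baseline(self) -> np.ndarray:
        """Per-gene baseline log2 CPM, a fixed stream shared by every
        experiment; module member baselines are floored at
        ``min_module_baseline`` when set."""
        rng = np.random.default_rng([self.seed % (2 ** 31), 901])
        base = rng.normal(self.baseline_log_mean, self.baseline_log_sd,
                          self.n_genes)
        if self.min_module_baseline is not None:
            for m in self.module_spec:
                idx = np.asarray(m.members)
                base[idx] = np.maximum(base[idx], self.min_module_baseline)
        return base

    def gene_lengths(self) -> pd.Series:
        rng = np.random.default_rng([self.seed % (2 ** 31), 902])
        lengths = rng.integers(500, 5000, self.n_genes)
        return pd.Series(lengths, index=self.gene_names(), name="length")


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a synthetic study, serializable next to the data."""

    true_deg_table: dict[str, dict[str, float]]
    true_modules: ModuleAssignment
    true_conserved: frozenset
    true_disease_genes: frozenset

    def to_mapping(self) -> dict:
        return {
            "true_deg_table": self.true_deg_table,
            "true_modules": self.true_modules.labels.to_dict(),
            "true_conserved": sorted(self.true_conserved),
            "true_disease_genes": sorted(self.true_disease_genes),
        }

    @classmethod
    def from_mapping(cls, d: Mapping) -> "GroundTruth":
        labels = pd.Series(d["true_modules"], dtype=object)
        return cls(true_deg_table={g: dict(v) for g, v in
                                   d["true_deg_table"].items()},
                   true_modules=ModuleAssignment(labels=labels),
                   true_conserved=frozenset(d["true_conserved"]),
                   true_disease_genes=frozenset(d["true_disease_genes"]))


def _experiment_index(cfg: SimConfig, experiment: str) -> int:
    exps = cfg.experiments()
    if experiment not in exps:
        raise ValueError(f"unknown experiment {experiment!r}")
    return exps.index(experiment)


def planted_lfc(cfg: SimConfig, gene_names: Sequence[str] | None = None
                ) -> dict[str, dict[str, float]]:
    """gene -> experiment -> signed planted log2FC."""
    names = gene_names or cfg.gene_names()
    out: dict[str, dict[str, float]] = {}
    for d in cfg.planted_degs:
        g = names[d.gene]
        per = out.setdefault(g, {})
        for j, exp in enumerate(d.experiments):
            sign = 1.0 if (d.concordant or j % 2 == 0) else -1.0
            per[exp] = sign * d.log2fc
    return out


def plant_modules(cfg: SimConfig, log_mean: pd.DataFrame,
                  treatment_mask: np.ndarray, rng: np.random.Generator,
                  in_death_experiment: bool = True) -> pd.DataFrame:
    """Add per-sample latent-factor contributions to a log2-mean matrix.

    Each module contributes loading_g * factor_s on the log2 scale;
    treatment-only modules contribute nothing to control samples, and
    modules scoped to death experiments nothing to stress experiments.
    Loadings are drawn per gene (fixed stream), factors per sample.
    """
    seen: set[int] = set()
    for m in cfg.module_spec:
        if set(m.members) & seen:
            raise ValueError("overlapping module memberships")
        seen |= set(m.members)
    out = log_mean.copy()
    names = cfg.gene_names()
    for k, m in enumerate(cfg.module_spec):
        if m.scope == "death" and not in_death_experiment:
            continue
        lrng = np.random.default_rng([cfg.seed % (2 ** 31), 903, k])
        lo, hi = m.loading_range
        loadings = lrng.uniform(lo, hi, len(m.members))
        factors = rng.normal(0.0, m.factor_sd, log_mean.shape[1])
        if m.condition == "treatment-only":
            active = treatment_mask > 0
        elif m.condition == "both":
            active = np.ones(log_mean.shape[1], dtype=bool)
        else:
            raise ValueError(f"unknown module condition {m.condition!r}")
        # center within the active arm: modules plant co-expression, not
        # arm-mean shifts (those belong to planted_degs)
        factors = np.where(active, factors - factors[active].mean(), 0.0)
        rows = [names[g] for g in m.members]
        contrib = np.outer(loadings, factors)
        # mean-neutral in linear space: a module modulates expression
        # around, not above, the baseline (2^x is convex, so the raw
        # contribution would inflate the active-arm mean)
        lin_mean = (2.0 ** contrib[:, active]).mean(axis=1, keepdims=True)
        contrib[:, active] -= np.log2(lin_mean)
        out.loc[rows] = out.loc[rows].values + contrib
    return out


def simulate_experiment(cfg: SimConfig, experiment: str
                        ) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts and design table for one experiment (both arms).

    log2 mean CPM = baseline + module latent-factor contribution + planted
    log2FC in the treatment arm; counts are gamma-Poisson draws against
    log-normal library sizes. Deterministic given the config seed.
    """
    idx = _experiment_index(cfg, experiment)
    is_death = experiment in cfg.death_experiments()
    rng = np.random.default_rng([cfg.seed % (2 ** 31), 1000 + idx])
    rng_mod = np.random.default_rng([cfg.seed % (2 ** 31), 5000 + idx])
    names = cfg.gene_names()
    n_rep = cfg.replicates_per_arm
    samples = ([f"{experiment}_t{r + 1}" for r in range(n_rep)]
               + [f"{experiment}_c{r + 1}" for r in range(n_rep)])
    treatment_mask = np.array([1.0] * n_rep + [0.0] * n_rep)

    log_mean = pd.DataFrame(
        np.tile(cfg.baseline()[:, None], (1, len(samples))),
        index=names, columns=samples)
    log_mean = plant_modules(cfg, log_mean, treatment_mask, rng_mod,
                             in_death_experiment=is_death)
    for gene, per_exp in planted_lfc(cfg).items():
        if experiment in per_exp:
            log_mean.loc[gene] += per_exp[experiment] * treatment_mask

    lib = rng.lognormal(np.log(cfg.lib_size_mean), cfg.lib_size_log_sd,
                        len(samples))
    mu = (2.0 ** log_mean.values) * (lib / 1e6)
    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * mu)
        counts = rng.poisson(lam)
    cm = CountMatrix(pd.DataFrame(counts, index=names, columns=samples),
                     pd.Series(lib, index=samples))
    design = pd.DataFrame({
        "sample": samples,
        "experiment": experiment,
        "condition": ["treatment"] * n_rep + ["control"] * n_rep,
        "replicate": list(range(1, n_rep + 1)) * 2,
    })
    return cm, design


def _true_modules(cfg: SimConfig) -> ModuleAssignment:
    names = cfg.gene_names()
    labels = pd.Series(UNASSIGNED, index=names, dtype=object)
    for m in cfg.module_spec:
        labels[[names[g] for g in m.members]] = m.module_id
    return ModuleAssignment(labels=labels)


def make_catalog(cfg: SimConfig, truth: GroundTruth, *,
                 odds_ratio: float = 20.0, term_size: int = 50,
                 terms_per_module: int = 1, n_null_terms: int = 20,
                 census_size: int = 50, exclude_conserved: bool = True,
                 seed_offset: int = 904) -> tuple[TermCatalog, list[str]]:
    """Annotation catalog (GMT-style) plus a decoy cancer-census list.

    Death-keyword terms ("apoptosis"/"autophagy"-named, alternating per
    planted module) over-sample that module's genes at the given enrichment
    odds ratio; with odds ratio 1 membership is independent of modules.
    ``exclude_conserved`` keeps the planted conserved genes out of
    death-keyword terms so they carry no death annotation. The census list
    is always disjoint from the planted conserved set.
    """
    rng = np.random.default_rng([cfg.seed % (2 ** 31), seed_offset])
    names = np.array(cfg.gene_names())
    members: dict[str, frozenset] = {}
    term_names: dict[str, str] = {}
    namespace: dict[str, str] = {}
    keywords = ("apoptosis", "autophagy")
    for k, m in enumerate(cfg.module_spec):
        kw = keywords[k % 2]
        in_mod = np.zeros(cfg.n_genes, dtype=bool)
        in_mod[list(m.members)] = True
        weights = np.where(in_mod, odds_ratio, 1.0)
        if exclude_conserved:
            conserved_idx = [i for i, g in enumerate(names)
                             if g in truth.true_conserved]
            weights[conserved_idx] = 0.0
        weights = weights / weights.sum()
        for j in range(terms_per_module):
            tid = f"death_{kw}_{m.module_id}_{j}"
            chosen = rng.choice(cfg.n_genes, size=min(term_size, cfg.n_genes),
                                replace=False, p=weights)
            members[tid] = frozenset(names[chosen])
            term_names[tid] = f"{kw} related process {m.module_id} {j}"
            namespace[tid] = "GO-like" if j % 2 == 0 else "pathway-like"
    for j in range(n_null_terms):
        tid = f"null_{j:03d}"
        chosen = rng.choice(cfg.n_genes, size=min(term_size, cfg.n_genes),
                            replace=False)
        members[tid] = frozenset(names[chosen])
        term_names[tid] = f"background process {j:03d}"
        namespace[tid] = "GO-like" if j % 2 == 0 else "pathway-like"
    catalog = TermCatalog(members, term_names, namespace)

    eligible = [g for g in names if g not in truth.true_conserved]
    census = sorted(rng.choice(eligible, size=min(census_size, len(eligible)),
                               replace=False).tolist())
    return catalog, census


def make_orthologs(cfg: SimConfig, truth: GroundTruth, *,
                   mapped_fraction: float = 0.3,
                   opposite_fraction: float = 0.0,
                   n_timepoints: int = 3,
                   seed_offset: int = 905
                   ) -> tuple[OrthologMap, list[DEGProfile]]:
    """Ortholog map and yeast DEG profiles with planted conservation.

    Every planted conserved gene maps to a yeast gene that is a DEG of the
    same sign in at least one yeast time point; a ``mapped_fraction`` of the
    remaining genes also map, and of those that carry a planted human
    direction an ``opposite_fraction`` receive an opposite-sign yeast call
    (the rest stay absent). Some duplicate non-best rows exercise the
    best-hit contract.
    """
    rng = np.random.default_rng([cfg.seed % (2 ** 31), seed_offset])
    names = cfg.gene_names()
    lfc = planted_lfc(cfg)
    death = set(cfg.death_experiments())

    def human_direction(g: str) -> str | None:
        per = {e: v for e, v in lfc.get(g, {}).items() if e in death}
        if not per:
            return None
        signs = {np.sign(v) for v in per.values()}
        if len(signs) != 1:
            return None
        return "up" if signs.pop() > 0 else "down"

    mapped = sorted(truth.true_conserved)
    others = [g for g in names if g not in truth.true_conserved]
    extra = rng.choice(others, size=int(mapped_fraction * len(others)),
                       replace=False)
    mapped += sorted(extra.tolist())

    yeast_of = {g: f"y{i:05d}" for i, g in enumerate(mapped)}
    rows = [{"human": g, "yeast": y, "best": True}
            for g, y in yeast_of.items()]
    # non-best duplicates for a few genes (must never be used downstream)
    for g in mapped[: min(5, len(mapped))]:
        rows.append({"human": g, "yeast": f"{yeast_of[g]}_alt", "best": False})
    omap = OrthologMap(pd.DataFrame(rows))

    yeast_genes = sorted({r["yeast"] for r in rows})
    timepoints = [f"yeast_t{k + 1}" for k in range(n_timepoints)]
    calls = {tp: pd.Series("none", index=yeast_genes, dtype=object)
             for tp in timepoints}
    for g in mapped:
        y = yeast_of[g]
        d = human_direction(g)
        if g in truth.true_conserved:
            if d is None:
                d = "up"
            n_called = int(rng.integers(1, n_timepoints + 1))
            for tp in rng.choice(timepoints, size=n_called, replace=False):
                calls[tp][y] = d
        elif d is not None and rng.random() < opposite_fraction:
            flip = "down" if d == "up" else "up"
            tp = timepoints[int(rng.integers(0, n_timepoints))]
            calls[tp][y] = flip
    profiles = [DEGProfile(experiment=tp, direction=calls[tp])
                for tp in timepoints]
    return omap, profiles


def make_network(cfg: SimConfig, truth: GroundTruth, *,
                 mean_degree: float = 8.0, background_rate: float = 0.05,
                 planted_neighbors: int = 10, planted_annotated: int = 8,
                 disease: str = "cancer", seed_offset: int = 906
                 ) -> tuple[nx.Graph, pd.DataFrame]:
    """Random functional network with planted disease neighborhoods.

    A background Erdos-Renyi-style graph over all genes plus, for each
    planted disease gene, extra edges guaranteeing ``planted_annotated`` of
    at least ``planted_neighbors`` direct neighbors carry the disease
    annotation; background genes are annotated at ``background_rate``.
    """
    rng = np.random.default_rng([cfg.seed % (2 ** 31), seed_offset])
    names = cfg.gene_names()
    n = len(names)
    n_edges = int(mean_degree * n / 2)
    g = nx.gnm_random_graph(n, n_edges, seed=int(rng.integers(2 ** 31)))
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    nx.set_edge_attributes(g, 1.0, "weight")

    annotated = set()
    for gene in names:
        if gene in truth.true_disease_genes:
            continue
        if rng.random() < background_rate:
            annotated.add(gene)
    ann_pool = sorted(annotated)
    for gene in sorted(truth.true_disease_genes):
        if ann_pool:
            want = rng.choice(ann_pool, size=min(planted_annotated,
                                                 len(ann_pool)),
                              replace=False)
            for v in want:
                g.add_edge(gene, v, weight=1.0)
        # pad with unannotated neighbors up to the planted degree
        while g.degree(gene) < planted_neighbors:
            v = names[int(rng.integers(0, n))]
            if v != gene and not g.has_edge(gene, v):
                g.add_edge(gene, v, weight=1.0)
    rows = [{"gene": a, "disease": disease} for a in sorted(annotated)]
    return g, pd.DataFrame(rows, columns=["gene", "disease"])


@dataclasses.dataclass
class SyntheticStudy:
    """All pipeline inputs for one synthetic study, plus the ground truth."""

    config: SimConfig
    counts: CountMatrix
    design: pd.DataFrame
    gene_lengths: pd.Series
    truth: GroundTruth
    catalog: TermCatalog
    census: list[str]
    orthologs: OrthologMap
    yeast_profiles: list[DEGProfile]
    network: nx.Graph
    disease_annotation: pd.DataFrame


def simulate_study(cfg: SimConfig, *, disease_genes: Iterable[str] = (),
                   catalog_kwargs: Mapping | None = None,
                   ortholog_kwargs: Mapping | None = None,
                   network_kwargs: Mapping | None = None,
                   conserved: Iterable[str] = ()) -> SyntheticStudy:
    """Generate every pipeline input for the configured study.

    ``conserved`` names the planted conserved gene set (genes expected to
    survive the whole cascade); ``disease_genes`` the planted disease
    neighborhood genes (defaults to the conserved set).
    """
    names = cfg.gene_names()
    truth = GroundTruth(
        true_deg_table=planted_lfc(cfg),
        true_modules=_true_modules(cfg),
        true_conserved=frozenset(conserved),
        true_disease_genes=frozenset(disease_genes or conserved),
    )
    mats, designs = [], []
    for exp in cfg.experiments():
        cm, des = simulate_experiment(cfg, exp)
        mats.append(cm)
        designs.append(des)
    counts = CountMatrix(
        pd.concat([m.counts for m in mats], axis=1),
        pd.concat([m.library_sizes for m in mats]))
    design = pd.concat(designs, ignore_index=True)
    catalog, census = make_catalog(cfg, truth, **(catalog_kwargs or {}))
    omap, yeast = make_orthologs(cfg, truth, **(ortholog_kwargs or {}))
    network, disease = make_network(cfg, truth, **(network_kwargs or {}))
    return SyntheticStudy(config=cfg, counts=counts, design=design,
                          gene_lengths=cfg.gene_lengths(), truth=truth,
                          catalog=catalog, census=census, orthologs=omap,
                          yeast_profiles=yeast, network=network,
                          disease_annotation=disease)


def default_study_config(seed: int = 0, n_genes: int = 2000,
                         replicates: int = 4) -> SimConfig:
    """Desk-scale study mirroring the 9 death + 27 stress experiment design."""
    return SimConfig(n_genes=n_genes, n_experiments_death=9,
                     n_experiments_stress=27, replicates_per_arm=replicates,
                     seed=seed)


def planted_recovery_config(seed: int = 0, n_genes: int = 2000,
                            n_conserved: int = 32, module_size: int = 100,
                            log2fc: float = 2.0, dispersion: float = 0.1,
                            replicates: int = 4
                            ) -> tuple[SimConfig, list[str]]:
    """Study with a fully planted candidate cascade; returns (config, conserved).

    Two treatment-only death modules are planted: an up-regulated
    (apoptosis-enriched) and a down-regulated (autophagy-enriched) one.
    Planted fold-changes share the module's direction so that DEG-pattern
    correlation reinforces the module factor instead of fragmenting the
    module. Half of the conserved genes live in each module and are
    concordant DEGs in three death experiments each; the remaining module
    genes are DEGs in two. Stress experiments are generated under the null
    so that cascade recovery is tested without confounding.
    """
    width = max(5, len(str(n_genes - 1)))
    death = [f"death{i + 1:02d}" for i in range(9)]
    mod1 = tuple(range(module_size))
    mod2 = tuple(range(module_size, 2 * module_size))
    half = n_conserved // 2
    conserved_idx = list(range(half)) + list(range(module_size,
                                                  module_size + (n_conserved - half)))
    planted = []

    def module_sign(g: int) -> float:
        return 1.0 if g < module_size else -1.0

    for j, g in enumerate(conserved_idx):
        exps = tuple(death[(j + k) % 9] for k in range(5))
        planted.append(PlantedDEG(gene=g, log2fc=module_sign(g) * log2fc,
                                  experiments=exps, concordant=True))
    # remaining module genes are DEGs too (the death-annotated pool)
    extra = [g for g in range(2 * module_size) if g not in set(conserved_idx)]
    for j, g in enumerate(extra):
        exps = tuple(death[(5 * j + k) % 9] for k in range(2))
        planted.append(PlantedDEG(gene=g, log2fc=module_sign(g) * log2fc,
                                  experiments=exps, concordant=True))
    cfg = SimConfig(
        n_genes=n_genes, n_experiments_death=9, n_experiments_stress=27,
        replicates_per_arm=replicates, baseline_log_mean=5.0,
        baseline_log_sd=1.5, dispersion=dispersion,
        planted_degs=tuple(planted),
        module_spec=(
            ModuleSpec("death_mod_apop", mod1, factor_sd=0.8,
                       loading_range=(0.85, 1.0), condition="treatment-only",
                       scope="death"),
            ModuleSpec("death_mod_auto", mod2, factor_sd=0.8,
                       loading_range=(0.85, 1.0), condition="treatment-only",
                       scope="death"),
        ),
        seed=seed, lib_size_mean=1e6, lib_size_log_sd=0.1,
        min_module_baseline=6.5)
    conserved = [f"g{i:0{width}d}" for i in conserved_idx]
    return cfg, conserved


def preservation_pair(seed: int = 0, n_genes: int = 2000,
                      module_size: int = 100, n_samples: int = 40,
                      factor_sd: float = 0.8,
                      loading_range: tuple[float, float] = (0.85, 1.0)
                      ) -> tuple[pd.DataFrame, pd.DataFrame, ModuleAssignment]:
    """Two independent expression datasets sharing one planted module.

    Each dataset is an independent draw (different seeds) from the same
    configuration: one experiment whose ``n_samples`` samples all carry a
    latent-factor module over the first ``module_size`` genes (within-module
    correlation ~0.7). Returns log2(RPKM+1) matrices filtered by the
    co-expression input rule, plus the true module assignment.
    """
    def one(sub_seed: int) -> tuple[pd.DataFrame, SimConfig]:
        cfg = SimConfig(
            n_genes=n_genes, n_experiments_death=1, n_experiments_stress=0,
            replicates_per_arm=(n_samples + 1) // 2,
            baseline_log_mean=5.0, baseline_log_sd=1.5, dispersion=0.1,
            module_spec=(ModuleSpec("planted", tuple(range(module_size)),
                                    factor_sd=factor_sd,
                                    loading_range=loading_range,
                                    condition="both", scope="death"),),
            seed=sub_seed, lib_size_mean=1e6, lib_size_log_sd=0.1,
            min_module_baseline=6.5)
        cm, _ = simulate_experiment(cfg, "death01")
        keep = _wgcna_filter(cm.counts)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            from .coexpnet import log_expression
            expr = log_expression(cm.counts.loc[keep], cm.library_sizes,
                                  cfg.gene_lengths().reindex(keep))
        return expr, cfg

    ref, cfg = one(seed * 2 + 1)
    test, _ = one(seed * 2 + 2)
    common = ref.index.intersection(test.index)
    truth = _true_modules(cfg)
    return ref.loc[common], test.loc[common], ModuleAssignment(
        labels=truth.labels.reindex(common).fillna(UNASSIGNED))


def _wgcna_filter(counts: pd.DataFrame) -> pd.Index:
    from .coexpnet import wgcna_input_filter
    return wgcna_input_filter(counts)


def table2_like_candidates(strata: Mapping[str, Mapping[str, int]] | None = None
                           ) -> pd.DataFrame:
    """Synthetic candidate table whose occurrence strata match the printed
    study summary (683/368 DEGs, 683/265 concordant, 561/173 specific,
    155/61 orthologs, 27/5 conserved in the two occurrence strata).

    Used to exercise the stratified report's additivity on realistic
    marginals; the per-gene rows are constructed, not estimated.
    """
    if strata is None:
        strata = {
            "1": {"degs": 683, "concordant": 683, "specific": 561,
                  "has_ortholog": 155, "conserved": 27},
            ">1": {"degs": 368, "concordant": 265, "specific": 173,
                   "has_ortholog": 61, "conserved": 5},
        }
    rows = []
    gid = 0
    for name, c in strata.items():
        occurrence = 1 if name == "1" else 2
        n = c["degs"]
        for j in range(n):
            rows.append({
                "gene": f"fx{gid:05d}",
                "occurrence": occurrence,
                "concordant": j < c["concordant"],
                "specific": j < c["specific"],
                "has_ortholog": j < c["has_ortholog"],
                "conserved": j < c["conserved"],
            })
            gid += 1
    return pd.DataFrame(rows).set_index("gene")
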