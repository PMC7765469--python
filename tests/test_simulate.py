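"""Synthetic study generator: distributions, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcdnet.enrich import ora
from pcdnet.integrate import ortholog_concordance, predict_disease
from pcdnet.simulate import (GroundTruth, ModuleSpec, PlantedDEG, SimConfig,
                             make_catalog, make_network, make_orthologs,
                             planted_lfc, planted_recovery_config,
                             simulate_experiment, simulate_study)


def small_cfg(**kw):
    defaults = dict(n_genes=100, n_experiments_death=2,
                    n_experiments_stress=1, replicates_per_arm=4,
                    dispersion=0.1, seed=1, lib_size_mean=1e6)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_invalid_experiment_rejected(self):
        with pytest.raises(ValueError, match="unknown experiment"):
            simulate_experiment(small_cfg(), "death99")

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            small_cfg(module_spec=(
                ModuleSpec("a", (0, 1, 2)), ModuleSpec("b", (2, 3))))

    def test_planted_gene_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            small_cfg(planted_degs=(
                PlantedDEG(gene=999, log2fc=2, experiments=("death01",)),))

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            small_cfg(dispersion=-0.1)


class TestCountDistribution:
    def test_deterministic_given_seed(self):
        cfg = small_cfg()
        a, da = simulate_experiment(cfg, "death01")
        b, db = simulate_experiment(cfg, "death01")
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.library_sizes, b.library_sizes)
        pd.testing.assert_frame_equal(da, db)

    def test_poisson_limit_variance_equals_mean(self):
        cfg = small_cfg(n_genes=300, dispersion=0.0, replicates_per_arm=50,
                        baseline_log_mean=5.0, baseline_log_sd=0.0,
                        lib_size_log_sd=0.0)
        cm, des = simulate_experiment(cfg, "death01")
        ctrl = des.loc[des["condition"] == "control", "sample"]
        sub = cm.counts[list(ctrl)].values
        ratio = sub.var(axis=1, ddof=1) / sub.mean(axis=1)
        # dispersion index concentrates at 1 for Poisson
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_planted_fold_change_recovered_in_mean(self):
        cfg = small_cfg(
            n_genes=50, replicates_per_arm=50, baseline_log_mean=np.log2(100),
            baseline_log_sd=0.0, lib_size_log_sd=0.0, dispersion=0.1,
            planted_degs=(PlantedDEG(0, 2.0, ("death01",)),))
        cm, des = simulate_experiment(cfg, "death01")
        treat = des.loc[des["condition"] == "treatment", "sample"]
        ctrl = des.loc[des["condition"] == "control", "sample"]
        g = cm.counts.index[0]
        t_mean = cm.counts.loc[g, list(treat)].mean()
        c_mean = cm.counts.loc[g, list(ctrl)].mean()
        # NB sampling error of the arm-mean ratio at 50 replicates
        assert t_mean / c_mean == pytest.approx(4.0, rel=0.2)
        assert c_mean == pytest.approx(100.0, rel=0.2)

    def test_overdispersion_present_when_phi_positive(self):
        cfg = small_cfg(n_genes=300, dispersion=0.3, replicates_per_arm=50,
                        baseline_log_mean=6.0, baseline_log_sd=0.0,
                        lib_size_log_sd=0.0)
        cm, des = simulate_experiment(cfg, "death01")
        ctrl = des.loc[des["condition"] == "control", "sample"]
        sub = cm.counts[list(ctrl)].values
        ratio = sub.var(axis=1, ddof=1) / sub.mean(axis=1)
        assert ratio.mean() > 5  # var = mu + phi mu^2 >> mu at mu=64


class TestModules:
    def test_zero_loading_is_identity(self):
        base = small_cfg(seed=3)
        with_mod = small_cfg(seed=3, module_spec=(
            ModuleSpec("m", tuple(range(10)), factor_sd=1.0,
                       loading_range=(0.0, 0.0)),))
        a, _ = simulate_experiment(base, "death01")
        b, _ = simulate_experiment(with_mod, "death01")
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_shared_factor_drives_high_correlation(self):
        cfg = SimConfig(
            n_genes=10, n_experiments_death=1, n_experiments_stress=0,
            replicates_per_arm=20, baseline_log_mean=8.0, baseline_log_sd=0.0,
            dispersion=0.0, lib_size_mean=1e7,
            module_spec=(ModuleSpec("m", (0, 1), factor_sd=2.0,
                                    loading_range=(1.0, 1.0),
                                    condition="both"),), seed=4)
        cm, _ = simulate_experiment(cfg, "death01")
        expr = np.log2(cm.counts.values[:2] + 1.0)
        assert np.corrcoef(expr)[0, 1] > 0.9

    def test_treatment_only_module_silent_in_controls(self):
        cfg = SimConfig(
            n_genes=30, n_experiments_death=1, n_experiments_stress=0,
            replicates_per_arm=40, baseline_log_mean=7.0, baseline_log_sd=0.0,
            dispersion=0.0, lib_size_mean=1e6, lib_size_log_sd=0.0,
            module_spec=(ModuleSpec("m", tuple(range(20)), factor_sd=1.5,
                                    loading_range=(0.9, 1.0),
                                    condition="treatment-only"),), seed=5)
        cm, des = simulate_experiment(cfg, "death01")
        for arm, bound in (("control", 0.2), ("treatment", 0.5)):
            cols = des.loc[des["condition"] == arm, "sample"]
            expr = np.log2(cm.counts[list(cols)].values[:20] + 1.0)
            c = np.corrcoef(expr)
            mean_off = c[np.triu_indices_from(c, 1)].mean()
            if arm == "control":
                assert abs(mean_off) < bound
            else:
                assert mean_off > bound

    def test_module_factor_does_not_shift_arm_mean(self):
        # planted co-expression must not masquerade as differential expression
        cfg = SimConfig(
            n_genes=20, n_experiments_death=1, n_experiments_stress=0,
            replicates_per_arm=200, baseline_log_mean=8.0,
            baseline_log_sd=0.0, dispersion=0.0, lib_size_mean=1e6,
            lib_size_log_sd=0.0,
            module_spec=(ModuleSpec("m", tuple(range(20)), factor_sd=1.0,
                                    loading_range=(0.9, 1.0),
                                    condition="treatment-only"),), seed=6)
        cm, des = simulate_experiment(cfg, "death01")
        treat = des.loc[des["condition"] == "treatment", "sample"]
        ctrl = des.loc[des["condition"] == "control", "sample"]
        lfc = np.log2(cm.counts[list(treat)].mean(axis=1)
                      / cm.counts[list(ctrl)].mean(axis=1))
        assert abs(lfc.mean()) < 0.1


class TestCatalog:
    @staticmethod
    def _study_bits(odds_ratio, seed=0):
        cfg = small_cfg(n_genes=600, seed=seed, module_spec=(
            ModuleSpec("mod", tuple(range(100))),))
        truth = GroundTruth(true_deg_table={},
                            true_modules=None, true_conserved=frozenset(),
                            true_disease_genes=frozenset())
        return cfg, truth

    def test_odds_ratio_one_is_null(self):
        cfg, truth = self._study_bits(1.0)
        ps = []
        for seed in range(20):
            catalog, _ = make_catalog(cfg, truth, odds_ratio=1.0,
                                      seed_offset=2000 + seed)
            res = ora([f"g{i:05d}" for i in range(100)], cfg.gene_names(),
                      catalog)
            ps.extend(res[res["term"].str.startswith("death")]["p"])
        # membership independent of the module: no systematic enrichment
        assert np.mean(ps) > 0.3

    def test_high_odds_ratio_flags_module(self):
        cfg, truth = self._study_bits(20.0)
        hits = 0
        for seed in range(10):
            catalog, _ = make_catalog(cfg, truth, odds_ratio=20.0,
                                      seed_offset=3000 + seed)
            res = ora([f"g{i:05d}" for i in range(100)], cfg.gene_names(),
                      catalog, fdr_cut=0.01)
            death = res[res["term"].str.startswith("death")]
            hits += bool(death["significant"].any())
        assert hits >= 9

    def test_empty_module_spec_still_valid(self):
        cfg = small_cfg()
        truth = GroundTruth({}, None, frozenset(), frozenset())
        catalog, census = make_catalog(cfg, truth)
        assert len(catalog.terms()) > 0
        assert len(census) > 0

    def test_census_disjoint_from_conserved(self):
        cfg = small_cfg()
        conserved = frozenset(cfg.gene_names()[:10])
        truth = GroundTruth({}, None, conserved, frozenset())
        _, census = make_catalog(cfg, truth)
        assert not (set(census) & conserved)

    def test_conserved_excluded_from_death_terms(self):
        cfg = small_cfg(module_spec=(ModuleSpec("mod", tuple(range(20))),))
        conserved = frozenset(cfg.gene_names()[:10])
        truth = GroundTruth({}, None, conserved, frozenset())
        catalog, _ = make_catalog(cfg, truth)
        for t in catalog.terms():
            if t.startswith("death"):
                assert not (catalog.members[t] & conserved)


class TestOrthologs:
    def test_no_conserved_genes_gives_empty_concordance(self):
        cfg = small_cfg()
        truth = GroundTruth({}, None, frozenset(), frozenset())
        omap, yeast = make_orthologs(cfg, truth, mapped_fraction=0.5)
        cand = pd.DataFrame({"direction": ["up", "down"]},
                            index=cfg.gene_names()[:2])
        out = ortholog_concordance(cand, omap, yeast)
        assert not out["conserved"].any()

    def test_conserved_genes_concordant_by_construction(self):
        cfg, conserved = planted_recovery_config(seed=2, n_genes=300,
                                                 n_conserved=8,
                                                 module_size=30)
        truth_lfc = planted_lfc(cfg)
        truth = GroundTruth(truth_lfc, None, frozenset(conserved),
                            frozenset())
        omap, yeast = make_orthologs(cfg, truth)
        direction = {g: ("up" if list(truth_lfc[g].values())[0] > 0
                         else "down") for g in conserved}
        cand = pd.DataFrame({"direction": [direction[g] for g in conserved]},
                            index=conserved)
        out = ortholog_concordance(cand, omap, yeast)
        assert out["conserved"].all()

    def test_one_to_many_keeps_single_best(self):
        cfg = small_cfg()
        truth = GroundTruth({}, None, frozenset(cfg.gene_names()[:5]),
                            frozenset())
        omap, _ = make_orthologs(cfg, truth)
        best = omap.best()
        assert best.index.is_unique


class TestNetwork:
    def test_planted_neighborhood_is_significant(self):
        cfg = small_cfg(n_genes=1000)
        disease_genes = frozenset(cfg.gene_names()[:5])
        truth = GroundTruth({}, None, frozenset(), disease_genes)
        net, ann = make_network(cfg, truth, background_rate=0.05,
                                planted_neighbors=10, planted_annotated=8)
        out = predict_disease(sorted(disease_genes), net, ann)
        assert (out["p"] < 1e-6).all()

    def test_empty_disease_annotation_no_predictions(self):
        cfg = small_cfg()
        truth = GroundTruth({}, None, frozenset(), frozenset())
        net, ann = make_network(cfg, truth, background_rate=0.0)
        out = predict_disease(cfg.gene_names()[:3], net, ann)
        assert len(out) == 0


class TestStudyConsistency:
    def test_truth_ids_exist_in_data(self):
        cfg, conserved = planted_recovery_config(seed=7, n_genes=300,
                                                 n_conserved=8,
                                                 module_size=30)
        study = simulate_study(cfg, conserved=conserved)
        genes = set(study.counts.genes)
        assert set(study.truth.true_deg_table) <= genes
        assert set(study.truth.true_conserved) <= genes
        assert set(study.truth.true_modules.labels.index) == genes
        assert set(study.design["sample"]) == set(study.counts.samples)
        # planted module members flagged in the truth labels
        labels = study.truth.true_modules.labels
        assert (labels != "unassigned").sum() == 60

    def test_study_deterministic(self):
        cfg, conserved = planted_recovery_config(seed=9, n_genes=200,
                                                 n_conserved=4,
                                                 module_size=20)
        a = simulate_study(cfg, conserved=conserved)
        b = simulate_study(cfg, conserved=conserved)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        assert a.catalog.members == b.catalog.members
        assert sorted(a.network.edges) == sorted(b.network.edges)
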