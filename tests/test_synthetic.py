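import json

import networkx as nx
import numpy as np
import pytest

from mprsnet.adm import cohens_d_ci
from mprsnet.annotation import module_coexpression
from mprsnet.synthetic import (
    ExpressionParams,
    MediationPaths,
    PlantedModule,
    SimulationConfig,
    SurvivalParams,
    _gene_names,
    generate_expression,
    generate_gene_scores,
    generate_genotypes_and_sumstats,
    generate_network,
    generate_phenotypes,
    simulate_to_dir,
    true_mediation_effects,
)


def small_config(**kw):
    defaults = dict(seed=0, n_genes=30, edge_prob=0.05,
                    planted=[PlantedModule(size=5, p_in=0.8)], n_individuals=50)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateNetwork:
    def test_full_p_in_gives_clique(self):
        cfg = small_config(planted=[PlantedModule(size=5, p_in=1.0)])
        edges, planted = generate_network(cfg)
        members = planted["planted1"]
        es = set(edges)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                assert ((a, b) if a < b else (b, a)) in es

    def test_deterministic_under_seed(self):
        cfg = small_config(seed=11)
        assert generate_network(cfg) == generate_network(small_config(seed=11))
        assert generate_network(cfg) != generate_network(small_config(seed=12))

    def test_scaffold_only_gives_spanning_path(self):
        cfg = small_config(edge_prob=0.0, planted=[PlantedModule(size=5, p_in=0.0)])
        edges, _ = generate_network(cfg)
        assert len(edges) == cfg.n_genes - 1
        assert nx.is_connected(nx.Graph(edges))

    def test_graph_always_connected(self):
        for seed in range(3):
            edges, _ = generate_network(small_config(seed=seed))
            g = nx.Graph(edges)
            assert g.number_of_nodes() == 30 and nx.is_connected(g)


class TestGeneScores:
    def test_null_alpha_indistinguishable(self):
        cfg = small_config(planted=[PlantedModule(size=5, gene_score_alpha=1.0)],
                           n_genes=3000 // 100)  # small but irrelevant here
        cfg = small_config(planted=[PlantedModule(size=15, gene_score_alpha=1.0)], n_genes=1000)
        edges, planted = generate_network(cfg)
        scores = generate_gene_scores(_gene_names(cfg.n_genes), planted, cfg)
        pl = scores[scores["gene_id"].isin(planted["planted1"])]["p_value"]
        bg = scores[~scores["gene_id"].isin(planted["planted1"])]["p_value"]
        # same Uniform(0,1) law: means within sampling noise
        assert abs(pl.mean() - bg.mean()) < 0.25

    def test_strong_alpha_separates_planted(self):
        cfg = small_config(planted=[PlantedModule(size=10, gene_score_alpha=0.01)], n_genes=200)
        _, planted = generate_network(cfg)
        scores = generate_gene_scores(_gene_names(200), planted, cfg)
        logp = -np.log10(scores.set_index("gene_id")["p_value"])
        pl = logp[planted["planted1"]].mean()
        bg = logp.drop(planted["planted1"]).mean()
        # Monte-Carlo mean of -log10 Beta(0.01, 1) is 1/(0.01 ln 10) ~ 43
        assert pl > 10 * bg

    def test_all_p_in_unit_interval(self):
        cfg = small_config()
        _, planted = generate_network(cfg)
        p = generate_gene_scores(_gene_names(30), planted, cfg)["p_value"]
        assert ((p > 0) & (p <= 1)).all()


class TestGenotypes:
    def _sim(self, target_d, seed=0, n=2000):
        cfg = SimulationConfig(seed=seed, n_genes=12, n_individuals=n,
                               planted=[PlantedModule(size=10)], target_cohens_d=target_d)
        planted = {"planted1": _gene_names(12)[:10]}
        return generate_genotypes_and_sumstats(cfg, planted), cfg

    def test_null_target_d_stays_small(self):
        sim, _ = self._sim(0.0)
        x, h = sim.true_mprs["planted1"], sim.case_status
        d, _, _ = cohens_d_ci(x[h == 1], x[h == 0])
        assert abs(d) < 0.1

    def test_target_d_realized_within_sampling_error(self):
        sim, _ = self._sim(0.5, n=4000)
        x, h = sim.true_mprs["planted1"], sim.case_status
        d, _, _ = cohens_d_ci(x[h == 1], x[h == 0])
        assert 0.35 <= d <= 0.65

    def test_calibration_unbiased_over_replicates(self):
        """Mean realized d over replicates within +/-0.05 of the 0.5 target."""
        ds = []
        for seed in range(60):
            sim, _ = self._sim(0.5, seed=seed, n=4000)
            x, h = sim.true_mprs["planted1"], sim.case_status
            d, _, _ = cohens_d_ci(x[h == 1], x[h == 0])
            ds.append(d)
        assert abs(np.mean(ds) - 0.5) < 0.05

    def test_boundary_snp_at_window_edge_exists(self):
        sim, _ = self._sim(0.5, n=50)
        ann = sim.annotation.set_index("gene_id")
        ss = sim.sumstats["meta1"].set_index("snp_id")
        g0 = sim.annotation["gene_id"].iloc[0]
        assert int(ss.at[f"rs_{g0}_0", "pos"]) == int(ann.at[g0, "start"]) - 20_000

    def test_dosages_in_range_and_deterministic(self):
        sim1, cfg = self._sim(0.5, n=100)
        sim2, _ = self._sim(0.5, n=100)
        assert np.array_equal(sim1.genotypes.dosages, sim2.genotypes.dosages)
        assert sim1.genotypes.dosages.min() >= 0 and sim1.genotypes.dosages.max() <= 2


class TestPhenotypes:
    def test_no_mediator_path_gives_zero_true_acme(self):
        cfg = small_config(mediation=MediationPaths(a=0.0))
        x = np.random.default_rng(0).standard_normal(500)
        _, truth = generate_phenotypes(x, cfg)
        assert truth["true_acme"] == pytest.approx(0.0, abs=1e-3)

    def test_true_hr_stored_by_construction(self):
        cfg = small_config(survival=SurvivalParams(log_hr_per_sd=float(np.log(1.3))))
        x = np.random.default_rng(0).standard_normal(500)
        _, truth = generate_phenotypes(x, cfg)
        assert truth["true_hr_per_sd"] == pytest.approx(1.3)

    def test_zero_censoring_rate_gives_all_events(self):
        cfg = small_config(survival=SurvivalParams(censoring_rate=0.0), n_individuals=800)
        x = np.random.default_rng(1).standard_normal(800)
        pheno, _ = generate_phenotypes(x, cfg)
        mci = pheno[pheno["conv_months"].notna()]
        assert len(mci) > 0 and (mci["conv_event"] == 1).all()

    def test_censoring_rate_approximately_met(self):
        cfg = SimulationConfig(seed=4, n_individuals=3000)
        x = np.random.default_rng(2).standard_normal(3000)
        pheno, _ = generate_phenotypes(x, cfg)
        mci = pheno[pheno["conv_months"].notna()]
        assert abs(1 - mci["conv_event"].mean() - 0.4) < 0.05

    def test_diagnosis_partition_and_conversion_fields(self):
        cfg = SimulationConfig(seed=5, n_individuals=2000)
        x = np.random.default_rng(3).standard_normal(2000)
        pheno, _ = generate_phenotypes(x, cfg)
        assert set(pheno["diagnosis"]) == {"CN", "SMC", "EMCI", "LMCI", "AD"}
        mci_mask = pheno["diagnosis"].isin(["EMCI", "LMCI"])
        assert pheno.loc[mci_mask, "conv_months"].notna().all()
        assert pheno.loc[~mci_mask, "conv_months"].isna().all()


class TestTrueMediationOracle:
    def test_default_paths_mediate_about_a_fifth(self):
        r = true_mediation_effects(MediationPaths(), n_draws=300_000, seed=1)
        assert r["true_prop_mediated"] == pytest.approx(0.22, abs=0.02)
        assert r["true_acme"] + r["true_ade"] == pytest.approx(r["true_total_effect"], abs=1e-12)

    def test_no_direct_path_gives_full_mediation(self):
        r = true_mediation_effects(MediationPaths(c=0.0, gamma_age=0, gamma_sex=0, gamma_edu=0),
                                   n_draws=300_000, seed=1)
        assert r["true_prop_mediated"] == pytest.approx(1.0, abs=1e-9)


class TestExpression:
    def _pcc(self, rho, tissue=None):
        cfg = small_config(expression=ExpressionParams(n_samples=500, rho_target=rho))
        _, planted = generate_network(cfg)
        mats = generate_expression(_gene_names(30), planted, cfg)
        label = tissue or cfg.expression.target_tissue
        return module_coexpression(mats[label], planted["planted1"])

    def test_high_rho_high_coexpression(self):
        assert self._pcc(0.9) > 0.8

    def test_zero_rho_null_coexpression(self):
        assert abs(self._pcc(0.0)) < 0.1

    def test_other_tissue_uncorrelated_regardless_of_rho(self):
        assert abs(self._pcc(0.9, tissue="cortex")) < 0.1


class TestSimulateToDir:
    def test_writes_all_inputs_and_ground_truth(self, tmp_path):
        cfg = small_config()
        truth = simulate_to_dir(cfg, tmp_path)
        for name in ["edges.tsv", "scores_L.tsv", "scores_R.tsv", "annotation.tsv",
                     "genotypes.tsv", "genotypes.tsv.alleles.tsv", "sumstats_meta1.tsv",
                     "sumstats_meta2.tsv", "phenotypes.tsv", "expression_amygdala.tsv",
                     "expression_blood.tsv", "genesets.gmt", "ground_truth.json"]:
            assert (tmp_path / name).exists(), name
        on_disk = json.loads((tmp_path / "ground_truth.json").read_text())
        assert on_disk["planted_modules"] == truth["planted_modules"]

    def test_byte_identical_under_same_seed(self, tmp_path):
        cfg = small_config(seed=21)
        simulate_to_dir(cfg, tmp_path / "a")
        simulate_to_dir(small_config(seed=21), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


class TestConfigValidation:
    def test_rejects_tiny_module(self):
        with pytest.raises(ValueError, match=">= 3"):
            small_config(planted=[PlantedModule(size=2)])

    def test_rejects_oversized_planting(self):
        with pytest.raises(ValueError, match="exceed"):
            small_config(planted=[PlantedModule(size=40)])

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError, match="probability"):
            small_config(edge_prob=1.5)

    def test_round_trips_through_dict(self):
        cfg = small_config(seed=9)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg
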