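"""Planted-truth generator: determinism, label consistency, limits."""

import math

import networkx as nx
import numpy as np
import pytest

from nutriconnect import synthetic as syn
from nutriconnect.synergy import build_gold_standard
from nutriconnect.synthetic import (ANTI, CORR, NULL, ConfigError,
                                    SyntheticConfig, classify_signed_pair,
                                    generate_disease_module,
                                    generate_expression_dataset,
                                    generate_interactome, generate_signatures)


class TestConfigValidation:
    def test_fraction_out_of_range(self):
        with pytest.raises(ConfigError, match="reversal_fraction"):
            SyntheticConfig(reversal_fraction=1.5)

    def test_module_exceeds_network(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(network_nodes=10, module_size=20, n_genes=100)

    def test_pathway_range_infeasible(self):
        with pytest.raises(ConfigError, match="pathway_size_range"):
            SyntheticConfig(pathway_size_range=(50, 10))

    def test_role_fractions_must_fit(self):
        with pytest.raises(ConfigError, match="food role"):
            SyntheticConfig(n_foods=4, frac_anti_foods=1.0,
                            n_synergy_pairs=2)


class TestInteractome:
    def test_construction_guarantees(self):
        g = generate_interactome(100, 2, seed=7)
        assert g.number_of_nodes() == 100
        assert nx.is_connected(g)
        assert not any(g.has_edge(n, n) for n in g)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigError):
            generate_interactome(10, 9 + 1, seed=1)
        with pytest.raises(ConfigError):
            generate_interactome(10, 10, seed=1)

    def test_determinism(self):
        g1 = generate_interactome(100, 2, seed=7)
        g2 = generate_interactome(100, 2, seed=7)
        assert set(g1.edges()) == set(g2.edges())

    def test_heavy_tail(self):
        g = generate_interactome(400, 3, seed=0)
        degrees = sorted((d for _, d in g.degree()), reverse=True)
        assert degrees[0] > 5 * np.median(degrees)


class TestDiseaseModule:
    def test_connected_and_sized(self):
        g = generate_interactome(80, 2, seed=3)
        m = generate_disease_module(g, 12, seed=5)
        assert len(m) == 12
        assert nx.is_connected(g.subgraph(m))

    def test_path_graph_pairs(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        m = generate_disease_module(g, 2, seed=3)
        assert m in ({"a", "b"}, {"b", "c"}, {"c", "d"})

    def test_full_graph_exhaustion(self):
        g = nx.cycle_graph(6)
        assert generate_disease_module(g, 6, seed=0) == set(range(6))

    def test_determinism(self):
        g = generate_interactome(80, 2, seed=3)
        assert generate_disease_module(g, 10, seed=9) == \
            generate_disease_module(g, 10, seed=9)

    def test_oversized_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ConfigError):
            generate_disease_module(g, 4, seed=0)


@pytest.fixture
def modules_and_config(small_config):
    g = generate_interactome(small_config.network_nodes,
                             small_config.edges_per_new_node,
                             seed=small_config.seed,
                             gene_universe=syn.gene_ids(
                                 small_config.n_genes)[:small_config.network_nodes])
    rng = np.random.default_rng(1)
    modules, used = {}, set()
    for i in range(1, small_config.n_diseases + 1):
        m = generate_disease_module(g, small_config.module_size, rng,
                                    exclude=used)
        modules[f"disease{i:02d}"] = m
        used |= m
    return small_config, modules


class TestSignatures:
    def test_planted_label_consistency(self, modules_and_config):
        cfg, modules = modules_and_config
        truth = generate_signatures(cfg, modules, seed=2)
        for (f, d), label in truth.pair_labels.items():
            recomputed = classify_signed_pair(truth.food_signatures[f],
                                              truth.disease_signatures[d])
            assert recomputed == label

    def test_reversal_share_within_one_gene(self, modules_and_config):
        cfg, modules = modules_and_config
        truth = generate_signatures(cfg, modules, seed=2)
        target = math.ceil(cfg.reversal_fraction * 2 * cfg.module_size)
        for (f, d), label in truth.pair_labels.items():
            if label != ANTI or f in {x for p in truth.synergy_pairs for x in p}:
                continue
            sig_d = truth.disease_signatures[d]
            sig_f = truth.food_signatures[f]
            flipped = sum(1 for g in sig_f
                          if g in sig_d and sig_f[g] == -sig_d[g])
            assert abs(flipped - target) <= 1

    def test_full_reversal_exactly_opposite(self, modules_and_config):
        cfg, modules = modules_and_config
        cfg_full = SyntheticConfig(**{**cfg.__dict__, "reversal_fraction": 1.0})
        truth = generate_signatures(cfg_full, modules, seed=2)
        for (f, d), label in truth.pair_labels.items():
            if label != ANTI:
                continue
            sig_d = truth.disease_signatures[d]
            sig_f = truth.food_signatures[f]
            overlap = {g for g in sig_f if g in sig_d}
            if f in {x for p in truth.synergy_pairs for x in p}:
                continue
            assert overlap == set(sig_d)
            assert all(sig_f[g] == -sig_d[g] for g in overlap)

    def test_zero_reversal_no_anti_labels(self, modules_and_config):
        cfg, modules = modules_and_config
        cfg0 = SyntheticConfig(**{**cfg.__dict__, "reversal_fraction": 0.0})
        truth = generate_signatures(cfg0, modules, seed=2)
        assert ANTI not in set(truth.pair_labels.values())

    def test_correlated_pairs_copy_directions(self, modules_and_config):
        cfg, modules = modules_and_config
        truth = generate_signatures(cfg, modules, seed=2)
        corr_pairs = [(f, d) for (f, d), v in truth.pair_labels.items()
                      if v == CORR]
        assert corr_pairs
        for f, d in corr_pairs:
            sig_d, sig_f = truth.disease_signatures[d], truth.food_signatures[f]
            shared = {g for g in sig_f if g in sig_d}
            assert all(sig_f[g] == sig_d[g] for g in shared)

    def test_planted_gold_matches_gold_standard_builder(self,
                                                        modules_and_config):
        cfg, modules = modules_and_config
        truth = generate_signatures(cfg, modules, seed=2)
        gold = build_gold_standard(truth.reference_table)
        assert gold == {tuple(sorted(p)) for p in truth.synergy_pairs}

    def test_determinism(self, modules_and_config):
        cfg, modules = modules_and_config
        t1 = generate_signatures(cfg, modules, seed=2)
        t2 = generate_signatures(cfg, modules, seed=2)
        assert t1.food_signatures == t2.food_signatures
        assert t1.pair_labels == t2.pair_labels


class TestExpressionDataset:
    def test_noiseless_limit_exact_shift(self, small_config):
        cfg = SyntheticConfig(**{**small_config.__dict__, "baseline_sd": 0.0,
                                 "noise_sd": 0.0})
        sig = {"G0001": 1, "G0002": -1}
        b = generate_expression_dataset(sig, cfg, seed=0)
        case = b.values.loc[:, b.labels == "case"].mean(axis=1)
        ctrl = b.values.loc[:, b.labels == "control"].mean(axis=1)
        diff = case - ctrl
        assert diff["G0001"] == pytest.approx(cfg.effect_size)
        assert diff["G0002"] == pytest.approx(-cfg.effect_size)
        assert (diff.drop(["G0001", "G0002"]) == 0).all()

    def test_fixed_seed_identical(self, small_config):
        a = generate_expression_dataset({"G0001": 1}, small_config, seed=4)
        b = generate_expression_dataset({"G0001": 1}, small_config, seed=4)
        assert a.values.equals(b.values)

    def test_unknown_signature_gene_rejected(self, small_config):
        with pytest.raises(ConfigError, match="universe"):
            generate_expression_dataset({"NOPE": 1}, small_config, seed=0)


class TestAnnotations:
    def test_limits_and_seeded_pathways(self, modules_and_config):
        cfg, modules = modules_and_config
        cfg0 = SyntheticConfig(**{**cfg.__dict__, "ortholog_dropout": 0.0,
                                  "ambiguous_probe_fraction": 0.0})
        truth = generate_signatures(cfg0, modules, seed=2)
        annot = syn.generate_annotations(cfg0, truth, seed=3)
        # no dropout: every gene has an ortholog row
        assert len(annot.ortholog_pairs) == cfg0.n_genes
        # no ambiguity: the probe map is a function probe -> gene
        probes = [p for p, _ in annot.probe_pairs]
        assert len(probes) == len(set(probes))
        # each disease module is >=60% covered by some pathway
        for d, module in truth.disease_modules.items():
            best = max(len(module & pw) / len(module)
                       for pw in annot.pathways.values())
            assert best >= 0.6

    def test_designated_identical_compound_pair(self, modules_and_config):
        from nutriconnect.chemsim import fingerprint, tanimoto

        cfg, modules = modules_and_config
        truth = generate_signatures(cfg, modules, seed=2)
        annot = syn.generate_annotations(cfg, truth, seed=3)
        (food, drug), = annot.designated_similar[:1]
        f_smis = set(annot.food_compounds.loc[
            annot.food_compounds["entity"] == food, "smiles"])
        d_smis = set(annot.drug_compounds.loc[
            annot.drug_compounds["entity"] == drug, "smiles"])
        shared = f_smis & d_smis
        assert shared
        smi = shared.pop()
        assert tanimoto(fingerprint(smi), fingerprint(smi)) == 1.0
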