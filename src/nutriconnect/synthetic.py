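"""Synthetic study generator with planted ground truth.

Emulates the data substrate of a diet/drug/disease connectivity-mapping
study: for every entity (food, drug, disease) several noisy replicate
case/control expression datasets share one planted differential signature;
disease signatures are localized on a module of a scale-free interactome;
"therapeutic" food and drug signatures reverse a tunable fraction of a
disease signature; pathway annotations are seeded with the planted modules;
and a literature-style reference table defines gold-standard synergy pairs.

Every generator is a pure function of (config, seed): the same
configuration always produces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io

ANTI = "anti-correlated"
CORR = "correlated"
NULL = "null"

# Small fixture library of valid canonical SMILES for common dietary and
# pharmaceutical small molecules; keeps the chemistry stage free of any
# external database.
SMILES_LIBRARY: list[tuple[str, str]] = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("ethanol", "CCO"),
    ("quercetin", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"),
    ("resveratrol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1"),
    ("curcumin", "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("melatonin", "COc1ccc2[nH]cc(CCNC(C)=O)c2c1"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("capsaicin", "COc1cc(CNC(=O)CCCC/C=C/C(C)C)ccc1O"),
    ("menthol", "CC(C)[C@@H]1CC[C@@H](C)C[C@H]1O"),
    ("vanillin", "COc1cc(C=O)ccc1O"),
    ("limonene", "CC1=CCC(C(C)=C)CC1"),
    ("gallic_acid", "O=C(O)c1cc(O)c(O)c(O)c1"),
    ("catechin", "Oc1cc(O)c2c(c1)O[C@H](c1ccc(O)c(O)c1)[C@H](O)C2"),
    ("naringenin", "O=C1C[C@H](c2ccc(O)cc2)Oc2cc(O)cc(O)c21"),
    ("genistein", "O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12"),
    ("sulforaphane", "CS(=O)CCCCN=C=S"),
    ("citric_acid", "O=C(O)CC(O)(CC(=O)O)C(=O)O"),
    ("ascorbic_acid", "OC[C@H](O)[C@H]1OC(=O)C(O)=C1O"),
    ("salicylic_acid", "O=C(O)c1ccccc1O"),
    ("benzoic_acid", "O=C(O)c1ccccc1"),
    ("cinnamaldehyde", "O=C/C=C/c1ccccc1"),
    ("eugenol", "C=CCc1ccc(O)c(OC)c1"),
    ("thymol", "Cc1ccc(C(C)C)c(O)c1"),
    ("coumarin", "O=c1ccc2ccccc2o1"),
    ("ferulic_acid", "COc1cc(/C=C/C(=O)O)ccc1O"),
    ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
]


class ConfigError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, log2-expression scale throughout.

    The defaults define the study conditions: a strong but noisy planted
    effect (effect_size/noise_sd = 3), 80% signature reversal for
    therapeutic pairs, three replicate datasets per entity with five
    samples per arm, and a 500-node scale-free interactome carrying
    disjoint 20-gene disease modules.
    """

    seed: int = 0
    n_genes: int = 1000
    n_diseases: int = 10
    n_foods: int = 20
    n_drugs: int = 10
    datasets_per_entity: int = 3
    samples_per_arm: int = 5
    baseline_mean: float = 8.0
    baseline_sd: float = 0.5
    effect_size: float = 1.5
    noise_sd: float = 0.5
    reversal_fraction: float = 0.8
    extra_de_fraction: float = 0.02
    network_nodes: int = 500
    edges_per_new_node: int = 3
    module_size: int = 20
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (10, 50)
    ortholog_dropout: float = 0.1
    # plumbing knobs beyond the core study conditions
    frac_anti_foods: float = 0.5
    frac_corr_foods: float = 0.2
    n_synergy_pairs: int = 2
    synergy_split: float = 0.7
    ambiguous_probe_fraction: float = 0.05
    missing_value_fraction: float = 0.0
    probe_noise_sd: float = 0.05
    drug_species: str = "mouse"
    n_disease_classes: int = 3

    def __post_init__(self) -> None:
        fractions = {
            "reversal_fraction": self.reversal_fraction,
            "extra_de_fraction": self.extra_de_fraction,
            "ortholog_dropout": self.ortholog_dropout,
            "frac_anti_foods": self.frac_anti_foods,
            "frac_corr_foods": self.frac_corr_foods,
            "ambiguous_probe_fraction": self.ambiguous_probe_fraction,
            "missing_value_fraction": self.missing_value_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        counts = {
            "n_genes": self.n_genes, "n_diseases": self.n_diseases,
            "n_foods": self.n_foods, "n_drugs": self.n_drugs,
            "datasets_per_entity": self.datasets_per_entity,
            "samples_per_arm": self.samples_per_arm,
            "network_nodes": self.network_nodes,
            "edges_per_new_node": self.edges_per_new_node,
            "module_size": self.module_size, "n_pathways": self.n_pathways,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.module_size > self.network_nodes:
            raise ConfigError("module_size exceeds network_nodes")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError("pathway_size_range infeasible for n_genes")
        if self.network_nodes > self.n_genes:
            raise ConfigError("network_nodes exceeds the gene universe")
        if self.n_diseases * self.module_size > self.network_nodes:
            raise ConfigError(
                "disjoint disease modules need n_diseases*module_size "
                "<= network_nodes")
        if self.n_diseases * 2 * self.module_size > self.n_genes:
            raise ConfigError("gene universe too small for disjoint signatures")
        n_special = (self.n_anti_foods + self.n_corr_foods
                     + 2 * self.n_synergy_pairs)
        if n_special > self.n_foods:
            raise ConfigError("food role fractions exceed n_foods")
        if self.n_synergy_pairs >= self.n_diseases:
            raise ConfigError("need spare diseases beyond the synergy-reserved ones")

    @property
    def n_anti_foods(self) -> int:
        return round(self.frac_anti_foods * self.n_foods)

    @property
    def n_corr_foods(self) -> int:
        return round(self.frac_corr_foods * self.n_foods)


def gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def model_gene(gene: str) -> str:
    return "m" + gene


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, consumed only by tests."""

    disease_signatures: dict[str, dict[str, int]]
    food_signatures: dict[str, dict[str, int]]
    drug_signatures: dict[str, dict[str, int]]
    pair_labels: dict[tuple[str, str], str]
    drug_pair_labels: dict[tuple[str, str], str]
    disease_modules: dict[str, set[str]]
    synergy_pairs: set[tuple[str, str]]
    reference_table: pd.DataFrame
    known_indications: list[tuple[str, str]] = field(default_factory=list)
    disease_classes: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "disease_signatures": self.disease_signatures,
            "food_signatures": self.food_signatures,
            "drug_signatures": self.drug_signatures,
            "pair_labels": {f"{f}|{d}": v for (f, d), v in self.pair_labels.items()},
            "drug_pair_labels": {f"{a}|{d}": v
                                 for (a, d), v in self.drug_pair_labels.items()},
            "disease_modules": {k: sorted(v)
                                for k, v in self.disease_modules.items()},
            "synergy_pairs": sorted(list(p) for p in self.synergy_pairs),
            "reference_table": self.reference_table.to_dict(orient="records"),
            "known_indications": [list(p) for p in self.known_indications],
            "disease_classes": self.disease_classes,
        }


def classify_signed_pair(food_sig: dict[str, int],
                         disease_sig: dict[str, int]) -> str:
    """Label a (perturbation, disease) signed-set pair by direction agreement.

    Anti-correlated when shared genes are predominantly opposite in sign,
    correlated when predominantly concordant, null when there is no shared
    gene or no majority.
    """
    shared = food_sig.keys() & disease_sig.keys()
    if not shared:
        return NULL
    n_opp = sum(1 for g in shared if food_sig[g] == -disease_sig[g])
    n_same = len(shared) - n_opp
    if n_opp > n_same:
        return ANTI
    if n_same > n_opp:
        return CORR
    return NULL


def generate_interactome(n_nodes: int, edges_per_new_node: int, seed: int,
                         gene_universe: list[str] | None = None) -> nx.Graph:
    """Scale-free interactome by preferential attachment, gene-labelled.

    A Barabasi-Albert graph is simple and connected by construction and has
    the heavy-tailed degree distribution real protein-interaction networks
    show.
    """
    if not (n_nodes > edges_per_new_node >= 1):
        raise ConfigError(
            f"need n_nodes > edges_per_new_node >= 1, got "
            f"({n_nodes}, {edges_per_new_node})")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_new_node, seed=int(seed))
    labels = gene_universe if gene_universe is not None else gene_ids(n_nodes)
    if len(labels) < n_nodes:
        raise ConfigError("gene universe smaller than requested node count")
    return nx.relabel_nodes(g, dict(enumerate(labels)))


def generate_disease_module(graph: nx.Graph, module_size: int,
                            seed: int | np.random.Generator,
                            exclude: set | None = None) -> set:
    """Grow a connected node set by seeded random breadth-first expansion."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    exclude = exclude or set()
    candidates = sorted(set(graph.nodes()) - exclude)
    if module_size > graph.number_of_nodes():
        raise ConfigError("module_size exceeds graph order")
    if module_size > len(candidates):
        raise ConfigError("module_size exceeds available (non-excluded) nodes")
    for _ in range(200):  # restart if growth dead-ends against exclusions
        start = candidates[rng.integers(len(candidates))]
        module = {start}
        frontier = sorted(set(graph[start]) - exclude)
        while len(module) < module_size and frontier:
            nxt = frontier[rng.integers(len(frontier))]
            module.add(nxt)
            frontier = sorted(
                (set(frontier) | set(graph[nxt])) - module - exclude)
        if len(module) == module_size:
            return module
    raise ConfigError("could not grow a connected module; exclusions too tight")


def _signed(rng: np.random.Generator, genes: list[str]) -> dict[str, int]:
    dirs = rng.choice([-1, 1], size=len(genes))
    return {g: int(d) for g, d in zip(genes, dirs)}


def generate_signatures(config: SyntheticConfig,
                        modules: dict[str, set[str]],
                        seed: int | None = None) -> PlantedTruth:
    """Plant disease/food/drug signed signatures and all pair-level truth.

    Disease signatures are pairwise disjoint (module genes plus a private
    set of off-module genes), so that the label of any entity-disease pair
    is exactly recomputable from signed-set overlap. Anti-correlated
    entities flip ceil(reversal_fraction * |signature|) genes of their
    target disease; correlated entities copy the same share; synergy-pair
    foods split one reversed signature with partial overlap; everything
    else touches only genes outside every disease signature.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = gene_ids(config.n_genes)
    diseases = [f"disease{i:02d}" for i in range(1, config.n_diseases + 1)]
    foods = [f"food{i:02d}" for i in range(1, config.n_foods + 1)]
    drugs = [f"drug{i:02d}" for i in range(1, config.n_drugs + 1)]
    if set(modules) != set(diseases):
        modules = dict(zip(diseases, modules.values()))

    module_genes = set().union(*modules.values()) if modules else set()
    free_pool = [g for g in genes if g not in module_genes]
    rng.shuffle(free_pool)
    free_pool = list(free_pool)  # consumed from the end

    def take(n: int) -> list[str]:
        if n > len(free_pool):
            raise ConfigError("gene universe exhausted while planting signatures")
        out = [free_pool.pop() for _ in range(n)]
        return out

    disease_signatures: dict[str, dict[str, int]] = {}
    for d in diseases:
        sig_genes = sorted(modules[d]) + take(config.module_size)
        disease_signatures[d] = _signed(rng, sig_genes)

    # background pool: genes outside every disease signature and module.
    # Food/drug "extra" DE genes are drawn here; reuse across entities is
    # allowed (it cannot change any entity-disease label).
    background = sorted(free_pool)

    def draw_background(n: int) -> list[str]:
        if n > len(background):
            raise ConfigError("gene universe too small for extra DE genes")
        return list(rng.choice(background, size=n, replace=False))

    # reserve the trailing diseases exclusively for synergy pairs so no
    # spurious pair passes the gold-standard reference-count rule
    n_res = config.n_synergy_pairs
    open_diseases = diseases[: config.n_diseases - n_res]
    synergy_diseases = diseases[config.n_diseases - n_res:] if n_res else []

    n_anti, n_corr = config.n_anti_foods, config.n_corr_foods
    n_syn_foods = 2 * config.n_synergy_pairs
    roles: dict[str, str] = {}
    target: dict[str, str] = {}
    for i, f in enumerate(foods):
        if i < n_anti:
            roles[f] = "anti"
            target[f] = open_diseases[i % len(open_diseases)]
        elif i < n_anti + n_corr:
            roles[f] = "corr"
            target[f] = open_diseases[i % len(open_diseases)]
        elif i < n_anti + n_corr + n_syn_foods:
            roles[f] = "synergy"
        else:
            roles[f] = "null"

    n_extra = math.ceil(config.extra_de_fraction * config.n_genes)
    rho = config.reversal_fraction

    def reversal_subset(d: str) -> list[tuple[str, int]]:
        sig = disease_signatures[d]
        k = math.ceil(rho * len(sig))
        chosen = list(rng.choice(sorted(sig), size=k, replace=False)) if k else []
        return [(g, -sig[g]) for g in chosen]

    def copy_subset(d: str) -> list[tuple[str, int]]:
        sig = disease_signatures[d]
        k = math.ceil(rho * len(sig))
        chosen = list(rng.choice(sorted(sig), size=k, replace=False)) if k else []
        return [(g, sig[g]) for g in chosen]

    food_signatures: dict[str, dict[str, int]] = {}
    synergy_pairs: set[tuple[str, str]] = set()
    syn_foods = [f for f in foods if roles[f] == "synergy"]
    for p in range(config.n_synergy_pairs):
        f1, f2 = syn_foods[2 * p], syn_foods[2 * p + 1]
        d = synergy_diseases[p]
        rev = reversal_subset(d)
        rng.shuffle(rev)
        cut = math.ceil(config.synergy_split * len(rev))
        part1 = rev[:cut]
        part2 = rev[len(rev) - cut:]
        food_signatures[f1] = dict(part1) | _signed(rng, draw_background(n_extra))
        food_signatures[f2] = dict(part2) | _signed(rng, draw_background(n_extra))
        synergy_pairs.add(tuple(sorted((f1, f2))))
        target[f1] = target[f2] = d

    null_size = math.ceil(rho * 2 * config.module_size) + n_extra
    for f in foods:
        if roles[f] == "anti":
            food_signatures[f] = dict(reversal_subset(target[f])) | _signed(
                rng, draw_background(n_extra))
        elif roles[f] == "corr":
            food_signatures[f] = dict(copy_subset(target[f])) | _signed(
                rng, draw_background(n_extra))
        elif roles[f] == "null":
            food_signatures[f] = _signed(rng, draw_background(null_size))

    # drugs mirror the food roles (anti / corr / null, no synergy)
    n_anti_d = round(config.frac_anti_foods * config.n_drugs)
    n_corr_d = round(config.frac_corr_foods * config.n_drugs)
    drug_signatures: dict[str, dict[str, int]] = {}
    drug_target: dict[str, str] = {}
    known_indications: list[tuple[str, str]] = []
    for i, a in enumerate(drugs):
        if i < n_anti_d:
            d = open_diseases[i % len(open_diseases)]
            drug_signatures[a] = dict(reversal_subset(d)) | _signed(
                rng, draw_background(n_extra))
            drug_target[a] = d
            known_indications.append((a, d))
        elif i < n_anti_d + n_corr_d:
            d = open_diseases[i % len(open_diseases)]
            drug_signatures[a] = dict(copy_subset(d)) | _signed(
                rng, draw_background(n_extra))
            drug_target[a] = d
        else:
            drug_signatures[a] = _signed(rng, draw_background(null_size))

    pair_labels = {(f, d): classify_signed_pair(food_signatures[f],
                                                disease_signatures[d])
                   for f in foods for d in diseases}
    drug_pair_labels = {(a, d): classify_signed_pair(drug_signatures[a],
                                                     disease_signatures[d])
                        for a in drugs for d in diseases}

    rows = []
    for f in foods:
        if roles[f] == "anti":
            rows.append({"food": f, "disease": target[f], "reference_count": 4})
    for p, pair in enumerate(sorted(synergy_pairs)):
        d = target[pair[0]]
        rows.append({"food": pair[0], "disease": d, "reference_count": 8})
        rows.append({"food": pair[1], "disease": d, "reference_count": 7})
    reference_table = pd.DataFrame(
        rows, columns=["food", "disease", "reference_count"])

    classes = [f"class{chr(65 + i)}" for i in range(config.n_disease_classes)]
    disease_classes = {d: classes[i % len(classes)]
                       for i, d in enumerate(diseases)}

    return PlantedTruth(
        disease_signatures=disease_signatures,
        food_signatures=food_signatures,
        drug_signatures=drug_signatures,
        pair_labels=pair_labels,
        drug_pair_labels=drug_pair_labels,
        disease_modules=modules,
        synergy_pairs=synergy_pairs,
        reference_table=reference_table,
        known_indications=known_indications,
        disease_classes=disease_classes,
    )


def generate_expression_dataset(signature: dict[str, int],
                                config: SyntheticConfig,
                                seed: int | np.random.Generator,
                                name: str = "") -> "ExpressionBundle":
    """One case/control gene-level matrix carrying the planted signature.

    Controls are i.i.d. Normal(baseline_mean, baseline_sd^2); cases add
    +/- effect_size on signature genes plus Normal(0, noise_sd^2) noise.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    genes = gene_ids(config.n_genes)
    unknown = set(signature) - set(genes)
    if unknown:
        raise ConfigError(f"signature genes outside the universe: {sorted(unknown)[:3]}")
    n = config.samples_per_arm
    values = rng.normal(config.baseline_mean, config.baseline_sd,
                        size=(config.n_genes, 2 * n))
    shift = np.zeros(config.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    for g, direction in signature.items():
        shift[index[g]] = direction * config.effect_size
    values[:, n:] += shift[:, None]
    if config.noise_sd > 0:
        values[:, n:] += rng.normal(0.0, config.noise_sd,
                                    size=(config.n_genes, n))
    cols = [f"ctrl_{i + 1}" for i in range(n)] + [f"case_{i + 1}" for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=cols)
    labels = pd.Series(["control"] * n + ["case"] * n, index=cols, name="arm")
    return ExpressionBundle(values=df, labels=labels, name=name)


@dataclass
class ExpressionBundle:
    """A gene x sample matrix with its case/control sidecar."""

    values: pd.DataFrame
    labels: pd.Series
    name: str = ""
    species: str = "human"


@dataclass
class Annotations:
    pathways: dict[str, set[str]]
    functions: dict[str, set[str]]
    ortholog_pairs: list[tuple[str, str]]
    probe_pairs: list[tuple[str, str]]
    food_compounds: pd.DataFrame
    drug_compounds: pd.DataFrame
    designated_similar: list[tuple[str, str]]


def generate_annotations(config: SyntheticConfig, truth: PlantedTruth,
                         seed: int | None = None) -> Annotations:
    """Pathway/function collections, ortholog and probe maps, compounds.

    One pathway per disease is seeded to contain >=60% of that disease's
    module so over-representation is detectable downstream; the remaining
    pathways are random sets in the configured size range.
    """
    rng = np.random.default_rng((config.seed + 7) if seed is None else seed)
    genes = gene_ids(config.n_genes)
    lo, hi = config.pathway_size_range

    pathways: dict[str, set[str]] = {}
    names = [f"P{i:04d}" for i in range(1, config.n_pathways + 1)]
    diseases = sorted(truth.disease_modules)
    if len(diseases) > config.n_pathways:
        raise ConfigError("need at least one pathway per disease module")
    for i, name in enumerate(names):
        size = int(rng.integers(lo, hi + 1))
        if i < len(diseases):
            module = sorted(truth.disease_modules[diseases[i]])
            k_seed = math.ceil(0.6 * len(module))
            seeded = list(rng.choice(module, size=k_seed, replace=False))
            size = max(size, k_seed)
            pool = [g for g in genes if g not in set(seeded)]
            fill = list(rng.choice(pool, size=size - k_seed, replace=False))
            pathways[name] = set(seeded) | set(fill)
        else:
            pathways[name] = set(rng.choice(genes, size=size, replace=False))

    n_fun = max(5, config.n_pathways // 2)
    functions = {
        f"F{i:04d}": set(rng.choice(genes, size=int(rng.integers(lo, hi + 1)),
                                    replace=False))
        for i in range(1, n_fun + 1)
    }

    keep = rng.random(config.n_genes) >= config.ortholog_dropout
    ortholog_pairs = [(model_gene(g), g) for g, k in zip(genes, keep) if k]

    probe_pairs: list[tuple[str, str]] = []
    for prefix in ("", "m"):
        universe = [prefix + g for g in genes]
        for g in universe:
            n_probes = int(rng.integers(1, 4))
            for j in range(1, n_probes + 1):
                probe = f"{g}:p{j}"
                probe_pairs.append((probe, g))
                if rng.random() < config.ambiguous_probe_fraction:
                    other = universe[int(rng.integers(len(universe)))]
                    if other != g:
                        probe_pairs.append((probe, other))

    foods = sorted(truth.food_signatures)
    drugs = sorted(truth.drug_signatures)
    lib = SMILES_LIBRARY

    def assign(entities: list[str], offset: int) -> pd.DataFrame:
        rows = []
        for e in entities:
            n_cmpd = int(rng.integers(1, 6))
            picks = rng.choice(len(lib), size=n_cmpd, replace=False)
            for idx in picks:
                cid, smi = lib[(idx + offset) % len(lib)]
                rows.append({"entity": e, "compound_id": cid, "smiles": smi})
        return pd.DataFrame(rows, columns=["entity", "compound_id", "smiles"])

    food_compounds = assign(foods, 0)
    drug_compounds = assign(drugs, 11)
    # designated structurally identical pair: first food and first drug
    designated = []
    if foods and drugs:
        cid, smi = lib[0]
        for df, ent in ((food_compounds, foods[0]), (drug_compounds, drugs[0])):
            if not ((df["entity"] == ent) & (df["compound_id"] == cid)).any():
                df.loc[len(df)] = {"entity": ent, "compound_id": cid,
                                   "smiles": smi}
        designated.append((foods[0], drugs[0]))
    food_compounds = food_compounds.sort_values(
        ["entity", "compound_id"]).reset_index(drop=True)
    drug_compounds = drug_compounds.sort_values(
        ["entity", "compound_id"]).reset_index(drop=True)

    return Annotations(pathways=pathways, functions=functions,
                       ortholog_pairs=ortholog_pairs, probe_pairs=probe_pairs,
                       food_compounds=food_compounds,
                       drug_compounds=drug_compounds,
                       designated_similar=designated)


def _to_probe_matrix(bundle: ExpressionBundle, probe_map: dict[str, list[str]],
                     species: str, config: SyntheticConfig,
                     rng: np.random.Generator) -> ExpressionBundle:
    """Expand a gene-level matrix to probe level (optionally model-organism)."""
    prefix = "" if species == "human" else "m"
    gene_rows = {prefix + g: row for g, row in
                 zip(bundle.values.index, bundle.values.to_numpy())}
    probes, data = [], []
    for probe, mapped in probe_map.items():
        primary = mapped[0]
        if primary in gene_rows:
            row = gene_rows[primary] + rng.normal(
                0.0, config.probe_noise_sd, size=bundle.values.shape[1])
            probes.append(probe)
            data.append(row)
    values = pd.DataFrame(np.array(data), index=pd.Index(probes, name="probe"),
                          columns=bundle.values.columns)
    if config.missing_value_fraction > 0:
        mask = rng.random(values.shape) < config.missing_value_fraction
        values = values.mask(mask)
    return ExpressionBundle(values=values, labels=bundle.labels,
                            name=bundle.name, species=species)


def simulate(config: SyntheticConfig, out_dir: str | Path) -> PlantedTruth:
    """Generate the full synthetic study and write every pipeline input.

    Writes the interactome, disease modules, pathway and function GMTs,
    ortholog and probe maps, compound tables, reference association table,
    probe-level expression matrices with label sidecars, an entity
    manifest, and the planted truth as JSON.
    """
    out = Path(out_dir)
    (out / "expr").mkdir(parents=True, exist_ok=True)

    genes = gene_ids(config.n_genes)
    rng = np.random.default_rng(config.seed)
    net_genes = sorted(rng.choice(genes, size=config.network_nodes,
                                  replace=False))
    graph = generate_interactome(config.network_nodes,
                                 config.edges_per_new_node,
                                 seed=config.seed, gene_universe=net_genes)

    mod_rng = np.random.default_rng(config.seed + 1)
    modules: dict[str, set[str]] = {}
    used: set[str] = set()
    for i in range(1, config.n_diseases + 1):
        m = generate_disease_module(graph, config.module_size, mod_rng,
                                    exclude=used)
        modules[f"disease{i:02d}"] = m
        used |= m

    truth = generate_signatures(config, modules, seed=config.seed + 2)
    annot = generate_annotations(config, truth, seed=config.seed + 3)

    probe_map: dict[str, list[str]] = {}
    for probe, gene in annot.probe_pairs:
        probe_map.setdefault(probe, []).append(gene)

    io.write_edge_list(graph, out / "interactome.tsv")
    io.write_gmt({d: set(m) for d, m in truth.disease_modules.items()},
                 out / "disease_modules.gmt")
    io.write_gmt(annot.pathways, out / "pathways.gmt")
    io.write_gmt(annot.functions, out / "functions.gmt")
    io.write_pair_map(annot.ortholog_pairs, out / "ortholog_map.tsv",
                      header=("model_gene", "human_gene"))
    io.write_pair_map(annot.probe_pairs, out / "probe_map.tsv",
                      header=("probe", "gene"))
    io.write_table(annot.food_compounds, out / "food_compounds.tsv")
    io.write_table(annot.drug_compounds, out / "drug_compounds.tsv")
    io.write_table(truth.reference_table, out / "reference_associations.tsv")
    io.write_table(
        pd.DataFrame([{"drug": a, "disease": d}
                      for a, d in truth.known_indications],
                     columns=["drug", "disease"]),
        out / "known_indications.tsv")

    entity_rows = []
    signatures = [("disease", truth.disease_signatures, "human"),
                  ("food", truth.food_signatures, "human"),
                  ("drug", truth.drug_signatures, config.drug_species)]
    ds_rng = np.random.default_rng(config.seed + 4)
    for kind, sigs, species in signatures:
        for entity in sorted(sigs):
            entity_rows.append({
                "entity": entity, "kind": kind, "species": species,
                "disease_class": truth.disease_classes.get(entity, "")})
            for k in range(1, config.datasets_per_entity + 1):
                bundle = generate_expression_dataset(
                    sigs[entity], config, ds_rng, name=f"{entity}.ds{k}")
                probe_bundle = _to_probe_matrix(bundle, probe_map, species,
                                                config, ds_rng)
                io.write_matrix(probe_bundle.values,
                                out / "expr" / f"{entity}.ds{k}.tsv")
                io.write_labels(probe_bundle.labels,
                                out / "expr" / f"{entity}.ds{k}.labels.tsv")
    io.write_table(pd.DataFrame(entity_rows), out / "entities.tsv")
    io.write_json(truth.to_json_dict(), out / "truth.json")
    io.write_json({"config": asdict(config)}, out / "config_resolved.json")
    return truth
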