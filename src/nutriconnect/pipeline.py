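"""End-to-end orchestration of the synthetic connectivity-mapping study.

simulate -> preprocess -> differential expression -> enrichment-score
connectivity -> disease clustering -> pathway-space PCA -> network
proximity -> chemical similarity -> synergy. Every stage reads and writes
plain text (TSV / GMT / Newick / JSON) so stages are independently
runnable; a manifest records seeds, stage runtimes and output hashes. One
master seed deterministically derives all stage seeds, making reruns with
the same configuration byte-identical.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemsim, connectivity, io, pathway_space, proximity, synergy
from .preprocess import ProbeMatrix, preprocess
from .rankprod import SignatureRanking, build_signature, write_signature
from .synthetic import SyntheticConfig, simulate


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the study's stated settings
    (FDR 0.05 thresholds, 1,000 ES permutations, 0.4 similarity cutoff)."""

    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    alpha: float = 0.05
    rp_n_perm: int = 200
    es_n_perm: int = 1000
    tag_cap: int = 250
    tag_min: int = 5
    cluster_k: int = 2
    prox_n_random: int = 1000
    prox_bin_min: int = 100
    chem_cutoff: float = 0.4
    synergy_n_perm: int = 1000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        cfg = cls(**d, synthetic=SyntheticConfig(**syn))
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Derive a stable per-stage integer seed (< 2^31) from the master."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    t_all = time.perf_counter()

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(out)): _file_hash(p)
                        for p in outputs if p.exists()},
        }

    # ------------------------------------------------------------ simulate
    t0 = time.perf_counter()
    sim_dir = out / "sim"
    syn_cfg = SyntheticConfig(**{**asdict(config.synthetic),
                                 "seed": stage_seed(config.seed, "simulate")})
    truth = simulate(syn_cfg, sim_dir)
    record("simulate", t0, sorted(sim_dir.glob("*.tsv"))
           + sorted(sim_dir.glob("*.gmt")) + sorted(sim_dir.glob("*.json")))

    # ---------------------------------------------------------- preprocess
    t0 = time.perf_counter()
    pre_dir = out / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    probe_map = io.read_pair_map(sim_dir / "probe_map.tsv")
    orthologs = io.read_pair_map(sim_dir / "ortholog_map.tsv")
    entities = io.read_table(sim_dir / "entities.tsv")
    datasets: dict[str, list] = {}
    for rec in entities.itertuples(index=False):
        datasets[rec.entity] = []
        for path in sorted((sim_dir / "expr").glob(f"{rec.entity}.ds*.tsv")):
            if path.name.endswith(".labels.tsv"):
                continue
            labels = io.read_labels(path.with_name(
                path.name.replace(".tsv", ".labels.tsv")))
            pm = ProbeMatrix(values=io.read_matrix(path), labels=labels,
                             species=rec.species, name=path.stem)
            ds = preprocess(pm, probe_map, orthologs)
            io.write_matrix(ds.values, pre_dir / path.name)
            datasets[rec.entity].append(ds)
    record("preprocess", t0, sorted(pre_dir.glob("*.tsv")))

    # ------------------------------------------------- differential expr.
    t0 = time.perf_counter()
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    signatures: dict[str, SignatureRanking] = {}
    de_seed = stage_seed(config.seed, "de")
    for i, entity in enumerate(sorted(datasets)):
        if not datasets[entity]:
            raise PipelineError("de", f"no datasets for entity {entity}")
        sig = build_signature(datasets[entity], entity=entity,
                              alpha=config.alpha, n_perm=config.rp_n_perm,
                              seed=(de_seed + i) % (2**31))
        signatures[entity] = sig
        write_signature(sig, de_dir / f"{entity}.sig.tsv")
    record("de", t0, sorted(de_dir.glob("*.tsv")))

    kinds = dict(zip(entities["entity"], entities["kind"]))
    foods = {e: s for e, s in signatures.items() if kinds[e] == "food"}
    drugs = {e: s for e, s in signatures.items() if kinds[e] == "drug"}
    diseases = {e: s for e, s in signatures.items() if kinds[e] == "disease"}

    # -------------------------------------------------------------- connect
    t0 = time.perf_counter()
    con_dir = out / "connect"
    con_dir.mkdir(exist_ok=True)
    # foods and drugs are scored (and BH-corrected) as separate batches
    food_results = connectivity.score_pairs(
        foods, diseases, n_perm=config.es_n_perm, alpha=config.alpha,
        cap=config.tag_cap, min_tags=config.tag_min,
        seed=stage_seed(config.seed, "connect-food"))
    drug_results = connectivity.score_pairs(
        drugs, diseases, n_perm=config.es_n_perm, alpha=config.alpha,
        cap=config.tag_cap, min_tags=config.tag_min,
        seed=stage_seed(config.seed, "connect-drug"))
    food_results["query_class"] = "diet"
    drug_results["query_class"] = "drug"
    results = pd.concat([food_results, drug_results], ignore_index=True)
    io.write_table(results, con_dir / "pair_results.tsv")
    food_profile = connectivity.es_profile_matrix(food_results)
    drug_profile = connectivity.es_profile_matrix(drug_results)
    io.write_matrix(food_profile, con_dir / "es_profile_foods.tsv")
    io.write_matrix(drug_profile, con_dir / "es_profile_drugs.tsv")
    known = [(r.drug, r.disease) for r in io.read_table(
        sim_dir / "known_indications.tsv").itertuples(index=False)]
    class_map = dict(zip(entities.loc[entities["kind"] == "disease", "entity"],
                         entities.loc[entities["kind"] == "disease",
                                      "disease_class"]))
    overall, per_class = connectivity.recovery_stats(drug_results, known,
                                                     class_map)
    io.write_json({"overall": overall}, con_dir / "recovery_overall.json")
    io.write_table(per_class, con_dir / "recovery_per_class.tsv")
    record("connect", t0, sorted(con_dir.iterdir()))

    # -------------------------------------------------------------- cluster
    t0 = time.perf_counter()
    clu_dir = out / "cluster"
    clu_dir.mkdir(exist_ok=True)
    outputs = []
    for name, profile in (("foods", food_profile), ("drugs", drug_profile)):
        if profile.shape[0] >= 3:
            _, newick, labels = connectivity.cluster_diseases(
                profile, k=config.cluster_k)
            path = clu_dir / f"diseases_by_{name}.nwk"
            path.write_text(newick + "\n")
            outputs.append(path)
            if labels is not None:
                lp = clu_dir / f"clusters_by_{name}.tsv"
                labels.rename_axis("disease").to_frame().to_csv(lp, sep="\t")
                outputs.append(lp)
    record("cluster", t0, outputs)

    # ------------------------------------------------------------- pathways
    t0 = time.perf_counter()
    pw_dir = out / "pathways"
    pw_dir.mkdir(exist_ok=True)
    pathways = io.read_gmt(sim_dir / "pathways.gmt")
    functions = io.read_gmt(sim_dir / "functions.gmt")
    enriched: dict[str, set[str]] = {}
    fun_enriched: dict[str, set[str]] = {}
    for entity, sig in signatures.items():
        universe = set(sig.table.index)
        de_genes = sig.up_set | sig.down_set
        coll = pathway_space.PathwayCollection(
            pathways={k: set(v) for k, v in pathways.items()},
            universe=universe)
        enr = pathway_space.enrich_pathways(de_genes, coll, alpha=config.alpha)
        enriched[entity] = pathway_space.enriched_set(enr)
        fcoll = pathway_space.PathwayCollection(
            pathways={k: set(v) for k, v in functions.items()},
            universe=universe)
        fun_enriched[entity] = pathway_space.enriched_set(
            pathway_space.enrich_pathways(de_genes, fcoll, alpha=config.alpha))
    io.write_gmt(enriched, pw_dir / "enriched_pathways.gmt")

    anti = results[results["class"] == "anti-correlated"]
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in anti.itertuples(index=False):
        cls = class_map.get(rec.reference, "")
        ecls = "diet" if rec.query_class == "diet" else "drug"
        groups.setdefault((cls, ecls), [])
        if rec.query not in groups[(cls, ecls)]:
            groups[(cls, ecls)].append(rec.query)
    pathway_names = sorted(pathways)
    score_matrix = pathway_space.build_score_matrix(enriched, groups,
                                                    pathway_names)
    io.write_matrix(score_matrix, pw_dir / "score_matrix.tsv")
    pca_summary = {}
    if score_matrix.shape[0] >= 3:
        coords, var_frac, top = pathway_space.pca_scores(score_matrix)
        io.write_matrix(coords, pw_dir / "pca_coordinates.tsv")
        var_frac.to_frame().to_csv(pw_dir / "pca_variance.tsv", sep="\t",
                                   float_format="%.6g")
        top.rename("contribution").to_frame().to_csv(
            pw_dir / "pca_top_pathways.tsv", sep="\t", float_format="%.6g")
        pca_summary = {"pc1_pc2_variance_fraction":
                       float(var_frac.iloc[:2].sum())}
    io.write_json(pca_summary, pw_dir / "pca_summary.json")
    record("pathways", t0, sorted(pw_dir.iterdir()))

    # ------------------------------------------------------------ proximity
    t0 = time.perf_counter()
    px_dir = out / "proximity"
    px_dir.mkdir(exist_ok=True)
    net_path = sim_dir / "interactome.tsv"
    if not net_path.exists():
        raise PipelineError("proximity", f"missing network file {net_path}")
    net = proximity.Interactome(io.read_edge_list(net_path))
    modules = io.read_gmt(sim_dir / "disease_modules.gmt")
    px_seed = stage_seed(config.seed, "proximity")
    prox_results = []
    entity_class = {}
    for i, rec in enumerate(anti.sort_values(["query", "reference"])
                            .itertuples(index=False)):
        de_nodes = signatures[rec.query].up_set | signatures[rec.query].down_set
        module = modules.get(rec.reference, set())
        try:
            res = proximity.proximity_z(
                de_nodes, module, net, n_random=config.prox_n_random,
                bin_min=config.prox_bin_min, seed=(px_seed + i) % (2**31),
                entity=rec.query, disease=rec.reference)
        except ValueError:
            continue
        prox_results.append(res)
        entity_class[rec.query] = rec.query_class
    prox_df, fisher = proximity.classify_proximal(prox_results, entity_class)
    io.write_table(prox_df, px_dir / "proximity.tsv")
    io.write_json({"fisher": fisher}, px_dir / "diet_vs_drug_fisher.json")
    record("proximity", t0, sorted(px_dir.iterdir()))

    # -------------------------------------------------------------- chemsim
    t0 = time.perf_counter()
    ch_dir = out / "chemsim"
    ch_dir.mkdir(exist_ok=True)
    food_cmpd = io.read_table(sim_dir / "food_compounds.tsv")
    drug_cmpd = io.read_table(sim_dir / "drug_compounds.tsv")
    sim_pairs, edges = chemsim.similar_food_drug_pairs(
        food_cmpd, drug_cmpd, cutoff=config.chem_cutoff)
    io.write_table(sim_pairs, ch_dir / "similar_pairs.tsv")
    io.write_table(edges, ch_dir / "similarity_edges.tsv")
    similar = {(r.food, r.drug) for r in sim_pairs.itertuples(index=False)}
    all_fd = {(f, d) for f in foods for d in drugs}
    sim_counts, oth_counts, ranksum_p = chemsim.compare_shared_diseases(
        sorted(similar), sorted(all_fd - similar), results)
    io.write_json({"n_similar_pairs": len(similar),
                   "shared_anti_similar": sim_counts,
                   "shared_anti_other": oth_counts,
                   "ranksum_p": ranksum_p},
                  ch_dir / "shared_disease_comparison.json")
    record("chemsim", t0, sorted(ch_dir.iterdir()))

    # -------------------------------------------------------------- synergy
    t0 = time.perf_counter()
    sy_dir = out / "synergy"
    sy_dir.mkdir(exist_ok=True)
    food_names = sorted(foods)
    cores = {}
    rank4: dict[tuple[str, str], float | None] = {}
    sim_rows = {}
    import itertools as _it
    for fa, fb in _it.combinations(food_names, 2):
        core = synergy.core_gene_set(foods[fa], foods[fb])
        cores[(fa, fb)] = core
        rank4[(fa, fb)] = synergy.rank4_score(core)
        sim_rows[(fa, fb)] = {
            "expression": rank4[(fa, fb)],
            "pathway_jaccard": synergy.jaccard(enriched.get(fa, set()),
                                               enriched.get(fb, set())),
            "function_jaccard": synergy.jaccard(fun_enriched.get(fa, set()),
                                                fun_enriched.get(fb, set()))}
    calls = synergy.call_synergy(cores, n_perm=config.synergy_n_perm,
                                 seed=stage_seed(config.seed, "synergy"),
                                 alpha=config.alpha)
    similarities = pd.DataFrame.from_dict(sim_rows, orient="index")
    rank9 = synergy.rank9_aggregate(similarities)
    gold = synergy.build_gold_standard(
        io.read_table(sim_dir / "reference_associations.tsv"))
    recovery = synergy.evaluate_recovery(calls, rank4, rank9, gold)
    shared, ranksum_p_syn, corr = synergy.synergy_downstream(
        calls, food_results)
    calls_out = calls.copy()
    calls_out["rank4"] = [rank4[(a, b)] for a, b in
                          zip(calls_out["food_a"], calls_out["food_b"])]
    calls_out["rank9_rank"] = [
        float(rank9.get((a, b), np.nan)) for a, b in
        zip(calls_out["food_a"], calls_out["food_b"])]
    calls_out["gold"] = [tuple(sorted((a, b))) in
                         {tuple(sorted(p)) for p in gold}
                         for a, b in zip(calls_out["food_a"],
                                         calls_out["food_b"])]
    io.write_table(calls_out, sy_dir / "synergy_scores.tsv")
    io.write_table(shared, sy_dir / "shared_anti_diseases.tsv")
    io.write_table(corr, sy_dir / "es_profile_correlations.tsv")
    io.write_json({"recovery": recovery, "ranksum_p": ranksum_p_syn,
                   "gold_pairs": sorted(map(list, gold))},
                  sy_dir / "summary.json")
    record("synergy", t0, sorted(sy_dir.iterdir()))

    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    manifest["truth_synergy_pairs"] = sorted(map(list, truth.synergy_pairs))
    io.write_json(manifest, out / "manifest.json")
    return manifest
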