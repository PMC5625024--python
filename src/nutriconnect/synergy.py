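"""Transcriptional synergy prediction for food pairs.

Three scores over the pair's core genes (genes significantly DE in at
least one of the two foods): a directional-overlap interaction score
("rank 2": concordant minus discordant shared DE calls over the core
size), the Pearson correlation of the two fold-change profiles on the core
("rank 4"), and a Borda rank aggregation of expression correlation with
pathway- and function-overlap Jaccard indices ("rank 9"). Synergy calls
use a per-pair permutation null on the direction calls; the gold standard
is built from a literature-style (food, disease, reference_count) table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .rankprod import SignatureRanking
from .stats import ranksum_two_sided


@dataclass
class CoreGeneSet:
    pair: tuple[str, str]
    genes: list[str]
    calls_a: np.ndarray   # +1 / -1 / 0 per core gene
    calls_b: np.ndarray
    logfc_a: np.ndarray
    logfc_b: np.ndarray


def core_gene_set(sig_a: SignatureRanking,
                  sig_b: SignatureRanking) -> CoreGeneSet:
    """Genes significantly DE in at least one food, with per-food calls."""
    def calls(sig: SignatureRanking) -> dict[str, int]:
        return {**{g: 1 for g in sig.up_set}, **{g: -1 for g in sig.down_set}}

    ca, cb = calls(sig_a), calls(sig_b)
    genes = sorted(set(ca) | set(cb))
    shared_index = sig_a.table.index.intersection(sig_b.table.index)
    genes = [g for g in genes if g in shared_index]
    return CoreGeneSet(
        pair=(sig_a.entity, sig_b.entity), genes=genes,
        calls_a=np.array([ca.get(g, 0) for g in genes]),
        calls_b=np.array([cb.get(g, 0) for g in genes]),
        logfc_a=sig_a.table.loc[genes, "logfc"].to_numpy(),
        logfc_b=sig_b.table.loc[genes, "logfc"].to_numpy(),
    )


def rank2_score(core: CoreGeneSet) -> float | None:
    """(concordant - discordant both-DE genes) / |core|, in [-1, 1]."""
    n = len(core.genes)
    if n == 0:
        return None
    both = (core.calls_a != 0) & (core.calls_b != 0)
    concordant = int(np.sum(both & (core.calls_a == core.calls_b)))
    discordant = int(np.sum(both & (core.calls_a != core.calls_b)))
    return (concordant - discordant) / n


def rank4_score(core: CoreGeneSet) -> float | None:
    """Pearson correlation of the two logfc profiles on the core genes."""
    if len(core.genes) < 3:
        return None
    if np.std(core.logfc_a) == 0 or np.std(core.logfc_b) == 0:
        warnings.warn(f"zero-variance profile in pair {core.pair}; unscored")
        return None
    return float(pearsonr(core.logfc_a, core.logfc_b)[0])


def rank9_aggregate(similarities: pd.DataFrame) -> pd.Series:
    """Borda aggregation: mean of the three per-similarity descending
    ranks (average ranks on ties), smaller aggregated rank = more similar.

    ``similarities`` is indexed by pair with columns expression,
    pathway_jaccard, function_jaccard; rows with any missing similarity
    are excluded.
    """
    complete = similarities.dropna()
    dropped = len(similarities) - len(complete)
    if dropped:
        warnings.warn(f"{dropped} pair(s) lacking a similarity excluded")
    ranks = complete.rank(ascending=False, method="average")
    agg = ranks.mean(axis=1).rename("rank9")
    return agg.sort_values(kind="mergesort")


def jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def call_synergy(cores: dict[tuple[str, str], CoreGeneSet],
                 n_perm: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Permutation-based synergy calls on the rank-2 score.

    The per-pair null permutes each food's direction calls over the core
    gene identities; a pair is synergistic when its score is positive and
    the add-one upper-tail p is below alpha.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pair in sorted(cores):
        core = cores[pair]
        obs = rank2_score(core)
        if obs is None:
            rows.append({"food_a": pair[0], "food_b": pair[1],
                         "rank2": np.nan, "p_value": np.nan, "call": False})
            continue
        n = len(core.genes)
        perm_a = rng.permuted(np.tile(core.calls_a, (n_perm, 1)), axis=1)
        perm_b = rng.permuted(np.tile(core.calls_b, (n_perm, 1)), axis=1)
        both = (perm_a != 0) & (perm_b != 0)
        concordant = np.sum(both & (perm_a == perm_b), axis=1)
        discordant = np.sum(both & (perm_a != perm_b), axis=1)
        null = (concordant - discordant) / n
        p = (np.sum(null >= obs) + 1.0) / (n_perm + 1.0)
        rows.append({"food_a": pair[0], "food_b": pair[1], "rank2": obs,
                     "p_value": p, "call": bool(obs > 0 and p < alpha)})
    return pd.DataFrame(rows)


def build_gold_standard(reference_table: pd.DataFrame) -> set[tuple[str, str]]:
    """Gold pairs: share >=1 disease association and joint reference count
    over the shared diseases strictly above 10."""
    by_food: dict[str, dict[str, float]] = {}
    for rec in reference_table.itertuples(index=False):
        by_food.setdefault(rec.food, {})[rec.disease] = rec.reference_count
    gold = set()
    for fa, fb in itertools.combinations(sorted(by_food), 2):
        shared = by_food[fa].keys() & by_food[fb].keys()
        if not shared:
            continue
        total = sum(by_food[fa][d] + by_food[fb][d] for d in shared)
        if total > 10:
            gold.add((fa, fb))
    return gold


def evaluate_recovery(calls: pd.DataFrame,
                      rank4: dict[tuple[str, str], float | None],
                      rank9: pd.Series,
                      gold_pairs: set[tuple[str, str]]) -> dict:
    """Gold pairs recovered per method.

    Rank 2 counts gold pairs among its synergy calls; the score-only
    methods are evaluated on their top-k pairs with k equal to the number
    of rank-2 calls, for comparability.
    """
    if not gold_pairs:
        warnings.warn("empty gold-standard set")
    called = {tuple(sorted((r.food_a, r.food_b)))
              for r in calls.itertuples(index=False) if r.call}
    k = len(called)
    gold = {tuple(sorted(p)) for p in gold_pairs}

    r4 = pd.Series({p: v for p, v in rank4.items() if v is not None})
    top4 = {tuple(sorted(p))
            for p in r4.sort_values(ascending=False).head(k).index}
    top9 = {tuple(sorted(p)) for p in rank9.head(k).index}
    return {
        "n_gold": len(gold),
        "n_calls_rank2": k,
        "recovered_rank2": len(called & gold),
        "recovered_rank4": len(top4 & gold),
        "recovered_rank9": len(top9 & gold),
    }


def synergy_downstream(calls: pd.DataFrame, pair_results: pd.DataFrame):
    """(a) Shared anti-correlated disease counts, synergistic vs not, with
    a Wilcoxon rank-sum p; (b) per synergistic pair, the Pearson
    correlation of the two foods' ES profiles across diseases."""
    anti = pair_results[pair_results["class"] == "anti-correlated"]
    anti_map: dict[str, set[str]] = {}
    for rec in anti.itertuples(index=False):
        anti_map.setdefault(rec.query, set()).add(rec.reference)
    es_wide = pair_results.pivot(index="query", columns="reference",
                                 values="es")

    shared_rows = []
    for rec in calls.itertuples(index=False):
        a, b = rec.food_a, rec.food_b
        shared_rows.append({
            "food_a": a, "food_b": b, "call": rec.call,
            "n_shared_anti": len(anti_map.get(a, set())
                                 & anti_map.get(b, set()))})
    shared = pd.DataFrame(shared_rows)
    syn = shared.loc[shared["call"], "n_shared_anti"]
    non = shared.loc[~shared["call"], "n_shared_anti"]
    ranksum_p = None
    if len(syn) and len(non):
        ranksum_p = ranksum_two_sided(syn.tolist(), non.tolist())

    corr_rows = []
    for rec in calls.itertuples(index=False):
        if not rec.call:
            continue
        if rec.food_a not in es_wide.index or rec.food_b not in es_wide.index:
            continue
        va = es_wide.loc[rec.food_a]
        vb = es_wide.loc[rec.food_b]
        mask = va.notna() & vb.notna()
        if mask.sum() < 3 or va[mask].std() == 0 or vb[mask].std() == 0:
            continue
        r, p = pearsonr(va[mask], vb[mask])
        corr_rows.append({"food_a": rec.food_a, "food_b": rec.food_b,
                          "es_profile_r": float(r), "p_value": float(p),
                          "significant": bool(p < 0.05)})
    return shared, ranksum_p, pd.DataFrame(corr_rows)
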