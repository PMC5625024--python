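"""Bidirectional KS enrichment scoring of perturbation-disease pairs.

The connectivity-mapping statistic: a query's up- and down-regulated tag
sets are located in a reference fold-change-ranked gene list; a
Kolmogorov-Smirnov running-sum statistic per tag set is combined into an
enrichment score es in [-1, 1]. Positive es means the query's signature
runs with the reference (correlated pair); negative es means the query
reverses it (anti-correlated pair, the therapeutic hypothesis).
Significance comes from random tag sets of the observed sizes, with BH-FDR
across the scored batch, and diseases are clustered on their es profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .rankprod import SignatureRanking

TAG_CAP = 250
TAG_MIN = 5


@dataclass
class QuerySignature:
    up_tags: list[str]
    down_tags: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        if set(self.up_tags) & set(self.down_tags):
            raise ValueError("up and down tag sets must be disjoint")


def query_from_signature(sig: SignatureRanking, cap: int = TAG_CAP,
                         min_tags: int = TAG_MIN) -> QuerySignature | None:
    """Tag sets = significant DE genes per direction ranked by |logfc|,
    capped at ``cap``; entities with fewer than ``min_tags`` in either
    direction are not scorable (returns None)."""
    t = sig.table
    by_mag = lambda genes: sorted(genes, key=lambda g: (-abs(t.at[g, "logfc"]), g))
    up = by_mag(sig.up_set)[:cap]
    down = by_mag(sig.down_set)[:cap]
    if len(up) < min_tags or len(down) < min_tags:
        return None
    return QuerySignature(up_tags=up, down_tags=down, source=sig.entity)


def ks_tag_score(tags, ranked_list) -> float:
    """KS running-sum tag statistic on 1-based positions in a ranked list.

    With pos(1..t) the ascending positions of the t tags in a list of
    length n: a = max_j(j/t - pos_j/n), b = max_j(pos_j/n - (j-1)/t);
    the score is a if a >= b else -b. Positive scores mean tags pile up at
    the top of the list. Tags covering the whole list carry no positional
    information and score 0.
    """
    index = {g: i + 1 for i, g in enumerate(ranked_list)}
    present = [g for g in tags if g in index]
    if len(present) < len(list(tags)):
        warnings.warn("tags absent from the ranked list were dropped")
    if not present:
        raise ValueError("no tags present in the ranked list")
    n = len(ranked_list)
    pos = np.sort(np.array([index[g] for g in present], dtype=float))
    t = len(pos)
    if t == n:
        return 0.0
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a) if a >= b else float(-b)


def _ks_matrix(pos: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ks_tag_score for a (draws x t) matrix of sorted 1-based
    positions."""
    t = pos.shape[1]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - pos / n, axis=1)
    b = np.max(pos / n - (j - 1) / t, axis=1)
    return np.where(a >= b, a, -b)


def _combine(ks_up, ks_down):
    """Same-sign rule: a signature concordant in both tag sets is not a
    directional signal, so matching signs score 0."""
    same = np.sign(ks_up) == np.sign(ks_down)
    return np.where(same, 0.0, (ks_up - ks_down) / 2.0)


def directional_es(query: QuerySignature,
                   reference_ranking: SignatureRanking) -> float:
    """ES of one query signature against one reference ranked list."""
    ranked = reference_ranking.genes
    ks_up = ks_tag_score(query.up_tags, ranked)
    ks_down = ks_tag_score(query.down_tags, ranked)
    return float(_combine(np.array(ks_up), np.array(ks_down)))


def pair_es(entity_a: SignatureRanking, entity_b: SignatureRanking,
            cap: int = TAG_CAP, min_tags: int = TAG_MIN) -> float | None:
    """Bidirectional ES: mean of a-tags-in-b-list and b-tags-in-a-list.

    Returns None when either entity lacks scorable tag sets.
    """
    qa = query_from_signature(entity_a, cap, min_tags)
    qb = query_from_signature(entity_b, cap, min_tags)
    if qa is None or qb is None:
        return None
    return (directional_es(qa, entity_b) + directional_es(qb, entity_a)) / 2.0


def _null_directional(rng: np.random.Generator, n_ref: int, t_up: int,
                      t_down: int, n_perm: int) -> np.ndarray:
    """n_perm ES values for random query tag sets of the observed sizes,
    sampled without replacement from the reference list."""
    t = t_up + t_down
    u = rng.random((n_perm, n_ref))
    picks = np.argpartition(u, t - 1, axis=1)[:, :t]
    pos_up = np.sort(picks[:, :t_up], axis=1) + 1.0
    pos_down = np.sort(picks[:, t_up:], axis=1) + 1.0
    return _combine(_ks_matrix(pos_up, n_ref), _ks_matrix(pos_down, n_ref))


def permutation_significance(pairs: pd.DataFrame,
                             rankings: dict[str, SignatureRanking],
                             n_perm: int = 1000, alpha: float = 0.05,
                             cap: int = TAG_CAP, min_tags: int = TAG_MIN,
                             seed: int = 0) -> pd.DataFrame:
    """Two-sided permutation p per pair plus BH-FDR and correlation class.

    ``pairs`` needs columns query, reference, es. Per pair the null draws
    random up/down tag sets of the observed capped sizes for both
    directions and combines them exactly as the observed score was.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse ES null")
    rng = np.random.default_rng(seed)
    p_values = []
    for row in pairs.itertuples(index=False):
        sig_a, sig_b = rankings[row.query], rankings[row.reference]
        qa = query_from_signature(sig_a, cap, min_tags)
        qb = query_from_signature(sig_b, cap, min_tags)
        if qa is None or qb is None or not np.isfinite(row.es):
            p_values.append(np.nan)
            continue
        null_ab = _null_directional(rng, len(sig_b.table), len(qa.up_tags),
                                    len(qa.down_tags), n_perm)
        null_ba = _null_directional(rng, len(sig_a.table), len(qb.up_tags),
                                    len(qb.down_tags), n_perm)
        null = (null_ab + null_ba) / 2.0
        p = (np.sum(np.abs(null) >= abs(row.es)) + 1.0) / (n_perm + 1.0)
        p_values.append(p)
    out = pairs.copy()
    out["p_value"] = p_values
    scored = out["p_value"].notna()
    fdr = np.full(len(out), np.nan)
    if scored.any():
        fdr[scored.to_numpy()] = multipletests(
            out.loc[scored, "p_value"], method="fdr_bh")[1]
    out["fdr"] = fdr
    cls = np.where(~scored, "unscored",
                   np.where((out["fdr"] < alpha) & (out["es"] < 0),
                            "anti-correlated",
                            np.where((out["fdr"] < alpha) & (out["es"] > 0),
                                     "correlated", "not-significant")))
    out["class"] = cls
    return out


def score_pairs(queries: dict[str, SignatureRanking],
                references: dict[str, SignatureRanking],
                n_perm: int = 1000, alpha: float = 0.05, cap: int = TAG_CAP,
                min_tags: int = TAG_MIN, seed: int = 0) -> pd.DataFrame:
    """ES + significance for every (query, reference) combination."""
    rows = []
    for q in sorted(queries):
        for r in sorted(references):
            es = pair_es(queries[q], references[r], cap, min_tags)
            rows.append({"query": q, "reference": r,
                         "es": np.nan if es is None else es})
    pairs = pd.DataFrame(rows)
    rankings = dict(queries)
    rankings.update(references)
    return permutation_significance(pairs, rankings, n_perm=n_perm,
                                    alpha=alpha, cap=cap, min_tags=min_tags,
                                    seed=seed)


def es_profile_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Disease (reference) x entity (query) matrix of es values."""
    return results.pivot(index="reference", columns="query", values="es")


def cluster_diseases(profile: pd.DataFrame, k: int | None = None):
    """Average-linkage clustering of diseases on 1 - Pearson distance.

    Missing entries are imputed as 0 (no signal) for clustering only; a
    zero-variance profile row is put at the maximum distance 2 from every
    other row. Returns (linkage matrix, newick string, flat labels or None).
    """
    if profile.shape[0] < 3:
        raise ValueError("need at least 3 diseases to cluster")
    filled = profile.fillna(0.0)
    mat = filled.to_numpy()
    sd = mat.std(axis=1)
    n = len(filled)
    dist = np.full((n, n), 2.0)
    np.fill_diagonal(dist, 0.0)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(mat[ok])
        sub = np.atleast_2d(sub)
        idx = np.where(ok)[0]
        dist[np.ix_(idx, idx)] = 1.0 - sub
    if (~ok).any():
        warnings.warn("zero-variance profile rows set to maximum distance")
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    newick = _linkage_to_newick(z, list(filled.index))
    labels = None
    if k is not None:
        labels = pd.Series(fcluster(z, t=k, criterion="maxclust"),
                           index=filled.index, name="cluster")
    return z, newick, labels


def _linkage_to_newick(z: np.ndarray, names: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, names)
    return str(tree).strip()


def recovery_stats(results: pd.DataFrame,
                   known_indications: list[tuple[str, str]],
                   class_map: dict[str, str] | None = None):
    """Recovery of known (query, disease) indications by anti-correlation.

    Returns (overall table, per-class DataFrame with 2x2 Fisher tests).
    The per-class 2x2 crosses known-indication membership against
    anti-correlated classification over all scored pairs of that class.
    """
    scored = results[results["class"] != "unscored"].copy()
    valid_refs = set(scored["reference"])
    known = set()
    for q, d in known_indications:
        if d in valid_refs:
            known.add((q, d))
        else:
            warnings.warn(f"unknown disease {d!r} in indication list; skipped")
    scored["known"] = [
        (q, r) in known for q, r in zip(scored["query"], scored["reference"])]
    scored["recovered"] = scored["class"] == "anti-correlated"
    overall = {
        "n_known": len(known),
        "n_recovered": int((scored["known"] & scored["recovered"]).sum()),
    }
    class_rows = []
    if class_map:
        scored["disease_class"] = scored["reference"].map(class_map)
        for cls, grp in scored.groupby("disease_class"):
            a = int((grp["known"] & grp["recovered"]).sum())
            b = int((grp["known"] & ~grp["recovered"]).sum())
            c = int((~grp["known"] & grp["recovered"]).sum())
            d = int((~grp["known"] & ~grp["recovered"]).sum())
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            class_rows.append({"disease_class": cls, "known_recovered": a,
                               "known_missed": b, "other_recovered": c,
                               "other_missed": d, "fisher_p": p})
    return overall, pd.DataFrame(class_rows)
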