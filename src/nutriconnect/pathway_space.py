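"""Pathway over-representation and pathway-space PCA.

Each entity's DE genes are tested for over-representation in a pathway
collection (one-sided hypergeometric, BH-FDR). For the anti-correlated
pairs only, a (disease class x entity class) by pathway score matrix holds
the proportion of entities of the group whose signature is enriched for
the pathway; PCA of that matrix separates diet mechanism space from drug
mechanism space, and the intersection of entity and disease enrichment
defines disease-related pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class PathwayCollection:
    pathways: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.pathways.values()) - self.universe \
            if self.pathways else set()
        if stray:
            # clip pathway members to the declared universe
            self.pathways = {n: s & self.universe
                             for n, s in self.pathways.items()}


def enrich_pathways(de_genes: set[str], collection: PathwayCollection,
                    alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH-FDR.

    p = P(X >= k), X ~ Hypergeom(N=|universe|, K=|pathway|, n=|de_genes|),
    k = |overlap|. Returns one row per pathway with an ``enriched`` flag.
    """
    universe = collection.universe
    outside = de_genes - universe
    if outside:
        warnings.warn(f"{len(outside)} DE gene(s) outside the universe dropped")
    de = de_genes & universe
    rows = []
    N, n = len(universe), len(de)
    for name in sorted(collection.pathways):
        members = collection.pathways[name]
        K = len(members)
        k = len(de & members)
        p = 1.0 if n == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(fdr=[], enriched=[])
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["enriched"] = df["fdr"] < alpha
    return df


def enriched_set(enrichment: pd.DataFrame) -> set[str]:
    if enrichment.empty:
        return set()
    return set(enrichment.loc[enrichment["enriched"], "pathway"])


def build_score_matrix(enrichments: dict[str, set[str]],
                       groups: dict[tuple[str, str], list[str]],
                       pathway_names: list[str]) -> pd.DataFrame:
    """Proportion-of-entities-enriched score matrix.

    ``groups`` maps (disease_class, entity_class) -> entities whose pairs
    with that disease class are anti-correlated; each cell is the fraction
    of the group's entities enriched for the pathway.
    """
    rows = {}
    for (disease_class, entity_class), entities in sorted(groups.items()):
        entities = [e for e in entities if e in enrichments]
        if not entities:
            warnings.warn(
                f"group ({disease_class}, {entity_class}) has no entities; "
                "row omitted")
            continue
        counts = np.array([[1.0 if p in enrichments[e] else 0.0
                            for p in pathway_names] for e in entities])
        rows[f"{disease_class}|{entity_class}"] = counts.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=pathway_names)


def pca_scores(matrix: pd.DataFrame, n_top: int = 30):
    """PCA of the score matrix: centered columns, no scaling (entries are
    commensurable proportions).

    Returns (coordinates on all PCs, variance fractions, top contributing
    pathways by squared loading summed over PC1-PC2).
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need >=3 rows and >=2 columns for PCA")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention: largest |loading| positive
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    coords = pd.DataFrame(u * s, index=matrix.index,
                          columns=[f"PC{i+1}" for i in range(len(s))])
    loadings = pd.DataFrame(vt.T, index=matrix.columns,
                            columns=coords.columns)
    n_pc = min(2, loadings.shape[1])
    contribution = (loadings.iloc[:, :n_pc]**2).sum(axis=1)
    top = contribution.sort_values(ascending=False).head(n_top)
    return coords, pd.Series(var_frac, index=coords.columns,
                             name="variance_fraction"), top


def disease_related_pathways(entity_enrichment: set[str],
                             disease_enrichment: set[str]) -> set[str]:
    """Pathways enriched in both an entity's and a disease's signature."""
    return entity_enrichment & disease_enrichment


def top_shared_pathways(entity_enrichments: dict[str, set[str]],
                        disease_enrichment: set[str],
                        n_top: int = 3) -> pd.DataFrame:
    """Rank pathways shared with a disease by how many (anti-correlated)
    entities carry them; report the top ``n_top``."""
    counts: dict[str, int] = {}
    for enr in entity_enrichments.values():
        for p in disease_related_pathways(enr, disease_enrichment):
            counts[p] = counts.get(p, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top]
    return pd.DataFrame(rows, columns=["pathway", "n_entities"])
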