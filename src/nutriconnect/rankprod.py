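"""Rank-product differential-expression meta-analysis.

Combines an entity's replicate case/control datasets (possibly from
different platforms) into one signature: per-dataset log2 fold changes are
converted to ranks, the rank product RP_g = (prod_i r_{g,i})^(1/k_g) is a
nonparametric meta-statistic whose significance is assessed against random
rank permutations, yielding a per-gene estimated false-discovery
proportion (pfp). Genes are finally ordered by combined fold change.

Being rank-based, the statistic is invariant to any strictly increasing
transform of a dataset's values, which is what lets heterogeneous
platforms be combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class SignatureRanking:
    """Per-entity DE summary: fold-change ranking plus RP calls."""

    entity: str
    table: pd.DataFrame  # index gene; logfc, rp_up, rp_down, pfp_up, pfp_down, call

    @property
    def genes(self) -> list[str]:
        """Genes ordered by combined logfc descending (rank 1 = most up).

        Ties are broken by gene id so the ordering is deterministic.
        """
        t = self.table
        order = sorted(t.index, key=lambda g: (-t.at[g, "logfc"], g))
        return order

    @property
    def up_set(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down_set(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])


def fold_changes(datasets) -> pd.DataFrame:
    """Per-dataset log2 fold change, mean(case) - mean(control), on the
    union gene index (NaN where a gene is absent from a dataset)."""
    cols = {}
    for i, ds in enumerate(datasets):
        case = ds.labels[ds.labels == "case"].index
        ctrl = ds.labels[ds.labels == "control"].index
        if len(case) == 0 or len(ctrl) == 0:
            raise ValueError(
                f"dataset {ds.name or i} lacks case or control samples")
        fc = ds.values[list(case)].mean(axis=1) - ds.values[list(ctrl)].mean(axis=1)
        key = ds.name or f"ds{i}"
        if key in cols:  # replicate datasets may share a name
            key = f"{key}#{i}"
        cols[key] = fc
    return pd.DataFrame(cols)


def _rank_matrix(fc: pd.DataFrame, direction: str) -> np.ndarray:
    """Per-dataset ranks (1 = most extreme), average ranks on ties, NaN
    where a gene is absent."""
    sign = -1.0 if direction == "up" else 1.0
    out = np.full(fc.shape, np.nan)
    vals = fc.to_numpy()
    for j in range(fc.shape[1]):
        col = vals[:, j]
        present = ~np.isnan(col)
        out[present, j] = rankdata(sign * col[present], method="average")
    return out


def rank_product(datasets, direction: str = "up",
                 min_dataset_fraction: float = 0.5) -> pd.Series:
    """RP_g = geometric mean of g's fold-change ranks across datasets.

    Genes present in fewer than ``min_dataset_fraction`` of the datasets
    are excluded.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    fc = fold_changes(datasets)
    ranks = _rank_matrix(fc, direction)
    k_g = np.sum(~np.isnan(ranks), axis=1)
    keep = k_g >= min_dataset_fraction * fc.shape[1]
    with np.errstate(invalid="ignore"):
        rp = np.exp(np.nanmean(np.log(ranks), axis=1))
    return pd.Series(rp[keep], index=fc.index[keep], name=f"rp_{direction}")


def rp_significance(rp: pd.Series, rank_sizes: list[int], n_perm: int = 200,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Permutation p and pfp for observed rank products.

    The null pools RP values from ``n_perm`` independent uniform
    permutations of each dataset's rank vector (all genes x permutations),
    p_g = (#null <= RP_g + 1)/(n_genes*n_perm + 1), and
    pfp_g = p_g * n_genes / rank(RP_g ascending).
    ``rank_sizes`` gives the number of ranked genes per dataset.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse rank-product null")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    n_genes = len(rp)
    k = len(rank_sizes)
    log_null = np.zeros((n_perm, n_genes))
    for sz in rank_sizes:
        if sz >= n_genes:
            base = np.tile(np.arange(1.0, sz + 1), (n_perm, 1))
            perms = rng.permuted(base, axis=1)[:, :n_genes]
        else:
            # dataset ranked fewer genes than the union: uniform ranks
            perms = rng.integers(1, sz + 1, size=(n_perm, n_genes)).astype(float)
        log_null += np.log(perms)
    null_rp = np.exp(log_null / k).ravel()
    null_rp.sort()
    counts = np.searchsorted(null_rp, rp.to_numpy(), side="right")
    p = (counts + 1.0) / (null_rp.size + 1.0)
    asc_rank = rankdata(rp.to_numpy(), method="average")
    pfp = p * n_genes / asc_rank
    return pd.DataFrame({"p": p, "pfp": pfp}, index=rp.index)


def build_signature(datasets, entity: str = "", alpha: float = 0.05,
                    n_perm: int = 200,
                    seed: int | np.random.Generator = 0) -> SignatureRanking:
    """Full signature: combined logfc ranking plus up/down DE calls.

    A gene significant in both directions is assigned to the direction
    with the smaller pfp (tie broken by the sign of its combined logfc),
    keeping the up and down sets disjoint.
    """
    fc = fold_changes(datasets)
    rp_up = rank_product(datasets, "up")
    rp_down = rank_product(datasets, "down")
    sizes = [int((~fc[c].isna()).sum()) for c in fc.columns]
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    if seed_int is None:
        seed_int = int(seed.integers(2**31))
    # one shared null pool for both directions: label reversal then swaps
    # the up and down sets exactly
    sig_up = rp_significance(rp_up, sizes, n_perm=n_perm, seed=seed_int)
    sig_down = rp_significance(rp_down, sizes, n_perm=n_perm, seed=seed_int)

    genes = rp_up.index
    logfc = fc.loc[genes].mean(axis=1)
    pfp_up = sig_up["pfp"]
    pfp_down = sig_down["pfp"]
    call = pd.Series("ns", index=genes, dtype=object)
    up_ok = pfp_up.clip(upper=np.inf) <= alpha
    down_ok = pfp_down <= alpha
    both = up_ok & down_ok
    call[up_ok & ~both] = "up"
    call[down_ok & ~both] = "down"
    if both.any():
        prefer_up = (pfp_up[both] < pfp_down[both]) | (
            (pfp_up[both] == pfp_down[both]) & (logfc[both] >= 0))
        call[both] = np.where(prefer_up, "up", "down")
    table = pd.DataFrame({
        "logfc": logfc, "rp_up": rp_up, "rp_down": rp_down,
        "p_up": sig_up["p"], "p_down": sig_down["p"],
        "pfp_up": pfp_up, "pfp_down": pfp_down, "call": call,
    })
    table = table.sort_values(["logfc"], ascending=False,
                              kind="mergesort")
    table = table.loc[sorted(table.index,
                             key=lambda g: (-table.at[g, "logfc"], g))]
    if not (table["call"] != "ns").any():
        warnings.warn(f"no significant DE genes for {entity or 'entity'}")
    table.index.name = "gene"
    return SignatureRanking(entity=entity, table=table)


def write_signature(sig: SignatureRanking, path) -> None:
    sig.table.to_csv(path, sep="\t", float_format="%.6g")


def read_signature(path, entity: str = "") -> SignatureRanking:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureRanking(entity=entity, table=table)
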