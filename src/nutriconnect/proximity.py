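"""Interactome closest-distance proximity with a degree-matched null.

d_c(T, S) is the average over the entity's DE genes T of the shortest-path
hop distance to the nearest disease gene in S, measured on the largest
connected component of the interactome. Significance is a z-score against
random node sets matched to the degree distributions of both T and S
(degree bins merged upward until each holds at least ``bin_min`` nodes);
z_c < 0 means the entity is closer to the disease module than chance
("proximal").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.stats import fisher_exact


@dataclass
class ProximityResult:
    entity: str
    disease: str
    d_c: float
    null_mean: float
    null_sd: float
    z_c: float
    n_mapped_entity: int
    n_mapped_disease: int
    degenerate: bool = False

    @property
    def label(self) -> str:
        # boundary z_c = 0 is "distant": the proximal criterion is z_c < 0
        return "proximal" if self.z_c < 0 else "distant"


class Interactome:
    """LCC-restricted interactome with a cached hop-distance matrix."""

    def __init__(self, graph: nx.Graph):
        lcc = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)))
        self.graph = graph.subgraph(lcc).copy()
        self.nodes = sorted(self.graph.nodes())
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self._dist: np.ndarray | None = None
        self.degrees = np.array([self.graph.degree(n) for n in self.nodes])

    @property
    def dist(self) -> np.ndarray:
        if self._dist is None:
            adj = nx.to_scipy_sparse_array(self.graph, nodelist=self.nodes,
                                           format="csr")
            self._dist = shortest_path(adj, method="auto", unweighted=True)
        return self._dist

    def map_nodes(self, nodes) -> np.ndarray:
        return np.array(sorted(self._index[n] for n in nodes
                               if n in self._index), dtype=int)


def closest_distance(from_set, to_set, interactome: Interactome
                     ) -> tuple[float, int, int]:
    """d_c = mean over T of the hop distance to the nearest node of S.

    Members not on the LCC are dropped (and counted via the returned
    mapped sizes). Raises ValueError when either set is empty after
    mapping.
    """
    t_idx = interactome.map_nodes(from_set)
    s_idx = interactome.map_nodes(to_set)
    if t_idx.size == 0 or s_idx.size == 0:
        raise ValueError("a node set is empty after mapping onto the LCC")
    d = interactome.dist[np.ix_(t_idx, s_idx)].min(axis=1).mean()
    return float(d), int(t_idx.size), int(s_idx.size)


def degree_bins(interactome: Interactome, bin_min: int = 100
                ) -> list[np.ndarray]:
    """Partition node indices into degree bins of at least ``bin_min``
    nodes by merging adjacent degree values upward."""
    order = np.argsort(interactome.degrees, kind="stable")
    degs = interactome.degrees[order]
    n = len(order)
    if n <= bin_min:
        warnings.warn("graph smaller than bin_min; single-bin null")
        return [order]
    bins: list[np.ndarray] = []
    start = 0
    while start < n:
        end = start + bin_min
        if end >= n:
            end = n
        else:
            # extend to the end of the current degree value
            while end < n and degs[end] == degs[end - 1]:
                end += 1
        bins.append(order[start:end])
        start = end
    if len(bins) > 1 and bins[-1].size < bin_min:
        bins[-2] = np.concatenate([bins[-2], bins[-1]])
        bins.pop()
    return bins


def _degree_matched_draw(rng: np.random.Generator, idx: np.ndarray,
                         bins: list[np.ndarray],
                         bin_of: np.ndarray) -> np.ndarray:
    """Random node set matching the degree-bin profile of ``idx``."""
    need = np.bincount(bin_of[idx], minlength=len(bins))
    out = []
    for b, count in enumerate(need):
        if count == 0:
            continue
        pool = bins[b]
        if count <= pool.size:
            out.append(rng.choice(pool, size=count, replace=False))
        else:  # degenerate tiny bin: top up from the whole node pool
            out.append(pool)
            rest = rng.choice(len(bin_of), size=count - pool.size,
                              replace=False)
            out.append(rest)
    return np.concatenate(out)


def proximity_z(from_set, to_set, interactome: Interactome,
                n_random: int = 1000, bin_min: int = 100,
                seed: int | np.random.Generator = 0,
                entity: str = "", disease: str = "") -> ProximityResult:
    """z_c of d_c(T, S) against degree-matched random (T', S') draws."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    d_obs, n_t, n_s = closest_distance(from_set, to_set, interactome)
    t_idx = interactome.map_nodes(from_set)
    s_idx = interactome.map_nodes(to_set)
    bins = degree_bins(interactome, bin_min)
    bin_of = np.empty(len(interactome.nodes), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b
    dist = interactome.dist
    null = np.empty(n_random)
    for i in range(n_random):
        rt = _degree_matched_draw(rng, t_idx, bins, bin_of)
        rs = _degree_matched_draw(rng, s_idx, bins, bin_of)
        null[i] = dist[np.ix_(rt, rs)].min(axis=1).mean()
    mu, sd = float(null.mean()), float(null.std(ddof=0))
    degenerate = sd == 0.0
    if degenerate:
        warnings.warn("degenerate null (sd = 0); z undefined")
        z = np.nan
    else:
        z = (d_obs - mu) / sd
    return ProximityResult(entity=entity, disease=disease, d_c=d_obs,
                           null_mean=mu, null_sd=sd, z_c=float(z),
                           n_mapped_entity=n_t, n_mapped_disease=n_s,
                           degenerate=degenerate)


def classify_proximal(results: list[ProximityResult],
                      entity_classes: dict[str, str] | None = None):
    """Proximal/distant labels and, when two entity classes are present,
    the 2x2 Fisher test of class x proximal."""
    rows = [{
        "entity": r.entity, "disease": r.disease, "d_c": r.d_c,
        "null_mean": r.null_mean, "null_sd": r.null_sd, "z_c": r.z_c,
        "n_mapped_entity": r.n_mapped_entity,
        "n_mapped_disease": r.n_mapped_disease, "label": r.label,
    } for r in results]
    df = pd.DataFrame(rows)
    fisher = None
    if entity_classes and not df.empty:
        df["entity_class"] = df["entity"].map(entity_classes)
        classes = sorted(df["entity_class"].dropna().unique())
        if len(classes) == 2:
            table = [[int(((df["entity_class"] == c)
                           & (df["label"] == lab)).sum())
                      for lab in ("proximal", "distant")] for c in classes]
            _, p = fisher_exact(table, alternative="two-sided")
            fisher = {"classes": classes, "table": table, "p": float(p)}
    return df, fisher
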