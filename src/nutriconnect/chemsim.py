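"""Structural similarity between dietary compounds and drugs.

Morgan (ECFP-like) circular fingerprints, radius 2 hashed to 2048 bits,
compared by the Tanimoto coefficient; a food-drug pair is flagged similar
when at least one of its compound pairs reaches the 0.4 cutoff. Flagged
pairs can then be compared with the remaining pairs on how many diseases
both members are anti-correlated with.
"""

from __future__ import annotations

import warnings

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from .stats import ranksum_two_sided

RADIUS = 2
N_BITS = 2048
CUTOFF = 0.4

_generator = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS,
                                                       fpSize=N_BITS)


def fingerprint(smiles: str) -> frozenset[int]:
    """Morgan fingerprint on-bit set; raises ValueError on unparsable
    SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = _generator.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets score 0 (flagged)."""
    union = len(a | b)
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto set to 0")
        return 0.0
    return len(a & b) / union


def load_compounds(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Attach fingerprints to an (entity, compound_id, smiles) table.

    Unparsable records are rejected and counted.
    """
    rows, rejected = [], 0
    for rec in table.itertuples(index=False):
        try:
            fp = fingerprint(rec.smiles)
        except ValueError:
            rejected += 1
            continue
        rows.append({"entity": rec.entity, "compound_id": rec.compound_id,
                     "smiles": rec.smiles, "fp": fp})
    if rejected:
        warnings.warn(f"rejected {rejected} unparsable compound record(s)")
    return pd.DataFrame(rows, columns=["entity", "compound_id", "smiles",
                                       "fp"]), rejected


def similar_food_drug_pairs(food_compounds: pd.DataFrame,
                            drug_compounds: pd.DataFrame,
                            cutoff: float = CUTOFF):
    """Food-drug pairs with at least one compound pair at Tanimoto >=
    cutoff; returns (pairs DataFrame, supporting edges DataFrame)."""
    foods, _ = load_compounds(food_compounds)
    drugs, _ = load_compounds(drug_compounds)
    edges = []
    for f in foods.itertuples(index=False):
        for d in drugs.itertuples(index=False):
            t = tanimoto(f.fp, d.fp)
            if t >= cutoff:
                edges.append({"food": f.entity, "drug": d.entity,
                              "food_compound": f.compound_id,
                              "drug_compound": d.compound_id, "tanimoto": t})
    edges_df = pd.DataFrame(edges, columns=["food", "drug", "food_compound",
                                            "drug_compound", "tanimoto"])
    pairs = (edges_df[["food", "drug"]].drop_duplicates()
             .sort_values(["food", "drug"]).reset_index(drop=True))
    return pairs, edges_df


def shared_anticorrelated_count(food: str, drug: str,
                                pair_results: pd.DataFrame) -> int:
    """Diseases classed anti-correlated with both the food and the drug."""
    anti = pair_results[pair_results["class"] == "anti-correlated"]
    food_dis = set(anti.loc[anti["query"] == food, "reference"])
    drug_dis = set(anti.loc[anti["query"] == drug, "reference"])
    return len(food_dis & drug_dis)


def compare_shared_diseases(similar_pairs: list[tuple[str, str]],
                            other_pairs: list[tuple[str, str]],
                            pair_results: pd.DataFrame):
    """Wilcoxon rank-sum comparison of shared anti-correlated disease
    counts between structurally similar and other food-drug pairs.

    Returns (counts for similar, counts for others, two-sided p or None
    when a group is empty).
    """
    sim = [shared_anticorrelated_count(f, d, pair_results)
           for f, d in similar_pairs]
    oth = [shared_anticorrelated_count(f, d, pair_results)
           for f, d in other_pairs]
    if not sim or not oth:
        warnings.warn("a comparison group is empty; rank-sum test skipped")
        return sim, oth, None
    return sim, oth, ranksum_two_sided(sim, oth)
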