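"""Enrichment-score statistic, permutation significance, clustering."""

import numpy as np
import pandas as pd
import pytest

from nutriconnect import connectivity as cn
from nutriconnect.rankprod import SignatureRanking

RANKED10 = [f"g{i}" for i in range(1, 11)]


def make_ranking(entity, logfc: dict, calls: dict | None = None):
    genes = sorted(logfc, key=lambda g: (-logfc[g], g))
    calls = calls or {}
    table = pd.DataFrame({
        "logfc": [logfc[g] for g in genes],
        "call": [calls.get(g, "ns") for g in genes]},
        index=pd.Index(genes, name="gene"))
    return SignatureRanking(entity=entity, table=table)


class TestKsTagScore:
    def test_tags_at_top(self):
        assert cn.ks_tag_score(["g1", "g2"], RANKED10) == pytest.approx(0.8)

    def test_tags_at_bottom(self):
        assert cn.ks_tag_score(["g9", "g10"], RANKED10) == pytest.approx(-0.9)

    def test_full_coverage_scores_zero(self):
        assert cn.ks_tag_score(RANKED10, RANKED10) == 0.0

    def test_absent_tags_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            s = cn.ks_tag_score(["g1", "zz"], RANKED10)
        assert s == cn.ks_tag_score(["g1"], RANKED10)

    def test_score_depends_only_on_positions(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            t = int(rng.integers(1, n))
            ranked = [f"x{i}" for i in range(n)]
            tags = [ranked[i] for i in
                    sorted(rng.choice(n, size=t, replace=False))]
            s = cn.ks_tag_score(tags, ranked)
            assert -1.0 <= s <= 1.0
            # vectorized path agrees with the scalar path
            pos = np.sort([ranked.index(g) + 1 for g in tags])[None, :]
            assert cn._ks_matrix(pos.astype(float), n)[0] == pytest.approx(s)


class TestDirectionalES:
    def test_hand_example(self):
        q = cn.QuerySignature(up_tags=["g1", "g2"], down_tags=["g9", "g10"])
        ranking = make_ranking("ref", {g: 10 - i for i, g in enumerate(RANKED10)})
        assert cn.directional_es(q, ranking) == pytest.approx(0.85)

    def test_swap_negates(self):
        ranking = make_ranking("ref", {g: 10 - i for i, g in enumerate(RANKED10)})
        q = cn.QuerySignature(up_tags=["g1", "g2"], down_tags=["g9", "g10"])
        qs = cn.QuerySignature(up_tags=["g9", "g10"], down_tags=["g1", "g2"])
        assert cn.directional_es(qs, ranking) == pytest.approx(
            -cn.directional_es(q, ranking))

    def test_same_sign_scores_zero(self):
        ranking = make_ranking("ref", {g: 10 - i for i, g in enumerate(RANKED10)})
        q = cn.QuerySignature(up_tags=["g1", "g2"], down_tags=["g3", "g4"])
        assert cn.directional_es(q, ranking) == 0.0

    def test_overlapping_tags_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            cn.QuerySignature(up_tags=["g1"], down_tags=["g1"])


def planted_ranking(entity, n, up, down, rng, strength=5.0):
    logfc = {f"g{i}": float(rng.normal(0, 0.3)) for i in range(1, n + 1)}
    calls = {}
    for g in up:
        logfc[g] = strength + float(rng.normal(0, 0.1))
        calls[g] = "up"
    for g in down:
        logfc[g] = -strength + float(rng.normal(0, 0.1))
        calls[g] = "down"
    return make_ranking(entity, logfc, calls)


class TestPairES:
    def test_self_concordance_positive_and_flip_antisymmetric(self):
        rng = np.random.default_rng(1)
        n = 60
        up = [f"g{i}" for i in range(1, 9)]
        down = [f"g{i}" for i in range(9, 17)]
        a = planted_ranking("a", n, up, down, rng)
        twin = planted_ranking("twin", n, down, up, rng)  # sign-flipped
        es_self = cn.pair_es(a, a, min_tags=5)
        es_flip = cn.pair_es(a, twin, min_tags=5)
        assert es_self > 0
        assert es_flip < 0

    def test_too_few_tags_unscorable(self):
        rng = np.random.default_rng(2)
        a = planted_ranking("a", 30, ["g1", "g2"], ["g29", "g30"], rng)
        b = planted_ranking("b", 30, [f"g{i}" for i in range(1, 7)],
                            [f"g{i}" for i in range(25, 31)], rng)
        assert cn.pair_es(a, b, min_tags=5) is None


class TestPermutationSignificance:
    def _toy(self, es):
        rng = np.random.default_rng(3)
        up = [f"g{i}" for i in range(1, 7)]
        down = [f"g{i}" for i in range(55, 61)]
        a = planted_ranking("a", 60, up, down, rng)
        b = planted_ranking("b", 60, up, down, rng)
        pairs = pd.DataFrame([{"query": "a", "reference": "b", "es": es}])
        return pairs, {"a": a, "b": b}

    def test_extreme_es_gets_add_one_p(self):
        pairs, rankings = self._toy(es=0.99)
        out = cn.permutation_significance(pairs, rankings, n_perm=500, seed=0)
        assert out.loc[0, "p_value"] == pytest.approx(1 / 501)

    def test_zero_es_gets_p_one(self):
        pairs, rankings = self._toy(es=0.0)
        out = cn.permutation_significance(pairs, rankings, n_perm=200, seed=0)
        assert out.loc[0, "p_value"] == 1.0

    def test_classes_follow_sign_and_fdr(self):
        rng = np.random.default_rng(4)
        up = [f"g{i}" for i in range(1, 7)]
        down = [f"g{i}" for i in range(55, 61)]
        a = planted_ranking("a", 60, up, down, rng)
        b = planted_ranking("b", 60, up, down, rng)
        c = planted_ranking("c", 60, down, up, rng)
        res = cn.score_pairs({"a": a}, {"b": b, "c": c}, n_perm=300, seed=1)
        by_ref = res.set_index("reference")
        assert by_ref.loc["b", "class"] == "correlated"
        assert by_ref.loc["b", "es"] > 0
        assert by_ref.loc["c", "class"] == "anti-correlated"
        assert by_ref.loc["c", "es"] < 0

    def test_bh_fdr_monotone_in_p(self):
        rng = np.random.default_rng(5)
        rankings, rows = {}, []
        for i in range(6):
            up = list(rng.choice([f"g{j}" for j in range(1, 41)], 6, replace=False))
            rest = [f"g{j}" for j in range(1, 41) if f"g{j}" not in up]
            down = rest[:6]
            rankings[f"e{i}"] = planted_ranking(f"e{i}", 40, up, down, rng)
        res = cn.score_pairs({k: rankings[k] for k in list(rankings)[:3]},
                             {k: rankings[k] for k in list(rankings)[3:]},
                             n_perm=200, seed=2)
        scored = res.dropna(subset=["p_value"]).sort_values("p_value")
        assert scored["fdr"].is_monotonic_increasing


class TestClusterDiseases:
    def test_identical_profiles_merge_at_zero(self):
        profile = pd.DataFrame(
            [[1.0, 0.2, -0.5], [1.0, 0.2, -0.5], [-0.8, 0.9, 0.1]],
            index=["d1", "d2", "d3"], columns=["f1", "f2", "f3"])
        z, newick, _ = cn.cluster_diseases(profile)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert "d1" in newick and "d3" in newick

    def test_anticorrelated_profiles_at_maximum_distance(self):
        profile = pd.DataFrame(
            [[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0], [0.5, 1.0, 0.0]],
            index=["d1", "d2", "d3"], columns=["f1", "f2", "f3"])
        z, _, _ = cn.cluster_diseases(profile)
        # the d1-d2 merge happens at distance 2 or is the last merge
        assert z[:, 2].max() <= 2.0 + 1e-12

    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(7)
        base_a = rng.normal(0, 1, size=10)
        base_b = rng.normal(0, 1, size=10)
        rows, names = [], []
        for i in range(4):
            rows.append(base_a + rng.normal(0, 0.05, size=10))
            names.append(f"a{i}")
        for i in range(4):
            rows.append(base_b + rng.normal(0, 0.05, size=10))
            names.append(f"b{i}")
        profile = pd.DataFrame(rows, index=names)
        _, _, labels = cn.cluster_diseases(profile, k=2)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]
        # independent oracle: within-group correlations exceed between
        corr = np.corrcoef(profile.to_numpy())
        assert corr[:4, :4].min() > corr[:4, 4:].max()

    def test_too_few_diseases_rejected(self):
        profile = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            cn.cluster_diseases(profile)


class TestRecoveryStats:
    def test_fisher_exact_hand_table(self):
        # known/recovered 2x2 of (3,0,0,3): two-sided p = 0.1 by
        # hypergeometric enumeration over C(6,3) = 20 tables
        res = pd.DataFrame([
            {"query": "q", "reference": f"d{i}",
             "class": "anti-correlated" if i < 3 else "not-significant",
             "es": -0.5 if i < 3 else 0.1}
            for i in range(6)])
        known = [("q", f"d{i}") for i in range(3)]
        overall, per_class = cn.recovery_stats(
            res, known, class_map={f"d{i}": "one" for i in range(6)})
        assert overall == {"n_known": 3, "n_recovered": 3}
        assert per_class.loc[0, "fisher_p"] == pytest.approx(0.1)

    def test_empty_indication_list(self):
        res = pd.DataFrame([{"query": "q", "reference": "d0",
                             "class": "not-significant", "es": 0.0}])
        overall, per_class = cn.recovery_stats(res, [], class_map=None)
        assert overall == {"n_known": 0, "n_recovered": 0}
        assert per_class.empty

    def test_unknown_disease_skipped_with_warning(self):
        res = pd.DataFrame([{"query": "q", "reference": "d0",
                             "class": "anti-correlated", "es": -0.4}])
        with pytest.warns(UserWarning, match="unknown disease"):
            overall, _ = cn.recovery_stats(res, [("q", "nope")], None)
        assert overall["n_known"] == 0


from hypothesis import given, settings, strategies as st  # noqa: E402


@given(st.integers(min_value=2, max_value=200).flatmap(
    lambda n: st.tuples(st.just(n),
                        st.sets(st.integers(1, n), min_size=1,
                                max_size=n - 1))))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_ks_bounded_and_reversal_invariant(case):
    """Scores stay in [-1, 1]; mirroring tag positions in a reversed list
    leaves the statistic unchanged (it only sees positions)."""
    n, positions = case
    ranked = [f"g{i}" for i in range(1, n + 1)]
    tags = [f"g{i}" for i in sorted(positions)]
    s = cn.ks_tag_score(tags, ranked)
    assert -1.0 <= s <= 1.0
    mirrored = [f"g{n + 1 - i}" for i in sorted(positions)]
    s_rev = cn.ks_tag_score(mirrored, list(reversed(ranked)))
    assert s_rev == pytest.approx(s, abs=1e-12)
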