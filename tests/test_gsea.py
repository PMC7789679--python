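"""Enrichment-score and permutation-GSEA correctness."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from secretoscope.containers import DataError, GeneSetCollection
from secretoscope.gsea import (
    GseaConfig,
    PrerankedGSEA,
    _es_batch,
    enrichment_score,
    gsea,
    make_ranked_list,
    top_terms,
)


def ranked_from(scores):
    ids = [f"g{i+1}" for i in range(len(scores))]
    return pd.DataFrame({"id": ids, "score": scores})


class TestEnrichmentScore:
    def test_hand_executed_running_sum(self):
        # scores (3,2,1,-1,-2,-3), set {g1,g4}: +3/4, -1/4 per miss, +1/4
        ranked = ranked_from([3, 2, 1, -1, -2, -3])
        es, running, leading = enrichment_score(ranked, {"g1", "g4"})
        assert es == pytest.approx(0.75)
        np.testing.assert_allclose(running, [0.75, 0.5, 0.25, 0.5, 0.25, 0.0])
        assert leading == ["g1"]

    def test_whole_list_gives_unit_score(self):
        ranked = ranked_from([3, 2, 1, -1])
        es, running, _ = enrichment_score(ranked, set(ranked["id"]))
        assert es == pytest.approx(1.0)
        assert np.max(running) == pytest.approx(1.0)

    def test_negation_and_reversal_flips_sign(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = np.sort(rng.normal(size=30))[::-1]
            ranked = ranked_from(scores)
            members = set(rng.choice(ranked["id"], size=6, replace=False))
            es, _, _ = enrichment_score(ranked, members)
            flipped = ranked_from((-scores)[::-1])
            flip_members = {
                f"g{30 - int(m[1:]) + 1}" for m in members
            }  # same genes after reversal
            es_flip, _, _ = enrichment_score(flipped, flip_members)
            assert es_flip == pytest.approx(-es, abs=1e-12)

    def test_batch_path_equals_reference_loop(self):
        rng = np.random.default_rng(1)
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = ranked_from(scores)
        w = np.abs(scores)
        for _ in range(100):
            k = int(rng.integers(2, 15))
            pos = np.sort(rng.choice(40, size=k, replace=False))
            es_loop, _, _ = enrichment_score(ranked, {f"g{p+1}" for p in pos})
            es_vec = _es_batch(pos[None, :], w[pos][None, :], 40)[0]
            assert es_vec == pytest.approx(es_loop, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.normal(size=25))[::-1]
        ranked = ranked_from(scores)
        for _ in range(50):
            members = set(rng.choice(ranked["id"], size=int(rng.integers(1, 25)), replace=False))
            es, _, _ = enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(DataError):
            enrichment_score(ranked_from([1, -1]), {"absent"})

    def test_matches_gseapy_on_tie_free_list(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(5)
        n = 80
        ids = [f"G{i:03d}" for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1]
        rk = pd.DataFrame({"id": ids, "score": scores})
        sets = {f"S{j}": list(rng.choice(ids, size=12, replace=False)) for j in range(4)}
        pre = gseapy.prerank(
            rnk=rk.set_index("id"), gene_sets=sets, permutation_num=5,
            min_size=2, max_size=50, seed=1, outdir=None, no_plot=True, weight=1.0,
        )
        for name, members in sets.items():
            mine, _, _ = enrichment_score(rk, members, weight=1.0)
            theirs = float(pre.res2d.loc[pre.res2d.Term == name, "ES"].iloc[0])
            assert mine == pytest.approx(theirs, abs=1e-6)


class TestGsea:
    def _collection(self, sets):
        coll = GeneSetCollection({})
        for name, members in sets.items():
            coll.add(name, members)
        return coll

    def test_exact_enumeration_equals_vectorized_on_small_list(self):
        # every C(8,3) placement: batch ES equals the reference loop
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(size=8))[::-1]
        ranked = ranked_from(scores)
        w = np.abs(scores)
        for pos in combinations(range(8), 3):
            pos = np.array(pos)
            es_loop, _, _ = enrichment_score(ranked, {f"g{p+1}" for p in pos})
            es_vec = _es_batch(pos[None, :], w[pos][None, :], 8)[0]
            assert es_vec == pytest.approx(es_loop, abs=1e-12)

    def test_exact_null_on_six_gene_example(self):
        ranked = ranked_from([3, 2, 1, -1, -2, -3])
        coll = self._collection({"S": ["g1", "g4"]})
        res = gsea(ranked, coll, GseaConfig(min_set_size=1, n_permutations=100, seed=0),
                   exact_null=True)
        row = res.iloc[0]
        assert row["es"] == pytest.approx(0.75)
        # exact null: all C(6,2)=15 placements enumerated
        placements = np.array(list(combinations(range(6), 2)))
        w = np.abs(np.array([3, 2, 1, -1, -2, -3], float))
        es_all = _es_batch(placements, w[placements], 6)
        same = es_all[es_all >= 0]
        expected_p = (1 + np.sum(np.abs(same) >= 0.75)) / (1 + len(same))
        assert row["p"] == pytest.approx(expected_p)

    def test_min_set_size_filter_and_skip_reason(self):
        ranked = ranked_from(np.linspace(3, -3, 20))
        coll = self._collection({"small": ["g1", "g2"], "big": [f"g{i}" for i in range(1, 12)]})
        est = PrerankedGSEA(min_set_size=10, n_permutations=50, seed=0).fit(ranked, coll)
        assert list(est.results_["name"]) == ["big"]
        assert "small" in est.skipped_

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=100)
        ranked = ranked_from(np.sort(scores)[::-1])
        sets = {f"S{j}": [f"g{i+1}" for i in rng.choice(100, 15, replace=False)] for j in range(10)}
        r1 = gsea(ranked, self._collection(sets), GseaConfig(10, 200, 1.0, 7))
        r2 = gsea(ranked, self._collection(sets), GseaConfig(10, 200, 1.0, 7))
        pd.testing.assert_frame_equal(r1, r2)

    def test_nes_sign_matches_es_and_p_monotone(self):
        rng = np.random.default_rng(6)
        scores = np.sort(rng.normal(size=120))[::-1]
        ranked = ranked_from(scores)
        sets = {f"S{j}": [f"g{i+1}" for i in rng.choice(120, 15, replace=False)] for j in range(15)}
        res = gsea(ranked, self._collection(sets), GseaConfig(5, 2000, 1.0, 2))
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()
        pos = res[res["nes"] > 0].sort_values("nes", ascending=False)
        # larger |NES| should not have a clearly larger p (permutation noise
        # bounded by the high permutation count)
        assert (np.diff(pos["p"]) >= -0.02).all()

    def test_ranked_list_from_effects_breaks_ties_on_id(self):
        eff = pd.DataFrame(
            {"protein": ["b", "a", "c"], "condition": "t", "log2fc": [1.0, 1.0, 2.0]}
        )
        rk = make_ranked_list(eff, "t")
        assert list(rk["id"]) == ["c", "a", "b"]


class TestTopTerms:
    def _results(self, nes_values, p=0.001):
        return pd.DataFrame(
            {
                "name": [f"S{i}" for i in range(len(nes_values))],
                "size": 10,
                "es": np.sign(nes_values),
                "nes": nes_values,
                "p": p,
                "fdr": 0.0,
                "leading_edge": "",
            }
        )

    def test_ordering_by_descending_nes(self):
        res = self._results([1.0, 3.0, 2.0])
        top = top_terms(res, k=10)
        up = top[top.direction == "up"]
        assert list(up["nes"]) == [3.0, 2.0, 1.0]

    def test_k_larger_than_available_returns_all(self):
        res = self._results([1.0, -1.5])
        top = top_terms(res, k=50)
        assert len(top) == 2

    def test_p_threshold_filters(self):
        res = self._results([2.0, 1.5], p=0.5)
        assert top_terms(res, k=5).empty

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(8)
        res = self._results(list(rng.normal(size=30)))
        top = top_terms(res, k=5)
        up_expected = sorted(
            [(r.nes, r.name) for r in res.itertuples() if r.nes > 0],
            key=lambda t: (-t[0], t[1]),
        )[:5]
        up = top[top.direction == "up"]
        assert list(zip(up["nes"], up["name"])) == up_expected
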