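"""The six search engines: neighbor lists, scoring rules, ranking,
degeneracies, and equivalence with the exact brute-force reimplementation."""

from fractions import Fraction

import numpy as np
import pytest

from profsearch.search import (
    ENGINES,
    build_neighbor_list,
    build_profile_units,
    default_k,
    rank_hits,
    run_search,
)
from profsearch.similarity import tanimoto_binary
from tests import oracles
from tests.conftest import random_fps


def _bits(on, m=16):
    v = np.zeros(m, dtype=np.uint8)
    v[list(on)] = 1
    return v


class TestNeighborList:
    def test_identical_active_reference_always_included(self):
        q = _bits({0, 1, 2})
        nl = build_neighbor_list("q", q, ["r0"], q[None, :], np.array(["active"]))
        assert nl.active_ids == ["r0"]

    def test_cutoff_is_strict(self):
        q = _bits({0, 1, 2})
        # reference sharing 3 of 10 union bits -> Tc exactly 0.3
        r = _bits({0, 1, 2, 3, 4, 5, 6, 7, 8, 9})
        assert tanimoto_binary(q, r) == 0.3
        nl = build_neighbor_list("q", q, ["r"], r[None, :], np.array(["active"]))
        assert nl.n_active == 0

    def test_mixed_similarities_thresholded(self):
        q = _bits(range(10))
        refs = np.stack([_bits(range(2)), _bits(range(7)), _bits(range(9))])
        # Tc to q: 0.2, 0.7, 0.9
        nl = build_neighbor_list(
            "q", q, ["a", "b", "c"], refs, np.array(["active", "active", "inactive"])
        )
        assert nl.active_ids == ["b"]
        assert nl.inactive_ids == ["c"]

    def test_empty_reference_set_is_valid(self):
        q = _bits({0})
        nl = build_neighbor_list("q", q, [], np.zeros((0, 16), dtype=np.uint8), np.array([]))
        assert nl.n_active == 0 and nl.n_inactive == 0


class TestProfileUnits:
    def test_identical_active_refs_compress_to_one_profile(self):
        fp = _bits({0, 1, 2, 3})
        nl = build_neighbor_list(
            "q", fp, [f"r{i}" for i in range(5)], np.tile(fp, (5, 1)),
            np.array(["active"] * 5),
        )
        model = build_profile_units(nl, "pbiss", query_fp=fp)
        assert len(model.active_units) == 1
        assert model.compression_ratio == 6.0  # 5 refs + query -> 1 profile

    def test_dissimilar_refs_stay_singleton_profiles(self):
        refs = np.eye(16, dtype=np.uint8)[:4] # pairwise similarity 0
        q = _bits({10, 11})
        nl_fps = np.vstack([np.tile(q, (3, 1))])  # neighbors identical to query
        nl = build_neighbor_list("q", q, ["a", "b", "c"], nl_fps, np.array(["active"] * 3))
        model = build_profile_units(nl, "pbiss", query_fp=q)
        assert model.compression_ratio == 4.0
        model2 = build_profile_units(
            build_neighbor_list("q", q, [], np.zeros((0, 16), dtype=np.uint8), np.array([])),
            "pbiss", query_fp=q,
        )
        assert model2.compression_ratio == 1.0

    def test_mixed_cluster_yields_two_labeled_profiles(self):
        fp = _bits({0, 1, 2, 3})
        ids = [f"r{i}" for i in range(5)]
        labels = np.array(["active"] * 3 + ["inactive"] * 2)
        nl = build_neighbor_list("q", fp, ids, np.tile(fp, (5, 1)), labels)
        model = build_profile_units(nl, "pbisc", query_fp=fp)
        # one cluster of 6 (query + 5), mixed -> one active + one inactive profile
        assert len(model.active_units) == 1
        assert len(model.inactive_units) == 1
        assert model.active_units[0].label == "active"
        assert model.inactive_units[0].label == "inactive"
        assert model.compression_ratio == 3.0


class TestRanking:
    def test_truncation_matches_one_percent_floor(self):
        assert default_k(494_199) == 4941
        assert default_k(200) == 2
        assert default_k(50) == 1  # floor would be 0; at least one hit

    def test_ties_broken_by_ascending_id(self):
        hits = rank_hits(["z", "a", "m"], np.array([0.5, 0.5, 0.9]), k=3)
        assert hits.ids == ["m", "a", "z"]

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rank_hits(["a"], np.array([1.0]), k=0)


def _small_problem(rng, n_db=60, n_ref=12, m=32):
    db = random_fps(rng, n_db, m, density=0.3)
    db_ids = [f"d{i:03d}" for i in range(n_db)]
    # make references related to the query so neighbor lists are nonempty
    q = db[0].copy()
    refs = []
    for i in range(n_ref):
        r = q.copy()
        flip = rng.integers(0, m, size=3)
        r[flip] ^= 1
        refs.append(r)
    refs = np.stack(refs)
    labels = np.array(["active", "inactive"] * (n_ref // 2))
    ref_ids = [f"r{i}" for i in range(n_ref)]
    return q, db_ids, db, ref_ids, refs, labels


class TestRunSearch:
    def test_exact_copy_of_query_ranks_first(self, rng):
        q, db_ids, db, ref_ids, refs, labels = _small_problem(rng)
        db = np.vstack([db, q[None, :]])
        db_ids = db_ids + ["copy"]
        res = run_search("css", "q", q, db_ids, db, ref_ids, refs, labels, k=5)
        assert res.hits.ids[0] == "copy"
        assert res.hits.scores[0] == 1.0

    def test_query_and_references_excluded_from_hits(self, rng):
        q, db_ids, db, ref_ids, refs, labels = _small_problem(rng)
        db2 = np.vstack([db, refs])
        ids2 = db_ids + ref_ids
        res = run_search("css", "q", q, ids2, db2, ref_ids, refs, labels, k=20)
        assert not set(res.hits.ids) & set(ref_ids)

    def test_isc_rejects_decoy_identical_to_inactive_reference(self, rng):
        q = _bits({0, 1, 2, 3}, m=32)
        decoy = _bits({0, 1, 2, 3, 4}, m=32)  # Tc(q,decoy)=0.8
        refs = np.stack([q, decoy])
        labels = np.array(["active", "inactive"])
        db = np.vstack([decoy[None, :], random_fps(rng, 20, 32)])
        db_ids = ["decoy"] + [f"d{i}" for i in range(20)]
        res_iss = run_search("iss", "q", q, db_ids, db, ["ra", "ri"], refs, labels, k=10)
        res_isc = run_search("isc", "q", q, db_ids, db, ["ra", "ri"], refs, labels, k=10)
        assert "decoy" in res_iss.hits.ids
        assert "decoy" not in res_isc.hits.ids

    def test_tie_between_active_and_inactive_max_is_rejected(self):
        q = _bits({0, 1, 2, 3}, m=32)
        ref_act = _bits({0, 1, 2, 4}, m=32)
        ref_inact = _bits({0, 1, 2, 5}, m=32)
        comp = _bits({0, 1, 2, 6}, m=32)  # equally similar to both refs
        res = run_search(
            "isc", "q", q, ["comp"], comp[None, :], ["a", "i"],
            np.stack([ref_act, ref_inact]), np.array(["active", "inactive"]), k=1,
        )
        # max active sim: via query = 3/5; ref_act also 3/5; inactive 3/5 -> tie -> rejected
        assert res.kept.tolist() == [False]
        assert len(res.hits) == 0

    @pytest.mark.parametrize("engine", ENGINES)
    def test_empty_reference_set_degenerates_to_css(self, engine, rng):
        q, db_ids, db, *_ = _small_problem(rng)
        empty_refs = np.zeros((0, db.shape[1]), dtype=np.uint8)
        res = run_search(engine, "q", q, db_ids, db, [], empty_refs, np.array([]), k=10)
        base = run_search("css", "q", q, db_ids, db, [], empty_refs, np.array([]), k=10)
        assert res.hits.entries == base.hits.entries

    def test_singleton_clusters_make_profile_engines_match_fingerprint_engines(self, rng):
        q, db_ids, db, ref_ids, refs, labels = _small_problem(rng)
        # cluster cutoff above 1 is invalid; use 0.999... by forcing all refs distinct
        for a, b, cutoff in (("pbiss", "iss", 0.995), ("pbisc", "isc", 0.995)):
            r1 = run_search(a, "q", q, db_ids, db, ref_ids, refs, labels, k=15,
                            cluster_cutoff=cutoff)
            r2 = run_search(b, "q", q, db_ids, db, ref_ids, refs, labels, k=15)
            if r1.model.n_units == r1.model.n_references:  # all singletons
                assert r1.hits.entries == r2.hits.entries

    def test_iss_dominates_css_scores(self, rng):
        q, db_ids, db, ref_ids, refs, labels = _small_problem(rng)
        css = run_search("css", "q", q, db_ids, db, ref_ids, refs, labels, k=10)
        iss = run_search("iss", "q", q, db_ids, db, ref_ids, refs, labels, k=10)
        assert (iss.scores >= css.scores).all()

    def test_isc_candidates_subset_of_iss(self, rng):
        q, db_ids, db, ref_ids, refs, labels = _small_problem(rng)
        iss = run_search("iss", "q", q, db_ids, db, ref_ids, refs, labels, k=60)
        isc = run_search("isc", "q", q, db_ids, db, ref_ids, refs, labels, k=60)
        assert set(isc.hits.ids) <= set(iss.hits.ids)

    def test_unknown_engine_rejected(self, rng):
        q, db_ids, db, ref_ids, refs, labels = _small_problem(rng)
        with pytest.raises(ValueError, match="unknown engine"):
            run_search("sum", "q", q, db_ids, db, ref_ids, refs, labels)


class TestOracleEquivalence:
    """Each engine must reproduce a naive exact-arithmetic reimplementation."""

    @pytest.mark.parametrize("engine", ENGINES)
    def test_ranked_lists_match_brute_force(self, engine):
        rng = np.random.default_rng(777)
        for trial in range(6):
            n_db, n_ref, m = 50, 10, 24
            q, db_ids, db, ref_ids, refs, labels = _small_problem(
                rng, n_db=n_db, n_ref=n_ref, m=m
            )
            k = 12
            res = run_search(engine, "q", q, db_ids, db, ref_ids, refs, labels, k=k)
            expected = oracles.search(
                engine, "q", list(map(int, q)), db_ids,
                [list(map(int, r)) for r in db],
                [list(map(int, r)) for r in refs], list(labels), k,
            )
            assert res.hits.ids == [cid for cid, _ in expected]
            for (got_id, got_s), (exp_id, exp_s) in zip(res.hits.entries, expected):
                assert got_s == pytest.approx(float(exp_s), abs=1e-12)
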