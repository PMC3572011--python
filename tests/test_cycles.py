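"""Cycle decomposition, encoding, alignment (vs brute force), clustering,
mechanism classification."""

import itertools
import math

import numpy as np
import pytest

import poregraph as pg
from poregraph.cycles import Scoring

from conftest import AD_SCRIPT, KO_SCRIPT


def brute_force_align(a: str, b: str, sc: Scoring) -> float:
    """Exhaustive maximum over every global alignment (no memoisation):
    an independent oracle for the dynamic-programming aligner."""

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = sc.match if a[i] == b[j] else sc.mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, sc.gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, sc.gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestDecomposeCycles:
    def test_two_simple_round_trips(self):
        labels = ["K:0:2:4", "K:0:1:3", "K:0:2:4", "K:0:2:5", "K:0:2:4"]
        decomp = pg.decompose_cycles(labels)
        assert len(decomp) == 2
        assert decomp.cycles[0].state_sequence == ["K:0:2:4", "K:0:1:3", "K:0:2:4"]
        assert decomp.cycles[1].state_sequence == ["K:0:2:4", "K:0:2:5", "K:0:2:4"]

    def test_constant_resting_has_no_cycles(self):
        decomp = pg.decompose_cycles(["K:0:2:4"] * 3)
        assert len(decomp) == 0

    def test_missing_resting_state_rejected(self):
        with pytest.raises(ValueError, match="never visited"):
            pg.decompose_cycles(["K:1:3", "K:0:2"])

    def test_cycle_count_equals_resting_reentries(self):
        traj = pg.simulate_hopping(pg.KMCParams(duration_ns=150.0, seed=13))
        labels = traj.state_labels()
        runs = [k for k, _ in itertools.groupby(labels)]
        reentries = max(0, runs.count("K:0:2:4") - 1)
        assert len(pg.decompose_cycles(traj)) == reentries

    def test_durations_partition_trajectory(self, kmc_traj):
        decomp = pg.decompose_cycles(kmc_traj)
        total = sum(c.duration_ps for c in decomp.cycles)
        total += decomp.leading_ps + decomp.trailing_ps
        assert total == pytest.approx(kmc_traj.duration_ps, abs=1e-6)


class TestEncoding:
    def test_worked_paths_encode_to_canonical_strings(self, ad_traj, ko_traj):
        for traj, expect in ((ad_traj, "EB310HFE"), (ko_traj, "EkidKIGE")):
            decomp = pg.decompose_cycles(traj)
            assert pg.encode_path(decomp.cycles[0]) == expect

    def test_degenerate_cycle_collapses_to_single_char(self):
        p = pg.CyclicPath(runs=[("K:0:2:4", 0.0, 1.0)])
        assert pg.encode_path(p) == "E"

    def test_code_map_is_bijective_and_deterministic(self):
        m1, m2 = pg.StateCodeMap(), pg.StateCodeMap()
        labels = ["K:2:4", "K:3:5", "K:2:4", "K:0:3:5"]
        assert m1.encode(labels) == m2.encode(labels)
        chars = [c for _, c in m1.items()]
        assert len(chars) == len(set(chars))
        for lab, c in m1.items():
            assert m1.label(c) == lab

    def test_duplicate_seed_codes_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            pg.StateCodeMap({"K:1:3": "A", "K:0:2": "A"})


class TestAlignment:
    def test_self_alignment_scores_full_match(self):
        res = pg.align_paths("EB310HFE", "EB310HFE")
        assert res.score == 8.0
        assert res.aligned_a == res.aligned_b == "EB310HFE"

    def test_alignment_against_empty_is_all_gaps(self):
        sc = Scoring(match=1, mismatch=0, gap=-0.5)
        res = pg.align_paths("E", "", sc)
        assert res.score == -0.5
        assert res.aligned_b == "-"

    @pytest.mark.parametrize("scoring", [
        Scoring(1, 0, 0), Scoring(2, -1, -1), Scoring(1, -0.5, -2),
    ])
    def test_matches_brute_force_enumeration(self, scoring):
        rng = np.random.default_rng(42)
        alphabet = "ABCD"
        for _ in range(60):
            a = "".join(rng.choice(list(alphabet), rng.integers(0, 7)))
            b = "".join(rng.choice(list(alphabet), rng.integers(0, 7)))
            assert pg.align_paths(a, b, scoring).score == pytest.approx(
                brute_force_align(a, b, scoring)
            )

    def test_traceback_is_a_valid_alignment(self):
        res = pg.align_paths("EB310HFE", "EkidKIGE")
        assert len(res.aligned_a) == len(res.aligned_b)
        assert res.aligned_a.replace("-", "") == "EB310HFE"
        assert res.aligned_b.replace("-", "") == "EkidKIGE"


class TestDistanceMatrix:
    def test_identical_paths_distance_zero(self):
        d = pg.path_distance_matrix(["EB310HFE", "EB310HFE"])
        assert d[0, 1] == 0.0

    def test_contract_symmetric_nonnegative_zero_diagonal(self):
        paths = ["EB310HFE", "EkidKIGE", "EBE", "E3HFE"]
        d = pg.path_distance_matrix(paths)
        assert np.allclose(d, d.T)
        assert np.all(d >= 0)
        assert np.all(np.diag(d) == 0)

    def test_mechanistically_distinct_paths_are_farther(self):
        paths = ["EB310HFE", "EkidKIGE", "EB31HFE"]
        d = pg.path_distance_matrix(paths)
        assert d[0, 1] > d[0, 2]

    def test_fewer_than_two_paths_rejected(self):
        with pytest.raises(ValueError):
            pg.path_distance_matrix(["EB310HFE"])


class TestClustering:
    def test_two_duplicated_sequences_split_into_two_clusters(self):
        paths = ["EB310HFE", "EB310HFE", "EkidKIGE", "EkidKIGE"]
        d = pg.path_distance_matrix(paths)
        res = pg.cluster_paths(d, cut=0.5 * d[0, 2])
        assert len(set(res.labels)) == 2
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]

    def test_single_linkage_recovers_ultrametric_heights(self):
        d = np.array(
            [[0.0, 0.2, 0.8, 0.8],
             [0.2, 0.0, 0.8, 0.8],
             [0.8, 0.8, 0.0, 0.4],
             [0.8, 0.8, 0.4, 0.0]]
        )
        res = pg.cluster_paths(d, linkage="single")
        assert sorted(res.linkage[:, 2]) == pytest.approx([0.2, 0.4, 0.8])

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            pg.cluster_paths(np.zeros((1, 1)))

    def test_newick_export_has_all_leaves(self):
        paths = ["EB310HFE", "EkidKIGE", "EBE"]
        d = pg.path_distance_matrix(paths)
        res = pg.cluster_paths(d)
        nwk = pg.dendrogram_newick(res.linkage, ["a", "b", "c"])
        assert nwk.endswith(";")
        for leaf in ("a", "b", "c"):
            assert leaf in nwk

    def test_cluster_majorities_agree_with_mechanism_labels(self):
        """Clusters of aligned cycle strings, each named by its majority
        mechanism, should largely agree with the per-cycle mechanism
        classification (adjusted Rand > 0.5)."""
        from collections import Counter

        from sklearn.metrics import adjusted_rand_score

        traj = pg.simulate_hopping(pg.KMCParams(duration_ns=300.0, seed=0))
        decomp = pg.conduction_cycles(traj)
        pairs = [
            (c.encoded, c.category)
            for c in decomp.cycles
            if c.category in ("knock_on", "assoc_dissoc") and len(c.encoded) > 1
        ]
        paths = [p for p, _ in pairs]
        truth = [cat for _, cat in pairs]
        d = pg.path_distance_matrix(paths)
        res = pg.cluster_paths(d, n_clusters=8)
        majority = {
            k: Counter(t for t, l in zip(truth, res.labels) if l == k).most_common(1)[0][0]
            for k in set(res.labels)
        }
        predicted = [majority[l] for l in res.labels]
        assert adjusted_rand_score(truth, predicted) > 0.5


class TestMechanism:
    def test_worked_paths_classified_by_mechanism(self, ad_traj, ko_traj):
        for traj, expect in ((ad_traj, "assoc_dissoc"), (ko_traj, "knock_on")):
            decomp = pg.conduction_cycles(traj)
            assert decomp.cycles[0].category == expect

    def test_internal_shuffle_is_no_conduction(self):
        traj = pg.scripted_trajectory(["K:0:2:4", "K:0:1:3", "K:0:2:4"])
        decomp = pg.conduction_cycles(traj)
        assert decomp.cycles[0].category == "no_conduction"

    def test_back_running_detected(self):
        # S0 ion dissociates, an extracellular ion re-binds S0: net zero
        traj = pg.scripted_trajectory(
            ["K:0:2:4", "K:2:4", "K:0:2:4"]
        )
        decomp = pg.conduction_cycles(traj)
        assert decomp.cycles[0].conductions == 0
        assert decomp.cycles[0].category == "back_running"

    @pytest.mark.parametrize(
        "n_ko,n_ad,expect",
        [(10, 21, 0.48), (0, 5, 0.0)],
    )
    def test_ratio_arithmetic(self, n_ko, n_ad, expect):
        cats = ["knock_on"] * n_ko + ["assoc_dissoc"] * n_ad
        r = pg.mechanism_ratio(cats)
        assert round(r.ratio, 2) == expect
        assert r.finite

    def test_ratio_undefined_without_ad_cycles(self):
        r = pg.mechanism_ratio(["knock_on"] * 4)
        assert not r.finite
        assert math.isinf(r.ratio)
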