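"""Spatial statistics against brute-force and graph-theoretic oracles."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from spinemap import (
    LabeledSpinePattern,
    apply_exclusions,
    cluster_single_linkage,
    first_neighbor_distances,
    neighbor_probability_curve,
    pairwise_distances,
    patterns_from_table,
    separation_index,
    shuffle_null,
    unit_statistics,
    ztest_vs_one,
)

from conftest import random_pattern, straight_pattern


# --- independent oracles ----------------------------------------------------

def brute_force_first_neighbors(pattern):
    """All-pairs double loop, no vectorization: the independent route."""
    pos = pattern.positions
    out = []
    for i in range(pattern.T):
        if pattern.labels[i] != 1:
            continue
        d_pp, d_pn = np.inf, np.inf
        for j in range(pattern.T):
            if j == i:
                continue
            d = float(np.sqrt(((pos[i] - pos[j]) ** 2).sum()))
            if pattern.labels[j] == 1:
                d_pp = min(d_pp, d)
            else:
                d_pn = min(d_pn, d)
        out.append((i, d_pp if np.isfinite(d_pp) else np.nan,
                    d_pn if np.isfinite(d_pn) else np.nan))
    return out


def components_partition(pattern, cutoff):
    """Connected components of the strict <cutoff proximity graph (networkx)."""
    pos_idx = np.flatnonzero(pattern.labels == 1)
    g = nx.Graph()
    g.add_nodes_from(pos_idx.tolist())
    for a in range(pos_idx.size):
        for b in range(a + 1, pos_idx.size):
            i, j = pos_idx[a], pos_idx[b]
            if np.linalg.norm(pattern.positions[i]
                              - pattern.positions[j]) < cutoff:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def assignment_partition(asg):
    return {frozenset(asg.spine_index[asg.unit_id == u])
            for u in range(asg.n_units)}


def brute_force_curve(pattern, n_positions):
    """Neighbor-rank label matrix by explicit sort per focal spine."""
    rows = []
    for i in range(pattern.T):
        if pattern.labels[i] != 1:
            continue
        ranked = sorted(
            (float(np.linalg.norm(pattern.positions[j] - pattern.positions[i])), j)
            for j in range(pattern.T) if j != i)
        rows.append([pattern.labels[j] for _, j in ranked[:n_positions]])
    matrix = np.asarray(rows)
    prob = matrix.mean(axis=0)
    expected = (pattern.p - 1) / (pattern.T - 1)
    return prob, expected, prob / expected


# --- tests ------------------------------------------------------------------

class TestPairwiseDistances:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1, 1, 1), (1, 1, 1), 0.0),
        ((1, 2, 2), (0, 0, 0), 3.0),
    ])
    def test_euclidean_examples(self, a, b, expected):
        pat = LabeledSpinePattern("d", np.array([a, b], float), [1, 1])
        dm = pairwise_distances(pat)
        assert dm[0, 1] == pytest.approx(expected, abs=1e-12)
        assert dm[1, 0] == dm[0, 1] and dm[0, 0] == 0.0

    def test_single_spine_rejected(self):
        pat = LabeledSpinePattern("d", np.zeros((1, 3)), [1])
        with pytest.raises(ValueError):
            pairwise_distances(pat)


class TestFirstNeighborDistances:
    def test_two_collinear_positives(self):
        pat = straight_pattern([0.0, 3.0], [1, 1])
        res = first_neighbor_distances(pat)
        assert np.allclose(res.d_pp, [3.0, 3.0])
        assert res.n_skipped_pn == 2   # no negative spines exist

    def test_single_positive_is_skipped(self):
        pat = straight_pattern([0.0, 1.0, 2.0], [0, 1, 0])
        res = first_neighbor_distances(pat)
        assert np.isnan(res.d_pp).all() and res.n_skipped_pp == 1
        assert res.d_pn[0] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_patterns(self, rng):
        for _ in range(30):
            pat = random_pattern(rng, int(rng.integers(2, 60)))
            res = first_neighbor_distances(pat)
            oracle = brute_force_first_neighbors(pat)
            assert list(res.spine_index) == [i for i, _, _ in oracle]
            np.testing.assert_array_equal(res.d_pp, [d for _, d, _ in oracle])
            np.testing.assert_array_equal(res.d_pn, [d for _, _, d in oracle])


class TestShuffleNull:
    def test_all_positive_labels_shuffle_to_themselves(self):
        pat = straight_pattern([0.0, 1.0, 5.0], [1, 1, 1])
        obs = first_neighbor_distances(pat)
        null = shuffle_null(pat, n_shuffles=5, rng=0)
        for res in null.results:
            np.testing.assert_array_equal(res.d_pp, obs.d_pp)

    def test_shuffles_preserve_counts_and_positions(self, rng):
        pat = random_pattern(rng, 40, label_fraction=0.25)
        null = shuffle_null(pat, n_shuffles=5, rng=3)
        assert null.n_shuffles == 5
        for res in null.results:
            assert res.d_pp.size == pat.p   # p preserved by permutation

    def test_deterministic_under_fixed_seed(self, rng):
        pat = random_pattern(rng, 30)
        a = shuffle_null(pat, rng=42).pooled_d_pp()
        b = shuffle_null(pat, rng=42).pooled_d_pp()
        np.testing.assert_array_equal(a, b)


class TestProbabilityCurve:
    def test_saturated_labels_give_unit_curve(self):
        pat = straight_pattern(np.arange(25.0), np.ones(25, int))
        curve = neighbor_probability_curve(pat)
        assert np.allclose(curve.probability, 1.0)
        assert curve.expected == 1.0 and np.allclose(curve.increase, 1.0)

    def test_expected_probability_formula(self):
        labels = np.zeros(21, int)
        labels[:5] = 1
        pat = straight_pattern(np.arange(21.0), labels)
        curve = neighbor_probability_curve(pat)
        assert curve.expected == pytest.approx((5 - 1) / (21 - 1))  # 0.2

    def test_crafted_cluster_matches_enumeration_oracle(self, rng):
        # 25 spines, one tight 3-positive cluster plus scattered negatives
        arc = np.sort(rng.uniform(0, 50, size=25))
        labels = np.zeros(25, int)
        labels[[10, 11, 12]] = 1
        arc[10:13] = [20.0, 20.6, 21.1]
        pat = straight_pattern(np.sort(arc), labels[np.argsort(arc)])
        curve = neighbor_probability_curve(pat)
        prob, expected, increase = brute_force_curve(pat, 20)
        np.testing.assert_allclose(curve.probability, prob)
        assert curve.expected == pytest.approx(expected)
        np.testing.assert_allclose(curve.increase, increase)

    def test_random_patterns_match_oracle_both_rank_modes(self, rng):
        for _ in range(20):
            pat = random_pattern(rng, 30, label_fraction=0.4)
            if pat.p < 2:
                continue
            curve = neighbor_probability_curve(pat, rank_mode="euclidean")
            prob, _, _ = brute_force_curve(pat, 20)
            np.testing.assert_allclose(curve.probability, prob)
            # ordinal mode: still a valid probability curve over 20 ranks
            ordinal = neighbor_probability_curve(pat, rank_mode="ordinal")
            assert ordinal.probability.shape == (20,)
            assert np.all((0 <= ordinal.probability)
                          & (ordinal.probability <= 1))

    def test_too_few_spines_rejected(self):
        pat = straight_pattern(np.arange(10.0), [1] * 10)
        with pytest.raises(ValueError, match="cannot fill"):
            neighbor_probability_curve(pat)


class TestExclusions:
    def test_rules_and_retention(self):
        low_frac = straight_pattern(np.arange(40.0),
                                    [1] + [0] * 39, dendrite_id="low")
        short = straight_pattern(np.arange(15.0),
                                 [1, 1] + [0] * 13, dendrite_id="short")
        keep = straight_pattern(np.arange(30.0),
                                [1, 1, 1] + [0] * 27, dendrite_id="keep")
        retained, log = apply_exclusions([low_frac, short, keep])
        assert [p.dendrite_id for p in retained] == ["keep"]
        rules = {e["dendrite_id"]: e["rule"] for e in log}
        assert rules == {"low": "i", "short": "ii"}


class TestZtestVsOne:
    def test_identically_one_sample(self):
        assert ztest_vs_one([1.0, 1.0, 1.0]) == (0.0, 1.0)

    def test_symmetric_sample_gives_zero_z(self):
        z, p = ztest_vs_one([0.5, 1.5, 0.8, 1.2])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula_on_normal_draws(self):
        rng = np.random.default_rng(7)
        v = rng.normal(1.2, 0.5, size=100)
        z, p = ztest_vs_one(v)
        z_hand = (v.mean() - 1.0) / (v.std(ddof=1) / np.sqrt(100))
        assert z == pytest.approx(z_hand, rel=1e-12)
        assert p == pytest.approx(2 * norm.sf(abs(z_hand)), rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ztest_vs_one([1.3])
        with pytest.raises(ValueError, match="variance"):
            ztest_vs_one([2.0, 2.0, 2.0])


class TestClustering:
    def test_hand_checkable_chain(self):
        pat = straight_pattern([0.0, 1.5, 3.0, 10.0], [1, 1, 1, 1])
        asg = cluster_single_linkage(pat)
        sizes = sorted(asg.unit_sizes.tolist())
        assert sizes == [1, 3]
        stats = unit_statistics([asg])
        assert stats["fraction_in_clusters"] == pytest.approx(0.75)

    def test_boundary_distance_is_strictly_excluded(self):
        pat = straight_pattern([0.0, 2.0], [1, 1])
        asg = cluster_single_linkage(pat, cutoff=2.0)
        assert asg.n_units == 2   # exactly 2.0 um does NOT join

    def test_single_positive_is_a_unit_of_one(self):
        pat = straight_pattern([0.0, 1.0], [1, 0])
        asg = cluster_single_linkage(pat)
        assert asg.n_units == 1 and asg.unit_sizes.tolist() == [1]

    def test_matches_connected_components_on_random_patterns(self, rng):
        for _ in range(60):
            pat = random_pattern(rng, int(rng.integers(2, 80)),
                                 label_fraction=0.5, box=12.0)
            asg = cluster_single_linkage(pat)
            assert assignment_partition(asg) == components_partition(pat, 2.0)

    @given(st.lists(st.integers(0, 24), min_size=2, max_size=8, unique=True))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_grid_patterns_match_components(self, slots):
        # collinear spines on a 0.5 um grid: exercises exact-cutoff ties
        arc = np.array(sorted(slots)) * 0.5
        pat = straight_pattern(arc, np.ones(arc.size, int))
        asg = cluster_single_linkage(pat)
        assert assignment_partition(asg) == components_partition(pat, 2.0)

    def test_cutoff_monotonicity_never_splits_units(self, rng):
        for _ in range(20):
            pat = random_pattern(rng, 40, label_fraction=0.5, box=10.0)
            prev = None
            for cutoff in (0.5, 1.0, 2.0, 4.0, 8.0):
                asg = cluster_single_linkage(pat, cutoff=cutoff)
                if prev is not None:
                    assert asg.n_units <= prev.n_units
                    # every previous unit stays within a single new unit
                    for u in range(prev.n_units):
                        members = prev.spine_index[prev.unit_id == u]
                        sel = np.isin(asg.spine_index, members)
                        assert np.unique(asg.unit_id[sel]).size == 1
                prev = asg


class TestUnitStatistics:
    def test_sizes_three_and_one(self):
        pat = straight_pattern([0.0, 1.5, 3.0, 10.0], [1, 1, 1, 1])
        stats = unit_statistics([cluster_single_linkage(pat)])
        assert stats["mean_unit_size"] == pytest.approx(2.0)
        assert stats["fraction_in_clusters"] == pytest.approx(0.75)

    def test_all_singletons(self):
        pat = straight_pattern([0.0, 5.0, 10.0], [1, 1, 1])
        stats = unit_statistics([cluster_single_linkage(pat)])
        assert stats["fraction_in_clusters"] == 0.0
        assert np.isnan(stats["cluster_size_p5"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            unit_statistics([])


class TestSeparationIndex:
    def test_hand_arithmetic_slice(self):
        d1 = straight_pattern(np.arange(10.0), [1, 1, 1, 1] + [0] * 6,
                              dendrite_id="d1", slice_id="s0")
        d2 = straight_pattern(np.arange(10.0), [0] * 10,
                              dendrite_id="d2", slice_id="s0")
        si = separation_index([d1, d2]).set_index("dendrite_id")
        assert si.loc["d1", "f"] == pytest.approx(0.2)
        assert si.loc["d1", "p_star"] == pytest.approx(2.0)
        assert si.loc["d1", "si"] == pytest.approx(1.0)
        assert si.loc["d2", "si"] == pytest.approx(1.0)

    def test_exact_proportions_give_zero(self):
        pats = [straight_pattern(np.arange(10.0), [1, 1] + [0] * 8,
                                 dendrite_id=f"d{i}", slice_id="s0")
                for i in range(3)]
        si = separation_index(pats)
        assert np.allclose(si["si"], 0.0)

    def test_zero_positive_slice_logged_as_nan(self):
        pats = [straight_pattern(np.arange(5.0), [0] * 5,
                                 dendrite_id="d0", slice_id="s0")]
        si = separation_index(pats)
        assert np.isnan(si["si"]).all()

    def test_matches_spreadsheet_recomputation(self, rng):
        pats = [random_pattern(rng, int(rng.integers(10, 40)),
                               dendrite_id=f"d{i}") for i in range(8)]
        for p in pats:
            p.slice_id = "s0"
        si = separation_index(pats)
        f = sum(p.p for p in pats) / sum(p.T for p in pats)
        for p in pats:
            expect = abs(p.p - f * p.T) / (f * p.T)
            got = si.set_index("dendrite_id").loc[p.dendrite_id, "si"]
            assert got == pytest.approx(expect, rel=1e-12)


class TestPermutationInvariance:
    def test_row_order_never_changes_statistics(self, small_config):
        from spinemap import generate_dataset
        table, _ = generate_dataset(small_config)
        shuffled = table.sample(frac=1.0, random_state=0)
        a = patterns_from_table(table)
        b = patterns_from_table(shuffled)
        assert [p.dendrite_id for p in a] == [p.dendrite_id for p in b]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.positions, pb.positions)
            np.testing.assert_array_equal(pa.labels, pb.labels)
            res_a, res_b = (first_neighbor_distances(x) for x in (pa, pb))
            np.testing.assert_array_equal(res_a.d_pp, res_b.d_pp)
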