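"""Distance operations and the greedy caliper matcher.

The matcher is checked against a brute-force oracle that re-implements
the greedy contract directly: visit group-1 subjects in the seeded
order and, at each step, enumerate every remaining (group-2, group-3)
pair, drop inadmissible ones, and take the smallest total distance with
lexicographic tie-breaking.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplematch import (
    CaliperSpec,
    GreedyMatcher,
    greedy_match,
    matching_ratio,
    pairwise_distance,
    triplet_distance,
    within_caliper,
)

from conftest import random_logit_instance


def naive_greedy_triplets(scores, groups, caliper, order_seed, caliper_rule="distance"):
    """Brute-force per-step enumeration of the greedy contract (G=3)."""
    labels = np.unique(groups)
    pos = {g: list(np.nonzero(groups == g)[0]) for g in labels}
    sds = np.asarray(caliper.pooled_sds)
    w = caliper.width_multiplier
    pair_budget = (len(labels) - 1) * w * w * float(np.sum(sds * sds))

    def adm(i, j):
        if caliper_rule == "component":
            return within_caliper(scores[i], scores[j], caliper)
        if caliper_rule == "distance":
            return pairwise_distance(scores[i], scores[j]) <= pair_budget
        raise ValueError(caliper_rule)

    order = np.random.default_rng(order_seed).permutation(len(pos[labels[0]]))
    free2, free3 = list(pos[labels[1]]), list(pos[labels[2]])
    triplets = []
    for a_local in order:
        a = pos[labels[0]][a_local]
        best = None
        for b, c in itertools.product(sorted(free2), sorted(free3)):
            if caliper_rule == "total":
                if triplet_distance(scores[a], scores[b], scores[c]) > 3 * pair_budget:
                    continue
            elif not (adm(a, b) and adm(a, c) and adm(b, c)):
                continue
            d = triplet_distance(scores[a], scores[b], scores[c])
            if best is None or d < best[0]:
                best = (d, b, c)
        if best is not None:
            _, b, c = best
            free2.remove(b)
            free3.remove(c)
            triplets.append((a, b, c))
    return triplets


class TestDistances:
    def test_pairwise_closed_forms(self):
        assert pairwise_distance([0, 0, 0], [1, 1, 1]) == pytest.approx(3.0)
        assert pairwise_distance([1, 2], [1, 2]) == 0.0
        assert pairwise_distance([0, 0], [1, 2], "absolute") == pytest.approx(3.0)
        with pytest.raises(ValueError):
            pairwise_distance([0, 0], [0, 0, 0])

    def test_triplet_closed_form(self):
        a, b, c = [0, 0, 0], [1, 1, 1], [2, 2, 2]
        assert triplet_distance(a, b, c) == pytest.approx(3 + 12 + 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 3))
        assert pairwise_distance(a, b) == pytest.approx(pairwise_distance(b, a))
        base = triplet_distance(a, b, c)
        for x, y, z in itertools.permutations([a, b, c]):
            assert triplet_distance(x, y, z) == pytest.approx(base)


class TestWithinCaliper:
    def test_component_rule(self):
        spec = CaliperSpec(0.2, (1.0, 1.0, 1.0))
        a = np.zeros(3)
        assert within_caliper(a, a + 0.19, spec)
        assert not within_caliper(a, np.array([0.0, 0.0, 0.21]), spec)
        assert within_caliper(a, a, CaliperSpec(0.01, (1, 1, 1)))

    def test_zero_width_rejects_distinct_rows(self):
        spec = CaliperSpec(0.0, (1.0, 1.0, 1.0))
        assert within_caliper(np.zeros(3), np.zeros(3), spec)
        assert not within_caliper(np.zeros(3), np.ones(3), spec)


class TestGreedyMatch:
    @pytest.mark.parametrize("caliper_rule", ["distance", "component", "total"])
    def test_matches_bruteforce_oracle_on_small_instances(self, caliper_rule):
        rng = np.random.default_rng(2024)
        for case in range(150):
            scores, groups = random_logit_instance(rng)
            sds = tuple(rng.uniform(0.5, 2.0, size=3))
            w = float(rng.choice([0.1, 0.3, 0.8, 2.0]))
            caliper = CaliperSpec(w, sds)
            seed = int(rng.integers(2**31))
            sample = greedy_match(
                scores, groups, caliper, seed, caliper_rule=caliper_rule
            )
            expected = naive_greedy_triplets(
                scores, groups, caliper, seed, caliper_rule
            )
            got = [t.indices for t in sample.triplets]
            assert got == [tuple(e) for e in expected], f"case {case}"

    def test_identical_rows_match_min_group_size(self):
        groups = np.repeat([1, 2, 3], [3, 5, 4])
        scores = np.zeros((len(groups), 3))
        sample = greedy_match(scores, groups, CaliperSpec(0.1, (1, 1, 1)), 0)
        assert sample.n_triplets == 3
        assert matching_ratio(sample) == 1.0

    def test_zero_caliper_distinct_rows_matches_nothing(self):
        rng = np.random.default_rng(0)
        groups = np.repeat([1, 2, 3], 4)
        scores = rng.normal(size=(12, 3))
        sample = greedy_match(scores, groups, CaliperSpec(0.0, (1, 1, 1)), 0)
        assert sample.n_triplets == 0
        assert len(sample.unmatched) == 12

    def test_without_replacement_and_caliper_audit(self, fitted_cohort):
        _, _, logits, groups = fitted_cohort
        caliper = CaliperSpec.from_scores(logits, groups, 0.2)
        sample = greedy_match(logits, groups, caliper, 7)
        ids = sample.matched_ids()
        assert len(ids) == len(set(ids)) == 3 * sample.n_triplets
        budget = 2 * 0.2**2 * np.sum(np.asarray(caliper.pooled_sds) ** 2)
        for t in sample.triplets:
            i, j, k = t.indices
            assert groups[i] == 1 and groups[j] == 2 and groups[k] == 3
            for a, b in [(i, j), (i, k), (j, k)]:
                assert pairwise_distance(logits[a], logits[b]) <= budget + 1e-12

    def test_deterministic_given_order_seed(self, fitted_cohort):
        _, _, logits, groups = fitted_cohort
        caliper = CaliperSpec.from_scores(logits, groups, 0.3)
        s1 = greedy_match(logits, groups, caliper, 99)
        s2 = greedy_match(logits, groups, caliper, 99)
        assert [t.indices for t in s1.triplets] == [t.indices for t in s2.triplets]
        s3 = greedy_match(logits, groups, caliper, 100)
        assert [t.indices for t in s1.triplets] != [t.indices for t in s3.triplets]

    def test_two_group_reduction_to_classic_greedy(self):
        """With G=2 the matcher is classic greedy caliper matching on |d logit|."""
        rng = np.random.default_rng(11)
        n1, n2 = 12, 20
        ell = rng.normal(size=n1 + n2)
        scores = np.column_stack([ell, -ell])  # logits of (p, 1-p)
        groups = np.repeat([1, 2], [n1, n2])
        s = np.std(ell, ddof=1)
        caliper = CaliperSpec(0.25, (s, s))
        sample = greedy_match(scores, groups, caliper, 5)

        # classic algorithm on the scalar logit
        order = np.random.default_rng(5).permutation(n1)
        free = list(range(n1, n1 + n2))
        expected = []
        for a in order:
            cands = [(abs(ell[a] - ell[b]), b) for b in free if abs(ell[a] - ell[b]) <= 0.25 * s]
            if cands:
                _, b = min(cands)
                free.remove(b)
                expected.append((a, b))
        assert [t.indices for t in sample.triplets] == expected

    def test_degenerate_inputs_rejected(self):
        # a single group cannot be matched; option names are validated
        with pytest.raises(ValueError):
            greedy_match(np.zeros((4, 3)), np.array([1, 1, 1, 1]), CaliperSpec(0.2, (1, 1, 1)), 0)
        with pytest.raises(ValueError):
            GreedyMatcher(np.zeros((2, 3)), np.array([1, 2]), caliper_rule="nope")


class TestMatchingRatio:
    def test_definition_arithmetic(self):
        groups = np.repeat([1, 2, 3], [100, 200, 700])
        scores = np.zeros((1000, 3))
        sample = greedy_match(scores, groups, CaliperSpec(0.5, (1, 1, 1)), 0)
        sample.triplets = sample.triplets[:82]
        assert matching_ratio(sample) == pytest.approx(0.82)
        sample.triplets = []
        assert matching_ratio(sample) == 0.0
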