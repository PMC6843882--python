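import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from scdiscrim import SyntheticSpec, discretize, filter_by_max_expression, generate
from scdiscrim.mrmr import (
    MrmrState,
    entropy,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)
from scdiscrim.preprocessing import DiscretizedMatrix

from conftest import planted_rows


# -- independent oracles ---------------------------------------------------

def mi_oracle(x, y) -> float:
    """Plug-in MI by direct dictionary counting; independent of the package."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log2(pab * n * n / (px[a] * py[b]))
    return total


def greedy_mrmr_oracle(states, target, top_n):
    """Brute-force greedy ranking evaluating the criterion from scratch."""
    p = len(states)
    selected = []
    while len(selected) < min(top_n, p):
        best, best_crit = None, -math.inf
        for t in range(p):
            if t in selected:
                continue
            rel = mi_oracle(states[t], target)
            red = (
                sum(mi_oracle(states[t], states[s]) for s in selected) / len(selected)
                if selected else 0.0
            )
            crit = rel - red
            if crit > best_crit + 1e-12:
                best, best_crit = t, crit
        selected.append(best)
    return selected


def _disc(states) -> DiscretizedMatrix:
    states = np.asarray(states, dtype=np.int8)
    return DiscretizedMatrix(
        states=states,
        low_cut=np.zeros(len(states)),
        high_cut=np.zeros(len(states)),
        transform="identity",
        sigma=1.0,
    )


# -- mutual information ----------------------------------------------------

class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        assert mutual_information(list("AABB"), list("AABB")) == pytest.approx(1.0)

    def test_constant_partner_is_zero(self):
        assert mutual_information(list("AABB"), list("CCCC")) == pytest.approx(0.0)

    def test_hand_evaluated_joint_table(self):
        # joint counts {(A,C):4, (A,D):1, (B,C):1, (B,D):4}; double sum by hand
        x = list("AAAAA" + "BBBBB")
        y = list("CCCCD" + "CDDDD")
        assert mutual_information(x, y) == pytest.approx(0.2780719051, abs=1e-9)
        assert mi_oracle(x, y) == pytest.approx(0.2780719051, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1, 2, 3])

    def test_matches_sklearn_contingency_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 3, size=50)
            y = rng.integers(0, 4, size=50)
            ours = mutual_information(x, y)
            theirs = mutual_info_score(x, y) / math.log(2)
            assert ours == pytest.approx(theirs, abs=1e-12)

    @given(
        st.lists(st.integers(0, 2), min_size=2, max_size=40),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_nonnegativity_entropy_bound(self, x, data):
        y = data.draw(st.lists(st.integers(0, 3), min_size=len(x), max_size=len(x)))
        ixy = mutual_information(x, y)
        assert ixy == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert ixy >= -1e-12
        assert ixy <= min(entropy(x), entropy(y)) + 1e-12


# -- relevance / redundancy ------------------------------------------------

class TestRelevanceRedundancy:
    def _state(self, n_selected, n_candidates, target):
        return MrmrState(
            selected=list(range(n_selected)),
            candidates=set(range(n_selected, n_selected + n_candidates)),
            all_indices=range(n_selected + n_candidates),
            target=np.asarray(target),
        )

    def test_relevance_of_label_copy_equals_label_entropy(self):
        target = np.array([1, 1, 1, 0, 0])
        disc = _disc([target])
        state = self._state(0, 1, target)
        assert relevance(0, state, disc) == pytest.approx(entropy(target))

    def test_relevance_of_independent_transcript_is_zero(self):
        target = np.array([1, 1, 0, 0])
        disc = _disc([[1, -1, 1, -1]])
        assert relevance(0, self._state(0, 1, target), disc) == pytest.approx(0.0)

    def test_relevance_matches_direct_mi_call(self):
        rng = np.random.default_rng(4)
        states = rng.integers(-1, 2, size=(3, 30))
        target = rng.integers(0, 2, size=30)
        disc = _disc(states)
        state = self._state(0, 3, target)
        for t in range(3):
            assert relevance(t, state, disc) == pytest.approx(
                mutual_information(states[t], target)
            )

    def test_redundancy_empty_selected_is_zero(self):
        disc = _disc([[1, 0, -1]])
        assert redundancy(0, self._state(0, 1, [1, 0, 1]), disc) == 0.0

    def test_redundancy_against_own_copy_is_entropy(self):
        row = [1, 1, 0, -1]
        disc = _disc([row, row])
        state = self._state(1, 1, [1, 0, 1, 0])
        assert redundancy(1, state, disc) == pytest.approx(entropy(row))

    def test_redundancy_is_mean_of_pairwise_mi(self):
        rng = np.random.default_rng(8)
        states = rng.integers(-1, 2, size=(4, 25))
        disc = _disc(states)
        state = self._state(3, 1, rng.integers(0, 2, 25))
        expected = np.mean([mi_oracle(states[3], states[s]) for s in range(3)])
        assert redundancy(3, state, disc) == pytest.approx(expected, abs=1e-12)

    def test_already_selected_is_an_error(self):
        disc = _disc([[1, 0, -1]])
        with pytest.raises(ValueError):
            relevance(0, self._state(1, 0, [1, 0, 1]), disc)


# -- greedy ranking --------------------------------------------------------

class TestMrmrRank:
    def test_single_transcript_universe(self):
        target = np.array([1, 1, 0, 0])
        disc = _disc([[1, 1, -1, -1]])
        r = mrmr_rank(disc, target, top_n=5)
        assert r.order == [0]
        assert r.scores[0] == pytest.approx(1.0)

    def test_redundancy_penalty_displaces_duplicate(self):
        # A1 and A2 are identical perfect predictors (with extra entropy, so
        # the self-redundancy penalty bites); B is weaker but novel
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        a = [1, 1, 0, 0, -1, -1, -1, -1]
        b = [1, 1, 1, -1, -1, -1, -1, 1]
        r = mrmr_rank(_disc([a, a, b]), target, top_n=2)
        assert r.order == [0, 2]
        assert r.order == greedy_mrmr_oracle([tuple(a), tuple(a), tuple(b)],
                                             tuple(target), 2)

    def test_first_rank_maximizes_relevance(self):
        rng = np.random.default_rng(12)
        states = rng.integers(-1, 2, size=(15, 40))
        target = rng.integers(0, 2, size=40)
        r = mrmr_rank(_disc(states), target, top_n=15)
        assert r.relevance[0] == pytest.approx(max(r.relevance))
        assert r.scores[0] == pytest.approx(r.relevance[0])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        states = rng.integers(-1, 2, size=(6, 40))
        target = rng.integers(0, 2, size=40)
        r = mrmr_rank(_disc(states), target, top_n=6)
        assert r.order == greedy_mrmr_oracle([tuple(s) for s in states], tuple(target), 6)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(30)
        states = rng.integers(-1, 2, size=(40, 60))
        target = rng.integers(0, 2, size=60)
        r1 = mrmr_rank(_disc(states), target, top_n=40)
        r2 = mrmr_rank(_disc(states), target, top_n=40)
        assert r1.order == r2.order
        assert r1.scores == r2.scores

    def test_tie_break_prefers_lower_row_index(self):
        target = np.array([1, 1, 0, 0])
        row = [1, 1, -1, -1]
        r = mrmr_rank(_disc([row, row]), target, top_n=1)
        assert r.order == [0]

    def test_invalid_inputs(self):
        disc = _disc([[1, -1]])
        with pytest.raises(ValueError):
            mrmr_rank(disc, [1, 0], top_n=0)
        with pytest.raises(ValueError):
            mrmr_rank(disc, [1, 1], top_n=1)  # single-class target

    def test_planted_transcripts_rank_near_top(self):
        """>=90% of 20 planted transcripts among 500 appear in the top 40."""
        matrix, truth = generate(SyntheticSpec(n_transcripts=500, n_de=20, seed=1))
        filtered = filter_by_max_expression(matrix)
        ranking = mrmr_rank(discretize(filtered), filtered.labels, top_n=40)
        planted = planted_rows(filtered, truth)
        recovered = planted & set(ranking.order)
        assert len(recovered) >= 0.9 * len(planted)
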