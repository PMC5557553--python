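"""Reactive units, categories, classification, lexicon and CS windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexinet import agents as ag


class TestActivation:
    def test_unit_center_gives_one(self):
        u = ag.ReactiveUnit(center=[1.0, 2.0, 3.0])
        assert ag.activation(u, [1.0, 2.0, 3.0]) == 1.0

    def test_closed_form(self):
        u = ag.ReactiveUnit(center=[0.0, 0.0])
        assert ag.activation(u, [1.0, 1.0]) == pytest.approx(math.exp(-1))

    def test_distant_stimulus_underflows_to_zero(self):
        u = ag.ReactiveUnit(center=[0.0, 0.0, 0.0])
        assert ag.activation(u, [50.0, 0.0, 0.0]) == 0.0

    def test_dimension_mismatch_rejected(self):
        u = ag.ReactiveUnit(center=[0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            ag.activation(u, [0.0, 0.0])

    @given(st.floats(0.1, 40.0), st.floats(0.1, 40.0))
    def test_monotone_decreasing_in_distance(self, d1, d2):
        u = ag.ReactiveUnit(center=[0.0])
        lo, hi = sorted([d1, d2])
        assert ag.activation(u, [hi]) <= ag.activation(u, [lo])


class TestCategoryResponse:
    def test_weighted_sum(self):
        c = ag.Category(id=0, units=[
            ag.ReactiveUnit(center=[0.0, 0.0], weight=2.0),
            ag.ReactiveUnit(center=[1.0, 1.0], weight=3.0),
        ])
        expected = 2.0 + 3.0 * math.exp(-1)
        assert ag.category_response(c, [0.0, 0.0]) == pytest.approx(expected)

    def test_zero_weights_zero_response(self):
        c = ag.Category(id=0, units=[
            ag.ReactiveUnit(center=[0.0, 0.0], weight=0.0)])
        assert ag.category_response(c, [0.0, 0.0]) == 0.0

    def test_linear_in_weights(self):
        units = [ag.ReactiveUnit(center=[0.0, 1.0], weight=1.5),
                 ag.ReactiveUnit(center=[2.0, 0.0], weight=0.5)]
        c = ag.Category(id=0, units=units)
        x = [0.3, 0.3]
        base = ag.category_response(c, x)
        for u in units:
            u.weight *= 3.0
        assert ag.category_response(c, x) == pytest.approx(3.0 * base)


class TestClassification:
    def test_no_categories_gives_none(self):
        assert ag.Agent().classify([0.0, 0.0, 0.0]) is None

    def test_nearer_category_wins(self):
        a = ag.Agent()
        a.learn_topic(np.array([1.0, 0.0, 0.0]))
        a.learn_topic(np.array([3.0, 0.0, 0.0]))
        assert a.classify([0.0, 0.0, 0.0]) == 0

    def test_tie_breaks_to_earliest_category(self):
        a = ag.Agent()
        a.learn_topic(np.array([1.0, 0.0, 0.0]))
        a.learn_topic(np.array([-1.0, 0.0, 0.0]))
        # equidistant -> identical responses -> earliest id
        assert a.classify([0.0, 0.0, 0.0]) == 0

    def test_unfamiliar_stimulus_all_zero_earliest(self):
        a = ag.Agent()
        a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.learn_topic(np.array([100.0, 0.0, 0.0]))
        assert a.classify([0.0, 200.0, 0.0]) == 0

    def test_permutation_invariant_over_unit_order(self):
        a = ag.Agent()
        cat = a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.history.extend([True] * 50)  # CS = 1 > 0.95: absorb next topics
        a.learn_topic(np.array([0.5, 0.0, 0.0]))
        a.learn_topic(np.array([0.0, 0.5, 0.0]))
        assert len(a.categories) == 1
        x = [0.2, 0.1, 0.0]
        before = a.responses(np.array([x]))[0, 0]
        cat.units.reverse()
        a._flat_dirty = True
        assert a.responses(np.array([x]))[0, 0] == pytest.approx(before)


class TestLearning:
    def test_fresh_agent_creates_category(self):
        a = ag.Agent()
        a.learn_topic(np.array([1.0, 2.0, 3.0]))
        assert len(a.categories) == 1
        assert a.categories[0].units[0].weight == 1.0

    def test_high_cs_appends_unit_instead(self):
        a = ag.Agent()
        a.learn_topic(np.array([1.0, 2.0, 3.0]))
        a.history.extend([True] * 49 + [False])  # CS = 0.98
        a.learn_topic(np.array([1.5, 2.0, 3.0]))
        assert len(a.categories) == 1
        assert len(a.categories[0].units) == 2

    def test_cs_exactly_at_threshold_creates_category(self):
        a = ag.Agent()
        a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.history.extend([True] * 19 + [False])  # CS = 0.95, not > 0.95
        assert a.cs() == pytest.approx(0.95)
        a.learn_topic(np.array([1.0, 0.0, 0.0]))
        assert len(a.categories) == 2

    def test_reinforce_at_center(self):
        a = ag.Agent()
        cat = a.learn_topic(np.array([1.0, 2.0, 3.0]))
        a.reinforce_category(cat, np.array([1.0, 2.0, 3.0]))
        assert cat.units[0].weight == pytest.approx(2.0)

    def test_reinforce_closed_form_and_zero_beta(self):
        a = ag.Agent(learning_rate=1.0)
        cat = a.learn_topic(np.array([0.0, 0.0]))
        cat.units[0].weight = 0.5
        a._flat_dirty = True
        a.reinforce_category(cat, np.array([1.0, 1.0]))
        assert cat.units[0].weight == pytest.approx(0.5 + math.exp(-1))
        b = ag.Agent(learning_rate=0.0)
        cb = b.learn_topic(np.array([0.0, 0.0]))
        b.reinforce_category(cb, np.array([0.0, 0.0]))
        assert cb.units[0].weight == 1.0

    def test_reinforce_foreign_category_rejected(self):
        a, b = ag.Agent(), ag.Agent()
        cat = b.learn_topic(np.array([0.0, 0.0, 0.0]))
        with pytest.raises((ValueError, KeyError)):
            a.reinforce_category(cat, np.array([0.0, 0.0, 0.0]))

    def test_decay_is_multiplicative_and_composes(self):
        a = ag.Agent(forgetting_rate=0.01)
        cat = a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.decay_units()
        assert cat.units[0].weight == pytest.approx(0.99)
        for _ in range(9):
            a.decay_units()
        assert cat.units[0].weight == pytest.approx(0.99**10)

    def test_zero_forgetting_is_identity(self):
        a = ag.Agent(forgetting_rate=0.0)
        cat = a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.decay_units()
        assert cat.units[0].weight == 1.0

    def test_decay_preserves_within_category_ordering(self):
        a = ag.Agent()
        a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.learn_topic(np.array([10.0, 0.0, 0.0]))
        x = [0.1, 0.0, 0.0]
        before = a.classify(x)
        a.decay_units()
        assert a.classify(x) == before


class TestLexicon:
    def test_strongest_word_argmax(self):
        lex = ag.Lexicon()
        lex.set(0, "w1", 0.5)
        lex.set(0, "w2", 0.7)
        assert lex.strongest_word(0) == "w2"
        assert lex.strongest_word(1) is None

    def test_strongest_word_tie_breaks_to_earliest_token(self):
        wf = ag.WordFactory()
        w1, w2 = wf.new_word(), wf.new_word()
        lex = ag.Lexicon()
        lex.set(0, w2, 0.5)
        lex.set(0, w1, 0.5)
        assert lex.strongest_word(0) == w1

    def test_strongest_category_mirror(self):
        lex = ag.Lexicon()
        lex.set(1, "w", 0.6)
        lex.set(2, "w", 0.4)
        assert lex.strongest_category("w") == 1
        assert lex.strongest_category("unknown") is None
        lex.set(3, "v", 0.4)
        lex.set(0, "v", 0.4)
        assert lex.strongest_category("v") == 0

    def test_update_clamps_to_unit_interval(self):
        lex = ag.Lexicon()
        lex.set(0, "w", 0.5)
        assert lex.update(0, "w", 0.1) == pytest.approx(0.6)
        lex.set(0, "w", 0.05)
        assert lex.update(0, "w", -0.1) == 0.0
        lex.set(0, "w", 0.95)
        assert lex.update(0, "w", 0.1) == 1.0

    def test_missing_pair_counts_as_zero(self):
        lex = ag.Lexicon()
        assert lex.update(0, "w", 0.1) == pytest.approx(0.1)

    def test_lateral_inhibition_touches_only_existing_pairs(self):
        lex = ag.Lexicon()
        lex.set(0, "w", 0.5)
        lex.set(1, "w", 0.3)
        lex.inhibit_other_categories("w", keep=0)
        assert lex.strength(0, "w") == 0.5
        assert lex.strength(1, "w") == pytest.approx(0.2)
        assert lex.strength(2, "w") == 0.0
        assert 2 not in lex.categories_for("w")

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3),
                              st.sampled_from([0.1, -0.1])),
                    max_size=60))
    @settings(deadline=None)
    def test_strengths_stay_in_unit_interval(self, ops):
        lex = ag.Lexicon()
        words = ["a", "b", "c", "d"]
        for cat, wi, delta in ops:
            lex.update(cat, words[wi], delta)
        assert all(0.0 <= s <= 1.0 for _, _, s in lex.items())


class TestLogSpaceAndPruning:
    def test_log_space_agrees_with_linear_when_no_underflow(self):
        a = ag.Agent()
        b = ag.Agent(log_space=True)
        for topic in ([0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [0.0, 5.0, 0.0]):
            a.learn_topic(np.array(topic))
            b.learn_topic(np.array(topic))
        for x in ([1.0, 1.0, 0.0], [4.0, 0.5, 0.0], [0.0, 4.0, 1.0]):
            assert a.classify(x) == b.classify(x)

    def test_log_space_resolves_underflowed_comparisons(self):
        # both categories respond exactly 0 in linear space; the log-space
        # comparison still finds the nearer one
        b = ag.Agent(log_space=True)
        b.learn_topic(np.array([100.0, 0.0, 0.0]))
        b.learn_topic(np.array([120.0, 0.0, 0.0]))
        assert b.classify([119.0, 0.0, 0.0]) == 1

    def test_prune_drops_dead_units_and_lexicon_rows(self):
        a = ag.Agent()
        a.learn_topic(np.array([0.0, 0.0, 0.0]))
        a.learn_topic(np.array([50.0, 0.0, 0.0]))
        a.lexicon.set(1, "w", 0.5)
        a.categories[1].units[0].weight = 0.0
        a._flat_dirty = True
        removed = a.prune_units(min_weight=0.0)
        assert removed == 1
        assert [c.id for c in a.categories] == [0]
        assert a.lexicon.strongest_category("w") is None
        assert a.classify([50.0, 0.0, 0.0]) == 0


class TestHistoryAndWords:
    def test_cs_window_and_partial_window(self):
        a = ag.Agent()
        assert a.cs() == 0.0
        for ok in (True, True, True):
            a.record_outcome(ok)
        assert a.cs() == 1.0
        for _ in range(50):
            a.record_outcome(False)
        assert a.cs() == 0.0
        for _ in range(25):
            a.record_outcome(True)
        assert a.cs() == pytest.approx(0.5)
        assert len(a.history) == 50

    def test_word_factory_unique_and_ordered(self):
        wf = ag.WordFactory()
        tokens = [wf.new_word() for _ in range(1000)]
        assert len(set(tokens)) == 1000
        assert tokens == sorted(tokens)

    def test_module_level_new_word_distinct(self):
        assert ag.new_word() != ag.new_word()


class TestSerialization:
    def test_agent_json_round_trip(self):
        a = ag.Agent(forgetting_rate=0.02)
        a.learn_topic(np.array([1.0, 2.0, 3.0]))
        a.learn_topic(np.array([60.0, 0.0, 0.0]))
        a.lexicon.set(0, "w00000001", 0.4)
        a.record_outcome(True)
        a.record_outcome(False)
        b = ag.Agent.from_json(a.to_json())
        assert b.to_json() == a.to_json()
        assert b.classify([1.0, 2.0, 3.0]) == a.classify([1.0, 2.0, 3.0])

    def test_naming_agent_round_trip(self):
        a = ag.NamingAgent()
        a.set("s1", "w1", 0.5)
        a.record_outcome(True)
        b = ag.NamingAgent.from_json(a.to_json())
        assert b.to_json() == a.to_json()
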