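"""Task environment: designs, balance, orders, trials, dynamics, NMI."""

import numpy as np
import pytest

from gridgen import taskenv
from gridgen.taskenv import (DesignError, GridWorld, build_design,
                             generate_context_order, generate_trial, nmi,
                             transition)


class TestDesigns:
    @pytest.mark.parametrize("key,n_train,n_test,n_train_ctx", [
        ("1_repeat", 32, 16, 3),
        ("1_switch", 32, 16, 3),
        ("2", 112, 24, 7),
        ("3", 120, 30, 5),
    ])
    def test_trial_totals(self, designs, key, n_train, n_test, n_train_ctx):
        d = designs[key]
        assert d.n_train_trials == n_train
        assert d.n_test_trials == n_test
        assert len(d.training_contexts) == n_train_ctx

    def test_exp1_context_structure(self, designs):
        d = designs["1_repeat"]
        counts = [c.n_trials for c in d.training_contexts]
        assert sorted(counts) == [8, 8, 16]
        # the doubly frequent context carries the low-popularity goal/mapping
        big = max(d.training_contexts, key=lambda c: c.n_trials)
        assert big.rewarded_goal == "B"
        # repeat test keeps goal A with its trained mapping
        a_train_map = {c.rewarded_goal: c.mapping_id for c in d.training_contexts}
        for c in d.test_contexts:
            assert c.mapping_id == a_train_map[c.rewarded_goal]
        ds = designs["1_switch"]
        for c in ds.test_contexts:
            assert c.mapping_id != a_train_map[c.rewarded_goal]

    def test_exp2_balance_derived(self, designs):
        d = designs["2"]
        per_goal, per_map = {}, {}
        for c in d.training_contexts:
            per_goal[c.rewarded_goal] = per_goal.get(c.rewarded_goal, 0) + c.n_trials
            per_map[c.mapping_id] = per_map.get(c.mapping_id, 0) + c.n_trials
        assert set(per_goal.values()) == {28}
        assert set(per_map.values()) == {56}
        pops = {}
        for c in d.training_contexts:
            pops[c.rewarded_goal] = pops.get(c.rewarded_goal, 0) + 1
        assert pops == {"A": 3, "B": 2, "C": 1, "D": 1}

    def test_exp3_balance_derived(self, designs):
        d = designs["3"]
        per_goal, per_map = {}, {}
        for c in d.training_contexts:
            per_goal[c.rewarded_goal] = per_goal.get(c.rewarded_goal, 0) + c.n_trials
            per_map[c.mapping_id] = per_map.get(c.mapping_id, 0) + c.n_trials
        assert set(per_goal.values()) == {40}
        assert set(per_map.values()) == {60}
        low = sorted(c.n_trials for c in d.training_contexts
                     if c.mapping_id == "m_low")
        high = sorted(c.n_trials for c in d.training_contexts
                      if c.mapping_id == "m_high")
        assert low == [20, 40] and high == [10, 10, 40]

    def test_bad_requests(self):
        with pytest.raises(DesignError):
            build_design(4)
        with pytest.raises(DesignError):
            build_design(1)
        with pytest.raises(DesignError):
            build_design(2, "repeat")

    def test_json_round_trip(self, designs):
        d = designs["2"]
        d2 = taskenv.ExperimentDesign.from_json(d.to_json())
        assert d2.experiment == d.experiment
        assert [c.n_trials for c in d2.contexts] == [c.n_trials for c in d.contexts]
        assert d2.mappings["m_low"].assignment == d.mappings["m_low"].assignment


class TestKeyMapping:
    def test_active_hand_bijection(self, designs):
        for m in designs["2"].mappings.values():
            a = m.assignment
            active = [k for k, v in a.items() if v != "NONE"]
            assert len(active) == 4
            assert sorted(a[k] for k in active) == sorted("NSEW")
            hand = taskenv.LEFT_KEYS if m.hand == "left" else taskenv.RIGHT_KEYS
            assert set(active) == set(hand)

    def test_admissible_patterns_only(self):
        with pytest.raises(DesignError):
            taskenv.KeyMapping("m", "left", "NSWE")


class TestContextOrder:
    def test_counts_conserved(self, designs):
        for key, d in designs.items():
            for phase in ("training", "test"):
                order = generate_context_order(d, phase, seed=7)
                ctxs = (d.training_contexts if phase == "training"
                        else d.test_contexts)
                for c in ctxs:
                    assert order.count(c.context_id) == c.n_trials

    def test_half_balance_exp1(self, designs):
        d = designs["1_repeat"]
        for seed in range(20):
            order = generate_context_order(d, "training", seed)
            half = len(order) // 2
            for c in d.training_contexts:
                assert order[:half].count(c.context_id) == c.n_trials // 2

    def test_first_half_switch_rate(self, designs):
        # Monte-Carlo estimate of the adjacent-context switch rate in the
        # first half of training, which targets the stated 25% hazard.
        d = designs["1_repeat"]
        switches = total = 0
        for seed in range(1000):
            order = generate_context_order(d, "training", seed)
            half = order[:len(order) // 2]
            switches += sum(a != b for a, b in zip(half, half[1:]))
            total += len(half) - 1
        assert abs(switches / total - 0.25) < 0.03

    def test_second_half_rarely_switches(self, designs):
        d = designs["3"]
        rates = []
        for seed in range(300):
            order = generate_context_order(d, "training", seed)
            half = order[len(order) // 2:]
            rates.append(np.mean([a != b for a, b in zip(half, half[1:])]))
        # 8% hazard, floored by the need to show every context in each half
        assert np.mean(rates) < 0.15


class TestTrials:
    def test_start_never_on_goal(self, designs, rng):
        d = designs["2"]
        for _ in range(300):
            t = generate_trial(d, 0, rng)
            assert t.start_cell not in t.grid.goal_cells.values()
            assert len(t.grid.goal_cells) == len(d.goal_labels)

    def test_goals_reachable_with_walls(self, designs, rng):
        d = designs["3"]
        walled = 0
        for _ in range(300):
            t = generate_trial(d, 0, rng)
            walled += bool(t.grid.walls)
            for cell in t.grid.goal_cells.values():
                assert taskenv._reachable(t.grid, t.start_cell, cell)
        assert 0 < walled < 300

    def test_goal_placement_uniformity(self, designs, rng):
        from scipy.stats import chisquare
        d = designs["1_repeat"]
        counts = np.zeros(36)
        n = 4000
        for _ in range(n):
            t = generate_trial(d, 0, rng)
            c, r = t.grid.goal_cells["A"]
            counts[r * 6 + c] += 1
        assert chisquare(counts).pvalue > 0.01


class TestTransition:
    def test_convention_and_boundaries(self, open_trial):
        assert transition(open_trial, (0, 0), "E") == ((1, 0), False)
        assert transition(open_trial, (0, 0), "S") == ((0, 1), False)
        assert transition(open_trial, (3, 0), "N") == ((3, 0), True)
        assert transition(open_trial, (0, 3), "W") == ((0, 3), True)
        assert transition(open_trial, (2, 2), "NONE") == ((2, 2), False)

    def test_walls_block_symmetrically(self, designs):
        grid = GridWorld(walls=frozenset({frozenset({(2, 2), (3, 2)})}),
                         goal_cells={"A": (5, 5)})
        t = taskenv.TrialSpec(0, 0, grid, (0, 0), "training")
        assert transition(t, (2, 2), "E") == ((2, 2), True)
        assert transition(t, (3, 2), "W") == ((3, 2), True)

    def test_pure_function(self, open_trial):
        assert all(transition(open_trial, (1, 1), m)
                   == transition(open_trial, (1, 1), m)
                   for m in taskenv.KEY_OUTCOMES)

    def test_out_of_bounds_rejected(self, open_trial):
        with pytest.raises(ValueError):
            transition(open_trial, (6, 0), "N")


class TestNMI:
    def test_printed_design_statistics(self, designs):
        assert nmi(designs["1_repeat"]) == pytest.approx(1.0)
        assert nmi(designs["2"]) == pytest.approx(0.1661, abs=5e-4)
        assert nmi(designs["3"]) == pytest.approx(0.3063, abs=5e-4)

    def test_bounds_and_degenerate(self, designs):
        for d in designs.values():
            assert 0.0 <= nmi(d) <= 1.0
        single = taskenv.ExperimentDesign(
            experiment="toy", goal_labels=("A",), mappings=designs["2"].mappings,
            training_contexts=[
                taskenv.ContextSpec(0, "m_low", "A", "training", 4),
                taskenv.ContextSpec(1, "m_high", "A", "training", 4),
            ],
            test_contexts=[])
        with pytest.raises(DesignError):
            nmi(single)
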