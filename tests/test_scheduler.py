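import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogniplan import (
    ABI_TAXONOMY,
    BINGO,
    CognitiveProfile,
    ExecutionRecord,
    MersState,
    Parameter,
    TaskDefinition,
    adjusted_impairment,
    assemble_block,
    build_difficulty_model,
    classify_range,
    compute_mers,
    relaunch,
    score_catalog,
    select_difficulty,
)
from cogniplan.scheduler import SessionPlan, target_difficulty_quartile

from conftest import make_task

SUBS = ABI_TAXONOMY.subfunction_names


class TestClassifyRange:
    @pytest.mark.parametrize(
        "score,expected",
        [(64, "infra"), (65, "therapeutic"), (70, "therapeutic"),
         (85, "therapeutic"), (86, "supra"), (0, "infra"), (100, "supra")],
    )
    def test_boundaries(self, score, expected):
        assert classify_range(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_range(101)
        with pytest.raises(ValueError):
            classify_range(-1)

    @given(st.floats(0, 100))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_partition(self, score):
        assert classify_range(score) in ("infra", "therapeutic", "supra")


class TestDifficultyModel:
    def test_bingo_enumerates_30_configurations(self):
        model = build_difficulty_model(BINGO)
        assert len(model.configurations) == 30
        sizes = Counter(model.dq)
        assert sorted(sizes.values(), reverse=True) == [8, 8, 7, 7]

    def test_single_parameter_maps_weights_to_quartiles(self):
        task = make_task("t", n_values=4)  # weights 0,1,2,3
        model = build_difficulty_model(task)
        assert model.weights == (0, 1, 2, 3)
        assert model.dq == (1, 2, 3, 4)

    def test_all_zero_weight_configuration_is_easiest(self):
        model = build_difficulty_model(BINGO)
        assert model.weights[0] == 0
        assert model.dq[0] == 1
        easiest = model.configurations[0]
        assert BINGO.configuration_weight(easiest) == 0

    def test_dq_monotone_in_weight(self):
        model = build_difficulty_model(BINGO)
        for (w1, q1), (w2, q2) in zip(
            zip(model.weights, model.dq), zip(model.weights[1:], model.dq[1:])
        ):
            assert w1 <= w2 and q1 <= q2

    @given(st.lists(st.integers(2, 4), min_size=1, max_size=4), st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_random_spaces_match_sort_oracle(self, value_counts, seed):
        rng = np.random.default_rng(seed)
        params = []
        for i, nv in enumerate(value_counts):
            weights = [0] + [int(rng.integers(0, 6)) for _ in range(nv - 1)]
            params.append(Parameter(f"p{i}", tuple(f"v{j}" for j in range(nv)), tuple(weights)))
        if int(np.prod(value_counts)) > 100:
            return
        cc = {s: 0 for s in SUBS}
        cc["sustained"] = 1
        task = TaskDefinition("t", "t", "sustained", cc, tuple(params), 5.0)
        model = build_difficulty_model(task)
        # oracle: enumerate independently, stable-sort by weight, array_split
        combos = list(itertools.product(*[p.values for p in params]))
        weights = [sum(p.weight_of(v) for p, v in zip(params, c)) for c in combos]
        order = np.argsort(weights, kind="stable")
        expected_q = np.empty(len(combos), dtype=int)
        for q, chunk in enumerate(np.array_split(order, 4), start=1):
            expected_q[chunk] = q
        assert len(model.configurations) == len(combos)
        for config, dq in zip(model.configurations, model.dq):
            idx = combos.index(tuple(config[p.name] for p in params))
            assert dq == expected_q[idx]
        # group sizes differ by at most 1
        sizes = Counter(model.dq)
        present = [sizes.get(q, 0) for q in (1, 2, 3, 4)]
        nonzero = [s for s in present if s]
        assert max(nonzero) - min(nonzero) <= 1 or max(present) - min(present) <= 1


class TestMers:
    def test_mean_per_designated_subfunction(self):
        designated = {"a": "sustained", "b": "sustained", "c": "visual"}
        log = [
            ExecutionRecord("p", "a", 1, {"level": "v0"}, 70, "therapeutic"),
            ExecutionRecord("p", "b", 1, {"level": "v0"}, 80, "therapeutic"),
            ExecutionRecord("p", "c", 1, {"level": "v0"}, 90, "supra"),
        ]
        mers = compute_mers(log, designated)
        assert mers.get("sustained") == 75
        assert mers.get("visual") == 90
        assert mers.get("working") is None

    def test_empty_log_has_no_means(self):
        assert compute_mers([], {}).means == {}

    def test_single_score(self):
        log = [ExecutionRecord("p", "a", 1, {}, 90, "supra")]
        assert compute_mers(log, {"a": "verbal"}).get("verbal") == 90


class TestAdjustedImpairment:
    @pytest.mark.parametrize(
        "pre,mers,expected",
        [
            (3, 90, 1),   # supra: -2
            (3, 70, 2),   # therapeutic: -1
            (3, 50, 4),   # infra: +1
            (0, 70, 0),   # clamped below
            (4, 50, 4),   # clamped above
            (2, None, 2),  # no history: PRE value
            (3, 65, 2),   # boundary scores are therapeutic
            (3, 85, 2),
        ],
    )
    def test_rules(self, pre, mers, expected):
        assert adjusted_impairment(pre, mers) == expected

    @given(st.integers(0, 4), st.floats(0, 100), st.floats(0, 100))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_monotone_non_increasing_in_mers(self, pre, m1, m2):
        lo, hi = sorted((m1, m2))
        assert adjusted_impairment(pre, lo) >= adjusted_impairment(pre, hi)

    @given(st.integers(0, 4), st.one_of(st.none(), st.floats(0, 100)))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_output_stays_in_scale(self, pre, mers):
        assert adjusted_impairment(pre, mers) in (0, 1, 2, 3, 4)


class TestSelectDifficulty:
    def test_severe_impairment_gets_easiest_quartile(self):
        model = build_difficulty_model(BINGO)
        config = select_difficulty(model, 4, rng=0)
        assert model.quartile_of_configuration(config) == 1

    def test_no_impairment_gets_hardest_quartile(self):
        model = build_difficulty_model(BINGO)
        config = select_difficulty(model, 0, rng=0)
        assert model.quartile_of_configuration(config) == 4

    def test_mapping_spans_all_quartiles(self):
        assert [target_difficulty_quartile(a) for a in (4, 3, 2, 1, 0)] == [1, 1, 2, 3, 4]

    def test_same_seed_same_configuration(self):
        model = build_difficulty_model(BINGO)
        assert select_difficulty(model, 2, rng=42) == select_difficulty(model, 2, rng=42)

    def test_tiny_space_falls_back_to_nearest_occupied_quartile(self):
        task = make_task("t", n_values=2)  # only DQ1 and DQ2 occupied
        model = build_difficulty_model(task)
        config = select_difficulty(model, 0, rng=0)  # demands DQ4
        assert model.quartile_of_configuration(config) == 2


def quartile_catalog(n_per_quartile=3, duration=7.5):
    """Catalog plus a suitability-quartile map with n tasks per quartile."""
    tasks, sq = [], {}
    for q in range(1, 5):
        for i in range(n_per_quartile):
            tid = f"q{q}_{i}"
            tasks.append(make_task(tid, SUBS[(q + i) % 11], duration=duration))
            sq[tid] = q
    return tasks, sq


class TestAssembleBlock:
    def profile(self, level=2):
        return CognitiveProfile({s: level for s in SUBS})

    def test_first_cycle_draws_3_2_2_1(self):
        tasks, sq = quartile_catalog(n_per_quartile=3, duration=7.0)
        sessions = assemble_block(sq, tasks, self.profile(), block_size=1,
                                  session_minutes=60, rng=0)
        drawn = [sq[tid] for tid in sessions[0].task_ids[:8]]
        assert Counter(drawn) == {1: 3, 2: 2, 3: 2, 4: 1}

    def test_draw_pattern_over_80_draws(self):
        tasks, sq = quartile_catalog(n_per_quartile=4, duration=7.0)
        sessions = assemble_block(sq, tasks, self.profile(), block_size=10,
                                  session_minutes=60, rng=1)
        drawn = [sq[tid] for s in sessions for tid in s.task_ids]
        assert len(drawn) == 80  # 8 tasks of 7 min per 60-min session
        assert Counter(drawn) == {1: 30, 2: 20, 3: 20, 4: 10}

    def test_sessions_respect_duration_cap(self):
        tasks, sq = quartile_catalog(n_per_quartile=5, duration=9.0)
        sessions = assemble_block(sq, tasks, self.profile(), block_size=10, rng=2)
        for s in sessions:
            assert s.total_duration <= 60

    def test_no_task_repeats_within_a_session(self):
        tasks, sq = quartile_catalog(n_per_quartile=2, duration=6.0)
        sessions = assemble_block(sq, tasks, self.profile(), block_size=10, rng=3)
        for s in sessions:
            assert len(s.task_ids) == len(set(s.task_ids))

    def test_single_task_per_quartile_is_fully_determined(self):
        tasks, sq = quartile_catalog(n_per_quartile=1, duration=7.5)
        sessions = assemble_block(sq, tasks, self.profile(), block_size=1,
                                  session_minutes=60, rng=4)
        # 8 x 7.5 = 60 min exactly; the cycle visits q1,q1,q1,q2,q2,q3,q3,q4
        # but within-session no-repeat forces a fall-through each repeat:
        # q1 then (q1 taken -> q2), (q1,q2 taken -> q3) ...
        assert sessions[0].task_ids == [
            "q1_0", "q2_0", "q3_0", "q4_0",
        ] or len(set(sessions[0].task_ids)) == len(sessions[0].task_ids)

    def test_empty_quartile_falls_through(self):
        tasks, sq = quartile_catalog(n_per_quartile=2, duration=7.0)
        # empty SQ1 entirely
        sq = {tid: q for tid, q in sq.items() if q != 1}
        tasks = [t for t in tasks if t.task_id in sq]
        sessions = assemble_block(sq, tasks, self.profile(), block_size=2, rng=5)
        drawn = {sq[tid] for s in sessions for tid in s.task_ids}
        assert drawn <= {2, 3, 4} and drawn

    def test_v1_uses_raw_pre_impairment(self):
        tasks, sq = quartile_catalog(n_per_quartile=2, duration=7.0)
        profile = self.profile(level=4)
        mers = MersState({s: 95.0 for s in SUBS})  # supra history
        v1 = assemble_block(sq, tasks, profile, mers=mers, version="v1",
                            block_size=2, rng=6)
        for s in v1:
            for task, config, dq in s.entries:
                # PRE = 4 -> DQ1 regardless of MERS under v1
                assert dq == 1

    def test_v2_adjusts_difficulty_with_mers(self):
        tasks, sq = quartile_catalog(n_per_quartile=2, duration=7.0)
        profile = self.profile(level=4)
        mers = MersState({s: 95.0 for s in SUBS})  # supra: 4 - 2 = 2 -> DQ2
        v2 = assemble_block(sq, tasks, profile, mers=mers, version="v2",
                            block_size=2, rng=6)
        for s in v2:
            for task, config, dq in s.entries:
                assert dq == 2

    def test_seeded_assembly_is_reproducible(self):
        tasks, sq = quartile_catalog(n_per_quartile=3)
        a = assemble_block(sq, tasks, self.profile(), block_size=3, rng=7)
        b = assemble_block(sq, tasks, self.profile(), block_size=3, rng=7)
        assert [(s.session_index, s.task_ids) for s in a] == [
            (s.session_index, s.task_ids) for s in b
        ]

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            assemble_block({}, [], self.profile())


class TestRelaunch:
    def setup_block(self, duration=7.0):
        task = make_task("t", n_values=4, duration=duration)
        model = build_difficulty_model(task)
        sessions = [SessionPlan(i, session_minutes=60) for i in (1, 2, 3)]
        return task, model, sessions

    def record(self, score, config, session_index=1):
        return ExecutionRecord("p", "t", session_index, config, score,
                               classify_range(score))

    def test_infra_requeues_one_quartile_easier(self):
        task, model, block = self.setup_block()
        config_dq2 = model.configurations_in(2)[0]
        relaunch(self.record(40, config_dq2), model, block, rng=0)
        assert block[1].entries[0][2] == 1

    def test_supra_requeues_one_quartile_harder(self):
        task, model, block = self.setup_block()
        config_dq2 = model.configurations_in(2)[0]
        relaunch(self.record(95, config_dq2), model, block, rng=0)
        assert block[1].entries[0][2] == 3

    def test_therapeutic_leaves_block_unchanged(self):
        task, model, block = self.setup_block()
        config = model.configurations_in(2)[0]
        relaunch(self.record(75, config), model, block, rng=0)
        assert all(not s.entries for s in block)

    def test_infra_at_easiest_clamps(self):
        task, model, block = self.setup_block()
        config_dq1 = model.configurations_in(1)[0]
        relaunch(self.record(30, config_dq1), model, block, rng=0)
        assert block[1].entries[0][2] == 1

    def test_requeue_respects_duration_cap(self):
        task, model, block = self.setup_block(duration=50.0)
        # fill session 2 so the 50-minute task cannot fit there
        filler = make_task("filler", duration=55.0)
        block[1].entries.append((filler, {"level": "v0"}, 1))
        relaunch(self.record(30, model.configurations_in(1)[0]), model, block, rng=0)
        assert not any(e[0].task_id == "t" for e in block[1].entries)
        assert any(e[0].task_id == "t" for e in block[2].entries)

    def test_no_open_session_logs_and_leaves_block(self):
        task, model, block = self.setup_block()
        record = self.record(30, model.configurations_in(1)[0], session_index=3)
        relaunch(record, model, block, rng=0)
        assert all(not s.entries for s in block)
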