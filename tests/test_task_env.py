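"""Task environment: payout tables, observation channels, session mechanics."""

import itertools

import numpy as np
import pytest

from tigertask import task_env as te
from tigertask.task_env import (ACTIONS, CL, CR, GL, GR, L, OL, OR, S, SIDES,
                                TL, TR, FixedAgent, UniformRandomAgent,
                                make_payout, mirror, run_session,
                                sample_physical_obs, sample_social_obs, step)


class TestPayouts:
    @pytest.mark.parametrize("variant, action, side, expected", [
        ("modified", L, TL, -1), ("modified", OR, TL, 20),
        ("modified", OL, TL, -50), ("original", L, TL, -1),
        ("original", OR, TL, 10), ("original", OL, TL, -100),
    ])
    def test_solo_cells(self, variant, action, side, expected):
        pay = make_payout(variant, "solo")
        assert pay.reward(action, None, side) == expected

    def test_modified_competitive_printed_cells(self):
        pay = make_payout("modified", "competitive")
        # gold door open while the other hits the tiger: large win / larger loss
        assert pay.joint(OR, OL, TL) == (45, -60)
        assert pay.joint(OL, OR, TL) == (-60, 45)
        assert pay.joint(L, L, TL) == (-1, -1)
        assert pay.joint(OR, OR, TL) == (20, 20)
        assert pay.joint(OL, OL, TL) == (-50, -50)

    def test_modified_cooperative_printed_cells(self):
        pay = make_payout("modified", "cooperative")
        assert pay.joint(L, L, TL) == (-1, -1)
        assert pay.joint(OR, OR, TL) == (20, 20)   # joint gold: the maximum
        assert pay.joint(OL, OL, TL) == (-50, -50)  # joint tiger: the worst
        best = max(v for pair in pay.table.values() for v in pair)
        worst = min(v for pair in pay.table.values() for v in pair)
        assert best == 20 and worst == -50

    def test_original_cooperative_half_share_rule(self):
        # X opens gold (+10 base) while Y listens (-1 base)
        pay = make_payout("original", "cooperative")
        assert pay.joint(OR, L, TL) == (9.5, 4.0)
        # both cells carry half the partner's base in the right direction
        comp = make_payout("original", "competitive")
        assert comp.joint(OR, L, TL) == (10.5, -6.0)

    @pytest.mark.parametrize("variant, context",
                             list(itertools.product(te.VARIANTS, te.CONTEXTS)))
    def test_mirror_symmetry(self, variant, context):
        """Swapping tiger side and OL/OR in both slots leaves payouts fixed."""
        pay = make_payout(variant, context)
        for (own, oth, side), pts in pay.table.items():
            mirrored = (mirror(own), None if oth is None else mirror(oth),
                        mirror(side))
            assert pay.table[mirrored] == pts

    @pytest.mark.parametrize("variant", te.VARIANTS)
    def test_cooperative_exchange_symmetry(self, variant):
        pay = make_payout(variant, "cooperative")
        for own, oth in itertools.product(ACTIONS, repeat=2):
            for side in SIDES:
                a, b = pay.joint(own, oth, side)
                b2, a2 = pay.joint(oth, own, side)
                assert (a, b) == (a2, b2)

    def test_listen_base_cost_is_one_point(self):
        for variant, context in itertools.product(te.VARIANTS, te.CONTEXTS):
            pay = make_payout(variant, context)
            assert pay.base(L, TL) == -1
        # in the modified tables a joint listen costs exactly 1 each
        for context in ("cooperative", "competitive"):
            pay = make_payout("modified", context)
            assert pay.joint(L, L, TL) == (-1, -1)

    def test_unknown_variant_context_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            make_payout("classic", "solo")
        with pytest.raises(ValueError, match="context"):
            make_payout("modified", "triadic")


class TestObservationChannels:
    def test_degenerate_accuracies(self):
        rng = np.random.default_rng(0)
        assert all(sample_physical_obs(TL, 1.0, rng) == GL for _ in range(20))
        assert all(sample_social_obs(L, 1.0, rng) == S for _ in range(20))

    def test_growl_frequency_calibration(self):
        rng = np.random.default_rng(1)
        n = 10_000
        hits = sum(sample_physical_obs(TL, 0.7, rng) == GL for _ in range(n))
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(hits / n - 0.7) < 3 * se

    def test_growl_uninformative_at_half(self):
        rng = np.random.default_rng(2)
        n = 10_000
        hits = sum(sample_physical_obs(TL, 0.5, rng) == GL for _ in range(n))
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_creak_error_split_uniform(self):
        rng = np.random.default_rng(3)
        n = 10_000
        draws = [sample_social_obs(OR, 0.8, rng) for _ in range(n)]
        freq = {c: draws.count(c) / n for c in (CR, CL, S)}
        assert abs(freq[CR] - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)
        for wrong in (CL, S):
            assert abs(freq[wrong] - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_physical_obs(TL, 1.5, rng)
        with pytest.raises(ValueError):
            sample_social_obs("OX", 0.8, rng)


class TestStep:
    def test_solo_listen_round(self):
        state = te.EnvState(tiger_side=TL)
        pay = make_payout("modified", "solo")
        events, rewards, ended = step(state, (L, None), pay,
                                      np.random.default_rng(0))
        assert rewards[0] == -1 and not ended
        assert events[0].physical_obs in (GL, GR)
        assert events[0].social_obs is None

    def test_joint_correct_open_ends_trial(self):
        state = te.EnvState(tiger_side=TR)
        pay = make_payout("modified", "cooperative")
        events, rewards, ended = step(state, (OL, OL), pay,
                                      np.random.default_rng(0))
        assert ended and rewards == (20, 20)
        assert state.trial == 1

    def test_listener_gets_no_growl_when_partner_opens(self):
        state = te.EnvState(tiger_side=TL)
        pay = make_payout("modified", "competitive")
        events, _, ended = step(state, (L, OR), pay, np.random.default_rng(0))
        assert ended
        assert events[0].physical_obs is None       # growl suppressed
        assert events[0].social_obs is not None     # creak still emitted

    def test_out_of_set_action_rejected(self):
        state = te.EnvState(tiger_side=TL)
        pay = make_payout("modified", "solo")
        with pytest.raises(ValueError, match="out-of-set"):
            step(state, ("OX", None), pay, np.random.default_rng(0))


class TestRunSession:
    def test_always_open_has_one_round_per_trial(self):
        pay = make_payout("modified", "solo")
        log = run_session(FixedAgent(OL), None, pay, n_trials=10, seed=0)
        assert log.n_trials == 10
        assert len(log.events) == 10

    def test_opener_ends_every_trial_of_a_listener(self):
        pay = make_payout("modified", "competitive")
        lx, ly = run_session(FixedAgent(L), FixedAgent(OR), pay,
                             n_trials=10, seed=1)
        assert all(len(t) == 1 for t in lx.trials())
        assert lx.n_trials == ly.n_trials == 10

    def test_total_score_is_sum_of_round_rewards(self):
        pay = make_payout("modified", "cooperative")
        lx, ly = run_session(UniformRandomAgent(), UniformRandomAgent(),
                             pay, n_trials=10, seed=2)
        for log in (lx, ly):
            assert log.total_score == pytest.approx(
                sum(e.reward for e in log.events))

    def test_no_round_has_both_growl_and_outcome(self):
        pay = make_payout("modified", "solo")
        log = run_session(UniformRandomAgent(), None, pay, n_trials=10,
                          seed=3)
        for ev in log.events:
            if ev.trial_ended:
                assert ev.physical_obs is None

    def test_left_right_exchangeability(self):
        """Mirror symmetry: opens split evenly between doors over trials."""
        from tigertask.synthetic_participants import (ThresholdAgent,
                                                      ThresholdAgentParams)
        pay = make_payout("modified", "solo")
        rng = np.random.default_rng(4)
        opens = []
        for _ in range(60):
            log = run_session(
                ThresholdAgent(ThresholdAgentParams(2)), None, pay,
                n_trials=10, rng=rng)
            opens += [t[-1].own_action for t in log.trials()]
        frac_left = opens.count(OL) / len(opens)
        assert abs(frac_left - 0.5) < 3 * np.sqrt(0.25 / len(opens))

    def test_threshold_agent_trial_length_matches_first_passage_oracle(
            self, first_passage_oracle):
        """Mean rounds/trial = exact two-sided first-passage time + 1."""
        from tigertask.synthetic_participants import (ThresholdAgent,
                                                      ThresholdAgentParams)
        pay = make_payout("modified", "solo")
        rng = np.random.default_rng(5)
        rounds = []
        for _ in range(50):
            log = run_session(
                ThresholdAgent(ThresholdAgentParams(3, lapse=0.0)), None,
                pay, n_trials=10, rng=rng)
            rounds += [len(t) for t in log.trials()]
        expected = first_passage_oracle(3, 0.7) + 1.0
        se = np.std(rounds, ddof=1) / np.sqrt(len(rounds))
        assert abs(np.mean(rounds) - expected) < 3 * se
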