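"""Level-1 interactive agents: Level-0 models, the interactive particle
filter, action valuation, prediction, dyad simulation and replay."""

import numpy as np
import pytest

from tigertask import ipomdp
from tigertask.ipomdp import (IPOMDPConfig, Level0Model, ParticleSet,
                              action_values, ipf_update, level0_action_probs,
                              predict_other, replay_model, simulate_dyad)
from tigertask.pomdp import belief_after_net
from tigertask.task_env import (ACTIONS, GL, GR, L, OL, OR, S, TL, TR,
                                PayoutSpec, make_payout)


def comp_config(**kw):
    kw.setdefault("payout", make_payout("modified", "competitive"))
    kw.setdefault("n_particles", 500)
    return IPOMDPConfig(**kw)


class TestLevel0:
    def test_uniform_subintentional(self):
        m = Level0Model("subintentional_fixed")
        probs = level0_action_probs(m, 0.9)
        assert probs == pytest.approx({a: 1 / 3 for a in ACTIONS})

    def test_noisy_pomdp_listens_most_at_half(self, policy_modified):
        m = Level0Model("pomdp_noisy", policy=policy_modified,
                        qre_lambda=0.22)
        probs = level0_action_probs(m, 0.5)
        assert probs[L] > probs[OL]
        assert probs[OL] == pytest.approx(probs[OR], abs=1e-9)

    def test_argmax_limit_beyond_threshold(self, policy_modified):
        m = Level0Model("pomdp_noisy", policy=policy_modified,
                        qre_lambda=1e6)
        probs = level0_action_probs(m, 0.99)  # tiger left: open right
        assert probs[OR] == pytest.approx(1.0, abs=1e-6)

    def test_invalid_kind_and_missing_policy(self):
        with pytest.raises(ValueError):
            Level0Model("oracle")
        with pytest.raises(ValueError):
            Level0Model("pomdp_noisy")


class TestParticleFilter:
    def test_posterior_matches_exact_enumeration_two_rounds(self):
        """With the trial continuing, the other provably listened; the
        tiger-side posterior after two supporting growls must match the
        exact Bayes value within 3 s.e. of the particle approximation."""
        cfg = comp_config(n_particles=1000)
        rng = np.random.default_rng(0)
        ps = ParticleSet.prior(cfg.n_particles)
        for _ in range(2):
            ps = ipf_update(ps, L, S, GL, cfg, rng)
        exact = belief_after_net(2, 0.7)
        se = np.sqrt(exact * (1 - exact) / cfg.n_particles)
        assert abs(ps.p_tiger_left() - exact) < 3 * se

    def test_social_channel_only_when_no_growl(self, policy_modified):
        """Without a physical observation the weights depend only on the
        social channel: the tiger-side marginal stays at the prior."""
        cfg = comp_config(level0_kind="pomdp_noisy", n_particles=2000)
        rng = np.random.default_rng(1)
        ps = ipf_update(ParticleSet.prior(cfg.n_particles), OL, S, None,
                        cfg, rng, trial_continues=True)
        assert abs(ps.p_tiger_left() - 0.5) < 0.05

    def test_weight_collapse_rejuvenates_with_warning(self):
        # perfect creak channel: silence contradicts "the other opened"
        cfg = comp_config(p_creak=1.0)
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="rejuvenat"):
            ps = ipf_update(ParticleSet.prior(cfg.n_particles), L, S, None,
                            cfg, rng, trial_continues=False)
        assert ps.n == cfg.n_particles
        assert ps.weights.sum() == pytest.approx(1.0)

    def test_resampling_preserves_count_and_normalization(self):
        cfg = comp_config()
        rng = np.random.default_rng(3)
        ps = ipf_update(ParticleSet.prior(cfg.n_particles), L, S, GR, cfg,
                        rng)
        assert ps.n == cfg.n_particles
        assert ps.weights.sum() == pytest.approx(1.0)

    def test_monte_carlo_error_shrinks_with_particle_count(self):
        """Posterior RMSE scales roughly as 1/sqrt(N)."""
        exact = belief_after_net(2, 0.7)

        def rmse(n, reps=24):
            errs = []
            for r in range(reps):
                cfg = comp_config(n_particles=n)
                rng = np.random.default_rng(100 + r)
                ps = ParticleSet.prior(n)
                for _ in range(2):
                    ps = ipf_update(ps, L, S, GL, cfg, rng)
                errs.append(ps.p_tiger_left() - exact)
            return np.sqrt(np.mean(np.square(errs)))

        r_small, r_big = rmse(64), rmse(4096)
        assert r_big < r_small / 3  # expected factor 8, generous slack


class TestActionValues:
    def test_horizon1_equals_direct_summation(self):
        """Horizon-1 values equal the brute-force expectation over the
        joint payout table on a fixed particle set."""
        cfg = comp_config(n_particles=4)
        level0 = cfg.make_level0()
        ps = ParticleSet(tiger_left=np.array([True, True, False, False]),
                         other_belief=np.array([0.3, 0.6, 0.5, 0.9]),
                         weights=np.array([0.4, 0.1, 0.25, 0.25]))
        vals = action_values(ps, cfg, level0, horizon=1)
        probs = level0.action_probs(ps.other_belief)
        for a in ACTIONS:
            direct = sum(
                w * probs[i, j] * cfg.payout.reward(a, a_oth,
                                                    TL if tl else TR)
                for i, (w, tl) in enumerate(zip(ps.weights, ps.tiger_left))
                for j, a_oth in enumerate(ACTIONS))
            assert vals[a] == pytest.approx(direct, abs=1e-12)

    def test_all_zero_payout_table_gives_zero_values(self):
        table = {(a, o, s): (0.0, 0.0) for a in ACTIONS for o in ACTIONS
                 for s in (TL, TR)}
        cfg = comp_config(payout=PayoutSpec("modified", "competitive", table))
        vals = action_values(ParticleSet.prior(100), cfg)
        assert all(v == 0 for v in vals.values())

    def test_confident_particles_with_opening_partner(self):
        """Tiger believed left and the partner surely opens right: opening
        right pays the joint-gold +20; it beats listening."""
        cfg = IPOMDPConfig(payout=make_payout("modified", "cooperative"),
                           level0_kind="subintentional_fixed",
                           level0_probs=(0.0, 0.0, 1.0), n_particles=8)
        ps = ParticleSet(tiger_left=np.ones(8, dtype=bool),
                         other_belief=np.full(8, 0.99),
                         weights=np.full(8, 1 / 8))
        vals = action_values(ps, cfg, horizon=1)
        assert vals[OR] == pytest.approx(20.0)
        assert vals[OL] == pytest.approx(-40.0)  # tiger door while other wins
        assert vals[L] < vals[OR]

    def test_horizon2_adds_discounted_lookahead(self):
        cfg1 = comp_config(horizon=1)
        cfg2 = comp_config(horizon=2)
        ps = ParticleSet.prior(500)
        v1 = action_values(ps, cfg1)
        v2 = action_values(ps, cfg2)
        # open values gain exactly gamma * fresh-trial value
        level0 = cfg2.make_level0()
        fresh = ipomdp._fresh_trial_value(cfg2, level0)
        for a in (OL, OR):
            assert v2[a] == pytest.approx(v1[a] + cfg2.gamma * fresh,
                                          abs=1e-9)
        # listening's continuation value exceeds opening's (information)
        assert v2[L] - v1[L] >= cfg2.gamma * fresh - 1e-9


class TestPrediction:
    def test_uniform_other_ties_to_listen(self):
        cfg = comp_config()
        assert predict_other(ParticleSet.prior(100), cfg) == L

    def test_other_beyond_threshold_predicted_to_open(self, policy_modified):
        cfg = comp_config(level0_kind="pomdp_noisy")
        ps = ParticleSet(tiger_left=np.ones(50, dtype=bool),
                         other_belief=np.full(50, 0.995),
                         weights=np.full(50, 1 / 50))
        level0 = Level0Model("pomdp_noisy", policy=policy_modified,
                             qre_lambda=50.0)
        assert predict_other(ps, cfg, level0) == OR

    def test_silent_history_keeps_listen_prediction(self):
        # one round in: the other's hypothesized belief is at most one
        # growl from the prior, inside the listen region
        cfg = comp_config(level0_kind="pomdp_noisy", p_creak=1.0,
                          level0_lambda=5.0)
        rng = np.random.default_rng(4)
        ps = ipf_update(ParticleSet.prior(cfg.n_particles), L, S, GL, cfg,
                        rng)
        assert predict_other(ps, cfg) == L


class TestDyadsAndReplay:
    def test_simulated_dyad_has_exact_trial_counts(self):
        cfg = comp_config(n_particles=100)
        lx, ly = simulate_dyad(cfg, cfg, n_trials=10, seed=5)
        assert lx.n_trials == ly.n_trials == 10
        assert len(lx.events) == len(ly.events)
        for ex, ey in zip(lx.events, ly.events):
            assert (ex.trial, ex.round_index) == (ey.trial, ey.round_index)
            assert ex.prediction is not None

    def test_mismatched_environments_rejected(self):
        cfg1 = comp_config()
        cfg2 = IPOMDPConfig(payout=make_payout("modified", "cooperative"))
        with pytest.raises(ValueError, match="environment"):
            simulate_dyad(cfg1, cfg2, seed=0)

    def test_exchange_symmetry_of_equal_configs(self):
        """With identical configs the two agents' listen counts are
        statistically exchangeable."""
        cfg = comp_config(n_particles=100)
        rng = np.random.default_rng(6)
        nx, ny = [], []
        for _ in range(8):
            lx, ly = simulate_dyad(cfg, cfg, n_trials=10, rng=rng)
            nx.append(np.mean([sum(e.own_action == L for e in t)
                               for t in lx.trials()]))
            ny.append(np.mean([sum(e.own_action == L for e in t)
                               for t in ly.trials()]))
        diff = np.array(nx) - np.array(ny)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * max(se, 0.05)

    def test_replay_reproducible_under_seed(self):
        cfg = comp_config(n_particles=100)
        lx, _ = simulate_dyad(cfg, cfg, n_trials=3, seed=7)
        r1 = replay_model(lx, cfg, n_completions=5,
                          rng=np.random.default_rng(8))
        r2 = replay_model(lx, cfg, n_completions=5,
                          rng=np.random.default_rng(8))
        assert [t["nlisten"] for t in r1] == [t["nlisten"] for t in r2]
        assert all(t["evidence"] >= 0 for t in r1)


@pytest.fixture(scope="module")
def replay_means():
    from tigertask.reproduce import interactive_model_replay
    out = {}
    for horizon in (1, 2):
        for context in ("competitive", "cooperative"):
            out[(horizon, context)] = interactive_model_replay(
                context, horizon, seed=11, n_dyads=4, n_particles=300,
                n_completions=8)
    return out


class TestModelOrderings:
    def test_longer_horizon_listens_more(self, replay_means):
        for context in ("competitive", "cooperative"):
            assert replay_means[(2, context)]["nlisten"] > \
                replay_means[(1, context)]["nlisten"]

    def test_models_listen_more_in_competition(self, replay_means):
        """The models' context effect runs opposite to the synthetic
        participants' (who listen more under cooperation)."""
        for horizon in (1, 2):
            assert replay_means[(horizon, "competitive")]["nlisten"] > \
                replay_means[(horizon, "cooperative")]["nlisten"]
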