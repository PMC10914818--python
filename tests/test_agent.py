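"""Q-learning agent: epsilon schedule, featurization, action selection,
TD training, and episode generation."""

from dataclasses import replace
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import leadopt as L
from leadopt.agent import (
    AgentError,
    Featurizer,
    QNetwork,
    ReplayBuffer,
    Transition,
)


class TestEpsilonSchedule:
    def test_linear_decay_default(self):
        cfg = L.AgentConfig()
        assert L.epsilon_at(0, cfg) == 1.0
        assert L.epsilon_at(3000, cfg) == 0.5
        assert L.epsilon_at(6000, cfg) == 0.0

    def test_floor_applies(self):
        cfg = L.AgentConfig(epsilon_floor=Fraction(1, 10))
        assert L.epsilon_at(100000, cfg) == 0.1

    def test_negative_episode_rejected(self):
        with pytest.raises(AgentError):
            L.epsilon_at(-1, L.AgentConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(AgentError):
            L.AgentConfig(epsilon_init=2)
        with pytest.raises(AgentError):
            L.AgentConfig(episodes=0)


class TestFeaturize:
    def test_vector_length_is_width_plus_one(self):
        cfg = L.AgentConfig(fingerprint_bits=256)
        v = L.featurize(L.parse_smiles("C"), cfg, steps_remaining=3,
                        step_limit=8)
        assert v.shape == (257,)

    def test_identical_molecules_identical_vectors(self):
        cfg = L.AgentConfig(fingerprint_bits=128)
        a = L.featurize(L.parse_smiles("CCO"), cfg, 2, 8)
        b = L.featurize(L.parse_smiles("OCC"), cfg, 2, 8)
        assert np.array_equal(a, b)

    def test_benzene_pyridine_separate(self):
        cfg = L.AgentConfig(fingerprint_bits=2048)
        a = L.featurize(L.parse_smiles("c1ccccc1"), cfg, 2, 8)
        b = L.featurize(L.parse_smiles("c1ccncc1"), cfg, 2, 8)
        assert not np.array_equal(a, b)

    def test_steps_remaining_slot(self):
        f = Featurizer(L.AgentConfig(fingerprint_bits=64), step_limit=8)
        assert f("C", 4)[-1] == pytest.approx(0.5)


class TestSelectAction:
    def test_fully_random_is_uniform(self):
        rng = np.random.default_rng(3)
        cands = [f"{'C' * (i + 1)}" for i in range(9)]
        counts = {c: 0 for c in cands}
        for _ in range(90000):
            counts[L.select_action(cands, None, 1.0, rng)] += 1
        for c in cands:  # binomial 99% band around 10000
            assert abs(counts[c] - 10000) <= 400

    def test_greedy_argmax(self):
        rng = np.random.default_rng(0)
        got = L.select_action(["C", "CC", "CCC"], [0.1, 0.9, 0.5], 0.0, rng)
        assert got == "CC"

    def test_greedy_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(0)
        got = L.select_action(["CCC", "CC"], [1.0, 1.0], 0.0, rng)
        assert got == "CC"

    def test_empty_candidates_rejected(self):
        with pytest.raises(AgentError):
            L.select_action([], [], 0.5, np.random.default_rng(0))


class TestTrainOnBatch:
    def _setup(self, gamma=0.0):
        cfg = L.AgentConfig(fingerprint_bits=64, hidden_sizes=(16, 16),
                            learning_rate=1e-2, gamma=gamma, seed=0)
        feat = Featurizer(cfg, step_limit=4)
        rng = np.random.default_rng(0)
        online = QNetwork(feat.dim, cfg.hidden_sizes, cfg.learning_rate, rng)
        target = QNetwork(feat.dim, cfg.hidden_sizes, cfg.learning_rate, rng)
        target.copy_weights_from(online)
        return cfg, feat, online, target

    def test_zero_reward_zero_gamma_converges_to_zero(self):
        cfg, feat, online, target = self._setup()
        batch = [
            Transition("C", 1, 0.0, True, ()),
            Transition("CC", 1, 0.0, True, ()),
        ]
        losses = [
            L.train_on_batch(batch, online, target, cfg, feat)
            for _ in range(300)
        ]
        assert losses[-1] < 1e-3 and losses[-1] < losses[0]

    def test_single_transition_fixed_point_is_reward(self):
        cfg, feat, online, target = self._setup()
        tr = Transition("CCO", 2, 1.7, True, ())
        for _ in range(500):
            L.train_on_batch([tr], online, target, cfg, feat)
        q = online.forward(feat("CCO", 2)[None, :].astype(float))
        assert q[0] == pytest.approx(1.7, abs=0.05)

    def test_bootstrapped_target_uses_next_candidates(self):
        cfg, feat, online, target = self._setup(gamma=0.9)
        tr = Transition("C", 2, 0.5, False, ("CC", "CO"))
        loss = L.train_on_batch([tr], online, target, cfg, feat)
        assert np.isfinite(loss)

    def test_loss_finite_over_many_random_batches(self):
        cfg, feat, online, target = self._setup(gamma=0.9)
        rng = np.random.default_rng(5)
        pool = ["C", "CC", "CCO", "CN", "C=O", "CCN", "c1ccccc1"]
        for k in range(300):
            batch = [
                Transition(pool[int(rng.integers(len(pool)))], 1,
                           float(rng.normal()), bool(rng.integers(2)),
                           ("C", "CC"))
                for _ in range(8)
            ]
            assert np.isfinite(
                L.train_on_batch(batch, online, target, cfg, feat)
            )

    def test_empty_batch_rejected(self):
        cfg, feat, online, target = self._setup()
        with pytest.raises(AgentError):
            L.train_on_batch([], online, target, cfg, feat)


class TestReplayBuffer:
    def test_capacity_wraps(self):
        buf = ReplayBuffer(capacity=3)
        for i in range(5):
            buf.push(Transition(f"C{'C' * i}", 1, float(i), True, ()))
        assert len(buf) == 3
        rewards = {tr.reward for tr in buf._data}
        assert rewards == {3.0, 4.0, 2.0}


class TestRunOptimization:
    def test_record_count_epsilon_column_and_validity(self, smoke,
                                                      smoke_records):
        assert len(smoke_records) == smoke.agent.episodes
        for rec in smoke_records:
            assert rec.epsilon == L.epsilon_at(rec.episode, smoke.agent)
            L.validate_valence(L.parse_smiles(rec.smiles))
            if not rec.failed:
                assert 0.0 <= rec.reward.qed <= 1.0
                assert 0.0 <= rec.reward.sa <= 1.0

    def test_short_run_reproducible(self, lead):
        cfg = replace(L.seeded_smoke_config(seed=9).agent, episodes=8)
        mdp = L.MDPConfig(step_limit=4)
        rf = L.surrogate_reward_fn()
        a = L.run_optimization(lead, mdp, cfg, rf)
        b = L.run_optimization(lead, mdp, cfg, rf)
        assert [r.smiles for r in a] == [r.smiles for r in b]
        assert [r.scalar_reward for r in a] == [r.scalar_reward for r in b]

    def test_best_so_far_improves_with_episodes(self, smoke_records):
        best = np.maximum.accumulate(
            [r.scalar_reward for r in smoke_records]
        )
        rho, _ = stats.spearmanr(np.arange(len(best)), best)
        assert rho > 0

    def test_total_reward_failure_aborts(self, lead):
        def bad_reward(mol):
            raise RuntimeError("oracle down")

        cfg = replace(L.seeded_smoke_config(seed=2).agent, episodes=30)
        with pytest.raises(AgentError, match="reward failures"):
            L.run_optimization(lead, L.MDPConfig(step_limit=2), cfg,
                               bad_reward)

    def test_sporadic_failure_marked_and_run_continues(self, lead):
        calls = {"n": 0}
        good = L.surrogate_reward_fn()

        def flaky(mol):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("transient")
            return good(mol)

        cfg = replace(L.seeded_smoke_config(seed=3).agent, episodes=12)
        recs = L.run_optimization(lead, L.MDPConfig(step_limit=2), cfg, flaky)
        assert len(recs) == 12
        assert recs[0].failed and np.isnan(recs[0].scalar_reward)
        assert not any(r.failed for r in recs[1:])


class TestEpisodeCsv:
    def test_round_trip(self, tmp_path, smoke_records):
        path = tmp_path / "episodes.csv"
        L.episodes_to_csv(smoke_records[:25], path)
        back = L.episodes_from_csv(path)
        assert [r.smiles for r in back] == [r.smiles for r in smoke_records[:25]]
        assert back[3].reward.affinity == smoke_records[3].reward.affinity
        assert back[3].epsilon == smoke_records[3].epsilon
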