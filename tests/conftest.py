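import numpy as np
import pytest

import leadopt as L


@pytest.fixture(scope="session")
def lead():
    return L.lead_structure()


@pytest.fixture(scope="session")
def smoke():
    return L.seeded_smoke_config(seed=1)


@pytest.fixture(scope="session")
def smoke_records(smoke, lead):
    """One full deterministic smoke optimization run (200 episodes)."""
    return L.run_optimization(
        lead, smoke.mdp, smoke.agent, L.surrogate_reward_fn(smoke.surrogate),
        smoke.reward,
    )


@pytest.fixture(scope="session")
def smoke_records_repeat(smoke, lead):
    """An independent rerun with the same master seed."""
    return L.run_optimization(
        lead, smoke.mdp, smoke.agent, L.surrogate_reward_fn(smoke.surrogate),
        smoke.reward,
    )


@pytest.fixture(scope="session")
def random_records(smoke, lead):
    """The pure-random control arm (epsilon pinned at 1, no training)."""
    return L.run_random_baseline(
        lead, smoke.mdp, smoke.agent, L.surrogate_reward_fn(smoke.surrogate),
        smoke.reward,
    )


def random_walk_smiles(seed: int, n_steps: int = 4, start: str = "C") -> str:
    """A random valence-valid molecule built by seeded random MDP edits."""
    rng = np.random.default_rng(seed)
    cfg = L.MDPConfig(step_limit=n_steps)
    state = L.initial_state(L.parse_smiles(start), cfg)
    for _ in range(n_steps):
        cands = L.enumerate_actions(state, cfg)
        state = L.step(state, cands[int(rng.integers(len(cands)))], cfg)
    return state.smiles
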