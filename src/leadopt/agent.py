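"""Deep Q-learning over the molecule-modification MDP.

The action value Q(s, a) is evaluated on the *resulting* molecule of an
action (plus the normalized steps-remaining counter), so one network scores
every candidate in a state in a single batched forward pass.  Exploration
follows a linearly decaying epsilon-greedy schedule: epsilon starts at 1.0
(fully random) and drops by a fixed decrement each episode (default 1/6000
over 6000 episodes), held internally as exact rationals so the schedule is
bit-exact.

The Q-network is a compact two-hidden-layer ReLU MLP on a Morgan circular
fingerprint, trained by Adam on the one-step temporal-difference objective
with an experience-replay buffer and a periodically synced target network.
Rewards are terminal-only: a scalarized (affinity, QED, SA) triple of the
episode's final molecule, discounted backwards with gamma.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import parse_smiles, to_canonical_smiles
from .mdp import MDPConfig, MDPState, enumerate_actions, initial_state
from .rewards import RewardConfig, RewardVector


class AgentError(RuntimeError):
    pass


class TrainingDivergenceError(AgentError):
    """The TD loss became non-finite."""


def _as_fraction(x) -> Fraction:
    # exact when given a Fraction / int / decimal string; floats are taken
    # at their binary value (0.5, 0.25 ... are exact anyway)
    return x if isinstance(x, Fraction) else Fraction(x)


@dataclass(frozen=True)
class AgentConfig:
    """Learner and schedule settings.

    Epsilon parameters may be ints, floats, strings or Fractions; they are
    normalized to exact rationals.  Defaults mirror a full production run:
    6000 episodes with the decrement 1/6000 (epsilon reaches 0 exactly at
    the last episode + 1).
    """

    episodes: int = 6000
    epsilon_init: Fraction = Fraction(1)
    epsilon_decrement: Fraction = Fraction(1, 6000)
    epsilon_floor: Fraction = Fraction(0)
    gamma: float = 0.9
    replay_capacity: int = 5000
    batch_size: int = 128
    target_sync_every: int = 20
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    hidden_sizes: tuple[int, int] = (1024, 512)
    learning_rate: float = 1e-4
    seed: int = 0
    train: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "epsilon_init", _as_fraction(self.epsilon_init))
        object.__setattr__(
            self, "epsilon_decrement", _as_fraction(self.epsilon_decrement)
        )
        object.__setattr__(self, "epsilon_floor", _as_fraction(self.epsilon_floor))
        if not (0 <= self.epsilon_init <= 1):
            raise AgentError(f"epsilon_init out of [0,1]: {self.epsilon_init}")
        if self.epsilon_decrement < 0:
            raise AgentError("epsilon_decrement must be >= 0")
        if self.episodes < 1:
            raise AgentError("episodes must be >= 1")


def epsilon_at(episode: int, cfg: AgentConfig) -> float:
    """Exploration probability at a given episode index (exact arithmetic):
    max(floor, init - episode * decrement)."""
    if episode < 0:
        raise AgentError(f"episode must be >= 0, got {episode}")
    eps = cfg.epsilon_init - episode * cfg.epsilon_decrement
    return float(max(cfg.epsilon_floor, eps))


# ---------------------------------------------------------------------------
# State featurization
# ---------------------------------------------------------------------------

class Featurizer:
    """Morgan fingerprint + normalized steps-remaining, cached by SMILES."""

    def __init__(self, cfg: AgentConfig, step_limit: int):
        self.cfg = cfg
        self.step_limit = step_limit
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=cfg.fingerprint_radius, fpSize=cfg.fingerprint_bits
        )
        self._cache: dict[str, np.ndarray] = {}

    @property
    def dim(self) -> int:
        return self.cfg.fingerprint_bits + 1

    def fingerprint(self, smiles: str) -> np.ndarray:
        fp = self._cache.get(smiles)
        if fp is None:
            mol = parse_smiles(smiles)
            fp = np.asarray(
                self._gen.GetFingerprintAsNumPy(mol), dtype=np.float32
            )
            self._cache[smiles] = fp
        return fp

    def __call__(self, smiles: str, steps_remaining: int) -> np.ndarray:
        vec = np.empty(self.dim, dtype=np.float32)
        vec[:-1] = self.fingerprint(smiles)
        vec[-1] = steps_remaining / self.step_limit
        return vec

    def batch(self, smiles_list, steps_remaining: int) -> np.ndarray:
        out = np.empty((len(smiles_list), self.dim), dtype=np.float32)
        for i, s in enumerate(smiles_list):
            out[i, :-1] = self.fingerprint(s)
        out[:, -1] = steps_remaining / self.step_limit
        return out


def featurize(mol: Chem.Mol, cfg: AgentConfig, steps_remaining: int = 0,
              step_limit: int | None = None) -> np.ndarray:
    """Feature vector of one molecule: ``fingerprint_bits`` Morgan bits plus
    the normalized steps-remaining slot (length fingerprint_bits + 1)."""
    limit = step_limit if step_limit is not None else max(steps_remaining, 1)
    f = Featurizer(cfg, step_limit=limit)
    return f(to_canonical_smiles(mol), steps_remaining)


# ---------------------------------------------------------------------------
# numpy Q-network
# ---------------------------------------------------------------------------

class QNetwork:
    """Two-hidden-layer ReLU MLP mapping a feature vector to a scalar Q,
    trained with Adam.  Small enough that numpy on one core is adequate."""

    def __init__(self, input_dim: int, hidden_sizes: tuple[int, int],
                 learning_rate: float, rng: np.random.Generator):
        h1, h2 = hidden_sizes
        self.lr = learning_rate
        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
                np.float64
            )
        self.params = {
            "W1": he(input_dim, (input_dim, h1)), "b1": np.zeros(h1),
            "W2": he(h1, (h1, h2)), "b2": np.zeros(h2),
            "W3": he(h2, (h2, 1)), "b3": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        z1 = X @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        return (a2 @ p["W3"] + p["b3"]).ravel()

    def train_step(self, X: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on the mean-squared TD error; returns the loss."""
        p = self.params
        n = X.shape[0]
        z1 = X @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        q = (a2 @ p["W3"] + p["b3"]).ravel()
        err = q - y
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                f"non-finite TD loss {loss}; |q|max={np.abs(q).max()}"
            )
        d_q = (2.0 / n) * err[:, None]
        grads = {
            "W3": a2.T @ d_q, "b3": d_q.sum(axis=0),
        }
        d_a2 = d_q @ p["W3"].T
        d_z2 = d_a2 * (z2 > 0)
        grads["W2"] = a1.T @ d_z2
        grads["b2"] = d_z2.sum(axis=0)
        d_a1 = d_z2 @ p["W2"].T
        d_z1 = d_a1 * (z1 > 0)
        grads["W1"] = X.T @ d_z1
        grads["b1"] = d_z1.sum(axis=0)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** t)
            vhat = self._adam_v[k] / (1 - b2 ** t)
            p[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def copy_weights_from(self, other: "QNetwork") -> None:
        for k in self.params:
            self.params[k] = other.params[k].copy()

    def save(self, path: str) -> None:
        np.savez(path, **self.params)

    def load(self, path: str) -> None:
        with np.load(path) as data:
            for k in self.params:
                self.params[k] = data[k]


def select_action(candidates, q_values, epsilon: float,
                  rng: np.random.Generator):
    """Epsilon-greedy choice over candidate molecules.

    ``candidates`` is a sequence of canonical SMILES (or molecules, keyed by
    canonical SMILES); ``q_values`` aligns with it.  Ties at the maximum are
    broken by lexicographically smallest canonical SMILES.
    """
    if len(candidates) == 0:
        raise AgentError("empty candidate set")
    keys = [
        c if isinstance(c, str) else to_canonical_smiles(c) for c in candidates
    ]
    if rng.random() < epsilon:
        return candidates[int(rng.integers(len(candidates)))]
    q = np.asarray(q_values, dtype=float)
    if len(q) != len(candidates):
        raise AgentError("q_values misaligned with candidates")
    best = np.flatnonzero(q == q.max())
    idx = min(best, key=lambda i: keys[i])
    return candidates[int(idx)]


# ---------------------------------------------------------------------------
# Replay buffer and batch training
# ---------------------------------------------------------------------------

@dataclass
class Transition:
    """(action-result, reward, successor candidates) — features are looked
    up lazily through the run's featurizer cache."""

    chosen_smiles: str
    steps_remaining: int  # after the action
    reward: float
    terminal: bool
    next_candidates: tuple[str, ...]  # empty when terminal


class ReplayBuffer:
    def __init__(self, capacity: int):
        self.capacity = capacity
        self._data: list[Transition] = []
        self._pos = 0

    def push(self, tr: Transition) -> None:
        if len(self._data) < self.capacity:
            self._data.append(tr)
        else:
            self._data[self._pos] = tr
            self._pos = (self._pos + 1) % self.capacity

    def __len__(self) -> int:
        return len(self._data)

    def sample(self, n: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(len(self._data), size=n)
        return [self._data[int(i)] for i in idx]


def train_on_batch(batch: list[Transition], online: QNetwork, target: QNetwork,
                   cfg: AgentConfig, feat: Featurizer) -> float:
    """One TD gradient step: y = r for terminal transitions, else
    r + gamma * max_a' Q_target(s', a').  Returns the (finite) batch loss."""
    if not batch:
        raise AgentError("empty training batch")
    X = np.stack([feat(tr.chosen_smiles, tr.steps_remaining) for tr in batch])
    y = np.array([tr.reward for tr in batch], dtype=float)
    # batched target evaluation over all successors of all sampled transitions
    blocks, owners = [], []
    for i, tr in enumerate(batch):
        if not tr.terminal and tr.next_candidates:
            blocks.append(feat.batch(tr.next_candidates, tr.steps_remaining - 1))
            owners.append((i, blocks[-1].shape[0]))
    if blocks:
        qn = target.forward(np.concatenate(blocks, axis=0))
        pos = 0
        for i, size in owners:
            y[i] += cfg.gamma * qn[pos:pos + size].max()
            pos += size
    return online.train_step(X.astype(np.float64), y)


# ---------------------------------------------------------------------------
# Episode generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpisodeRecord:
    """Outcome of one optimization episode."""

    episode: int
    smiles: str
    reward: RewardVector | None
    epsilon: float
    scalar_reward: float
    trajectory: tuple[str, ...] = field(default=(), repr=False)
    failed: bool = False


def run_optimization(lead: Chem.Mol, mdp_cfg: MDPConfig, agent_cfg: AgentConfig,
                     reward_fn, reward_cfg: RewardConfig | None = None,
                     ) -> list[EpisodeRecord]:
    """Generate and learn from ``agent_cfg.episodes`` episodes.

    ``reward_fn`` maps a final molecule to a :class:`RewardVector` (wire in
    the surrogate oracle or a docking-backed oracle).  Fully reproducible
    for a fixed ``agent_cfg.seed`` with a deterministic reward function.
    Episodes whose reward evaluation raises are recorded as failed (the run
    aborts if more than 10% fail).
    """
    reward_cfg = reward_cfg or RewardConfig()
    ss = np.random.SeedSequence(agent_cfg.seed)
    init_rng, act_rng, sample_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    feat = Featurizer(agent_cfg, step_limit=mdp_cfg.step_limit)
    online = QNetwork(feat.dim, agent_cfg.hidden_sizes,
                      agent_cfg.learning_rate, init_rng)
    target = QNetwork(feat.dim, agent_cfg.hidden_sizes,
                      agent_cfg.learning_rate, init_rng)
    target.copy_weights_from(online)
    replay = ReplayBuffer(agent_cfg.replay_capacity)
    action_cache: dict[str, tuple[str, ...]] = {}

    def legal_actions(smiles: str, steps_taken: int) -> tuple[str, ...]:
        cands = action_cache.get(smiles)
        if cands is None:
            state = MDPState(mol=parse_smiles(smiles), steps_taken=steps_taken,
                             step_limit=mdp_cfg.step_limit)
            cands = tuple(
                to_canonical_smiles(m) for m in enumerate_actions(state, mdp_cfg)
            )
            action_cache[smiles] = cands
        return cands

    lead_smiles = to_canonical_smiles(initial_state(lead, mdp_cfg).mol)
    records: list[EpisodeRecord] = []
    failures = 0
    for ep in range(agent_cfg.episodes):
        eps = epsilon_at(ep, agent_cfg)
        cur = lead_smiles
        trajectory: list[str] = []
        pending: list[Transition] = []
        for t in range(mdp_cfg.step_limit):
            steps_remaining = mdp_cfg.step_limit - t
            cands = legal_actions(cur, steps_taken=t)
            if act_rng.random() < eps:
                chosen = cands[int(act_rng.integers(len(cands)))]
            else:
                q = online.forward(
                    feat.batch(cands, steps_remaining - 1).astype(np.float64)
                )
                best = np.flatnonzero(q == q.max())
                chosen = cands[int(min(best, key=lambda i: cands[i]))]
            trajectory.append(chosen)
            terminal = (t + 1) == mdp_cfg.step_limit
            next_cands = () if terminal else legal_actions(chosen, t + 1)
            pending.append(Transition(
                chosen_smiles=chosen, steps_remaining=steps_remaining - 1,
                reward=0.0, terminal=terminal, next_candidates=next_cands,
            ))
            cur = chosen
            if agent_cfg.train and len(replay) >= agent_cfg.batch_size:
                train_on_batch(
                    replay.sample(agent_cfg.batch_size, sample_rng),
                    online, target, agent_cfg, feat,
                )
        try:
            rv = reward_fn(parse_smiles(cur))
            scalar = reward_cfg.scalarize(rv)
        except Exception:
            failures += 1
            records.append(EpisodeRecord(
                episode=ep, smiles=cur, reward=None, epsilon=eps,
                scalar_reward=float("nan"), trajectory=tuple(trajectory),
                failed=True,
            ))
            if failures > 0.1 * (ep + 1) and ep >= 9:
                raise AgentError(
                    f"{failures} reward failures in {ep + 1} episodes (>10%)"
                )
            continue
        pending[-1].reward = scalar
        for tr in pending:
            replay.push(tr)
        if agent_cfg.train and (ep + 1) % agent_cfg.target_sync_every == 0:
            target.copy_weights_from(online)
        records.append(EpisodeRecord(
            episode=ep, smiles=cur, reward=rv, epsilon=eps,
            scalar_reward=scalar, trajectory=tuple(trajectory),
        ))
    return records


def run_random_baseline(lead: Chem.Mol, mdp_cfg: MDPConfig,
                        agent_cfg: AgentConfig, reward_fn,
                        reward_cfg: RewardConfig | None = None):
    """Pure uniform-random search: epsilon pinned at 1, no training.  The
    control arm for learning-progress comparisons."""
    cfg = replace(agent_cfg, epsilon_init=Fraction(1),
                  epsilon_decrement=Fraction(0), epsilon_floor=Fraction(1),
                  train=False)
    return run_optimization(lead, mdp_cfg, cfg, reward_fn, reward_cfg)


# ---------------------------------------------------------------------------
# Episode-log I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("episode", "smiles", "affinity_kcal_mol", "qed", "sa",
               "epsilon", "scalar_reward")


def episodes_to_csv(records: list[EpisodeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in records:
            if r.failed or r.reward is None:
                w.writerow([r.episode, r.smiles, "", "", "", repr(r.epsilon), ""])
            else:
                w.writerow([
                    r.episode, r.smiles, repr(r.reward.affinity),
                    repr(r.reward.qed), repr(r.reward.sa), repr(r.epsilon),
                    repr(r.scalar_reward),
                ])


def episodes_from_csv(path) -> list[EpisodeRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            failed = row["qed"] == ""
            rv = None if failed else RewardVector(
                affinity=float(row["affinity_kcal_mol"]),
                qed=float(row["qed"]), sa=float(row["sa"]),
            )
            records.append(EpisodeRecord(
                episode=int(row["episode"]), smiles=row["smiles"], reward=rv,
                epsilon=float(row["epsilon"]),
                scalar_reward=float(row["scalar_reward"]) if not failed
                else float("nan"),
                failed=failed,
            ))
    return records
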