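"""Centralized training / decentralized execution Q-learning.

The team interacts episodically with the patch-navigation environment under
epsilon-greedy exploration; transitions go to a uniform replay buffer and
gradient steps regress the team value of the taken action onto the one-step
TD target y = r + gamma * max_a' Q_tot(s', a'; theta-) computed with frozen
target networks (plain max, no double-Q correction). Target networks are
hard-synced every ``target_sync`` gradient steps.

The temporal agent's hidden state is computed once per episode from the
lesion's text descriptor and held fixed while the team navigates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import SpatialQNet, TemporalQNet
from .descriptors import (
    DEFAULT_DESCRIPTOR,
    DescriptorConfig,
    describe,
    describe_measured,
)
from .environment import (
    N_NAV_ACTIONS,
    LesionEnv,
    PatchGrid,
    episode_return,
    positional_embedding,
)
from .errors import ConfigurationError, ContractError, DomainError
from .fusion import (
    FusionRule,
    class_probabilities,
    fuse_class_values,
    make_fusion,
    select_joint_action,
    team_values,
)
from .nn import Adam, Module
from .synthetic import LesionImage, LesionSequence


# ---------------------------------------------------------------------------
# samples and transitions
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    """One classification case: current image + descriptor token sequence."""

    pixels: np.ndarray  # (224, 224, 3) in [0, 1]
    label: int
    tokens: tuple[int, ...]


def build_samples(
    items,
    descriptor_config: DescriptorConfig = DEFAULT_DESCRIPTOR,
) -> list[TrainingSample]:
    """LesionImages and/or LesionSequences -> training samples.

    For a sequence the spatial agent sees the current (last) frame and the
    temporal agent encodes the concatenated per-frame descriptors in time
    order; a single image contributes its own descriptor.
    """
    def _tokens(image: LesionImage) -> tuple[int, ...]:
        if image.features is not None:
            return describe(image, descriptor_config).tokens
        return describe_measured(image, descriptor_config).tokens

    samples = []
    for item in items:
        if isinstance(item, LesionSequence):
            tokens: tuple[int, ...] = ()
            for frame in item.frames:
                tokens += _tokens(frame)
            samples.append(
                TrainingSample(item.frames[-1].pixels, item.label, tokens)
            )
        elif isinstance(item, LesionImage):
            samples.append(TrainingSample(item.pixels, item.label, _tokens(item)))
        else:
            raise DomainError(f"cannot build a sample from {type(item).__name__}")
    return samples


@dataclass
class Transition:
    """One replay record; patches are re-cropped lazily from the shared image."""

    sample: TrainingSample
    pos: tuple[int, int]
    action: int
    reward: float
    next_pos: tuple[int, int] | None
    terminal: bool
    next_forced: bool = False


class ReplayBuffer:
    """Bounded FIFO with uniform without-replacement batch sampling."""

    def __init__(self, capacity: int, rng: np.random.Generator) -> None:
        self.capacity = capacity
        self.rng = rng
        self._storage: list[Transition] = []
        self._next = 0

    def __len__(self) -> int:
        return len(self._storage)

    def add(self, transition: Transition) -> None:
        if len(self._storage) < self.capacity:
            self._storage.append(transition)
        else:
            self._storage[self._next] = transition
            self._next = (self._next + 1) % self.capacity

    def sample(self, batch_size: int) -> list[Transition]:
        if batch_size > len(self._storage):
            raise ContractError("not enough transitions to sample a batch")
        idx = self.rng.choice(len(self._storage), size=batch_size, replace=False)
        return [self._storage[i] for i in idx]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    gamma: float = 0.99
    tau: float = 1.0
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_frac: float = 0.6  # fraction of episodes over which to anneal
    batch_size: int = 32
    replay_capacity: int = 10_000
    warmup_transitions: int = 200
    target_sync: int = 200  # gradient steps between hard target syncs
    learning_rate: float = 1e-4
    episodes: int = 3000
    train_every: int = 4  # environment steps per gradient step
    t_max: int = 16
    pos_frequencies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ConfigurationError("gamma must lie in (0, 1]")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        for eps in (self.epsilon_start, self.epsilon_end):
            if not 0 <= eps <= 1:
                raise ConfigurationError("epsilon must lie in [0, 1]")

    def epsilon_at(self, episode: int) -> float:
        decay = max(int(self.epsilon_decay_frac * self.episodes), 1)
        frac = min(episode / decay, 1.0)
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)


class _TeamBundle(Module):
    """All trainable modules under one parameter registry (one optimizer)."""

    def __init__(self, spatial: Module, temporal: Module, fusion: FusionRule) -> None:
        super().__init__()
        self.add_child("spatial", spatial)
        self.add_child("temporal", temporal)
        self.add_child("fusion", fusion)


# ---------------------------------------------------------------------------
# TD targets and loss
# ---------------------------------------------------------------------------

def _next_state_value(
    transition: Transition,
    spatial: SpatialQNet,
    temporal: TemporalQNet,
    rule: FusionRule,
    grid: PatchGrid,
    pos_frequencies: int,
) -> float:
    patch = grid.crop(transition.sample.pixels, transition.next_pos)
    pe = positional_embedding(transition.next_pos, grid, pos_frequencies)
    q1 = spatial.q_values(patch[None], pe[None])
    h = temporal.encode([transition.sample.tokens])
    q2 = temporal.head_values(h)
    summaries = (spatial.last_features, h) if rule.has_summaries else None
    values = team_values(q1, q2, rule, summaries=summaries)[0]
    if transition.next_forced:
        return float(values[N_NAV_ACTIONS:].max())
    return float(values.max())


def td_target(
    transition: Transition,
    nets: tuple[SpatialQNet, TemporalQNet],
    rule: FusionRule,
    gamma: float = 0.99,
    grid: PatchGrid | None = None,
    pos_frequencies: int = 2,
) -> float:
    """One-step bootstrap target y = r + gamma * max_a' Q_tot(s', a').

    ``nets`` should be the frozen target-network pair; terminal transitions
    reduce to the reward.
    """
    if transition.terminal:
        return float(transition.reward)
    grid = grid or PatchGrid()
    spatial, temporal = nets
    return float(
        transition.reward
        + gamma
        * _next_state_value(transition, spatial, temporal, rule, grid, pos_frequencies)
    )


def _batch_arrays(batch, grid, pos_frequencies):
    patches = np.stack([grid.crop(t.sample.pixels, t.pos) for t in batch])
    pes = np.stack([positional_embedding(t.pos, grid, pos_frequencies) for t in batch])
    tokens = [t.sample.tokens for t in batch]
    return patches, pes, tokens


def vdn_loss(
    batch: list[Transition],
    nets: tuple[SpatialQNet, TemporalQNet],
    target_nets: tuple[SpatialQNet, TemporalQNet],
    rule: FusionRule,
    gamma: float = 0.99,
    grid: PatchGrid | None = None,
    pos_frequencies: int = 2,
    target_rule: FusionRule | None = None,
    accumulate_grads: bool = False,
) -> float:
    """Mean squared TD error of the team value of the taken actions.

    With ``accumulate_grads`` the loss gradient is backpropagated into the
    online networks' (and any learned fusion rule's) gradient buffers.
    """
    if not batch:
        raise ContractError("empty transition batch")
    grid = grid or PatchGrid()
    spatial, temporal = nets
    target_rule = target_rule or rule
    n = len(batch)
    k = temporal.n_classes

    # batched TD targets with the frozen target networks
    t_spatial, t_temporal = target_nets
    ys = np.array([t.reward for t in batch], dtype=float)
    nonterm = [i for i, t in enumerate(batch) if not t.terminal]
    if nonterm:
        npatches = np.stack([grid.crop(batch[i].sample.pixels, batch[i].next_pos) for i in nonterm])
        npes = np.stack(
            [positional_embedding(batch[i].next_pos, grid, pos_frequencies) for i in nonterm]
        )
        q1n = t_spatial.q_values(npatches, npes)
        hn = t_temporal.encode([batch[i].sample.tokens for i in nonterm])
        q2n = t_temporal.head_values(hn)
        nsummaries = (
            (t_spatial.last_features, hn) if target_rule.has_summaries else None
        )
        vals = team_values(q1n, q2n, target_rule, summaries=nsummaries)
        forced = np.array([batch[i].next_forced for i in nonterm])
        best = np.where(
            forced, vals[:, N_NAV_ACTIONS:].max(axis=1), vals.max(axis=1)
        )
        ys[nonterm] += gamma * best

    patches, pes, tokens = _batch_arrays(batch, grid, pos_frequencies)
    q1 = spatial.q_values(patches, pes)
    h = temporal.encode(tokens)
    q2 = temporal.head_values(h)
    summaries = (spatial.last_features, h) if rule.has_summaries else None
    fused = fuse_class_values(q1, q2, rule, summaries=summaries)

    actions = np.array([t.action for t in batch])
    is_class = actions >= N_NAV_ACTIONS
    qtot = np.where(
        is_class,
        fused[np.arange(n), np.clip(actions - N_NAV_ACTIONS, 0, k - 1)],
        q1[np.arange(n), np.clip(actions, 0, N_NAV_ACTIONS - 1)],
    )
    residual = qtot - ys
    loss = float(np.mean(residual**2))

    if accumulate_grads:
        g = 2.0 * residual / n
        dfused = np.zeros_like(fused)
        rows = np.flatnonzero(is_class)
        dfused[rows, actions[rows] - N_NAV_ACTIONS] = g[rows]
        dq1c, dq2 = rule.backward(dfused)
        dq1 = np.zeros_like(q1)
        dq1[:, N_NAV_ACTIONS:] = dq1c
        nav_rows = np.flatnonzero(~is_class)
        dq1[nav_rows, actions[nav_rows]] += g[nav_rows]
        spatial.backward(dq1)
        temporal.backward(dq2)
    return loss


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    spatial: SpatialQNet
    temporal: TemporalQNet
    fusion: FusionRule
    log: pd.DataFrame
    config: TrainConfig
    grid: PatchGrid = field(default_factory=PatchGrid)


def _build_team(
    n_classes: int,
    vocab_size: int,
    pos_dim: int,
    rng: np.random.Generator,
    spatial_backbone: str,
    temporal_backbone: str,
    fusion_kind: str,
):
    spatial = SpatialQNet(n_classes, pos_dim, rng, backbone=spatial_backbone)
    temporal = TemporalQNet(vocab_size, n_classes, rng, backbone=temporal_backbone)
    fusion = make_fusion(
        fusion_kind,
        n_classes,
        rng,
        d_spatial=spatial.backbone.out_dim,
        d_temporal=temporal.d_hidden,
    )
    return spatial, temporal, fusion


def train(
    samples: list[TrainingSample],
    config: TrainConfig,
    vocab_size: int,
    fusion_kind: str = "vdn-sum",
    spatial_backbone: str = "small-cnn",
    temporal_backbone: str = "gru",
    grid: PatchGrid | None = None,
) -> TrainResult:
    """Run CTDE Q-learning on a labelled sample set; reproducible from seed."""
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ConfigurationError("training needs at least two classes present")
    n_classes = max(labels) + 1
    grid = grid or PatchGrid()
    rng = np.random.default_rng(config.seed)
    pos_dim = positional_embedding((0, 0), grid, config.pos_frequencies).shape[0]

    spatial, temporal, fusion = _build_team(
        n_classes, vocab_size, pos_dim, rng,
        spatial_backbone, temporal_backbone, fusion_kind,
    )
    t_spatial, t_temporal, t_fusion = _build_team(
        n_classes, vocab_size, pos_dim, np.random.default_rng(config.seed),
        spatial_backbone, temporal_backbone, fusion_kind,
    )
    for online, target in ((spatial, t_spatial), (temporal, t_temporal), (fusion, t_fusion)):
        target.copy_from(online)

    bundle = _TeamBundle(spatial, temporal, fusion)
    optimizer = Adam(bundle, lr=config.learning_rate)
    buffer = ReplayBuffer(config.replay_capacity, rng)
    env = LesionEnv(
        n_classes, grid=grid, t_max=config.t_max,
        pos_frequencies=config.pos_frequencies,
    )

    log_rows = []
    total_steps = 0
    grad_steps = 0
    last_loss = np.nan
    for episode in range(config.episodes):
        sample = samples[int(rng.integers(len(samples)))]
        h = temporal.encode([sample.tokens])
        state = env.reset(sample.pixels, sample.label, h[0])
        epsilon = config.epsilon_at(episode)
        rewards = []
        while True:
            q1 = spatial.q_values(state.patch[None], state.pos_embed[None])
            q2 = temporal.head_values(h)
            summaries = (spatial.last_features, h) if fusion.has_summaries else None
            allowed = np.ones(env.n_actions, dtype=bool)
            if state.forced_classification:
                allowed[:N_NAV_ACTIONS] = False
            action = select_joint_action(
                q1[0], q2[0], fusion, epsilon, rng,
                allowed=allowed, summaries=summaries,
            )
            outcome = env.step(action)
            buffer.add(
                Transition(
                    sample=sample,
                    pos=state.grid_pos,
                    action=action,
                    reward=outcome.reward,
                    next_pos=None if outcome.terminal else outcome.next_state.grid_pos,
                    terminal=outcome.terminal,
                    next_forced=(
                        False
                        if outcome.terminal
                        else outcome.next_state.forced_classification
                    ),
                )
            )
            rewards.append(outcome.reward)
            total_steps += 1
            if (
                len(buffer) >= max(config.warmup_transitions, config.batch_size)
                and total_steps % config.train_every == 0
            ):
                batch = buffer.sample(config.batch_size)
                bundle.zero_grad()
                last_loss = vdn_loss(
                    batch,
                    (spatial, temporal),
                    (t_spatial, t_temporal),
                    fusion,
                    gamma=config.gamma,
                    grid=grid,
                    pos_frequencies=config.pos_frequencies,
                    target_rule=t_fusion,
                    accumulate_grads=True,
                )
                optimizer.step()
                grad_steps += 1
                if grad_steps % config.target_sync == 0:
                    t_spatial.copy_from(spatial)
                    t_temporal.copy_from(temporal)
                    t_fusion.copy_from(fusion)
            if outcome.terminal:
                break
            state = outcome.next_state
        log_rows.append(
            {
                "episode": episode,
                "return": episode_return(rewards, config.gamma),
                "loss": last_loss,
                "epsilon": epsilon,
                "steps": len(rewards),
            }
        )
    log = pd.DataFrame(log_rows)
    return TrainResult(spatial, temporal, fusion, log, config, grid)


# ---------------------------------------------------------------------------
# greedy rollout prediction
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    predicted_class: int
    probabilities: np.ndarray
    trajectory: list[tuple[int, int]]
    actions: list[int]


def predict(
    sample: TrainingSample,
    spatial: SpatialQNet,
    temporal: TemporalQNet,
    rule: FusionRule,
    grid: PatchGrid | None = None,
    t_max: int = 16,
    pos_frequencies: int = 2,
    tau: float = 1.0,
) -> Prediction:
    """Greedy (epsilon = 0) rollout from the start position.

    Returns the terminating class, the temperature-softmax class
    probabilities at the terminal step, and the visited-position trace.
    """
    grid = grid or PatchGrid()
    n_classes = temporal.n_classes
    env = LesionEnv(n_classes, grid=grid, t_max=t_max, pos_frequencies=pos_frequencies)
    h = temporal.encode([sample.tokens])
    state = env.reset(sample.pixels, sample.label, h[0])
    rng = np.random.default_rng(0)  # unused at epsilon=0
    trajectory = [state.grid_pos]
    actions: list[int] = []
    while True:
        q1 = spatial.q_values(state.patch[None], state.pos_embed[None])
        q2 = temporal.head_values(h)
        summaries = (spatial.last_features, h) if rule.has_summaries else None
        allowed = np.ones(env.n_actions, dtype=bool)
        if state.forced_classification:
            allowed[:N_NAV_ACTIONS] = False
        action = select_joint_action(
            q1[0], q2[0], rule, 0.0, rng, allowed=allowed, summaries=summaries
        )
        fused = fuse_class_values(q1[0], q2[0], rule, summaries=summaries)
        outcome = env.step(action)
        actions.append(action)
        if outcome.terminal:
            return Prediction(
                predicted_class=outcome.predicted_class,
                probabilities=class_probabilities(fused, tau),
                trajectory=trajectory,
                actions=actions,
            )
        state = outcome.next_state
        trajectory.append(state.grid_pos)


def supervised_warm_start(
    spatial: SpatialQNet,
    temporal: TemporalQNet,
    samples: list[TrainingSample],
    epochs: int = 3,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
    grid: PatchGrid | None = None,
    pos_frequencies: int = 2,
) -> float:
    """Optional supervised pre-fit of both agents' classification values.

    Regresses each agent's class entries toward +1 for the true class and
    -1 otherwise, on center patches; returns the final batch loss. This
    mirrors a supervised pre-fine-tuning stage that accelerates the RL
    phase; it is never required by the tests.
    """
    grid = grid or PatchGrid()
    rng = np.random.default_rng(seed)
    bundle = _TeamBundle(spatial, temporal, make_fusion("vdn-sum", temporal.n_classes))
    optimizer = Adam(bundle, lr=lr)
    start = grid.start_position()
    pe = positional_embedding(start, grid, pos_frequencies)
    loss = np.nan
    for _ in range(epochs):
        order = rng.permutation(len(samples))
        for i in range(0, len(order), batch_size):
            chunk = [samples[j] for j in order[i : i + batch_size]]
            patches = np.stack([grid.crop(s.pixels, start) for s in chunk])
            pes = np.tile(pe, (len(chunk), 1))
            targets = -np.ones((len(chunk), temporal.n_classes))
            targets[np.arange(len(chunk)), [s.label for s in chunk]] = 1.0
            bundle.zero_grad()
            q1 = spatial.q_values(patches, pes)
            q2 = temporal.q_values([s.tokens for s in chunk])
            r1 = q1[:, N_NAV_ACTIONS:] - targets
            r2 = q2 - targets
            loss = float(np.mean(r1**2) + np.mean(r2**2))
            dq1 = np.zeros_like(q1)
            dq1[:, N_NAV_ACTIONS:] = 2.0 * r1 / r1.size
            spatial.backward(dq1)
            temporal.backward(2.0 * r2 / r2.size)
            optimizer.step()
    return loss
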