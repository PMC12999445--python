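"""Episodic patch-navigation environment.

One episode inspects a single 224x224 image through a 64x64 window on a
grid of 50%-overlapping patches (stride 32 -> 6x6 positions). At each step
the team either moves the window (reward -0.01) or terminates with a class
decision (reward +1 if correct, -1 otherwise). Off-grid moves clip to the
boundary and still cost the navigation penalty. After ``t_max`` navigation
steps the environment forces a classification decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import ConfigurationError, ContractError, DomainError

GAMMA_DEFAULT = 0.99
NAV_REWARD = -0.01
T_MAX_DEFAULT = 16


class NavAction(IntEnum):
    MOVE_UP = 0
    MOVE_DOWN = 1
    MOVE_LEFT = 2
    MOVE_RIGHT = 3


N_NAV_ACTIONS = 4


def is_classification(action: int, n_classes: int) -> bool:
    if not 0 <= action < N_NAV_ACTIONS + n_classes:
        raise DomainError(f"action {action} outside the joint action space")
    return action >= N_NAV_ACTIONS


def action_class(action: int, n_classes: int) -> int:
    if not is_classification(action, n_classes):
        raise ContractError(f"action {action} is not a classification action")
    return action - N_NAV_ACTIONS


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of the overlapping patch lattice."""

    image_size: int = 224
    patch_size: int = 64
    stride: int = 32

    def __post_init__(self) -> None:
        if self.patch_size > self.image_size:
            raise ConfigurationError("patch_size exceeds image_size")
        if (self.image_size - self.patch_size) % self.stride != 0:
            raise ConfigurationError(
                f"(image_size - patch_size) = {self.image_size - self.patch_size} "
                f"is not divisible by stride {self.stride}"
            )

    @property
    def n_positions_per_axis(self) -> int:
        return (self.image_size - self.patch_size) // self.stride + 1

    @property
    def n_positions(self) -> int:
        return self.n_positions_per_axis**2

    def crop(self, image: np.ndarray, pos: tuple[int, int]) -> np.ndarray:
        """Half-open pixel window [stride*row, stride*row + patch_size)."""
        row, col = pos
        n = self.n_positions_per_axis
        if not (0 <= row < n and 0 <= col < n):
            raise DomainError(f"grid position {pos} outside {n}x{n} grid")
        r0, c0 = self.stride * row, self.stride * col
        return image[r0 : r0 + self.patch_size, c0 : c0 + self.patch_size]

    def start_position(self) -> tuple[int, int]:
        """Grid index nearest the image center; ties toward the lower index."""
        centers = self.stride * np.arange(self.n_positions_per_axis) + self.patch_size / 2
        idx = int(np.argmin(np.abs(centers - self.image_size / 2)))
        return (idx, idx)


def build_grid(image_size: int = 224, patch_size: int = 64, stride: int = 32) -> PatchGrid:
    return PatchGrid(image_size=image_size, patch_size=patch_size, stride=stride)


def navigate(
    pos: tuple[int, int], action: int, grid: PatchGrid
) -> tuple[int, int]:
    """Move one cell in the given direction, clipping at the grid boundary."""
    if action >= N_NAV_ACTIONS:
        raise ContractError("navigate() takes navigation actions only")
    row, col = pos
    n = grid.n_positions_per_axis
    if not (0 <= row < n and 0 <= col < n):
        raise DomainError(f"position {pos} outside grid")
    if action == NavAction.MOVE_UP:
        row -= 1
    elif action == NavAction.MOVE_DOWN:
        row += 1
    elif action == NavAction.MOVE_LEFT:
        col -= 1
    elif action == NavAction.MOVE_RIGHT:
        col += 1
    return (int(np.clip(row, 0, n - 1)), int(np.clip(col, 0, n - 1)))


def positional_embedding(
    pos: tuple[int, int], grid: PatchGrid, n_frequencies: int = 2
) -> np.ndarray:
    """Patch-center coordinates normalized to [0,1]^2, plus optional sinusoids."""
    n = grid.n_positions_per_axis
    coords = np.array(pos, dtype=float) / max(n - 1, 1)
    parts = [coords]
    for f in range(1, n_frequencies + 1):
        parts.append(np.sin(np.pi * f * coords))
        parts.append(np.cos(np.pi * f * coords))
    return np.concatenate(parts)


def pos_embed_dim(n_frequencies: int = 2) -> int:
    return 2 * (1 + 2 * n_frequencies)


@dataclass
class EnvState:
    """Joint observation: spatial patch + position for agent 1, text state for agent 2."""

    patch: np.ndarray  # (patch, patch, 3) raw [0,1] crop
    grid_pos: tuple[int, int]
    pos_embed: np.ndarray
    text_hidden: np.ndarray | None
    step_index: int
    forced_classification: bool = False


@dataclass
class StepOutcome:
    reward: float
    next_state: EnvState | None
    terminal: bool
    predicted_class: int | None = None


def episode_return(rewards, gamma: float = GAMMA_DEFAULT) -> float:
    """Discounted return sum_t gamma^t r_t of one episode's reward list."""
    rewards = list(rewards)
    if not rewards:
        raise DomainError("empty reward list")
    return float(sum(g * r for g, r in zip(gamma ** np.arange(len(rewards)), rewards)))


class LesionEnv:
    """Episodic environment over one image at a time."""

    def __init__(
        self,
        n_classes: int,
        grid: PatchGrid | None = None,
        t_max: int = T_MAX_DEFAULT,
        pos_frequencies: int = 2,
    ) -> None:
        if n_classes < 2:
            raise ConfigurationError("need at least two classes")
        self.n_classes = n_classes
        self.grid = grid or PatchGrid()
        self.t_max = t_max
        self.pos_frequencies = pos_frequencies
        self._image: np.ndarray | None = None
        self._label: int | None = None
        self._state: EnvState | None = None
        self._done = True

    @property
    def n_actions(self) -> int:
        return N_NAV_ACTIONS + self.n_classes

    def _make_state(self, pos: tuple[int, int], step_index: int,
                    text_hidden: np.ndarray | None) -> EnvState:
        return EnvState(
            patch=self.grid.crop(self._image, pos),
            grid_pos=pos,
            pos_embed=positional_embedding(pos, self.grid, self.pos_frequencies),
            text_hidden=text_hidden,
            step_index=step_index,
            forced_classification=step_index >= self.t_max,
        )

    def reset(
        self,
        image: np.ndarray,
        label: int,
        text_hidden: np.ndarray | None = None,
    ) -> EnvState:
        if image.shape[0] != self.grid.image_size or image.shape[1] != self.grid.image_size:
            raise DomainError(
                f"image must be {self.grid.image_size}x{self.grid.image_size}"
            )
        self._image = image
        self._label = int(label)
        self._done = False
        self._state = self._make_state(self.grid.start_position(), 0, text_hidden)
        return self._state

    def step(self, action: int) -> StepOutcome:
        if self._done or self._state is None:
            raise ContractError("step() called on a terminated episode")
        state = self._state
        if is_classification(action, self.n_classes):
            pred = action_class(action, self.n_classes)
            reward = 1.0 if pred == self._label else -1.0
            self._done = True
            self._state = None
            return StepOutcome(reward=reward, next_state=None, terminal=True,
                               predicted_class=pred)
        if state.forced_classification:
            raise ContractError(
                "navigation not allowed once the decision is forced at t_max"
            )
        new_pos = navigate(state.grid_pos, action, self.grid)
        self._state = self._make_state(new_pos, state.step_index + 1, state.text_hidden)
        return StepOutcome(reward=NAV_REWARD, next_state=self._state, terminal=False)
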