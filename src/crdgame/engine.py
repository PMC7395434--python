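"""Mechanics and accounting of the threshold public-goods game.

A group of ``n`` players, each endowed with 40 units of capital, plays 10
rounds.  Each round every player invests 0, 2 or 4 units into a common pool.
The group succeeds if the pool reaches the target ``2 * 10 * n`` — the total
reached when everyone invests the fair share of 2 units every round.  On
success each player converts remaining savings to money; on failure a loss
lottery (probability 0.5) decides whether savings are wiped out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GameConfig",
    "GroupTrajectory",
    "make_config",
    "feasible_choices",
    "surplus_series",
    "settle",
]


@dataclass(frozen=True)
class GameConfig:
    """Parameters of one collective-risk game.

    The target is derived, never stored: ``fair_share * n_rounds *
    group_size``, i.e. 60 / 140 / 220 units for groups of 3 / 7 / 11.

    ``per_player_lottery`` selects the granularity of the loss lottery on
    failure.  The default is a single draw per group (all members share the
    outcome), matching the shared-risk framing of the dilemma; set it to
    True for one independent draw per player.
    """

    group_size: int
    n_rounds: int = 10
    endowment: int = 40
    choices: tuple[int, ...] = (0, 2, 4)
    fair_share: int = 2
    loss_probability: float = 0.5
    payout_rate: float = 2.0
    show_up_fee: float = 15.0
    per_player_lottery: bool = False

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError(f"group_size must be >= 1, got {self.group_size}")
        if self.n_rounds < 1:
            raise ValueError(f"n_rounds must be >= 1, got {self.n_rounds}")
        if not 0.0 <= self.loss_probability <= 1.0:
            raise ValueError("loss_probability must be a probability")
        if tuple(sorted(set(self.choices))) != tuple(self.choices) or 0 not in self.choices:
            raise ValueError("choices must be strictly increasing and contain 0")

    @property
    def target(self) -> int:
        return self.fair_share * self.n_rounds * self.group_size

    @property
    def max_choice(self) -> int:
        return max(self.choices)


def make_config(group_size: int, **overrides) -> GameConfig:
    """Default game configuration for a group of ``group_size`` players."""
    return GameConfig(group_size=group_size, **overrides)


def feasible_choices(capital: float, config: GameConfig) -> tuple[int, ...]:
    """Contribution levels affordable with ``capital`` units remaining.

    Always contains 0.  Under the default configuration (endowment 40 =
    max choice x rounds) the full menu is affordable in every round, so this
    guard never binds; it exists to keep the accounting safe for non-default
    dilemmas.
    """
    if capital < 0:
        raise ValueError(f"capital must be non-negative, got {capital}")
    return tuple(c for c in config.choices if c <= capital)


def _as_investment_matrix(investments, config: GameConfig) -> np.ndarray:
    arr = np.asarray(investments)
    if arr.ndim != 2 or arr.shape != (config.group_size, config.n_rounds):
        raise ValueError(
            f"investments must be a ({config.group_size}, {config.n_rounds}) "
            f"matrix, got shape {arr.shape}"
        )
    if not np.isin(arr, config.choices).all():
        bad = arr[~np.isin(arr, config.choices)]
        raise ValueError(f"investments outside menu {config.choices}: {np.unique(bad)}")
    return arr


def surplus_series(investments, config: GameConfig) -> np.ndarray:
    """Per-round investment surplus (positive) or deficit (negative).

    ``surplus[r] = cumulative pool after round r - fair_share * n * r``; the
    final entry equals cumulative total minus the target, so the group
    succeeds iff the series ends at or above zero.
    """
    arr = _as_investment_matrix(investments, config)
    cumulative = arr.sum(axis=0).cumsum()
    on_track = config.fair_share * config.group_size * np.arange(1, config.n_rounds + 1)
    return cumulative - on_track


@dataclass
class GroupTrajectory:
    """Complete record of one group's play."""

    group_id: str
    arm: Literal["control", "treatment"]
    investments: np.ndarray  # shape (group_size, n_rounds)
    config: GameConfig
    cumulative: np.ndarray = field(init=False)
    surplus: np.ndarray = field(init=False)
    success: bool = field(init=False)
    savings: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.investments = _as_investment_matrix(self.investments, self.config)
        self.cumulative = self.investments.sum(axis=0).cumsum()
        self.surplus = surplus_series(self.investments, self.config)
        self.success = bool(self.cumulative[-1] >= self.config.target)
        self.savings = self.config.endowment - self.investments.sum(axis=1)
        if (self.savings < 0).any():
            raise ValueError("a player invested more than the endowment")


def settle(trajectory: GroupTrajectory, config: GameConfig, rng: np.random.Generator) -> np.ndarray:
    """Monetary payout per player, in currency units.

    On success every player receives ``show_up_fee + payout_rate * savings``.
    On failure the loss lottery decides whether savings are wiped: one
    Bernoulli(loss_probability) draw for the whole group by default, or one
    per player when ``config.per_player_lottery`` is set.  Payouts always lie
    in ``[show_up_fee, show_up_fee + payout_rate * endowment]`` (Y=15..95
    under defaults).
    """
    if trajectory.investments.shape[1] != config.n_rounds:
        raise ValueError("trajectory incomplete: not all rounds played")
    savings = trajectory.savings.astype(float)
    if trajectory.success:
        kept = savings
    elif config.per_player_lottery:
        wiped = rng.random(config.group_size) < config.loss_probability
        kept = np.where(wiped, 0.0, savings)
    else:
        kept = np.zeros_like(savings) if rng.random() < config.loss_probability else savings
    return config.show_up_fee + config.payout_rate * kept
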