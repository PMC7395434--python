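"""Random-play null model: exact sum distributions and significance envelopes.

Under the null every player draws uniformly from the {0, 2, 4} menu each
round.  The group's cumulative investment is then a sum of ``n x rounds``
i.i.d. draws whose distribution is computed exactly by convolution; the
uniform draw is symmetric about the fair share, so the null's expected
surplus is zero in every round and its success probability obeys
``P(success) = (1 + P(sum = target)) / 2``.

The significance envelope is the per-round lower quantile of the surplus
among random-play groups that ultimately fail: an observed trajectory
dipping below the 95% envelope has a deficit deeper than 95% of
unsuccessful random play — evidence of systematically giving up rather
than drifting by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import GameConfig

__all__ = [
    "SumDistribution",
    "Envelope",
    "exact_sum_distribution",
    "success_probability",
    "failure_envelope",
    "flag_beyond_envelope",
]


@dataclass(frozen=True)
class SumDistribution:
    """Exact pmf of the cumulative group investment after all rounds."""

    support: np.ndarray  # capital units, ascending
    probabilities: np.ndarray
    n_players: int
    n_rounds: int

    def tail_probability(self, threshold: float) -> float:
        """P(sum >= threshold)."""
        return float(self.probabilities[self.support >= threshold].sum())


def _per_draw_pmf(draw_dist, choices: tuple[int, ...]) -> np.ndarray:
    """pmf indexed on 0..max(choices) (step-1 grid) for one draw."""
    if draw_dist is None:
        draw_dist = {c: 1.0 / len(choices) for c in choices}
    probs = np.asarray([draw_dist.get(v, 0.0) for v in range(max(choices) + 1)], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid per-draw distribution: {draw_dist}")
    extra = set(draw_dist) - set(range(max(choices) + 1))
    if extra:
        raise ValueError(f"per-draw support outside 0..{max(choices)}: {sorted(extra)}")
    return probs


def exact_sum_distribution(
    n_players: int, n_rounds: int, draw_dist: dict[int, float] | None = None,
    choices: tuple[int, ...] = (0, 2, 4),
) -> SumDistribution:
    """Distribution of the total group investment, by iterated convolution.

    ``draw_dist`` maps a contribution level to its per-draw probability
    (default: uniform over ``choices``).  The result is exact up to
    floating-point rounding over the ``n_players * n_rounds`` draws.
    """
    pmf = _per_draw_pmf(draw_dist, choices)
    n_draws = n_players * n_rounds
    total = np.array([1.0])
    for _ in range(n_draws):
        total = np.convolve(total, pmf)
    support = np.arange(total.size)
    keep = total > 0
    return SumDistribution(support[keep], total[keep], n_players, n_rounds)


def success_probability(
    n_players: int, config: GameConfig | None = None,
    draw_dist: dict[int, float] | None = None,
) -> float:
    """P(random play reaches the target) from the exact sum distribution."""
    config = config or GameConfig(group_size=n_players)
    dist = exact_sum_distribution(n_players, config.n_rounds, draw_dist, config.choices)
    return dist.tail_probability(config.target)


@dataclass(frozen=True)
class Envelope:
    """Per-round lower quantile of surplus among eventually-failing groups."""

    rounds: np.ndarray
    curve: np.ndarray  # surplus values, one per round
    level: float
    reps: int
    n_players: int
    seed: int
    n_failures: int


def failure_envelope(
    n_players: int,
    config: GameConfig | None = None,
    reps: int = 100_000,
    level: float = 0.95,
    seed: int = 0,
) -> Envelope:
    """Simulate random play and return the failure-conditional surplus envelope.

    Per round the curve is the ``(1 - level)`` empirical quantile (linear
    interpolation) of the surplus among the replicates that end below the
    target, so ``level`` of unsuccessful random-play groups stay above it.
    """
    config = config or GameConfig(group_size=n_players)
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable quantile")
    rng = np.random.default_rng(seed)
    choices = np.asarray(config.choices)
    # Per-round group totals: sum of n_players uniform draws, reps at a time.
    draws = rng.integers(0, len(choices), size=(reps, n_players, config.n_rounds))
    per_round = choices[draws].sum(axis=1)  # (reps, n_rounds)
    cumulative = per_round.cumsum(axis=1)
    on_track = config.fair_share * n_players * np.arange(1, config.n_rounds + 1)
    surplus = cumulative - on_track
    failing = surplus[:, -1] < 0  # final surplus < 0 <=> sum < target
    n_fail = int(failing.sum())
    if n_fail == 0:
        raise RuntimeError("no failing replicates; envelope undefined for this configuration")
    curve = np.quantile(surplus[failing], 1.0 - level, axis=0)
    return Envelope(
        np.arange(1, config.n_rounds + 1), curve, level, reps, n_players, seed, n_fail
    )


def flag_beyond_envelope(surplus: np.ndarray, envelope: Envelope) -> np.ndarray:
    """Rounds where an observed surplus lies strictly below the envelope."""
    surplus = np.asarray(surplus, dtype=float)
    if surplus.shape != envelope.curve.shape:
        raise ValueError(
            f"surplus has {surplus.shape[0]} rounds, envelope {envelope.curve.shape[0]}"
        )
    return surplus < envelope.curve
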