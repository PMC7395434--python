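"""Synthetic experiment generator mirroring the study design.

Generates full datasets with the study's arm structure — control groups of
sizes 3/7/11 in counts 11/8/8 and treatment groups in counts 10/8/8 —
where each player is drawn i.i.d. from an arm-specific mixture of the three
behavioral types.  The default mixtures put the prosocial types
(cooperators + altruists) at 57.5% in treatment and 42.5% in control, split
2:1 cooperator:altruist within prosocial.  Treatment players additionally
answer the scheduled questionnaire.  Output is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents as ag
from .communication import questions_for_round
from .engine import GameConfig, GroupTrajectory, make_config, settle

__all__ = ["ExperimentDesign", "default_design", "generate_experiment"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Arm layout and per-arm behavioral-type mixture.

    ``arms`` lists (arm, group_size, n_groups); ``mixtures`` maps each arm
    to probabilities over (cooperator, free_rider, altruist).
    """

    arms: tuple[tuple[str, int, int], ...]
    mixtures: dict[str, tuple[float, float, float]]
    type_params: dict[str, ag.TypeParams] = field(default_factory=ag.default_type_params)

    def __post_init__(self) -> None:
        for arm, probs in self.mixtures.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"mixture for {arm!r} does not sum to 1: {probs}")
        for arm, size, n in self.arms:
            if arm not in self.mixtures:
                raise ValueError(f"no mixture for arm {arm!r}")
            if size < 1 or n < 0:
                raise ValueError(f"invalid arm spec {(arm, size, n)}")

    def n_players(self, arm: str | None = None) -> int:
        return sum(s * n for a, s, n in self.arms if arm is None or a == arm)


def _mixture(prosocial: float, coop_share: float = 2.0 / 3.0) -> tuple[float, float, float]:
    coop = prosocial * coop_share
    alt = prosocial * (1.0 - coop_share)
    return (coop, 1.0 - prosocial, alt)


def default_design(
    prosocial_treatment: float = 0.575,
    prosocial_control: float = 0.425,
    coop_share: float = 2.0 / 3.0,
) -> ExperimentDesign:
    """The study's arm layout with the default type mixtures.

    Control: 11 groups of 3, 8 of 7, 8 of 11 (177 players); treatment: 10
    of 3, 8 of 7, 8 of 11 (174 players).  ``coop_share`` is the cooperator
    fraction within the prosocial mass.
    """
    return ExperimentDesign(
        arms=(
            ("control", 3, 11),
            ("control", 7, 8),
            ("control", 11, 8),
            ("treatment", 3, 10),
            ("treatment", 7, 8),
            ("treatment", 11, 8),
        ),
        mixtures={
            "control": _mixture(prosocial_control, coop_share),
            "treatment": _mixture(prosocial_treatment, coop_share),
        },
    )


def generate_experiment(
    design: ExperimentDesign, seed: int, session_id: str = "synthetic"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one full experiment.

    Returns ``(gameplay, questionnaire, true_types)`` data frames:

    - gameplay: one row per player-round with columns session_id, arm,
      group_id, group_size, round, player_id, investment, capital_after;
    - questionnaire: one row per treatment player-round-question with the
      yes/no answer (empty for control-only designs);
    - true_types: the planted behavioral type per player.

    Identical ``seed`` gives identical frames.
    """
    rng = np.random.default_rng(seed)
    gameplay_rows: list[dict] = []
    answer_rows: list[dict] = []
    type_rows: list[dict] = []

    for arm, size, n_groups in design.arms:
        config = make_config(size)
        probs = np.asarray(design.mixtures[arm])
        for g in range(n_groups):
            group_id = f"{arm}-{size}-{g:02d}"
            types = rng.choice(ag.TYPE_NAMES, size=size, p=probs)
            investments = np.vstack(
                [
                    ag.sample_investment_matrix(design.type_params[t], 1, rng, config)[0]
                    for t in types
                ]
            )
            traj = GroupTrajectory(group_id, arm, investments, config)
            payouts = settle(traj, config, rng)
            capital_after = config.endowment - investments.cumsum(axis=1)
            for p in range(size):
                player_id = f"{group_id}-p{p:02d}"
                type_rows.append(
                    {"player_id": player_id, "arm": arm, "group_id": group_id,
                     "type": types[p], "payout": payouts[p]}
                )
                for r in range(config.n_rounds):
                    gameplay_rows.append(
                        {
                            "session_id": session_id,
                            "arm": arm,
                            "group_id": group_id,
                            "group_size": size,
                            "round": r + 1,
                            "player_id": player_id,
                            "investment": int(investments[p, r]),
                            "capital_after": int(capital_after[p, r]),
                        }
                    )
            if arm == "treatment":
                for r in range(1, config.n_rounds + 1):
                    for p in range(size):
                        player_id = f"{group_id}-p{p:02d}"
                        yes_prob = design.type_params[types[p]].yes_prob
                        for q in questions_for_round(r, config.n_rounds):
                            pr = yes_prob.get(q.id, 0.5)
                            answer_rows.append(
                                {
                                    "session_id": session_id,
                                    "arm": arm,
                                    "group_id": group_id,
                                    "round": r,
                                    "player_id": player_id,
                                    "question": q.id,
                                    "answer": int(rng.random() < pr),
                                }
                            )

    gameplay = pd.DataFrame(gameplay_rows)
    answer_cols = ["session_id", "arm", "group_id", "round", "player_id", "question", "answer"]
    questionnaire = pd.DataFrame(answer_rows, columns=answer_cols)
    true_types = pd.DataFrame(type_rows)
    return gameplay, questionnaire, true_types
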