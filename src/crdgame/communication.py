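"""The between-round yes/no questionnaire and its majority-only display.

Treatment groups communicate only through five scheduled yes/no questions
answered between rounds; after everyone answers, players see the group
majority's verdict per question, never individual answers.  Groups have an
odd number of members so a majority always exists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = [
    "Question",
    "AnswerRecord",
    "MajoritySummary",
    "QUESTIONS",
    "questions_for_round",
    "majority",
]


@dataclass(frozen=True)
class Question:
    id: str
    text: str
    first_round: int


#: The five questions, in display order.  Q1/Q2 run from round 1, Q3/Q4 from
#: round 2 (they need at least one round of history), Q5 from round 6 (its
#: relevance grows as the end approaches).
QUESTIONS: tuple[Question, ...] = (
    Question("Q1", "Do you think that your group will reach the prescribed target?", 1),
    Question("Q2", "Are you satisfied with your group's performance in the current round?", 1),
    Question("Q3", "Are you satisfied with your group's overall performance so far?", 2),
    Question("Q4", "Would you like your group's investment to increase?", 2),
    Question(
        "Q5",
        "Do you think your group could lose everything if it fails to reach the prescribed target?",
        6,
    ),
)

QUESTION_BY_ID = {q.id: q for q in QUESTIONS}


@dataclass(frozen=True)
class AnswerRecord:
    """One player's yes/no answer to one scheduled question."""

    group_id: str
    round: int
    player_id: str
    question: str
    answer: bool

    def __post_init__(self) -> None:
        q = QUESTION_BY_ID.get(self.question)
        if q is None:
            raise ValueError(f"unknown question id {self.question!r}")
        if self.round < q.first_round:
            raise ValueError(
                f"{self.question} is not scheduled in round {self.round} "
                f"(first appears in round {q.first_round})"
            )


@dataclass(frozen=True)
class MajoritySummary:
    """The group-level verdict players actually see."""

    group_id: str
    round: int
    question: str
    majority_answer: bool
    yes_count: int
    n: int


def questions_for_round(round: int, n_rounds: int = 10) -> list[Question]:
    """Questions scheduled for a given round (1-based)."""
    if not 1 <= round <= n_rounds:
        raise ValueError(f"round must be in 1..{n_rounds}, got {round}")
    return [q for q in QUESTIONS if q.first_round <= round]


def majority(answers: list[AnswerRecord]) -> MajoritySummary:
    """Aggregate one group's answers to one question into the majority verdict.

    Requires an odd number of answers (one per member) so a tie is
    impossible; groups consist of an odd number of players for exactly this
    reason.
    """
    if not answers:
        raise ValueError("no answers supplied")
    keys = {(a.group_id, a.round, a.question) for a in answers}
    if len(keys) != 1:
        raise ValueError(f"answers span multiple group/round/question keys: {sorted(keys)}")
    players = Counter(a.player_id for a in answers)
    if any(c > 1 for c in players.values()):
        raise ValueError("duplicate answers from a single player")
    n = len(answers)
    if n % 2 == 0:
        raise ValueError(f"even number of answers ({n}) could tie; groups must be odd-sized")
    group_id, round_, question = next(iter(keys))
    yes = sum(a.answer for a in answers)
    return MajoritySummary(group_id, round_, question, yes * 2 > n, yes, n)
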