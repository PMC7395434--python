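"""Multiple correspondence analysis of the Q1-Q4 questionnaire answers.

MCA is correspondence analysis of the one-hot indicator matrix of the
yes/no answers: the correspondence matrix (counts over grand total) is
centered by the outer product of its margins, standardized by the square
roots of the row and column masses, and decomposed by SVD.  Squared
singular values are the principal inertias; for complete binary data on Q
questions the total inertia is J/Q - 1 (= 1 for the four 2-category
questions used here).  Q5 is excluded: it appears late in the game and asks
about risk perception rather than sentiment about performance.

Rows are player-rounds by default (each between-round questionnaire is an
observation); aggregation to one modal-answer row per player is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IndicatorMatrix", "McaSolution", "build_indicator", "fit_mca", "category_map"]

MCA_QUESTIONS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class IndicatorMatrix:
    """One-hot expansion of yes/no answers, rows x 2*Q category columns."""

    data: pd.DataFrame  # 0/1 entries; columns like "Q1_yes", "Q1_no", ...
    questions: tuple[str, ...]
    aggregation: str

    @property
    def n_rows(self) -> int:
        return len(self.data)


def build_indicator(
    questionnaire: pd.DataFrame,
    aggregation: str = "player_round",
    questions: tuple[str, ...] = MCA_QUESTIONS,
) -> IndicatorMatrix:
    """Build the indicator matrix from the questionnaire table.

    ``aggregation`` is ``player_round`` (one row per player per round with
    all of Q1-Q4 answered) or ``player`` (one row per player, using the
    modal answer per question; ties resolve to "no").  Q5 and control-arm
    rows never enter; players with no Q1-Q4 answers are dropped.
    """
    if aggregation not in ("player_round", "player"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    sub = questionnaire[questionnaire["question"].isin(questions)]
    if not len(sub):
        raise ValueError("no answers to the MCA questions (control-arm input?)")
    if aggregation == "player_round":
        wide = sub.pivot_table(
            index=["player_id", "round"], columns="question", values="answer", aggfunc="first"
        )
        wide = wide.reindex(columns=questions).dropna()
    else:
        # Modal answer per player and question; exact ties break to "no".
        modal = (
            sub.groupby(["player_id", "question"])["answer"]
            .apply(lambda a: int(a.mean() > 0.5))
            .unstack()
        )
        wide = modal.reindex(columns=questions).dropna()
    if not len(wide):
        raise ValueError("no complete rows over the MCA questions")
    cols = {}
    for q in questions:
        cols[f"{q}_yes"] = (wide[q] == 1).astype(int)
        cols[f"{q}_no"] = (wide[q] == 0).astype(int)
    data = pd.DataFrame(cols, index=wide.index)
    return IndicatorMatrix(data, tuple(questions), aggregation)


@dataclass(frozen=True)
class McaSolution:
    """Principal inertias and row/column principal coordinates."""

    inertias: np.ndarray  # squared singular values, descending
    row_coords: pd.DataFrame  # rows x dims, principal coordinates
    col_coords: pd.DataFrame  # categories x dims, principal coordinates
    total_inertia: float
    row_masses: np.ndarray
    col_masses: np.ndarray
    residuals: np.ndarray  # standardized residual matrix S (for reconstruction)

    @property
    def n_dims(self) -> int:
        return len(self.inertias)


def fit_mca(indicator: IndicatorMatrix, n_dims: int | None = None) -> McaSolution:
    """Correspondence analysis of the indicator matrix.

    P = N / total; S = D_r^{-1/2} (P - r c') D_c^{-1/2}; SVD of S gives
    principal inertias (squared singular values) and principal coordinates
    (mass-scaled singular vectors times singular values).
    """
    data = indicator.data
    empty = data.columns[data.sum(axis=0) == 0]
    if len(empty):  # a category nobody picked carries no mass; drop it
        data = data.drop(columns=empty)
    N = data.to_numpy(dtype=float)
    if N.shape[0] < 2:
        raise ValueError("need at least 2 rows for MCA")
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Dr = np.sqrt(r)
    Dc = np.sqrt(c)
    S = (P - np.outer(r, c)) / np.outer(Dr, Dc)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    inertias = sv**2
    keep = n_dims if n_dims is not None else int((sv > 1e-12).sum())
    keep = min(keep, len(sv))
    dims = [f"dim{i+1}" for i in range(keep)]
    row_coords = pd.DataFrame(
        (U[:, :keep] / Dr[:, None]) * sv[:keep], index=data.index, columns=dims
    )
    col_coords = pd.DataFrame(
        (Vt[:keep].T / Dc[:, None]) * sv[:keep], index=data.columns, columns=dims
    )
    total_inertia = float((S**2).sum())
    if total_inertia < 1e-14:
        raise ValueError("all rows identical: no non-trivial inertia to decompose")
    return McaSolution(inertias[:keep], row_coords, col_coords, total_inertia, r, c, S)


def category_map(
    solution: McaSolution, labels: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category coordinates on the first two dimensions, plus type centroids.

    ``labels`` maps player_id to behavioral type (from clustering or the
    planted truth); centroids are mass-weighted mean row coordinates per
    type.  Returns ``(categories, centroids)``.
    """
    if solution.n_dims < 2:
        raise ValueError("need at least 2 MCA dimensions for the category map")
    cats = solution.col_coords[["dim1", "dim2"]].copy()
    cats["inertia_dim1"] = solution.inertias[0]
    cats["inertia_dim2"] = solution.inertias[1]
    if labels is None:
        return cats, pd.DataFrame(columns=["dim1", "dim2", "n_rows"])
    rows = solution.row_coords[["dim1", "dim2"]].copy()
    idx = rows.index
    player_ids = idx.get_level_values("player_id") if isinstance(idx, pd.MultiIndex) else idx
    rows["type"] = pd.Series(player_ids, index=idx).map(labels).to_numpy()
    if rows["type"].isna().any():
        missing = sorted(set(player_ids) - set(labels.index))
        raise ValueError(f"labels missing for players: {missing[:5]}")
    centroids = rows.groupby("type")[["dim1", "dim2"]].mean()
    centroids["n_rows"] = rows.groupby("type").size()
    return cats, centroids
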