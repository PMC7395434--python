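"""Success contingency table and the nine hierarchical log-linear models.

Group outcomes form a three-way table, arm (control/treatment) x success
(no/yes) x group size (3/7/11).  The nine hierarchical log-linear models for
a three-way table — mutual independence, the three joint-independence and
three conditional-independence models, homogeneous association, and the
saturated model — are fitted by iterative proportional fitting (IPF) to
their sufficient margins, and compared by the G-squared deviance against a
chi-squared reference.  The model of interest links success to both arm and
size while leaving arm and size conditionally independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable3",
    "LoglinearFit",
    "MODELS",
    "CONDITIONAL_INDEPENDENCE_ARM_SIZE",
    "success_table",
    "fit_loglinear",
    "fit_all",
    "select_loglinear",
]

FACTORS = ("arm", "success", "size")

def _model_id(terms: tuple[tuple[str, ...], ...]) -> str:
    return "".join("[" + ",".join(t) + "]" for t in terms)


def _hierarchy() -> dict[str, tuple[tuple[str, ...], ...]]:
    a, s, z = FACTORS
    generators = [
        ((a,), (s,), (z,)),          # mutual independence
        ((a, s), (z,)),              # joint independence of size
        ((a, z), (s,)),
        ((s, z), (a,)),
        ((a, s), (a, z)),            # conditional independence given arm
        ((a, s), (s, z)),            # conditional independence given success
        ((a, z), (s, z)),
        ((a, s), (a, z), (s, z)),    # homogeneous association
        ((a, s, z),),                # saturated
    ]
    return {_model_id(g): g for g in generators}


#: The nine hierarchical models, id -> generating class (margin tuples).
MODELS = _hierarchy()

#: Conditional independence of arm and size given success: the model with
#: arm x success and size x success interactions.
CONDITIONAL_INDEPENDENCE_ARM_SIZE = _model_id((("arm", "success"), ("success", "size")))


@dataclass(frozen=True)
class ContingencyTable3:
    """Counts indexed arm x success x size."""

    counts: np.ndarray  # shape (2, 2, n_sizes)
    arms: tuple[str, ...] = ("control", "treatment")
    successes: tuple[str, ...] = ("no", "yes")
    sizes: tuple[int, ...] = (3, 7, 11)

    def __post_init__(self) -> None:
        expected = (len(self.arms), len(self.successes), len(self.sizes))
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"arm": a, "success": s, "size": z,
             "count": int(self.counts[i, j, k])}
            for i, a in enumerate(self.arms)
            for j, s in enumerate(self.successes)
            for k, z in enumerate(self.sizes)
        ]
        return pd.DataFrame(rows)


def group_outcomes(gameplay: pd.DataFrame, n_rounds: int = 10, fair_share: int = 2) -> pd.DataFrame:
    """One row per group: arm, size, total investment, success flag.

    Rejects groups with missing player-rounds.
    """
    out = []
    for group_id, g in gameplay.groupby("group_id", sort=True):
        size = int(g["group_size"].iloc[0])
        if len(g) != size * n_rounds or set(g["round"]) != set(range(1, n_rounds + 1)):
            raise ValueError(f"group {group_id!r} has incomplete trajectories")
        total = int(g["investment"].sum())
        target = fair_share * n_rounds * size
        out.append(
            {"group_id": group_id, "arm": g["arm"].iloc[0], "size": size,
             "total": total, "success": total >= target,
             "mean_percapita": total / (size * n_rounds)}
        )
    return pd.DataFrame(out)


def success_table(gameplay: pd.DataFrame, sizes: tuple[int, ...] = (3, 7, 11)) -> ContingencyTable3:
    """Tabulate group successes into the arm x success x size table."""
    arms = ("control", "treatment")
    counts = np.zeros((2, 2, len(sizes)), dtype=int)
    if len(gameplay):
        groups = group_outcomes(gameplay)
        for _, row in groups.iterrows():
            i = arms.index(row["arm"])
            j = int(bool(row["success"]))
            k = sizes.index(int(row["size"]))
            counts[i, j, k] += 1
    return ContingencyTable3(counts, arms, ("no", "yes"), sizes)


@dataclass(frozen=True)
class LoglinearFit:
    model: str
    fitted: np.ndarray
    g2: float
    df: int
    p_value: float
    aic: float
    n_params: int
    iterations: int


def _margin(table: np.ndarray, term: tuple[str, ...]) -> np.ndarray:
    axes = tuple(i for i, f in enumerate(FACTORS) if f not in term)
    return table.sum(axis=axes, keepdims=True)


def _n_params(terms: tuple[tuple[str, ...], ...], shape: tuple[int, ...]) -> int:
    """Parameter count of the hierarchical model: sum over the closure of
    the generating class of prod(levels - 1), plus the intercept."""
    levels = dict(zip(FACTORS, shape))
    closure: set[tuple[str, ...]] = set()
    for term in terms:
        for r in range(1, len(term) + 1):
            closure.update(itertools.combinations(term, r))
    return 1 + sum(int(np.prod([levels[f] - 1 for f in u])) for u in closure)


def fit_loglinear(
    table: ContingencyTable3, model: str, tol: float = 1e-10, max_iter: int = 5000
) -> LoglinearFit:
    """Fit one hierarchical log-linear model by iterative proportional fitting.

    Fitted cell means reproduce every sufficient margin of the model to
    within ``tol``; the deviance is ``G2 = 2 sum obs * ln(obs / fitted)``
    over cells with non-zero observed counts.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    terms = MODELS[model]
    obs = table.counts.astype(float)
    observed_margins = [_margin(obs, t) for t in terms]
    fitted = np.full_like(obs, obs.sum() / obs.size)
    it = 0
    for it in range(1, max_iter + 1):
        for t, om in zip(terms, observed_margins):
            fm = _margin(fitted, t)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(fm > 0, om / np.where(fm > 0, fm, 1.0), 0.0)
            fitted = fitted * ratio
        err = max(
            np.abs(_margin(fitted, t) - om).max() for t, om in zip(terms, observed_margins)
        )
        if err <= tol:
            break
    else:
        raise RuntimeError(
            f"IPF did not converge for {model} within {max_iter} iterations "
            f"(margin error {err:.3e})"
        )
    nz = obs > 0
    g2 = float(2.0 * np.sum(obs[nz] * np.log(obs[nz] / fitted[nz])))
    g2 = max(g2, 0.0)
    n_params = _n_params(terms, obs.shape)
    df = obs.size - n_params
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    return LoglinearFit(model, fitted, g2, df, p, g2 - 2 * df, n_params, it)


def fit_all(table: ContingencyTable3) -> dict[str, LoglinearFit]:
    """Fit all nine models."""
    return {m: fit_loglinear(table, m) for m in MODELS}


def select_loglinear(fits: dict[str, LoglinearFit], alpha: float = 0.05) -> str:
    """Most parsimonious model whose deviance p-value exceeds ``alpha``.

    Parsimony means fewest parameters; the saturated model (p = 1 by
    convention) guarantees an admissible candidate always exists.
    """
    if set(fits) != set(MODELS):
        raise ValueError("fits must cover all nine models")
    admissible = [f for f in fits.values() if f.p_value > alpha]
    admissible.sort(key=lambda f: (f.n_params, f.g2))
    return admissible[0].model
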