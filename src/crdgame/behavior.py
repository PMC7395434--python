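"""Behavioral-type analyses: clustering, trends, ANOVA, choice model, Q5 test.

Players are phenotyped from their 10-round investment vectors.  The default
pipeline cuts a Ward-linkage (Euclidean) hierarchical tree at three clusters
and refines the assignment by a latent-class trajectory model — an EM fit of
a three-component mixture whose expected investment is linear in the round
with a binomial observation law on the {0,2,4} menu, i.e. the same family
that defines the behavioral types.  The refinement recovers planted types at
close to the Bayes-optimal rate, where the plain tree cut loses several
points to the overlap between neighbouring types; ``method="ward"`` gives
the unrefined cut.  Clusters are labelled by ascending mean investment —
free riders lowest, cooperators in the middle, altruists highest.  Per-type
means and round trends are estimated by OLS and compared by ANCOVA;
per-group mean investments by a two-way ANOVA (arm x size, Type II sums of
squares for the unbalanced design); round-by-round choices by a multinomial
logit with the fair share (2 units) as reference outcome; and the Q5
risk-perception excess by an exact binomial tail test against chance (1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import special, stats
from scipy.cluster import hierarchy

__all__ = [
    "TypeAssignment",
    "cluster_players",
    "type_trends",
    "mean_investment_anova",
    "multinomial_choice_model",
    "q5_binomial_test",
]

TYPE_ORDER_BY_MEAN = ("free_rider", "cooperator", "altruist")  # ascending mean


@dataclass
class TypeAssignment:
    """Result of clustering players into the three behavioral types."""

    labels: pd.Series  # player_id -> type name
    linkage: np.ndarray  # scipy linkage matrix
    features: pd.DataFrame  # player_id x round investment matrix

    @property
    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def _feature_matrix(gameplay: pd.DataFrame, n_rounds: int = 10) -> pd.DataFrame:
    wide = gameplay.pivot_table(
        index="player_id", columns="round", values="investment", aggfunc="first"
    )
    if wide.isna().any().any() or wide.shape[1] != n_rounds:
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"players with incomplete 10-round vectors: {missing[:5]}")
    return wide.sort_index()


def _latent_class_em(
    X: np.ndarray, init: np.ndarray, k: int, rounds: np.ndarray,
    max_iter: int = 200, tol: float = 1e-8,
) -> np.ndarray:
    """EM for a k-component mixture of linear-in-round binomial trajectories.

    Observation model per player-round: investment = 2 * Binomial(2, q_c(r))
    with q_c(r) = clip((a_c + b_c r) / 4, eps, 1 - eps).  The M-step fits
    (a_c, b_c) by responsibility-weighted least squares on the per-round
    means; players are finally assigned to their posterior mode.
    Deterministic given the initial hard assignment.
    """
    n = len(X)
    successes = X // 2  # of Binomial(2, q)
    centered = rounds - rounds.mean()
    denom = float((centered**2).sum())
    resp = np.zeros((n, k))
    resp[np.arange(n), init] = 1.0
    prev = -np.inf
    for _ in range(max_iter):
        weights = resp.sum(axis=0) + 1e-12
        mix = weights / n
        q = np.empty((k, len(rounds)))
        for c in range(k):
            round_means = (resp[:, c][:, None] * X).sum(axis=0) / weights[c]
            b = float((round_means - round_means.mean()) @ centered) / denom
            a = round_means.mean() - rounds.mean() * b
            q[c] = np.clip((a + b * rounds) / 4.0, 1e-4, 1.0 - 1e-4)
        loglik = np.stack(
            [stats.binom.logpmf(successes, 2, q[c]).sum(axis=1) for c in range(k)],
            axis=1,
        ) + np.log(mix)
        norm = special.logsumexp(loglik, axis=1)
        resp = np.exp(loglik - norm[:, None])
        total = float(norm.sum())
        if total - prev < tol:
            break
        prev = total
    return resp.argmax(axis=1)


def cluster_players(
    gameplay: pd.DataFrame, k: int = 3, n_rounds: int = 10, method: str = "em"
) -> TypeAssignment:
    """Cluster per-player investment vectors into behavioral types.

    A Ward-linkage (Euclidean) hierarchical tree is always built and cut at
    ``k`` clusters; with ``method="em"`` (default) the cut initializes the
    latent-class trajectory EM and players get their posterior-mode class,
    with ``method="ward"`` the plain cut is kept.  Clusters are named by
    ascending mean investment.  Label assignment is deterministic and
    invariant to player order and cluster-id permutations by construction.
    """
    if method not in ("em", "ward"):
        raise ValueError(f"unknown method {method!r}")
    features = _feature_matrix(gameplay, n_rounds)
    if len(features) < k:
        raise ValueError(f"need at least {k} players, got {len(features)}")
    X = features.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    cluster_ids = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if method == "em":
        rounds = np.asarray(sorted(features.columns), dtype=float)
        refined = _latent_class_em(X, cluster_ids - 1, k, rounds) + 1
        if len(np.unique(refined)) == k:  # keep the tree cut if EM collapsed a class
            cluster_ids = refined
    means = pd.Series(features.mean(axis=1).to_numpy()).groupby(cluster_ids).mean()
    order = means.sort_values().index  # ascending mean investment
    if k == 3:
        name_of = {cid: TYPE_ORDER_BY_MEAN[i] for i, cid in enumerate(order)}
    else:
        name_of = {cid: f"type_{i}" for i, cid in enumerate(order)}
    labels = pd.Series(
        [name_of[c] for c in cluster_ids], index=features.index, name="type"
    )
    return TypeAssignment(labels, Z, features)


def _slope_ci(sub: pd.DataFrame, alpha: float = 0.05) -> tuple[float, float, float]:
    X = sm.add_constant(sub["round"].to_numpy(dtype=float))
    fit = sm.OLS(sub["investment"].to_numpy(dtype=float), X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    z = stats.norm.ppf(1 - alpha / 2)
    return slope, slope - z * se, slope + z * se


def type_trends(
    labels: pd.Series, gameplay: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-type means, round slopes (with CIs) and the ANCOVA table.

    Returns ``(trends, ancova)``: one row per type with the population mean
    investment, its normal-approximation CI, the OLS slope of investment on
    round and its CI; and the ANCOVA F tests for type, round and their
    interaction, from a Type II decomposition of the player-round data.
    A type with fewer than 2 players has undefined CIs (NaN).
    """
    data = gameplay.merge(labels.rename("type"), left_on="player_id", right_index=True)
    if len(data) != len(gameplay):
        raise ValueError("assignment does not cover every player in the dataset")
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for t, sub in data.groupby("type"):
        inv = sub["investment"].to_numpy(dtype=float)
        n_players = sub["player_id"].nunique()
        mean = float(inv.mean())
        if n_players >= 2 and inv.std(ddof=1) > 0:
            sem = inv.std(ddof=1) / np.sqrt(len(inv))
            mean_lo, mean_hi = mean - z * sem, mean + z * sem
            slope, slo, shi = _slope_ci(sub, alpha)
        else:
            mean_lo = mean_hi = np.nan
            slope, slo, shi = _slope_ci(sub, alpha)[0], np.nan, np.nan
        rows.append(
            {"type": t, "n_players": n_players, "mean": mean,
             "mean_lo": mean_lo, "mean_hi": mean_hi,
             "slope": slope, "slope_lo": slo, "slope_hi": shi}
        )
    trends = pd.DataFrame(rows).set_index("type")

    # ANCOVA needs at least two types; with one, only the round trend is testable
    formula = "investment ~ C(type) * round" if data["type"].nunique() > 1 else "investment ~ round"
    model = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ancova = anova.rename(
        index={"C(type)": "type", "round": "round", "C(type):round": "type:round"}
    )[["sum_sq", "df", "F", "PR(>F)"]]
    return trends, ancova


def mean_investment_anova(groups: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of per-group mean per-capita investment on arm and size.

    ``groups`` needs columns arm, size, mean_percapita (one row per group;
    see :func:`crdgame.loglinear.group_outcomes`).  Uses Type II sums of
    squares, appropriate for the study's unbalanced cell counts.
    """
    cells = groups.groupby(["arm", "size"]).size()
    for arm in groups["arm"].unique():
        for size in groups["size"].unique():
            if (arm, size) not in cells.index:
                raise ValueError(f"empty design cell: arm={arm!r}, size={size}")
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 groups: {bad}")
    model = smf.ols("mean_percapita ~ C(arm) * C(size)", data=groups).fit()
    if model.ssr <= 1e-12:
        raise ValueError("zero residual variance: ANOVA degenerate on this data")
    anova = sm.stats.anova_lm(model, typ=2)
    return anova.rename(
        index={"C(arm)": "arm", "C(size)": "size", "C(arm):C(size)": "arm:size"}
    )[["sum_sq", "df", "F", "PR(>F)"]]


def multinomial_choice_model(
    gameplay: pd.DataFrame,
    covariates: tuple[str, ...] = ("round", "arm", "size"),
    reference: int = 2,
    maxiter: int = 200,
) -> pd.DataFrame:
    """Multinomial logit of the round-by-round choice among {0, 2, 4}.

    The fair share (2 units) is the reference outcome.  ``covariates`` may
    include "round" (centered at its midpoint 5.5), "arm" (treatment
    indicator) and "size" (categorical, lowest size as baseline); an empty
    tuple fits intercepts only.  Returns a tidy coefficient table with
    standard errors, per non-reference outcome.

    Raises on (quasi-)separation — an outcome category absent or perfectly
    predicted — advising a regularized refit.
    """
    choices = sorted(gameplay["investment"].unique())
    if len(choices) < 2:
        raise ValueError(
            "outcome has a single category: perfect separation; "
            "use a regularized fit or pool data"
        )
    unknown = set(covariates) - {"round", "arm", "size"}
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    levels = [reference] + [c for c in sorted({0, 2, 4}) if c != reference]
    code = {c: i for i, c in enumerate(levels)}
    y = gameplay["investment"].map(code)
    if y.isna().any():
        raise ValueError(f"investments outside {{0,2,4}}: {sorted(set(gameplay['investment']) - {0, 2, 4})}")
    X = pd.DataFrame({"const": np.ones(len(gameplay))}, index=gameplay.index)
    if "round" in covariates:
        X["round_c"] = gameplay["round"] - 5.5
    if "arm" in covariates and gameplay["arm"].nunique() > 1:
        X["treatment"] = (gameplay["arm"] == "treatment").astype(float)
    if "size" in covariates:
        for s in sorted(gameplay["group_size"].unique())[1:]:
            X[f"size_{s}"] = (gameplay["group_size"] == s).astype(float)
    model = sm.MNLogit(y.to_numpy(), X.to_numpy())
    fit = model.fit(method="newton", maxiter=maxiter, disp=False)
    grad_norm = float(np.abs(model.score(fit.params.ravel(order="F"))).max())
    if not fit.mle_retvals.get("converged", False) or grad_norm > 1e-6:
        raise RuntimeError(
            f"multinomial logit did not converge (max |gradient| {grad_norm:.2e}); "
            "possible separation — consider a regularized fit"
        )
    rows = []
    for j, outcome in enumerate(levels[1:]):
        for i, name in enumerate(X.columns):
            rows.append(
                {"outcome": outcome, "reference": reference, "term": name,
                 "coef": float(fit.params[i, j]), "se": float(fit.bse[i, j])}
            )
    return pd.DataFrame(rows)


def q5_binomial_test(yes_count: int, n: int) -> float:
    """Exact one-sided tail P(X >= yes_count) under Binomial(n, 1/2).

    Used for the end-game risk question: with a known 50% loss probability,
    chance predicts half the answers positive; an excess of yes answers is
    tested against this exact null.
    """
    if not 0 <= yes_count <= n:
        raise ValueError(f"need 0 <= yes_count <= n, got {yes_count}/{n}")
    return float(stats.binomtest(yes_count, n, 0.5, alternative="greater").pvalue)
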