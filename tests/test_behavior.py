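import itertools

import numpy as np
import pandas as pd
import pytest

from crdgame import default_design, generate_experiment
from crdgame.behavior import (
    cluster_players,
    mean_investment_anova,
    multinomial_choice_model,
    q5_binomial_test,
    type_trends,
)
from crdgame.synthetic import ExperimentDesign


def _gameplay_from_vectors(vectors, arm="control", size=3):
    rows = []
    for p, vec in enumerate(vectors):
        for r, inv in enumerate(vec, start=1):
            rows.append(
                {"session_id": "s", "arm": arm, "group_id": f"g{p // size}",
                 "group_size": size, "round": r, "player_id": f"p{p:03d}",
                 "investment": inv, "capital_after": 40 - sum(vec[:r])}
            )
    return pd.DataFrame(rows)


class TestClustering:
    def test_archetypes_recovered_perfectly(self):
        vectors = [[0] * 10] * 10 + [[2] * 10] * 10 + [[4] * 10] * 10
        gameplay = _gameplay_from_vectors(vectors)
        assignment = cluster_players(gameplay)
        labels = assignment.labels.sort_index()
        assert (labels.iloc[:10] == "free_rider").all()
        assert (labels.iloc[10:20] == "cooperator").all()
        assert (labels.iloc[20:] == "altruist").all()

    def test_three_players_form_singletons(self):
        gameplay = _gameplay_from_vectors([[0] * 10, [2] * 10, [4] * 10])
        assignment = cluster_players(gameplay)
        assert assignment.counts.tolist() == [1, 1, 1]

    def test_too_few_players_rejected(self):
        gameplay = _gameplay_from_vectors([[0] * 10, [4] * 10])
        with pytest.raises(ValueError):
            cluster_players(gameplay)

    def test_incomplete_vector_rejected(self, default_experiment):
        gameplay, _, _ = default_experiment
        clipped = gameplay.drop(gameplay.index[0])
        with pytest.raises(ValueError):
            cluster_players(clipped)

    def test_invariant_to_player_order(self, default_experiment):
        gameplay, _, _ = default_experiment
        shuffled = gameplay.sample(frac=1.0, random_state=3)
        a = cluster_players(gameplay).labels.sort_index()
        b = cluster_players(shuffled).labels.sort_index()
        assert (a == b).all()

    def test_planted_types_recovered(self, default_experiment):
        gameplay, _, types = default_experiment
        assignment = cluster_players(gameplay)
        truth = types.set_index("player_id")["type"]
        agreement = (assignment.labels == truth.loc[assignment.labels.index]).mean()
        assert agreement >= 0.8

    def test_ward_method_available(self, default_experiment):
        gameplay, _, _ = default_experiment
        assignment = cluster_players(gameplay, method="ward")
        assert set(assignment.labels.unique()) == {
            "cooperator", "free_rider", "altruist"
        }
        with pytest.raises(ValueError):
            cluster_players(gameplay, method="kmedoids")


class TestTrends:
    def test_single_type_recovery(self):
        """Players generated from cooperator parameters alone recover the
        published mean 1.96 and slope 0.080 within Monte-Carlo error."""
        design = ExperimentDesign(
            arms=(("control", 3, 60),), mixtures={"control": (1.0, 0.0, 0.0)}
        )
        gameplay, _, types = generate_experiment(design, 11)
        labels = types.set_index("player_id")["type"]
        trends, ancova = type_trends(labels, gameplay)
        row = trends.loc["cooperator"]
        inv = gameplay["investment"].to_numpy(dtype=float)
        se = inv.std(ddof=1) / np.sqrt(len(inv))
        assert row["mean"] == pytest.approx(1.96, abs=3 * se)
        assert row["slope_lo"] <= 0.080 <= row["slope_hi"]

    def test_planted_two_type_mixture(self):
        design = ExperimentDesign(
            arms=(("control", 3, 80),), mixtures={"control": (0.5, 0.5, 0.0)}
        )
        gameplay, _, types = generate_experiment(design, 21)
        labels = types.set_index("player_id")["type"]
        trends, ancova = type_trends(labels, gameplay)
        assert trends.loc["cooperator", "mean"] == pytest.approx(1.96, abs=0.08)
        assert trends.loc["free_rider", "mean"] == pytest.approx(0.77, abs=0.08)
        # behavioral type separates strongly in the ANCOVA
        assert ancova.loc["type", "F"] > 50
        assert ancova.loc["type", "PR(>F)"] < 1e-6

    def test_constant_players_flagged(self):
        gameplay = _gameplay_from_vectors([[2] * 10] * 6 + [[0] * 10] * 6)
        labels = pd.Series(
            ["cooperator"] * 6 + ["free_rider"] * 6,
            index=[f"p{p:03d}" for p in range(12)],
        )
        trends, _ = type_trends(labels, gameplay)
        assert trends.loc["cooperator", "slope"] == pytest.approx(0.0)
        assert np.isnan(trends.loc["cooperator", "mean_lo"])

    def test_assignment_must_cover_players(self, default_experiment):
        gameplay, _, _ = default_experiment
        with pytest.raises(ValueError):
            type_trends(pd.Series(dtype=object), gameplay)

    def test_ancova_matches_rss_oracle(self):
        """F statistics agree with a from-scratch nested-RSS decomposition
        on a small handmade dataset."""
        rng = np.random.default_rng(8)
        vectors = [list(2 * rng.integers(0, 3, 10)) for _ in range(5)]
        gameplay = _gameplay_from_vectors(vectors)
        labels = pd.Series(
            ["cooperator", "cooperator", "free_rider", "free_rider", "altruist"],
            index=[f"p{p:03d}" for p in range(5)],
        )
        _, ancova = type_trends(labels, gameplay)

        data = gameplay.merge(labels.rename("type"), left_on="player_id", right_index=True)
        y = data["investment"].to_numpy(dtype=float)

        def rss(cols):
            X = np.column_stack([np.ones(len(y))] + cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ beta) ** 2).sum()

        types_d = pd.get_dummies(data["type"], drop_first=True).to_numpy(dtype=float)
        r = data["round"].to_numpy(dtype=float)
        inter = types_d * r[:, None]
        rss_full = rss([types_d, r[:, None], inter])
        df_resid = len(y) - (1 + types_d.shape[1] + 1 + inter.shape[1])
        ms_resid = rss_full / df_resid
        # Type II: a term's SS comes from dropping it from the model with
        # all terms not containing it; F uses the full-model residual MS
        f_type = ((rss([r[:, None]]) - rss([types_d, r[:, None]])) / types_d.shape[1]) / ms_resid
        f_round = ((rss([types_d]) - rss([types_d, r[:, None]])) / 1) / ms_resid
        f_inter = ((rss([types_d, r[:, None]]) - rss_full) / inter.shape[1]) / ms_resid
        assert ancova.loc["type", "F"] == pytest.approx(f_type, rel=1e-6)
        assert ancova.loc["round", "F"] == pytest.approx(f_round, rel=1e-6)
        assert ancova.loc["type:round", "F"] == pytest.approx(f_inter, rel=1e-6)


class TestAnova:
    def _balanced_frame(self):
        # hand-computable 2x2 with n=2 per cell; oracle sums of squares:
        # SS_arm = SS_size = 8, SS_inter = 0.5, SS_err = 3 -> F = 10.667, 10.667, 0.667
        cells = {
            ("control", 3): [1.0, 2.0],
            ("control", 7): [2.0, 4.0],
            ("treatment", 3): [3.0, 3.0],
            ("treatment", 7): [5.0, 6.0],
        }
        rows = [
            {"arm": a, "size": s, "mean_percapita": v}
            for (a, s), vs in cells.items()
            for v in vs
        ]
        return pd.DataFrame(rows)

    def test_matches_hand_oracle(self):
        anova = mean_investment_anova(self._balanced_frame())
        assert anova.loc["arm", "F"] == pytest.approx(32 / 3, rel=1e-9)
        assert anova.loc["size", "F"] == pytest.approx(32 / 3, rel=1e-9)
        assert anova.loc["arm:size", "F"] == pytest.approx(2 / 3, rel=1e-9)

    def test_degenerate_identical_values_rejected(self):
        df = self._balanced_frame()
        df["mean_percapita"] = 2.0
        with pytest.raises(ValueError):
            mean_investment_anova(df)

    def test_empty_cell_named_in_error(self):
        df = self._balanced_frame()
        df = df[~((df["arm"] == "treatment") & (df["size"] == 7))]
        with pytest.raises(ValueError, match="treatment"):
            mean_investment_anova(df)

    def test_arm_effect_direction_on_synthetic_data(self, replicate_tables):
        """Treatment groups out-invest control groups in most replicate
        experiments, and the pooled arm gap matches the mixture means."""
        _, outcomes = replicate_tables
        gaps = []
        for o in outcomes[:50]:
            means = o.groupby("arm")["mean_percapita"].mean()
            gaps.append(means["treatment"] - means["control"])
        gaps = np.array(gaps)
        assert (gaps > 0).mean() >= 0.8
        # prosocial prevalence 0.575 vs 0.425 implies a gap of ~0.23 units
        assert np.mean(gaps) == pytest.approx(0.229, abs=0.05)


class TestMultinomialChoice:
    def test_covariate_free_closed_form(self):
        """With no covariates the MLE intercepts are the log frequency
        ratios: ln(1/4 / 1/2) for both non-reference outcomes."""
        inv = [0] * 250 + [2] * 500 + [4] * 250
        gameplay = pd.DataFrame(
            {"investment": inv, "round": 1, "arm": "control", "group_size": 3}
        )
        coefs = multinomial_choice_model(gameplay, covariates=())
        consts = coefs[coefs["term"] == "const"].set_index("outcome")["coef"]
        assert consts[0] == pytest.approx(np.log(0.25 / 0.5), abs=1e-6)
        assert consts[4] == pytest.approx(np.log(0.25 / 0.5), abs=1e-6)

    def test_parameter_recovery(self):
        """Data simulated from a known multinomial logit is recovered within
        3 standard errors."""
        rng = np.random.default_rng(4)
        n = 6000
        rounds = rng.integers(1, 11, n)
        x = rounds - 5.5
        true = {"b0": (-0.8, 0.25), "b4": (-0.5, -0.15)}  # (const, round slope)
        eta0 = true["b0"][0] + true["b0"][1] * x
        eta4 = true["b4"][0] + true["b4"][1] * x
        denom = 1 + np.exp(eta0) + np.exp(eta4)
        u = rng.random(n)
        p0 = np.exp(eta0) / denom
        p4 = np.exp(eta4) / denom
        inv = np.where(u < p0, 0, np.where(u < p0 + p4, 4, 2))
        gameplay = pd.DataFrame(
            {"investment": inv, "round": rounds, "arm": "control", "group_size": 3}
        )
        coefs = multinomial_choice_model(gameplay, covariates=("round",))
        for outcome, (c_true, s_true) in zip((0, 4), (true["b0"], true["b4"])):
            sub = coefs[coefs["outcome"] == outcome].set_index("term")
            assert abs(sub.loc["const", "coef"] - c_true) < 3 * sub.loc["const", "se"]
            assert abs(sub.loc["round_c", "coef"] - s_true) < 3 * sub.loc["round_c", "se"]

    def test_single_category_separation_error(self):
        gameplay = pd.DataFrame(
            {"investment": [2] * 50, "round": 1, "arm": "control", "group_size": 3}
        )
        with pytest.raises(ValueError, match="separation"):
            multinomial_choice_model(gameplay)

    def test_full_covariates_on_synthetic_data(self, default_experiment):
        gameplay, _, _ = default_experiment
        coefs = multinomial_choice_model(gameplay)
        terms = set(coefs["term"])
        assert {"const", "round_c", "treatment", "size_7", "size_11"} == terms
        # communication suppresses free riding: treatment lowers the odds of 0
        treat0 = coefs[(coefs["outcome"] == 0) & (coefs["term"] == "treatment")]
        assert treat0["coef"].iloc[0] < 0


class TestQ5:
    def test_all_yes_tail(self):
        assert q5_binomial_test(10, 10) == pytest.approx(0.5**10)

    def test_midpoint_included(self):
        assert q5_binomial_test(5, 10) > 0.5

    def test_reconstructed_answer_count_beats_1e6(self):
        """527 of 870 yes answers (60.6%) is far beyond chance."""
        assert q5_binomial_test(527, 870) < 1e-6

    def test_bad_input(self):
        with pytest.raises(ValueError):
            q5_binomial_test(11, 10)
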