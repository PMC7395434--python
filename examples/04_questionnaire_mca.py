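"""Geometry of the between-round communication: MCA of Q1-Q4, and Q5.

Treatment players answer up to five yes/no questions between rounds.  MCA
of the Q1-Q4 one-hot indicator matrix places answer categories and players
in a common plane; behavioral types separate along the first dimension,
with prosocial players sharing optimism (Q1-yes) and a demand for more
action (Q4-yes).  Q5 (would everything be lost on failure?) is analyzed
separately: the loss chance is a known 50%, so any excess of yes answers
measures pessimism beyond the facts.
"""

from crdgame import default_design, generate_experiment
from crdgame.behavior import q5_binomial_test
from crdgame.mca import build_indicator, category_map, fit_mca

_, questionnaire, true_types = generate_experiment(default_design(), seed=0)

indicator = build_indicator(questionnaire)
solution = fit_mca(indicator)
print(f"total inertia: {solution.total_inertia:.4f} "
      f"(identity: 8 categories / 4 questions - 1 = 1)")
print("principal inertias:", solution.inertias.round(4))

labels = true_types.set_index("player_id")["type"]
categories, centroids = category_map(solution, labels)
print("\ncategory coordinates (dim 1):")
print(categories["dim1"].round(3))
print("\ntype centroids:")
print(centroids.round(3))

q5 = questionnaire[questionnaire["question"] == "Q5"]
yes, n = int(q5["answer"].sum()), len(q5)
print(f"\nQ5: {yes}/{n} yes ({yes / n:.1%}); "
      f"exact binomial tail vs chance: {q5_binomial_test(yes, n):.2e}")
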