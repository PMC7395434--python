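"""Play one threshold public-goods game and settle the payouts.

A group of three players, each endowed with 40 capital units, invests
0/2/4 units per round over 10 rounds toward a 60-unit target (the total
reached if everyone plays the 2-unit fair share every round).
"""

import numpy as np

from crdgame.engine import GroupTrajectory, make_config, settle, surplus_series

config = make_config(3)
print(f"group of {config.group_size}: target {config.target} units over {config.n_rounds} rounds")

# A free rider (never invests), a cooperator (fair share), an altruist (maximum).
investments = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [2, 2, 2, 2, 2, 2, 2, 2, 2, 2],
        [4, 4, 4, 4, 4, 4, 4, 4, 4, 4],
    ]
)
trajectory = GroupTrajectory("demo", "control", investments, config)
print("surplus per round:", surplus_series(investments, config))
print("reached target:", trajectory.success, f"(total {trajectory.cumulative[-1]})")

payouts = settle(trajectory, config, np.random.default_rng(0))
print("payouts (¥):", payouts)
# The free rider keeps all 40 units (¥15 + ¥2*40 = ¥95); the altruist keeps
# nothing beyond the ¥15 show-up fee — the dilemma in one line.
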