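"""Characterize random play: exact success odds and significance envelopes.

Under the null model every player picks 0/2/4 uniformly each round.  The
draw is symmetric about the fair share, so random groups succeed slightly
more often than half the time.  The failure envelope is the curve that 95%
of *unsuccessful* random groups stay above: a real group dipping below it
is running a deficit too deep to blame on chance — it has given up.
"""

import numpy as np

from crdgame.engine import make_config
from crdgame.envelope import failure_envelope, flag_beyond_envelope, success_probability

for n in (3, 7, 11):
    print(f"n={n:>2}: P(random play reaches target) = {success_probability(n):.4f}")

env = failure_envelope(3, reps=100_000, level=0.95, seed=42)
print("\n95% failure envelope (surplus), group of 3:")
print(np.round(env.curve, 1))

# A group that stops investing after round 3 plunges through the envelope.
config = make_config(3)
per_round = np.array([6, 6, 6, 0, 0, 0, 0, 0, 0, 0])  # group totals
surplus = per_round.cumsum() - config.fair_share * 3 * np.arange(1, 11)
print("\nquitting group surplus:", surplus)
print("beyond-envelope rounds:", flag_beyond_envelope(surplus, env))
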