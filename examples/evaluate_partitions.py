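"""NMI and ARI on small hand-checkable partitions.

Both indices compare two labelings of the same cells through their
contingency table; 1 means identical partitions, and ARI is centred so
that random labelings score about 0 (NMI of independent partitions is 0).
"""

import numpy as np

import rggc

truth = ["A", "A", "B", "B"]

for name, detected in [
    ("identical", ["x", "x", "y", "y"]),
    ("independent", ["x", "y", "x", "y"]),
    ("one merged", ["x", "x", "x", "y"]),
    ("single cluster", ["x", "x", "x", "x"]),
]:
    print(f"{name:>15}: NMI = {rggc.nmi(truth, detected):.3f}, "
          f"ARI = {rggc.ari(truth, detected):+.3f}")

rng = np.random.default_rng(0)
t = np.repeat(np.arange(4), 25)
mean_ari = np.mean([rggc.ari(t, rng.permutation(t)) for _ in range(200)])
print(f"mean ARI over 200 random permutations: {mean_ari:+.4f} (chance level ~ 0)")
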