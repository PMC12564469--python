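"""Calibration of the Monte-Carlo permutation chi-square CI test.

Tests independent binary variables 200 times and reports the empirical
rejection rate at alpha=0.05, then shows the test detecting the
conditional dependence created by a collider.
"""

import numpy as np
import pandas as pd

import g4causal as g

rng = np.random.default_rng(0)
rejections = 0
reps = 200
for rep in range(reps):
    data = pd.DataFrame({"X": rng.integers(0, 2, 500),
                         "Y": rng.integers(0, 2, 500)})
    test = g.PermutationCITest(data, g.CITestConfig(seed=rep))
    rejections += test.p_value("X", "Y") <= 0.05
print(f"size at alpha=0.05: {rejections / reps:.3f} "
      f"(should sit near 0.05)")

# collider X -> Z <- Y: marginally independent, dependent given Z
spec = g.GroundTruthSpec(
    nodes=("X", "Y", "Z"), edges=(("X", "Z"), ("Y", "Z")),
    levels={v: ("High", "Low") for v in "XYZ"},
    cpts={"X": np.array([0.5, 0.5]), "Y": np.array([0.5, 0.5]),
          "Z": np.array([[[0.9, 0.1], [0.5, 0.5]],
                         [[0.5, 0.5], [0.1, 0.9]]])},
    strata=("s1",))
data = g.simulate_observations(spec, 4000, seed=1)
test = g.PermutationCITest(data, g.CITestConfig(seed=1))
print("p(X,Y)    =", test.p_value("X", "Y"), " -> keep independence")
print("p(X,Y|Z)  =", test.p_value("X", "Y", ["Z"]),
      " -> conditioning on the collider opens the path")
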