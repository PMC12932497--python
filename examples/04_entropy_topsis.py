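"""Entropy-weighted TOPSIS on a small hand-built decision matrix.

Four management alternatives scored on three indicators of mixed
orientation.  Entropy weighting gives dispersed indicators more weight;
TOPSIS then ranks alternatives by closeness to the ideal solution.
"""

import numpy as np

from croprank import IndicatorMatrix, closeness, evaluate

matrix = IndicatorMatrix(
    alternative_ids=("conventional", "reduced-N", "split-CRU", "extra-water"),
    indicator_names=("yield", "net_income", "emissions"),
    values=np.array([
        [8100.0, 20100.0, 830.0],
        [8000.0, 21500.0, 620.0],
        [8500.0, 24100.0, 620.0],
        [8400.0, 23100.0, 700.0],
    ]),
    orientation={"yield": "benefit", "net_income": "benefit",
                 "emissions": "cost"},
)

result, weights = evaluate(matrix)
print("entropy weights:", dict(zip(matrix.indicator_names,
                                   weights.weights.round(3))))
print(result.to_frame().round(3).to_string())
print("\nCloseness C = D-/(D+ + D-) is 1 at the ideal, 0 at the worst point.")
print("The split controlled-release strategy pairs the best income and yield")
print("with the lowest emissions, so it sits closest to the ideal solution;")
print("the conventional practice is furthest despite a competitive yield.")
print(f"\nidentity check on published distances: C(0.056, 0.132) = "
      f"{closeness(0.056, 0.132):.3f}")
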