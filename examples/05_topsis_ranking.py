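"""Rank competing predictors across several metrics with TOPSIS.

Builds a small decision matrix of evaluation measures for three
hypothetical tools and ranks them by closeness to the ideal point.
"""

import pandas as pd

from methsemble import metrics

decision = pd.DataFrame(
    {
        "sensitivity": [0.93, 0.95, 0.78],
        "specificity": [0.93, 0.85, 0.80],
        "accuracy":    [0.93, 0.90, 0.79],
        "mcc":         [0.86, 0.80, 0.58],
        "auc":         [0.96, 0.93, 0.84],
    },
    index=["tool_a", "tool_b", "tool_c"],
)

result = metrics.topsis(decision)  # equal weights, all benefit criteria
print(result.to_frame().to_string())
# The closeness score is d-/(d+ + d-): 1 means the tool sits exactly at the
# per-criterion ideal point, 0 at the anti-ideal; rank 1 is the best tool.
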