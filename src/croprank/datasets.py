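"""Small published reference tables shipped with the package.

``published_distance_table`` holds the two-year comprehensive-evaluation
distances reported for a wheat-maize rotation trial on the North China
Plain: for each treatment, irrigation system and rotation year, the
Euclidean distances D+ / D- to the positive/negative ideal solution and
the published relative closeness and rank.  It is used to check the
closeness identity C = D- / (D+ + D-) against independently published
arithmetic.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_distance_table"]

# treatment, year, system, d_plus, d_minus, closeness, rank (as published)
_ROWS = [
    ("CK1", "2022-2023", "drip", 0.129, 0.072, 0.358, 9),
    ("CK2", "2022-2023", "drip", 0.105, 0.098, 0.481, 7),
    ("T1", "2022-2023", "drip", 0.105, 0.083, 0.440, 8),
    ("T2", "2022-2023", "drip", 0.066, 0.102, 0.608, 4),
    ("T3", "2022-2023", "drip", 0.069, 0.104, 0.600, 5),
    ("T4", "2022-2023", "drip", 0.056, 0.132, 0.702, 1),
    ("T5", "2022-2023", "drip", 0.068, 0.100, 0.593, 6),
    ("T6", "2022-2023", "drip", 0.063, 0.109, 0.635, 3),
    ("T7", "2022-2023", "drip", 0.062, 0.110, 0.641, 2),
    ("CK1", "2022-2023", "sprinkler", 0.119, 0.072, 0.377, 9),
    ("CK2", "2022-2023", "sprinkler", 0.114, 0.090, 0.441, 7),
    ("T1", "2022-2023", "sprinkler", 0.103, 0.076, 0.427, 8),
    ("T2", "2022-2023", "sprinkler", 0.066, 0.095, 0.590, 6),
    ("T3", "2022-2023", "sprinkler", 0.065, 0.102, 0.611, 5),
    ("T4", "2022-2023", "sprinkler", 0.056, 0.126, 0.694, 1),
    ("T5", "2022-2023", "sprinkler", 0.060, 0.107, 0.641, 4),
    ("T6", "2022-2023", "sprinkler", 0.058, 0.113, 0.663, 3),
    ("T7", "2022-2023", "sprinkler", 0.057, 0.116, 0.671, 2),
    ("CK1", "2023-2024", "drip", 0.121, 0.078, 0.393, 9),
    ("CK2", "2023-2024", "drip", 0.105, 0.099, 0.485, 7),
    ("T1", "2023-2024", "drip", 0.106, 0.084, 0.442, 8),
    ("T2", "2023-2024", "drip", 0.068, 0.101, 0.596, 6),
    ("T3", "2023-2024", "drip", 0.065, 0.110, 0.630, 2),
    ("T4", "2023-2024", "drip", 0.061, 0.123, 0.668, 1),
    ("T5", "2023-2024", "drip", 0.066, 0.107, 0.619, 3),
    ("T6", "2023-2024", "drip", 0.066, 0.107, 0.617, 4),
    ("T7", "2023-2024", "drip", 0.067, 0.102, 0.603, 5),
    ("CK1", "2023-2024", "sprinkler", 0.121, 0.082, 0.403, 8),
    ("CK2", "2023-2024", "sprinkler", 0.110, 0.0987, 0.471, 7),
    ("T1", "2023-2024", "sprinkler", 0.109, 0.071, 0.395, 9),
    ("T2", "2023-2024", "sprinkler", 0.075, 0.092, 0.550, 6),
    ("T3", "2023-2024", "sprinkler", 0.066, 0.115, 0.637, 2),
    ("T4", "2023-2024", "sprinkler", 0.064, 0.124, 0.660, 1),
    ("T5", "2023-2024", "sprinkler", 0.069, 0.105, 0.604, 5),
    ("T6", "2023-2024", "sprinkler", 0.068, 0.109, 0.617, 3),
    ("T7", "2023-2024", "sprinkler", 0.069, 0.108, 0.609, 4),
]


def published_distance_table() -> pd.DataFrame:
    """Published per-treatment ideal-solution distances and closeness."""
    return pd.DataFrame(
        _ROWS,
        columns=["treatment", "year", "system", "d_plus", "d_minus",
                 "closeness", "rank"],
    )
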