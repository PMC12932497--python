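"""Entropy-weighted TOPSIS multi-criteria ranking.

Alternatives (management treatments) are ranked across indicators of mixed
orientation (benefit columns: larger is better; cost columns: smaller is
better).  The procedure runs in two objective stages:

1. *Entropy weighting.*  Each indicator's weight is derived from its
   information content: columns whose values are spread across
   alternatives carry information (low entropy, high weight); constant
   columns carry none (weight 0).  Entropy is computed on the column
   proportions of the oriented raw matrix, which makes the weights
   invariant to the scale of each indicator.

2. *TOPSIS.*  The oriented matrix is column-wise vector (cosine)
   normalized, weighted, and each alternative's Euclidean distances D+ and
   D- to the positive ideal (column maxima) and negative ideal (column
   minima) are measured.  The relative closeness C = D- / (D+ + D-) in
   [0, 1] ranks the alternatives (1 = best).

Cost indicators are converted to benefit orientation beforehand by
``max - x`` (default) or the reciprocal, so the ideal solution is the
column maximum for every column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorMatrix",
    "EntropyWeights",
    "TopsisResult",
    "orient_matrix",
    "entropy_weights",
    "normalize_vector",
    "topsis_rank",
    "closeness",
    "evaluate",
]

logger = logging.getLogger(__name__)

ORIENTATIONS = ("benefit", "cost")


@dataclass(frozen=True)
class IndicatorMatrix:
    """Alternatives x indicators decision matrix with per-column orientation."""

    alternative_ids: tuple[str, ...]
    indicator_names: tuple[str, ...]
    values: np.ndarray                      # shape (n alternatives, m indicators)
    orientation: Mapping[str, str]          # indicator -> "benefit" | "cost"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, m = len(self.alternative_ids), len(self.indicator_names)
        if values.shape != (n, m):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} alternatives "
                f"x {m} indicators"
            )
        if n < 2:
            raise ValueError("need at least 2 alternatives to rank")
        if m < 1:
            raise ValueError("need at least 1 indicator")
        if not np.all(np.isfinite(values)):
            bad = [self.indicator_names[j]
                   for j in np.unique(np.argwhere(~np.isfinite(values))[:, 1])]
            raise ValueError(f"non-finite values in indicator(s): {bad}")
        for name in self.indicator_names:
            o = self.orientation.get(name)
            if o not in ORIENTATIONS:
                raise ValueError(
                    f"indicator {name!r} has orientation {o!r}; expected one of "
                    f"{ORIENTATIONS}"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, orientation: Mapping[str, str]
                   ) -> "IndicatorMatrix":
        return cls(
            alternative_ids=tuple(str(i) for i in df.index),
            indicator_names=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
            orientation=dict(orientation),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.alternative_ids),
                            columns=list(self.indicator_names))


@dataclass(frozen=True)
class EntropyWeights:
    """Per-indicator information entropy, divergence and normalized weight."""

    indicator_names: tuple[str, ...]
    entropy: np.ndarray      # e_j in [0, 1]
    divergence: np.ndarray   # d_j = 1 - e_j
    weights: np.ndarray      # w_j >= 0, sum 1
    shifts: dict[str, float] = field(default_factory=dict)  # negative-column shifts

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.indicator_names), name="weight")


@dataclass(frozen=True)
class TopsisResult:
    alternative_ids: tuple[str, ...]
    indicator_names: tuple[str, ...]
    z_plus: np.ndarray      # per-indicator ideal value (weighted normalized)
    z_minus: np.ndarray     # per-indicator worst value
    d_plus: np.ndarray      # distance of each alternative to the ideal
    d_minus: np.ndarray     # distance to the worst
    closeness: np.ndarray   # C_i in [0, 1]
    rank: np.ndarray        # 1 = best; ties share the smallest rank

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d_plus": self.d_plus, "d_minus": self.d_minus,
             "closeness": self.closeness, "rank": self.rank},
            index=list(self.alternative_ids),
        )


# ---------------------------------------------------------------------------
# stages


def orient_matrix(matrix: IndicatorMatrix, cost_transform: str = "max-minus"
                  ) -> IndicatorMatrix:
    """Convert cost columns to benefit orientation.

    ``max-minus`` (default) maps x to ``max(column) - x``; ``reciprocal``
    maps x to 1/x (requires strictly positive entries).  Benefit columns
    pass through unchanged; the result is declared all-benefit.  Note the
    max-minus transform is *not* an involution on the declared-benefit
    result — reapplying it to an already oriented matrix flips the order
    back.
    """
    if cost_transform not in ("max-minus", "reciprocal"):
        raise ValueError(f"unknown cost transform {cost_transform!r}")
    values = matrix.values.copy()
    for j, name in enumerate(matrix.indicator_names):
        if matrix.orientation[name] != "cost":
            continue
        col = values[:, j]
        if cost_transform == "max-minus":
            values[:, j] = col.max() - col
        else:
            if np.any(col <= 0):
                raise ValueError(
                    f"reciprocal transform needs positive values in {name!r}"
                )
            values[:, j] = 1.0 / col
    return replace(
        matrix, values=values,
        orientation={name: "benefit" for name in matrix.indicator_names},
    )


def entropy_weights(matrix: IndicatorMatrix) -> EntropyWeights:
    """Objective indicator weights from information entropy.

    Operates on the oriented raw matrix: per column, proportions
    p_ij = x_ij / sum_i x_ij, entropy e_j = -(1/ln n) sum p ln p (with
    0 ln 0 := 0), divergence d_j = 1 - e_j, and weights w_j proportional to
    d_j.  Columns containing negatives are shifted by their minimum first
    (recorded in ``shifts``).  Constant (or all-zero) columns carry no
    information and get weight 0 with a warning; a matrix with only
    constant columns is an error.
    """
    X = matrix.values.copy()
    n, m = X.shape
    shifts: dict[str, float] = {}
    for j, name in enumerate(matrix.indicator_names):
        col_min = X[:, j].min()
        if col_min < 0:
            shifts[name] = -float(col_min)
            X[:, j] = X[:, j] - col_min
            logger.warning("indicator %r shifted by %+.6g before entropy weighting",
                           name, -col_min)

    entropy = np.empty(m)
    divergence = np.empty(m)
    for j, name in enumerate(matrix.indicator_names):
        col = X[:, j]
        total = col.sum()
        if total == 0 or np.ptp(col) == 0:
            # no variability -> maximum entropy, zero information
            if total == 0:
                logger.warning("indicator %r is all-zero; weight set to 0", name)
            entropy[j] = 1.0
            divergence[j] = 0.0
            continue
        p = col / total
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy[j] = -plogp.sum() / np.log(n)
        divergence[j] = 1.0 - entropy[j]

    if divergence.sum() <= 0:
        raise ValueError("every indicator column is constant: no information to weight")
    weights = divergence / divergence.sum()
    return EntropyWeights(matrix.indicator_names, entropy, divergence, weights, shifts)


def normalize_vector(matrix: IndicatorMatrix) -> IndicatorMatrix:
    """Column-wise vector (cosine) normalization: each column divided by its
    Euclidean norm, giving unit-norm columns."""
    norms = np.linalg.norm(matrix.values, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [matrix.indicator_names[j] for j in zero]
        raise ValueError(f"cannot vector-normalize all-zero indicator(s): {names}")
    return replace(matrix, values=matrix.values / norms)


def closeness(d_plus: float, d_minus: float) -> float:
    """Relative closeness C = D- / (D+ + D-), in [0, 1]."""
    if d_plus < 0 or d_minus < 0:
        raise ValueError("distances must be >= 0")
    if d_plus + d_minus == 0:
        raise ValueError("closeness undefined when both distances are zero")
    return d_minus / (d_plus + d_minus)


def _min_ranks(scores: np.ndarray) -> np.ndarray:
    """Descending-score ranks; exact ties share the smallest ('min') rank."""
    order = np.argsort(-scores, kind="stable")  # stable: input order breaks ties
    ranks = np.empty(len(scores), dtype=int)
    pos = 1
    for k, idx in enumerate(order):
        if k > 0 and scores[idx] == scores[order[k - 1]]:
            ranks[idx] = ranks[order[k - 1]]
        else:
            ranks[idx] = pos
        pos += 1
    return ranks


def topsis_rank(matrix: IndicatorMatrix, weights: EntropyWeights) -> TopsisResult:
    """Classic TOPSIS on an oriented, vector-normalized matrix.

    The weighted matrix v_ij = w_j z_ij is compared against the positive
    ideal Z+ (column maxima) and negative ideal Z- (column minima) by
    Euclidean distance; alternatives are ranked by descending closeness.
    """
    if tuple(weights.indicator_names) != tuple(matrix.indicator_names):
        raise ValueError("weights and matrix indicator sets differ")
    if abs(weights.weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    V = matrix.values * weights.weights
    z_plus = V.max(axis=0)
    z_minus = V.min(axis=0)
    d_plus = np.sqrt(((z_plus - V) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - z_minus) ** 2).sum(axis=1))
    if np.all(d_plus + d_minus == 0):
        raise ValueError("all alternatives identical: closeness undefined")
    c = np.array([closeness(p, m) for p, m in zip(d_plus, d_minus)])
    ranks = _min_ranks(c)
    if len(set(ranks)) != len(ranks):
        logger.warning("ties in closeness; tied alternatives share the min rank")
    return TopsisResult(matrix.alternative_ids, matrix.indicator_names,
                        z_plus, z_minus, d_plus, d_minus, c, ranks)


def evaluate(matrix: IndicatorMatrix, cost_transform: str = "reciprocal"
             ) -> tuple[TopsisResult, EntropyWeights]:
    """End-to-end entropy-weighted TOPSIS on a raw mixed-orientation matrix.

    Pipeline: orient costs to benefits -> entropy weights on the oriented
    raw matrix -> vector normalization -> weighting, ideal solutions,
    distances, closeness, ranks.  Returns the full provenance (weights with
    any shifts, ideal solutions, distances) alongside the ranking.

    The default cost transform is the reciprocal: it preserves the relative
    dispersion of a cost column, whereas ``max-minus`` maps the worst
    alternative to exactly 0 and can blow a near-constant cost column up
    into the dominant source of entropy weight and ideal-solution distance,
    letting unfertilized controls outrank every fertilized strategy on cost
    savings alone.  ``max-minus`` remains selectable.
    """
    oriented = orient_matrix(matrix, cost_transform=cost_transform)
    weights = entropy_weights(oriented)
    normalized = normalize_vector(oriented)
    result = topsis_rank(normalized, weights)
    return result, weights
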