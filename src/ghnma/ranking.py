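"""Treatment rankings from posterior draws: rank probabilities, SUCRA and
probability-best.

Within each retained draw the treatments are ordered by their basic
parameter (descending when higher values are better, ascending otherwise);
the rank-probability matrix collects, per treatment, the share of draws in
which it occupies each rank.  SUCRA (surface under the cumulative ranking
curve) compresses that matrix into a single 0-100% score per treatment:

    SUCRA_k = (1 / (K - 1)) * sum_{j=1}^{K-1} P(rank_k <= j)

so 100% means always best and 0% always worst; the mean over treatments is
exactly 0.5 for any valid matrix.  Ties between draws (measure zero for
continuous posteriors) break deterministically toward the treatment earlier
in the network's node order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import PosteriorDraws

_DIRECTIONS = {"higher": "higher", "higher-better": "higher",
               "lower": "lower", "lower-better": "lower"}


def rank_draws(draws: Union[PosteriorDraws, np.ndarray],
               direction: str = "higher") -> np.ndarray:
    """Per-draw rank assignment, shape ``(n_draws, K)``, ranks 1..K."""
    try:
        direction = _DIRECTIONS[direction]
    except KeyError:
        raise ValueError(f"unknown direction {direction!r}") from None
    d = draws.stacked_d if isinstance(draws, PosteriorDraws) else d_arr(draws)
    key = -d if direction == "higher" else d
    order = np.argsort(key, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(d.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, d.shape[1] + 1)
    return ranks


def d_arr(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ValueError("draws must be a 2-D (n_draws, K) array")
    return a


def rank_probabilities(ranks: np.ndarray) -> np.ndarray:
    """K x K matrix; entry (k, j) = P(treatment k has rank j+1)."""
    n, K = ranks.shape
    probs = np.empty((K, K))
    for j in range(K):
        probs[:, j] = (ranks == j + 1).mean(axis=0)
    return probs


def sucra(rank_probs: np.ndarray) -> np.ndarray:
    """SUCRA score per treatment, in [0, 1]."""
    rank_probs = np.asarray(rank_probs, dtype=float)
    K = rank_probs.shape[0]
    if K < 2:
        raise ValueError("SUCRA needs at least 2 treatments")
    cum = np.cumsum(rank_probs, axis=1)[:, : K - 1]
    return cum.sum(axis=1) / (K - 1)


def probability_best(rank_probs: np.ndarray) -> np.ndarray:
    """Probability of rank 1 per treatment (first column of the matrix)."""
    return np.asarray(rank_probs, dtype=float)[:, 0]


@dataclass
class RankingResult:
    """Rank-probability matrix with its SUCRA and probability-best vectors."""

    treatments: tuple[str, ...]
    direction: str
    rank_probs: np.ndarray
    sucra: np.ndarray
    p_best: np.ndarray
    outcome: Optional[str] = None

    @classmethod
    def from_draws(cls, draws: PosteriorDraws, direction: str = "higher",
                   outcome: Optional[str] = None) -> "RankingResult":
        ranks = rank_draws(draws, direction)
        probs = rank_probabilities(ranks)
        return cls(
            treatments=draws.treatments,
            direction=_DIRECTIONS[direction],
            rank_probs=probs,
            sucra=sucra(probs),
            p_best=probability_best(probs),
            outcome=outcome,
        )

    @property
    def expected_rank(self) -> np.ndarray:
        K = len(self.treatments)
        return self.rank_probs @ np.arange(1, K + 1)

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: one row per treatment, SUCRA on the 0-100% scale
        (stored at full precision; display rounds to whole percent)."""
        return pd.DataFrame({
            "treatment": self.treatments,
            "p_best": self.p_best,
            "sucra": self.sucra,
            "sucra_percent": np.round(self.sucra * 100.0),
            "expected_rank": self.expected_rank,
        }).sort_values("sucra", ascending=False, ignore_index=True)
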