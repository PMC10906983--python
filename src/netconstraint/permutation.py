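"""Random-draw null for the network position of a focal gene set.

Whether an adaptation-associated gene set sits where it does by chance
is tested by comparing the set's mean topology/constraint values against
draws of equally many genes taken uniformly, without replacement, from
all analysis-graph nodes with non-missing metrics.  Empirical p-values
use the add-one estimator (1 + #extreme) / (n_draws + 1), which can
never be zero; the two-sided p doubles the smaller tail, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["NullResult", "random_draw_null"]

DEFAULT_METRICS = ("aspl", "bc", "nc", "mean_phylop")


@dataclass
class NullResult:
    metric: str
    observed: float              # mean over the focal set
    null_means: np.ndarray       # one mean per random draw
    empirical_p: float
    tail: str

    def to_dict(self, include_draws: bool = False) -> dict:
        d = {
            "metric": self.metric,
            "observed": self.observed,
            "n_draws": int(len(self.null_means)),
            "empirical_p": self.empirical_p,
            "tail": self.tail,
            "null_mean": float(np.mean(self.null_means)),
            "null_sd": float(np.std(self.null_means, ddof=1)),
        }
        if include_draws:
            d["null_means"] = self.null_means.tolist()
        return d


def _empirical_p(observed: float, null: np.ndarray, tail: str) -> float:
    n = len(null)
    p_greater = (1 + int(np.sum(null >= observed))) / (n + 1)
    p_less = (1 + int(np.sum(null <= observed))) / (n + 1)
    if tail == "greater":
        return p_greater
    if tail == "less":
        return p_less
    if tail == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown tail {tail!r}")


def random_draw_null(
    table: pd.DataFrame,
    focal: list[str],
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    n_draws: int = 1000,
    tail: str = "two-sided",
    seed: int = 0,
) -> dict[str, NullResult]:
    """Empirical null for the focal set's mean metric values.

    ``table`` is the per-node metrics (+ attributes) table; the sampling
    frame is its complete-case rows for the requested metrics, with the
    focal genes included in the frame.  Each draw samples ``len(focal)``
    nodes uniformly without replacement; the test statistic is the mean.
    """
    metrics = tuple(m for m in metrics if m in table.columns)
    frame = table[list(metrics)].dropna()
    focal = list(focal)
    missing = [g for g in focal if g not in frame.index]
    if missing:
        raise ValueError(f"focal genes absent from the sampling frame: {missing}")
    if len(focal) < 2:
        raise ValueError("focal set needs >= 2 genes")
    if len(focal) > len(frame):
        raise ValueError("focal set larger than the sampling frame")
    logger.info("null frame: %d nodes, focal %d, %d draws, tail=%s",
                len(frame), len(focal), n_draws, tail)

    rng = np.random.default_rng(seed)
    values = frame.to_numpy(dtype=float)
    k = len(focal)
    draws = np.empty((n_draws, len(metrics)))
    for i in range(n_draws):
        idx = rng.choice(len(frame), size=k, replace=False)
        draws[i] = values[idx].mean(axis=0)

    observed = frame.loc[focal].mean(axis=0)
    out = {}
    for j, m in enumerate(metrics):
        obs = float(observed.iloc[j])
        out[m] = NullResult(
            metric=m, observed=obs, null_means=draws[:, j].copy(),
            empirical_p=_empirical_p(obs, draws[:, j], tail), tail=tail)
    return out
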