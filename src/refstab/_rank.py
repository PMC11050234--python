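"""Ranking primitives shared by the stability methods and the consensus.

Ordinal ranking breaks ties deterministically by position in the
canonical (input) gene order: of two genes with equal stability, the one
that appears earlier receives the lower (better) rank.  Dense ranking
lets tied genes share a rank, matching how per-method rank columns are
commonly printed.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _as_series(values: "pd.Series | Mapping[str, float]") -> pd.Series:
    if isinstance(values, pd.Series):
        return values
    return pd.Series(dict(values))


def ordinal_ranks(values: "pd.Series | Mapping[str, float]") -> pd.Series:
    """Ordinal ranks 1..k, ascending by value, ties broken by input order.

    The result is always a permutation of ``1..k``.
    """
    s = _as_series(values).astype(float)
    if s.isna().any():
        raise ValueError("cannot rank missing values")
    order = np.lexsort((np.arange(len(s)), s.to_numpy()))
    ranks = np.empty(len(s), dtype=int)
    ranks[order] = np.arange(1, len(s) + 1)
    return pd.Series(ranks, index=s.index, name="rank")


def dense_ranks(values: "pd.Series | Mapping[str, float]") -> pd.Series:
    """Dense ranks: tied values share one rank, next distinct value gets
    the next integer."""
    s = _as_series(values).astype(float)
    return pd.Series(
        rankdata(s.to_numpy(), method="dense").astype(int), index=s.index, name="rank"
    )


def geometric_mean_rank(ranks: Iterable[float]) -> float:
    """Geometric mean of per-method ranks, the consensus score.

    All ranks must be >= 1, so the result lies in ``[1, k]``.
    """
    r = np.asarray(list(ranks), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one rank")
    if (r < 1).any():
        raise ValueError("ranks must be >= 1")
    return float(math.exp(np.mean(np.log(r))))
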