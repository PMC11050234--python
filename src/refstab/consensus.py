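"""Comprehensive (RefFinder-style) rank consensus across the four methods.

Each stability method produces a per-gene value on its own scale, so the
consensus works on *ranks*: every method's values are converted to
ordinal ranks 1..k (ascending stability, ties broken by canonical input
order), the geometric mean of a gene's four ranks is its comprehensive
value, and the final ranking is ascending by that value.  The number of
genes recommended defaults to geNorm's optimal reference count.

Dense ranks (tied genes sharing a rank) are reported alongside because
per-method rank columns are conventionally printed that way; the
comprehensive value itself always uses ordinal ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from ._rank import dense_ranks, geometric_mean_rank, ordinal_ranks
from .ct import CtMatrix, CtValidationError, StabilityTable
from .stability import (
    DEFAULT_M_THRESHOLD,
    DEFAULT_V_THRESHOLD,
    BestKeeper,
    DeltaCtStability,
    GeNorm,
    GenormResult,
    NormFinder,
)

__all__ = [
    "RankConsensus",
    "ReferenceGeneConsensus",
    "ordinal_ranks",
    "dense_ranks",
    "geometric_mean_rank",
    "consensus",
]

METHODS = ("delta_ct", "genorm", "normfinder", "bestkeeper")


@dataclass(frozen=True)
class RankConsensus:
    """Comprehensive ranking of candidate reference genes.

    ``table`` is indexed by gene in canonical order, with per-method
    ``<method>_stability`` / ``<method>_rank`` (ordinal) /
    ``<method>_rank_dense`` columns followed by ``comprehensive_value``
    (geometric mean of the four ordinal ranks) and ``comprehensive_rank``.
    """

    table: pd.DataFrame
    recommended: list[str]
    optimal_n: int
    optimal_n_found: bool
    genorm: GenormResult

    @property
    def comprehensive_value(self) -> pd.Series:
        return self.table["comprehensive_value"]

    @property
    def comprehensive_rank(self) -> pd.Series:
        return self.table["comprehensive_rank"]

    def ranking(self) -> list[str]:
        """Genes from most to least stable by comprehensive rank."""
        return list(self.table.sort_values("comprehensive_rank").index)


def method_ordinal_ranks(stability: StabilityTable | pd.Series) -> pd.Series:
    """Ordinal ranks of one method's stability values (canonical tie rule)."""
    values = stability.stability if isinstance(stability, StabilityTable) else stability
    return ordinal_ranks(values)


class ReferenceGeneConsensus(BaseEstimator):
    """Estimator running all four stability methods and aggregating ranks.

    Parameters
    ----------
    efficiency_base
        Amplification base for geNorm's relative quantities.
    use_groups
        Run NormFinder in grouped mode (group labels from ``y`` or the
        CtMatrix).
    n_recommend
        Number of genes to recommend; None uses geNorm's optimal
        reference count.
    m_threshold, v_threshold
        geNorm decision thresholds.
    """

    def __init__(
        self,
        efficiency_base: float = 2.0,
        use_groups: bool = False,
        n_recommend: int | None = None,
        m_threshold: float = DEFAULT_M_THRESHOLD,
        v_threshold: float = DEFAULT_V_THRESHOLD,
    ):
        self.efficiency_base = efficiency_base
        self.use_groups = use_groups
        self.n_recommend = n_recommend
        self.m_threshold = m_threshold
        self.v_threshold = v_threshold

    def fit(self, X, y=None):
        delta = DeltaCtStability().fit(X, y)
        if delta.n_features_in_ < 3:
            raise CtValidationError("consensus needs at least 3 genes")
        gn = GeNorm(
            efficiency_base=self.efficiency_base,
            m_threshold=self.m_threshold,
            v_threshold=self.v_threshold,
        ).fit(X, y)
        nf = NormFinder(use_groups=self.use_groups).fit(X, y)
        bk = BestKeeper().fit(X, y)

        genes = pd.Index(delta.genes_, name="gene")
        tables = {
            "delta_ct": delta.to_table(),
            "genorm": gn.to_table(),
            "normfinder": nf.to_table(),
            "bestkeeper": bk.to_table(),
        }
        cols: dict[str, pd.Series] = {}
        rank_frame = pd.DataFrame(index=genes)
        for name in METHODS:
            stab = tables[name].stability
            cols[f"{name}_stability"] = stab
            rank_frame[name] = ordinal_ranks(stab)
            cols[f"{name}_rank"] = rank_frame[name]
            cols[f"{name}_rank_dense"] = dense_ranks(stab)

        geo = rank_frame.apply(lambda row: geometric_mean_rank(row), axis=1)
        cols["comprehensive_value"] = geo
        cols["comprehensive_rank"] = ordinal_ranks(geo)
        table = pd.DataFrame(cols, index=genes)

        pv = gn.pairwise_variation_
        optimal_n, found = pv.optimal_n, pv.cutoff_met
        n_rec = self.n_recommend if self.n_recommend is not None else optimal_n
        order = list(table.sort_values("comprehensive_rank").index)

        self.genes_ = delta.genes_
        self.method_tables_ = tables
        self.table_ = table
        self.optimal_n_ = optimal_n
        self.optimal_n_found_ = found
        self.recommended_ = order[:n_rec]
        self.genorm_result_ = gn.result()
        self.ranking_ = table["comprehensive_rank"].to_numpy()
        self.stability_ = geo.to_numpy()
        return self

    def result(self) -> RankConsensus:
        return RankConsensus(
            table=self.table_,
            recommended=list(self.recommended_),
            optimal_n=self.optimal_n_,
            optimal_n_found=self.optimal_n_found_,
            genorm=self.genorm_result_,
        )


def consensus(
    m: CtMatrix,
    efficiency_base: float = 2.0,
    use_groups: bool = False,
    n_recommend: int | None = None,
    m_threshold: float = DEFAULT_M_THRESHOLD,
    v_threshold: float = DEFAULT_V_THRESHOLD,
) -> RankConsensus:
    """Run the four methods on ``m`` and aggregate their ordinal ranks."""
    est = ReferenceGeneConsensus(
        efficiency_base=efficiency_base,
        use_groups=use_groups,
        n_recommend=n_recommend,
        m_threshold=m_threshold,
        v_threshold=v_threshold,
    ).fit(m)
    return est.result()
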