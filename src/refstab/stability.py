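"""Per-method reference-gene stability algorithms.

Four classical RT-qPCR stability measures are implemented, each as a
scikit-learn style estimator plus a thin functional wrapper:

* **comparative ΔCt** (:class:`DeltaCtStability`) — a gene's stability is
  the mean, over all other genes, of the sample standard deviation of the
  pairwise Ct difference.
* **geNorm** (:class:`GeNorm`) — average pairwise variation M of log2
  expression ratios, with iterative exclusion of the least stable gene
  and the pairwise-variation series V_n/n+1 that decides how many
  reference genes are needed.
* **NormFinder** (:class:`NormFinder`) — model-based variance
  decomposition of Ct values into gene, sample, and (optionally) group
  effects; the stability value combines intragroup variance and shrunken
  intergroup bias.
* **BestKeeper** (:class:`BestKeeper`) — descriptive dispersion of raw
  Ct per gene: SD (mean absolute deviation by default) and CV.

Estimators accept a :class:`~refstab.ct.CtMatrix`, a samples x genes
DataFrame, or a samples x genes array, and expose ``stability_``,
``ranking_`` and ``genes_`` after ``fit``.  In all methods a *lower*
stability value means a *more stable* gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator

from ._rank import ordinal_ranks
from .ct import MIN_SAMPLES, CtMatrix, CtValidationError, StabilityTable

__all__ = [
    "DeltaCtStability",
    "GeNorm",
    "NormFinder",
    "BestKeeper",
    "RelativeQuantities",
    "GenormResult",
    "PairwiseVariationSeries",
    "NormFinderResult",
    "BestKeeperResult",
    "relative_quantities",
    "delta_ct_stability",
    "genorm",
    "optimal_reference_count",
    "normfinder",
    "bestkeeper",
]

DEFAULT_M_THRESHOLD = 1.5
DEFAULT_V_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelativeQuantities:
    """Relative quantities q = base^-(Ct - per-gene min Ct), genes x samples.

    Each gene's most abundant sample (lowest Ct) maps to q = 1 exactly.
    """

    q: pd.DataFrame
    base: float


@dataclass(frozen=True)
class PairwiseVariationSeries:
    """geNorm pairwise variation V_n/n+1 and the derived reference count.

    ``v`` maps n (2..k-1) to the SD of log2 ratios of normalization
    factors built from the n and n+1 most stable genes.  ``optimal_n`` is
    the smallest n with V < ``v_threshold``; when no n qualifies it
    equals the total gene count and ``cutoff_met`` is False.
    """

    v: dict[int, float]
    v_threshold: float
    optimal_n: int
    cutoff_met: bool


@dataclass(frozen=True)
class GenormResult:
    stability: pd.Series  # per gene, M at its exclusion step
    rank: pd.Series  # 1 = most stable, ordinal
    initial_m: pd.Series  # M over the full gene set
    exclusion_order: list[str]  # first entry = least stable (removed first)
    final_pair: tuple[str, str]
    pairwise_variation: PairwiseVariationSeries | None
    m_threshold: float
    unsuitable: list[str]  # genes with stability M > m_threshold

    def to_table(self) -> StabilityTable:
        frame = pd.DataFrame({"stability": self.stability, "rank": self.rank})
        return StabilityTable("genorm", frame)


@dataclass(frozen=True)
class NormFinderResult:
    stability: pd.Series  # SV per gene
    rank: pd.Series
    grouped: bool
    #: per-group components when grouped: DataFrames indexed by gene with
    #: columns sigma2 (intragroup variance), d_hat (intergroup deviation)
    #: and d_tilde (its shrunken value); None in ungrouped mode.
    components: dict[str, pd.DataFrame] | None = None

    def to_table(self) -> StabilityTable:
        frame = pd.DataFrame({"stability": self.stability, "rank": self.rank})
        return StabilityTable("normfinder", frame)


@dataclass(frozen=True)
class BestKeeperResult:
    #: per-gene descriptives: n, mean_ct, geo_mean_ct, min_ct, max_ct, sd, cv
    summary: pd.DataFrame
    rank: pd.Series  # ascending by SD
    sd_method: str

    @property
    def stability(self) -> pd.Series:
        return self.summary["sd"].rename("stability")

    def to_table(self) -> StabilityTable:
        frame = pd.DataFrame({"stability": self.stability, "rank": self.rank})
        return StabilityTable("bestkeeper", frame)


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------


def _coerce_ct(X, y=None) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Return (ct genes x samples, gene names, group labels or None).

    ``X`` may be a CtMatrix (genes x samples), or a samples x genes
    DataFrame/array following the scikit-learn convention.  ``y``
    overrides any group labels carried by a CtMatrix.
    """
    groups = None
    if isinstance(X, CtMatrix):
        ct = X.values
        genes = np.asarray(X.genes, dtype=object)
        g = X.groups()
        if g is not None:
            groups = g.to_numpy()
    elif isinstance(X, pd.DataFrame):
        ct = X.to_numpy(dtype=float).T
        genes = np.asarray([str(c) for c in X.columns], dtype=object)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise CtValidationError("expected a 2-D samples x genes array")
        ct = arr.T
        genes = np.asarray([f"gene{i + 1}" for i in range(ct.shape[0])], dtype=object)
    if y is not None:
        groups = np.asarray(list(y), dtype=object)
        if groups.shape[0] != ct.shape[1]:
            raise CtValidationError(
                f"got {groups.shape[0]} group labels for {ct.shape[1]} samples"
            )
    if not np.isfinite(ct).all():
        raise CtValidationError("Ct values must be finite")
    if ct.shape[0] < 2:
        raise CtValidationError("need at least 2 genes")
    if ct.shape[1] < MIN_SAMPLES:
        raise CtValidationError(f"need at least {MIN_SAMPLES} samples")
    return ct, genes, groups


# ---------------------------------------------------------------------------
# numeric cores (genes x samples arrays)
# ---------------------------------------------------------------------------


def _relative_quantities(ct: np.ndarray, base: float) -> np.ndarray:
    return np.power(base, -(ct - ct.min(axis=1, keepdims=True)))


def _pairwise_sd_matrix(values: np.ndarray) -> np.ndarray:
    """V[i, j] = sample SD (n-1 denominator) of values[i] - values[j]."""
    k = values.shape[0]
    V = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sd = float(np.std(values[i] - values[j], ddof=1))
            V[i, j] = V[j, i] = sd
    return V


def _delta_ct_core(ct: np.ndarray) -> np.ndarray:
    V = _pairwise_sd_matrix(ct)
    k = ct.shape[0]
    return V.sum(axis=1) / (k - 1)


def _mean_m(V: np.ndarray, active: list[int]) -> np.ndarray:
    sub = V[np.ix_(active, active)]
    return sub.sum(axis=1) / (len(active) - 1)


def _genorm_core(
    ct: np.ndarray, base: float
) -> tuple[np.ndarray, np.ndarray, list[int], tuple[int, int], np.ndarray | None]:
    """Return (M at exclusion, initial M, removal order, final pair, V series).

    The removal order lists gene indices from first removed (least
    stable) onward; a mid-iteration tie on the maximum M removes the
    gene later in canonical input order.
    """
    k, n = ct.shape
    logq = np.log2(_relative_quantities(ct, base))
    V = _pairwise_sd_matrix(logq)

    initial_m = _mean_m(V, list(range(k)))
    m_at_exclusion = np.empty(k)
    active = list(range(k))
    removal: list[int] = []
    while len(active) > 2:
        M = _mean_m(V, active)
        worst_value = M.max()
        # ties: drop the gene with the larger canonical index
        worst_pos = max(p for p in range(len(active)) if M[p] == worst_value)
        gene = active[worst_pos]
        m_at_exclusion[gene] = worst_value
        removal.append(gene)
        active.remove(gene)
    i, j = active
    m_at_exclusion[i] = m_at_exclusion[j] = V[i, j]
    final_pair = (i, j)

    v_series = None
    if k >= 3:
        # stability ranking: final pair first (canonical order), then the
        # removed genes from last removed to first removed
        ranking = [min(i, j), max(i, j)] + removal[::-1]
        lognf = [
            np.mean(logq[ranking[:n_top]], axis=0) for n_top in range(2, k + 1)
        ]
        v_series = np.array(
            [
                float(np.std(lognf[t] - lognf[t + 1], ddof=1))
                for t in range(len(lognf) - 1)
            ]
        )
    return m_at_exclusion, initial_m, removal, final_pair, v_series


def _two_way_residual_variances(ct: np.ndarray) -> np.ndarray:
    """u_i = sum_j r_ij^2 / (n-1) for two-way centered residuals."""
    n = ct.shape[1]
    r = (
        ct
        - ct.mean(axis=1, keepdims=True)
        - ct.mean(axis=0, keepdims=True)
        + ct.mean()
    )
    return (r**2).sum(axis=1) / (n - 1)


def _normfinder_sigma2(ct: np.ndarray) -> np.ndarray:
    """Per-gene variance estimates, clipped at zero, on the Ct scale."""
    k = ct.shape[0]
    if k < 3:
        raise CtValidationError("NormFinder needs at least 3 genes")
    u = _two_way_residual_variances(ct)
    sigma2 = (k / (k - 2)) * (u - u.sum() / (k * (k - 1)))
    return np.clip(sigma2, 0.0, None)


def _normfinder_ungrouped(ct: np.ndarray) -> np.ndarray:
    return np.sqrt(_normfinder_sigma2(ct))


def _normfinder_grouped(
    ct: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (SV, sigma2[g, i], d_hat[g, i], d_tilde[g, i])."""
    k = ct.shape[0]
    if k < 3:
        raise CtValidationError("NormFinder needs at least 3 genes")
    G = len(group_idx)
    if G < 2:
        raise CtValidationError("grouped NormFinder needs at least 2 groups")
    for idx in group_idx:
        if idx.size < 2:
            raise CtValidationError(
                "grouped NormFinder needs at least 2 samples per group"
            )
    grand = ct.mean()
    gene_mean = ct.mean(axis=1)

    sigma2 = np.empty((G, k))
    d_hat = np.empty((G, k))
    d_tilde = np.empty((G, k))
    sv_terms = np.empty((G, k))
    for g, idx in enumerate(group_idx):
        sub = ct[:, idx]
        n_g = idx.size
        sigma2[g] = _normfinder_sigma2(sub)
        group_gene_mean = sub.mean(axis=1)
        group_mean = sub.mean()
        d_hat[g] = (group_gene_mean - gene_mean) - (group_mean - grand)
        gamma2 = max(
            0.0, (d_hat[g] ** 2).sum() / (k - 1) - sigma2[g].mean() / n_g
        )
        denom = gamma2 + sigma2[g] / n_g
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
            spread = np.where(
                denom > 0,
                np.sqrt(gamma2 * (sigma2[g] / n_g) / np.where(denom > 0, denom, 1.0)),
                0.0,
            )
        d_tilde[g] = d_hat[g] * shrink
        sv_terms[g] = np.abs(d_tilde[g]) + spread
    sv = sv_terms.mean(axis=0)
    return sv, sigma2, d_hat, d_tilde


def _bestkeeper_core(ct: np.ndarray, sd_method: str) -> dict[str, np.ndarray]:
    mean_ct = ct.mean(axis=1)
    if sd_method == "mad":
        sd = np.abs(ct - mean_ct[:, None]).mean(axis=1)
    elif sd_method == "std":
        sd = ct.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown sd_method {sd_method!r} (expected 'mad' or 'std')")
    if (ct <= 0).any():
        raise CtValidationError("BestKeeper needs positive Ct values")
    return {
        "n": np.full(ct.shape[0], ct.shape[1]),
        "mean_ct": mean_ct,
        "geo_mean_ct": gmean(ct, axis=1),
        "min_ct": ct.min(axis=1),
        "max_ct": ct.max(axis=1),
        "sd": sd,
        "cv": 100.0 * sd / mean_ct,
    }


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _CtStabilityEstimator(BaseEstimator):
    """Shared fit plumbing: input coercion and rank bookkeeping."""

    def _finish(self, genes: np.ndarray, stability: np.ndarray) -> None:
        self.genes_ = genes
        self.stability_ = np.asarray(stability, dtype=float)
        series = pd.Series(self.stability_, index=genes)
        self.ranking_ = ordinal_ranks(series).to_numpy()
        self.n_features_in_ = len(genes)

    def to_table(self) -> StabilityTable:
        frame = pd.DataFrame(
            {"stability": self.stability_, "rank": self.ranking_},
            index=pd.Index(self.genes_, name="gene"),
        )
        return StabilityTable(self._method_name, frame)


class DeltaCtStability(_CtStabilityEstimator):
    """Comparative ΔCt stability.

    For gene *i*, stability is the mean over all other genes *j* of the
    sample standard deviation of ``Ct_i - Ct_j``.  A stable gene keeps a
    constant offset to every other candidate, so its pairwise SDs — and
    hence its stability — are small.
    """

    _method_name = "delta_ct"

    def fit(self, X, y=None):
        ct, genes, _ = _coerce_ct(X, y)
        self._finish(genes, _delta_ct_core(ct))
        return self


class GeNorm(_CtStabilityEstimator):
    """geNorm expression-stability M with iterative exclusion.

    Parameters
    ----------
    efficiency_base
        Amplification base used to turn Ct into relative quantities
        (2 = perfect doubling per cycle).
    m_threshold
        Genes whose M exceeds this are flagged unsuitable (default 1.5).
    v_threshold
        Pairwise-variation cutoff for the optimal number of reference
        genes (default 0.15).
    report
        ``"exclusion"`` (default) reports each gene's M at the step it
        was excluded, so the final pair shares one M; ``"initial"``
        reports M over the full gene set.
    """

    _method_name = "genorm"

    def __init__(
        self,
        efficiency_base: float = 2.0,
        m_threshold: float = DEFAULT_M_THRESHOLD,
        v_threshold: float = DEFAULT_V_THRESHOLD,
        report: str = "exclusion",
    ):
        self.efficiency_base = efficiency_base
        self.m_threshold = m_threshold
        self.v_threshold = v_threshold
        self.report = report

    def fit(self, X, y=None):
        if self.efficiency_base <= 1:
            raise ValueError("efficiency_base must be > 1")
        if self.report not in ("exclusion", "initial"):
            raise ValueError("report must be 'exclusion' or 'initial'")
        ct, genes, _ = _coerce_ct(X, y)
        k = ct.shape[0]
        m_excl, m_init, removal, final_pair, v_series = _genorm_core(
            ct, self.efficiency_base
        )
        stability = m_init if self.report == "initial" else m_excl

        self.initial_m_ = m_init
        self.m_at_exclusion_ = m_excl
        self.exclusion_order_ = [genes[i] for i in removal]
        self.final_pair_ = (genes[final_pair[0]], genes[final_pair[1]])
        if v_series is not None:
            v = {n_top: float(v_series[n_top - 2]) for n_top in range(2, k)}
            below = [n_top for n_top, value in v.items() if value < self.v_threshold]
            if below:
                self.pairwise_variation_ = PairwiseVariationSeries(
                    v, self.v_threshold, min(below), True
                )
            else:
                self.pairwise_variation_ = PairwiseVariationSeries(
                    v, self.v_threshold, k, False
                )
        else:
            self.pairwise_variation_ = None
        self.unsuitable_ = [g for g, m in zip(genes, stability) if m > self.m_threshold]
        self._finish(genes, stability)
        return self

    def result(self) -> GenormResult:
        genes = pd.Index(self.genes_, name="gene")
        return GenormResult(
            stability=pd.Series(self.stability_, index=genes, name="stability"),
            rank=pd.Series(self.ranking_, index=genes, name="rank"),
            initial_m=pd.Series(self.initial_m_, index=genes, name="initial_m"),
            exclusion_order=list(self.exclusion_order_),
            final_pair=self.final_pair_,
            pairwise_variation=self.pairwise_variation_,
            m_threshold=self.m_threshold,
            unsuitable=list(self.unsuitable_),
        )


class NormFinder(_CtStabilityEstimator):
    """NormFinder variance-decomposition stability.

    Works directly on the Ct scale (already log-linear in template).
    Ungrouped mode estimates a per-gene variance from two-way centered
    residuals; grouped mode (group labels passed as ``y`` or carried by
    the CtMatrix) adds a shrunken intergroup bias term per group.
    """

    _method_name = "normfinder"

    def __init__(self, use_groups: bool = False):
        self.use_groups = use_groups

    def fit(self, X, y=None):
        ct, genes, groups = _coerce_ct(X, y)
        if self.use_groups:
            if groups is None:
                raise CtValidationError(
                    "use_groups=True but no group labels available"
                )
            labels = list(dict.fromkeys(groups))
            group_idx = [np.flatnonzero(groups == lab) for lab in labels]
            sv, sigma2, d_hat, d_tilde = _normfinder_grouped(ct, group_idx)
            self.group_labels_ = labels
            self.components_ = {
                lab: pd.DataFrame(
                    {
                        "sigma2": sigma2[g],
                        "d_hat": d_hat[g],
                        "d_tilde": d_tilde[g],
                    },
                    index=pd.Index(genes, name="gene"),
                )
                for g, lab in enumerate(labels)
            }
        else:
            sv = _normfinder_ungrouped(ct)
            self.group_labels_ = None
            self.components_ = None
        self._finish(genes, sv)
        return self

    def result(self) -> NormFinderResult:
        genes = pd.Index(self.genes_, name="gene")
        return NormFinderResult(
            stability=pd.Series(self.stability_, index=genes, name="stability"),
            rank=pd.Series(self.ranking_, index=genes, name="rank"),
            grouped=self.use_groups,
            components=self.components_,
        )


class BestKeeper(_CtStabilityEstimator):
    """BestKeeper descriptive stability: per-gene SD and CV of raw Ct.

    ``sd_method="mad"`` (default) is the mean absolute deviation from
    the arithmetic mean, the original tool's convention; ``"std"``
    switches to the n-1 standard deviation.  CV is 100·SD/mean.  Ranking
    is ascending by SD.
    """

    _method_name = "bestkeeper"

    def __init__(self, sd_method: str = "mad"):
        self.sd_method = sd_method

    def fit(self, X, y=None):
        ct, genes, _ = _coerce_ct(X, y)
        cols = _bestkeeper_core(ct, self.sd_method)
        self.summary_ = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        self._finish(genes, cols["sd"])
        return self

    def result(self) -> BestKeeperResult:
        return BestKeeperResult(
            summary=self.summary_,
            rank=pd.Series(
                self.ranking_, index=pd.Index(self.genes_, name="gene"), name="rank"
            ),
            sd_method=self.sd_method,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def relative_quantities(
    m: CtMatrix, efficiency_base: float = 2.0
) -> RelativeQuantities:
    """Per-gene relative quantities q = base^-(Ct - min Ct over samples)."""
    if efficiency_base <= 1:
        raise ValueError("efficiency_base must be > 1")
    q = np.power(
        efficiency_base, -(m.ct.sub(m.ct.min(axis=1), axis=0))
    )
    return RelativeQuantities(q=q, base=efficiency_base)


def delta_ct_stability(m: CtMatrix) -> StabilityTable:
    """Comparative ΔCt stability table (see :class:`DeltaCtStability`)."""
    return DeltaCtStability().fit(m).to_table()


def genorm(
    m: CtMatrix,
    efficiency_base: float = 2.0,
    m_threshold: float = DEFAULT_M_THRESHOLD,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    report: str = "exclusion",
) -> GenormResult:
    """Run geNorm and return the full result (see :class:`GeNorm`)."""
    est = GeNorm(
        efficiency_base=efficiency_base,
        m_threshold=m_threshold,
        v_threshold=v_threshold,
        report=report,
    ).fit(m)
    return est.result()


def optimal_reference_count(
    g: GenormResult | PairwiseVariationSeries,
) -> tuple[int, bool]:
    """Smallest n with V_n/n+1 below the cutoff, plus a found flag.

    Returns ``(k, False)`` when no n satisfies the cutoff, where k is the
    total number of candidate genes.
    """
    pv = g.pairwise_variation if isinstance(g, GenormResult) else g
    if pv is None:
        raise CtValidationError("no pairwise-variation series available (k < 3)")
    return pv.optimal_n, pv.cutoff_met


def normfinder(m: CtMatrix, use_groups: bool = False) -> NormFinderResult:
    """Run NormFinder and return the result (see :class:`NormFinder`)."""
    return NormFinder(use_groups=use_groups).fit(m).result()


def bestkeeper(m: CtMatrix, sd_method: str = "mad") -> BestKeeperResult:
    """Run BestKeeper and return the result (see :class:`BestKeeper`)."""
    return BestKeeper(sd_method=sd_method).fit(m).result()
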