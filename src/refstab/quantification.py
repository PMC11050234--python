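"""Standard-curve amplification efficiency and 2^-ΔΔCt relative expression.

The efficiency of a primer pair is estimated from a template dilution
series: Ct regressed on log10(relative amount) gives a slope, and

    E = (10^(-1/slope) - 1) × 100 %

so a perfect doubling per cycle (slope -3.3219) gives E = 100 %.

Relative expression of a target gene uses the ΔΔCt method: the target Ct
is normalized per sample against the arithmetic mean Ct of the reference
genes (equivalently, the log2 of the geometric mean of their relative
quantities), referenced to the mean ΔCt of a calibrator group, and
converted to fold change rq = 2^-ΔΔCt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct import CtMatrix, CtValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DilutionSeries",
    "EfficiencyFit",
    "RelativeExpression",
    "fit_efficiency",
    "delta_delta_ct",
    "read_dilution_csv",
    "write_dilution_csv",
]


class QuantificationError(ValueError):
    """Invalid input to an efficiency or expression computation."""


@dataclass(frozen=True)
class DilutionSeries:
    """Standard-curve points: relative template amount and measured Ct.

    Amounts are relative (most concentrated point conventionally 1);
    technical replicates appear as repeated amounts.  At least three
    distinct amounts are required for a meaningful fit.
    """

    amount: np.ndarray
    ct: np.ndarray

    def __post_init__(self) -> None:
        amount = np.asarray(self.amount, dtype=float)
        ct = np.asarray(self.ct, dtype=float)
        if amount.shape != ct.shape or amount.ndim != 1:
            raise QuantificationError("amount and ct must be 1-D and equal length")
        if not (np.isfinite(amount).all() and np.isfinite(ct).all()):
            raise QuantificationError("amounts and Ct values must be finite")
        if (amount <= 0).any():
            raise QuantificationError("template amounts must be > 0")
        if np.unique(amount).size < 3:
            raise QuantificationError("need at least 3 distinct template amounts")
        object.__setattr__(self, "amount", amount)
        object.__setattr__(self, "ct", ct)

    def __len__(self) -> int:
        return self.amount.size


@dataclass(frozen=True)
class EfficiencyFit:
    """OLS standard-curve fit and the derived efficiency percentage."""

    slope: float  # cycles per log10 unit of template
    intercept: float  # Ct at relative amount 1
    e_percent: float  # (10^(-1/slope) - 1) * 100
    r_squared: float


@dataclass(frozen=True)
class RelativeExpression:
    """Per-sample and per-group 2^-ΔΔCt results for one target gene.

    ``per_sample`` columns: group, ct_target, ref_signal, delta_ct,
    delta_delta_ct, rq.  ``summary`` is indexed by group with columns
    mean_rq, sd_rq, n (SD uses the n-1 denominator; ``summary_on``
    records whether statistics were taken over per-sample rq or over
    ΔΔCt then exponentiated).
    """

    target: str
    references: tuple[str, ...]
    calibrator: str
    per_sample: pd.DataFrame
    summary: pd.DataFrame
    summary_on: str = "rq"


def fit_efficiency(
    d: DilutionSeries,
    *,
    warn_e_range: tuple[float, float] = (90.0, 110.0),
    warn_r2_min: float = 0.90,
) -> EfficiencyFit:
    """Fit Ct = slope·log10(amount) + intercept and derive E%.

    Replicate measurements enter as individual points.  Values of E
    outside ``warn_e_range`` or R² below ``warn_r2_min`` are logged as
    warnings, not errors — reaction chemistry, not arithmetic, decides
    what is acceptable.
    """
    x = np.log10(d.amount)
    fit = stats.linregress(x, d.ct)
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise QuantificationError("standard-curve slope is zero; E undefined")
    e_percent = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    r_squared = float(fit.rvalue**2)
    if not (warn_e_range[0] <= e_percent <= warn_e_range[1]):
        logger.warning(
            "amplification efficiency %.2f%% outside the usual %s band",
            e_percent,
            warn_e_range,
        )
    if r_squared < warn_r2_min:
        logger.warning("standard-curve R² = %.3f below %.2f", r_squared, warn_r2_min)
    return EfficiencyFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        e_percent=float(e_percent),
        r_squared=r_squared,
    )


def delta_delta_ct(
    m: CtMatrix,
    target: str,
    references: Sequence[str],
    calibrator: str,
    *,
    summary_on: str = "rq",
) -> RelativeExpression:
    """2^-ΔΔCt fold change of ``target`` normalized to ``references``.

    ``calibrator`` is a group label; ΔΔCt subtracts the mean ΔCt over the
    calibrator samples, so the calibrator group averages to fold change 1
    on the ΔΔCt scale.  With several references the per-sample reference
    signal is their arithmetic mean Ct, i.e. the geometric mean of their
    relative quantities.
    """
    references = tuple(references)
    if not references:
        raise QuantificationError("reference gene list is empty")
    if target in references:
        raise QuantificationError("target gene cannot be one of its references")
    for gene in (target, *references):
        if gene not in m.ct.index:
            raise QuantificationError(f"gene {gene!r} not in matrix")
    groups = m.groups()
    if groups is None:
        raise QuantificationError("ΔΔCt needs sample group labels")
    if calibrator not in set(groups):
        raise QuantificationError(f"unknown calibrator group {calibrator!r}")
    if summary_on not in ("rq", "ddct"):
        raise QuantificationError("summary_on must be 'rq' or 'ddct'")

    ct_target = m.ct.loc[target]
    ref_signal = m.ct.loc[list(references)].mean(axis=0)
    delta_ct = ct_target - ref_signal
    calibrator_mean = delta_ct[groups == calibrator].mean()
    ddct = delta_ct - calibrator_mean
    rq = np.power(2.0, -ddct)

    per_sample = pd.DataFrame(
        {
            "group": groups,
            "ct_target": ct_target,
            "ref_signal": ref_signal,
            "delta_ct": delta_ct,
            "delta_delta_ct": ddct,
            "rq": rq,
        }
    )
    per_sample.index.name = "sample"

    rows = []
    for label in dict.fromkeys(groups):
        sub = per_sample[per_sample["group"] == label]
        if summary_on == "rq":
            mean_rq = float(sub["rq"].mean())
            sd_rq = float(sub["rq"].std(ddof=1)) if len(sub) > 1 else 0.0
        else:  # statistics on the ΔΔCt (log) scale, then exponentiate the mean
            mean_rq = float(np.power(2.0, -sub["delta_delta_ct"].mean()))
            sd_rq = (
                float(sub["delta_delta_ct"].std(ddof=1)) if len(sub) > 1 else 0.0
            )
        rows.append(
            {"group": label, "mean_rq": mean_rq, "sd_rq": sd_rq, "n": len(sub)}
        )
    summary = pd.DataFrame(rows).set_index("group")

    return RelativeExpression(
        target=target,
        references=references,
        calibrator=calibrator,
        per_sample=per_sample,
        summary=summary,
        summary_on=summary_on,
    )


def read_dilution_csv(path: str | Path, *, delimiter: str = ",") -> DilutionSeries:
    """Read a dilution series CSV with columns ``amount`` and ``ct``."""
    path = Path(path)
    if not path.exists():
        raise QuantificationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, comment="#")
    for col in ("amount", "ct"):
        if col not in df.columns:
            raise QuantificationError(f"dilution series requires column {col!r}")
    return DilutionSeries(df["amount"].to_numpy(float), df["ct"].to_numpy(float))


def write_dilution_csv(
    d: DilutionSeries, path: str | Path, *, delimiter: str = ","
) -> None:
    pd.DataFrame({"amount": d.amount, "ct": d.ct}).to_csv(
        path, sep=delimiter, index=False
    )
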