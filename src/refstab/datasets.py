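"""Worked-example data: published per-method stability values.

A published RT-qPCR reference-gene evaluation of the leaf beetle
*Diorhabda rybakowi* scored ten candidate genes with the four stability
methods under two experimental conditions (among tissues, and between
sexes), then aggregated them by the geometric mean of per-method ranks.
The per-method stability values and the printed comprehensive values are
reproduced here as a worked example for the consensus step: feeding the
stability columns through :func:`refstab.consensus.ordinal_ranks` and
:func:`refstab.consensus.geometric_mean_rank` reproduces the printed
comprehensive values for every gene not involved in a geNorm tie.

Units are method-specific: cycles for ΔCt, dimensionless M for geNorm,
cycles-scale SV for NormFinder, cycles (SD) for BestKeeper.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "published_stability",
    "published_comprehensive",
    "GENES",
    "CONDITIONS",
]

GENES = (
    "ACT",
    "TUB",
    "RPS18",
    "GST",
    "SYN6",
    "GAPDH",
    "EF1a",
    "RPL13a",
    "RPL19",
    "RPL15",
)

CONDITIONS = ("tissue", "sex")

_STABILITY = {
    "tissue": {
        "delta_ct": (2.600, 1.320, 1.030, 1.600, 1.090, 1.440, 2.040, 1.120, 1.130, 1.200),
        "genorm": (1.455, 0.827, 0.394, 0.685, 0.527, 0.947, 1.168, 0.285, 0.356, 0.285),
        "normfinder": (2.457, 0.755, 0.125, 1.347, 0.047, 0.834, 1.816, 0.659, 0.583, 0.815),
        "bestkeeper": (2.140, 1.074, 0.388, 0.422, 0.732, 0.879, 1.783, 0.163, 0.381, 0.412),
    },
    "sex": {
        "delta_ct": (0.560, 0.790, 0.610, 0.650, 0.880, 0.840, 0.620, 0.680, 0.540, 0.570),
        "genorm": (0.331, 0.623, 0.199, 0.199, 0.674, 0.403, 0.489, 0.557, 0.279, 0.308),
        "normfinder": (0.249, 0.710, 0.445, 0.495, 0.802, 0.775, 0.346, 0.507, 0.169, 0.322),
        "bestkeeper": (0.926, 1.696, 0.797, 0.849, 1.670, 0.539, 1.376, 1.540, 1.079, 0.905),
    },
}

_COMPREHENSIVE = {
    "tissue": (10.000, 6.400, 2.210, 6.620, 2.780, 7.240, 9.000, 1.860, 2.910, 3.310),
    "sex": (3.160, 8.710, 2.510, 3.220, 9.740, 4.700, 5.600, 7.480, 2.060, 3.460),
}

#: genes whose printed comprehensive value is consistent with a purely
#: ordinal reading of the per-method ranks (no geNorm tie involvement)
ORDINAL_CONSISTENT = {
    "tissue": ("ACT", "TUB", "RPS18", "GST", "SYN6", "GAPDH", "EF1a", "RPL13a", "RPL19"),
    "sex": ("ACT", "TUB", "RPS18", "SYN6", "GAPDH", "EF1a", "RPL13a", "RPL19", "RPL15"),
}


def published_stability(condition: str) -> pd.DataFrame:
    """Per-method stability values for one condition (genes x methods)."""
    if condition not in _STABILITY:
        raise KeyError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    return pd.DataFrame(
        _STABILITY[condition], index=pd.Index(GENES, name="gene")
    )


def published_comprehensive(condition: str) -> pd.Series:
    """Printed comprehensive (geometric-mean-rank) values for one condition."""
    if condition not in _COMPREHENSIVE:
        raise KeyError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    return pd.Series(
        _COMPREHENSIVE[condition],
        index=pd.Index(GENES, name="gene"),
        name="comprehensive_value",
    )
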