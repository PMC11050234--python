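"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit Python loops and the standard
library (plus math) so it shares no code path with the package: these
are the oracles the package's vectorized implementations are checked
against.
"""

from __future__ import annotations

import itertools
import math
import statistics


def sd(values) -> float:
    """Sample standard deviation, n-1 denominator."""
    return statistics.stdev(values)


def brute_delta_ct(ct: dict[str, list[float]]) -> dict[str, float]:
    genes = list(ct)
    out = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            diffs = [a - b for a, b in zip(ct[g], ct[h])]
            sds.append(sd(diffs))
        out[g] = sum(sds) / len(sds)
    return out


def _log2_q(ct: dict[str, list[float]], base: float) -> dict[str, list[float]]:
    out = {}
    for g, row in ct.items():
        lo = min(row)
        out[g] = [-(c - lo) * math.log2(base) for c in row]
    return out


def brute_genorm_initial_m(
    ct: dict[str, list[float]], base: float = 2.0
) -> dict[str, float]:
    logq = _log2_q(ct, base)
    genes = list(ct)
    out = {}
    for g in genes:
        vs = []
        for h in genes:
            if h == g:
                continue
            ratios = [a - b for a, b in zip(logq[g], logq[h])]
            vs.append(sd(ratios))
        out[g] = sum(vs) / len(vs)
    return out


def brute_genorm_v_series(
    ct: dict[str, list[float]], ranking: list[str], base: float = 2.0
) -> dict[int, float]:
    """V_n/n+1 given a stability ranking (most stable first)."""
    logq = _log2_q(ct, base)
    n_samples = len(next(iter(ct.values())))
    k = len(ct)

    def log_nf(n_top: int) -> list[float]:
        top = ranking[:n_top]
        return [
            sum(logq[g][j] for g in top) / n_top for j in range(n_samples)
        ]

    out = {}
    for n_top in range(2, k):
        diffs = [a - b for a, b in zip(log_nf(n_top), log_nf(n_top + 1))]
        out[n_top] = sd(diffs)
    return out


def brute_normfinder_ungrouped(ct: dict[str, list[float]]) -> dict[str, float]:
    genes = list(ct)
    k = len(genes)
    n = len(ct[genes[0]])
    grand = sum(sum(row) for row in ct.values()) / (k * n)
    gene_mean = {g: sum(ct[g]) / n for g in genes}
    sample_mean = [sum(ct[g][j] for g in genes) / k for j in range(n)]
    u = {}
    for g in genes:
        ss = 0.0
        for j in range(n):
            r = ct[g][j] - gene_mean[g] - sample_mean[j] + grand
            ss += r * r
        u[g] = ss / (n - 1)
    total_u = sum(u.values())
    out = {}
    for g in genes:
        sigma2 = (k / (k - 2)) * (u[g] - total_u / (k * (k - 1)))
        out[g] = math.sqrt(max(sigma2, 0.0))
    return out


def brute_normfinder_grouped(
    ct: dict[str, list[float]], groups: list[str]
) -> dict[str, float]:
    genes = list(ct)
    k = len(genes)
    n = len(groups)
    labels = list(dict.fromkeys(groups))
    grand = sum(sum(row) for row in ct.values()) / (k * n)
    gene_mean = {g: sum(ct[g]) / n for g in genes}

    def sigma2_within(cols: list[int]) -> dict[str, float]:
        sub = {g: [ct[g][j] for j in cols] for g in genes}
        out = {}
        sv = brute_normfinder_ungrouped(sub)
        for g in genes:
            out[g] = sv[g] ** 2
        return out

    sv_terms = {g: [] for g in genes}
    for lab in labels:
        cols = [j for j, x in enumerate(groups) if x == lab]
        n_g = len(cols)
        s2 = sigma2_within(cols)
        group_mean = sum(ct[g][j] for g in genes for j in cols) / (k * n_g)
        d_hat = {}
        for g in genes:
            gg_mean = sum(ct[g][j] for j in cols) / n_g
            d_hat[g] = (gg_mean - gene_mean[g]) - (group_mean - grand)
        gamma2 = max(
            0.0,
            sum(d * d for d in d_hat.values()) / (k - 1)
            - sum(s2.values()) / k / n_g,
        )
        for g in genes:
            denom = gamma2 + s2[g] / n_g
            if denom > 0:
                d_tilde = d_hat[g] * gamma2 / denom
                spread = math.sqrt(gamma2 * (s2[g] / n_g) / denom)
            else:
                d_tilde = 0.0
                spread = 0.0
            sv_terms[g].append(abs(d_tilde) + spread)
    return {g: sum(t) / len(t) for g, t in sv_terms.items()}


def brute_geometric_mean(values) -> float:
    prod = 1.0
    vals = list(values)
    for v in vals:
        prod *= v
    return prod ** (1.0 / len(vals))


def brute_motif_matches(
    seq: str, gaps: list[tuple[int, int]], strict: bool = False
) -> list[tuple[int, ...]]:
    """All cysteine subsets satisfying the gap windows (1-based positions)."""
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    size = len(gaps) + 1
    hits = []
    for combo in itertools.combinations(cys, size):
        ok = True
        for (lo, hi), p1, p2 in zip(gaps, combo, combo[1:]):
            gap = p2 - p1 - 1
            if not lo <= gap <= hi:
                ok = False
                break
            if strict and "C" in seq[p1 + 1 : p2]:
                ok = False
                break
        if ok:
            hits.append(tuple(p + 1 for p in combo))
    return hits
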