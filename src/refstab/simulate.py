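"""Seeded generators for Ct matrices, dilution series, and motif sequences.

The Ct generator draws from an additive model on the cycle scale,

    Ct[i, j] = B_i + s_j + delta[i, g(j)] + eps[i, j]

with per-gene baselines ``B_i ~ Uniform(b_lo, b_hi)``, per-sample
loading offsets ``s_j ~ Normal(0, loading_sd)`` (shared RNA input /
pipetting variation, which cancels in ratio-based statistics), condition
shifts ``delta`` for designed-unstable genes, and replicate noise
``eps ~ Normal(0, sigma_i)``.  The known ground-truth instability of a
gene combines its condition-shift variance and noise variance on the
cycles² scale:

    score_i = sqrt(Var_g(delta[i, g]) + sigma_i²)

which is the scale the ΔCt/geNorm/NormFinder statistics operate on, so
method rankings are directly comparable to the truth.

All generators are deterministic given a seed: one SeedSequence is
spawned into independent sub-streams (baselines, sample offsets, one per
gene), so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ct import CtMatrix
from .motifs import AMINO_ACIDS, CysPattern
from .quantification import DilutionSeries

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "two_condition_preset",
    "preset",
    "simulate_ct",
    "simulate_dilution",
    "simulate_motif_sequence",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic Ct study design.

    ``group_effects`` has shape (k, G): the condition shift of gene i in
    group g, in cycles (all-zero rows are designed-stable genes).
    ``noise_sd`` has length k, in cycles.
    """

    gene_names: tuple[str, ...]
    group_names: tuple[str, ...]
    n_per_group: int
    noise_sd: tuple[float, ...]
    group_effects: tuple[tuple[float, ...], ...]
    baseline_range: tuple[float, float] = (18.0, 30.0)
    loading_sd: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        k, G = len(self.gene_names), len(self.group_names)
        if k < 2 or G < 1 or self.n_per_group < 1:
            raise ValueError("need >= 2 genes, >= 1 group, >= 1 sample per group")
        if len(self.noise_sd) != k:
            raise ValueError("noise_sd must have one entry per gene")
        if any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd entries must be > 0")
        effects = tuple(tuple(map(float, row)) for row in self.group_effects)
        if len(effects) != k or any(len(row) != G for row in effects):
            raise ValueError("group_effects must be shaped (genes, groups)")
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be >= 0")
        lo, hi = self.baseline_range
        if not lo < hi:
            raise ValueError("baseline_range must be (low, high) with low < high")
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "group_names", tuple(self.group_names))
        object.__setattr__(self, "noise_sd", tuple(map(float, self.noise_sd)))
        object.__setattr__(self, "group_effects", effects)

    @property
    def k(self) -> int:
        return len(self.gene_names)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)


@dataclass(frozen=True)
class GroundTruth:
    """Known instability per gene: score (cycles) and ordinal true rank."""

    table: pd.DataFrame  # columns: score, rank, designed_stable

    @property
    def score(self) -> pd.Series:
        return self.table["score"]

    @property
    def rank(self) -> pd.Series:
        return self.table["rank"]

    @property
    def stable_genes(self) -> list[str]:
        return list(self.table.index[self.table["designed_stable"]])


def two_condition_preset(
    seed: int = 42, n_per_group: int = 9
) -> SimulationSpec:
    """Default benchmark: 10 candidate genes, 2 conditions, 9 samples each.

    Two designed-stable genes (sigma = 0.1 cycles, no condition shift)
    sit among eight unstable candidates whose noise SDs and condition
    shifts range up to 2.0 cycles, mirroring the dispersion span commonly
    seen across candidate reference genes in insect RT-qPCR panels.  The
    third-most-stable candidate is a condition-responsive gene (tight
    replicate noise but a 0.7-cycle shift between conditions) — the
    classic trap a stability screen must catch.  Condition shifts are
    balanced in sign (some genes up-, some down-regulated), as real
    condition-responsive panels are; a one-sided design would let the
    shifted genes shadow each other in pairwise statistics.  By design
    two reference genes suffice here: the expected pairwise variation
    V_2/3 of the stable pair against the top three is about 0.11, under
    the conventional 0.15 cutoff.
    """
    genes = tuple(f"cand{i + 1:02d}" for i in range(10))
    noise = (0.1, 0.1, 0.1, 0.8, 0.5, 1.0, 0.7, 1.4, 1.3, 2.0)
    shift = (0.0, 0.0, 0.6, 0.0, -1.6, 0.0, 2.0, 0.0, -2.0, 0.0)
    effects = tuple((0.0, s) for s in shift)
    return SimulationSpec(
        gene_names=genes,
        group_names=("group1", "group2"),
        n_per_group=n_per_group,
        noise_sd=noise,
        group_effects=effects,
        seed=seed,
    )


def preset(name: str, seed: int = 42) -> SimulationSpec:
    """Named study designs.

    ``"default"`` is the two-condition benchmark; ``"tissue"`` mirrors a
    six-tissue × three-replicate design and ``"sex"`` a two-group ×
    three-replicate design.
    """
    if name == "default":
        return two_condition_preset(seed=seed)
    if name == "tissue":
        base = two_condition_preset(seed=seed, n_per_group=3)
        groups = ("antenna", "head", "thorax", "abdomen", "leg", "wing")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        effects = []
        for row in base.group_effects:
            spread = abs(row[1])
            eff = rng.normal(0.0, spread / 2.0, size=len(groups)) if spread else (
                np.zeros(len(groups))
            )
            effects.append(tuple(eff))
        return replace(
            base, group_names=groups, group_effects=tuple(effects), n_per_group=3
        )
    if name == "sex":
        return replace(
            two_condition_preset(seed=seed, n_per_group=3),
            group_names=("female", "male"),
        )
    raise ValueError(f"unknown preset {name!r}")


def _truth(spec: SimulationSpec) -> GroundTruth:
    effects = np.asarray(spec.group_effects)
    noise = np.asarray(spec.noise_sd)
    score = np.sqrt(effects.var(axis=1) + noise**2)
    order = np.lexsort((np.arange(spec.k), score))
    rank = np.empty(spec.k, dtype=int)
    rank[order] = np.arange(1, spec.k + 1)
    designed = (effects == 0).all(axis=1) & (noise == noise.min())
    table = pd.DataFrame(
        {"score": score, "rank": rank, "designed_stable": designed},
        index=pd.Index(spec.gene_names, name="gene"),
    )
    return GroundTruth(table)


def simulate_ct(spec: SimulationSpec) -> tuple[CtMatrix, GroundTruth]:
    """Draw a Ct matrix from ``spec`` together with its ground truth."""
    k, G, n_g = spec.k, spec.n_groups, spec.n_per_group
    n = G * n_g
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(2 + k)
    rng_base = np.random.default_rng(streams[0])
    rng_load = np.random.default_rng(streams[1])

    baseline = rng_base.uniform(*spec.baseline_range, size=k)
    loading = rng_load.normal(0.0, spec.loading_sd, size=n)
    effects = np.asarray(spec.group_effects)

    sample_names: list[str] = []
    sample_group: list[int] = []
    group_of: dict[str, str] = {}
    replicate_of: dict[str, str] = {}
    for g, gname in enumerate(spec.group_names):
        for r in range(n_g):
            name = f"{gname}_r{r + 1}"
            sample_names.append(name)
            sample_group.append(g)
            group_of[name] = gname
            replicate_of[name] = str(r + 1)
    sample_group_arr = np.asarray(sample_group)

    ct = np.empty((k, n))
    for i in range(k):
        rng_gene = np.random.default_rng(streams[2 + i])
        eps = rng_gene.normal(0.0, spec.noise_sd[i], size=n)
        ct[i] = baseline[i] + loading + effects[i, sample_group_arr] + eps

    matrix = CtMatrix(
        pd.DataFrame(ct, index=list(spec.gene_names), columns=sample_names),
        group_of=group_of,
        replicate_of=replicate_of,
    )
    return matrix, _truth(spec)


def simulate_dilution(
    true_base: float = 2.0,
    ct_at_1: float = 20.0,
    steps: int = 5,
    fold: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    replicates: int = 1,
) -> DilutionSeries:
    """Dilution series with a known true amplification base.

    Amounts are ``fold``-fold dilutions starting at 1; the noiseless Ct
    at amount x is ``ct_at_1 - log(x)/log(true_base)``, so fitting the
    series recovers E = (true_base - 1) × 100 %.  ``replicates``
    technical replicates per dilution point are drawn independently, as
    standard curves are conventionally run in duplicate wells.
    """
    if true_base <= 1:
        raise ValueError("true_base must be > 1")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if steps < 3:
        raise ValueError("need at least 3 dilution points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    amount = np.repeat(fold ** -np.arange(steps, dtype=float), replicates)
    ct = ct_at_1 - np.log(amount) / np.log(true_base)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, noise_sd, size=ct.size)
    return DilutionSeries(amount, ct)


def simulate_motif_sequence(
    pattern: CysPattern, flank: int = 10, seed: int | None = None
) -> str:
    """Sequence with exactly one planted occurrence of ``pattern``.

    Flanks and gap fillers are drawn from the 19 non-cysteine residues,
    so the planted conserved cysteines are the only cysteines and the
    pattern matches exactly once (also under the strict no-Cys-in-gap
    mode).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS.replace("C", "")))

    def filler(length: int) -> str:
        return "".join(rng.choice(letters, size=length))

    parts = [filler(flank), "C"]
    for lo, hi in pattern.gaps:
        parts.append(filler(int(rng.integers(lo, hi + 1))))
        parts.append("C")
    parts.append(filler(flank))
    return "".join(parts)
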