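# Methods

This note records the statistical definitions the package implements,
the numerical and design choices made where conventions diverge, what
the synthetic benchmark does and does not emulate, and the known
limitations.

## Data model

A `CtMatrix` is a complete genes × samples table of quantification
cycles with optional per-sample condition labels and replicate ids.
Completeness is enforced at load: a missing Ct cell is an error unless
imputation is explicitly requested, in which case the cell is filled
with the mean Ct of that gene within the sample's condition group and
the imputation is logged. Silent imputation is avoided because every
stability statistic below is a dispersion estimate that an invented
value would bias directly.

Technical replicates (rows sharing gene and sample but not replicate
id) are collapsed to their arithmetic mean Ct at load. This mirrors
standard qPCR practice of averaging duplicate wells before analysis; no
method here models within-well error separately.

Gene and sample order is first occurrence in the input, and that
canonical order is the tie-break everywhere: of two genes with equal
stability, the earlier one gets the better ordinal rank, and a geNorm
exclusion tie removes the later one. This makes every ranking
deterministic and reproducible.

## Stability methods

All four methods read *lower = more stable*. Sample standard deviations
use the n−1 denominator throughout, except BestKeeper's SD (below).

**Comparative ΔCt.** stability_i = mean_{j≠i} SD(Ct_i − Ct_j). No free
parameters.

**geNorm.** Relative quantities q = E^−(Ct − min Ct) per gene, with the
amplification base E a parameter (default 2; a single global base is
used — per-gene efficiency correction inside stability statistics is
out of scope). V_jk = SD(log2 q_j / q_k); M_j averages V_jk over the
current gene set; the highest-M gene is removed until two remain, which
share their mutual V as a common M. Because per-gene minima and
per-sample loading shift all log ratios by constants, M is invariant to
both (asserted by test), and with E = 2 the initial M is *identical* to
the comparative ΔCt statistic — a cross-method identity the test suite
checks to 1e−12. By default a gene's reported stability is its M at the
step it was excluded (so the final pair shares one value, the pattern
published consensus tables show); `report="initial"` switches to
full-set M. Normalization factors NF_n are per-sample geometric means
of the n top-ranked genes' q; V_n/n+1 = SD(log2 NF_n/NF_n+1) for
n = 2..k−1, and the optimal reference count is the smallest n with
V strictly below the 0.15 cutoff (returned as k with a flag when no n
qualifies). M > 1.5 flags a gene unsuitable. Both thresholds are
parameters; 1.5 and 0.15 are the conventional defaults.

**NormFinder.** Operates directly on the Ct scale, which is already
log-linear in template amount; all statistics used are sign-symmetric,
so no orientation flip is applied. Ungrouped: with two-way centered
residuals r_ij = y_ij − ȳ_i· − ȳ·j + ȳ··, u_i = Σ_j r_ij²/(n−1), the
variance estimate is σ̂²_i = (k/(k−2))·[u_i − Σ_l u_l/(k(k−1))], clipped
at zero, and SV_i = √σ̂²_i. The k/(k−2) factor is why at least three
genes are required. Grouped: σ̂²_ig is the same estimator within group
g; the intergroup deviation d̂_ig = (ȳ_ig − ȳ_i·) − (ȳ·g − ȳ··) is
shrunk by the empirical-Bayes factor γ̂²_g/(γ̂²_g + σ̂²_ig/n_g), with
γ̂²_g = max(0, Σ_i d̂²_ig/(k−1) − mean_i σ̂²_ig/n_g), and
SV_i = mean_g(|d̃_ig| + √(γ̂²_g(σ̂²_ig/n_g)/(γ̂²_g + σ̂²_ig/n_g))).
Numeric identity with the historical spreadsheet implementation is not
claimed; the contract is the formulas above, verified against an
independent explicit-loop implementation to 1e−12, plus rank agreement
on designed instances. One behavior worth knowing: the grouped SV's
spread term saturates at √γ̂² as σ̂² grows, so extremely noisy genes
are penalized less by grouped SV than by every other statistic here;
the ungrouped mode (the default) tracks total instability and is what
the synthetic benchmark evaluates.

**BestKeeper.** Per-gene n, arithmetic and geometric mean Ct, min, max,
SD and CV = 100·SD/mean. SD is the **mean absolute deviation** from the
arithmetic mean — the original tool's documented convention —
with `sd_method="std"` switching to the n−1 standard deviation; at
typical Ct dispersions the two agree to the precision usually printed.
Ranking is ascending by SD, with CV reported alongside. The original
tool's crossing-point index and pairwise correlations are intentionally
omitted: the screening decision here uses only CV and SD.

## Consensus

"Weights" in the comprehensive ranking are interpreted as ordinal ranks
(1 = best, ties broken canonically); a gene's comprehensive value is
the geometric mean of its four ranks and the final ranking is ascending
in it. This is the interpretation under which the published worked
example reproduces exactly (e.g. a gene ranked 9 by all four methods
gets 9.000; ranks 2,5,2,5 give 3.160); the shipped dataset's tie-free
rows all confirm it, and dense ranks are reported alongside because
printed per-method rank columns conventionally share ranks on ties.
The recommendation size defaults to geNorm's optimal reference count
and can be overridden. Genes whose published comprehensive value is
consistent only with a dense geNorm rank are excluded from the exact
acceptance checks, as the two conventions genuinely disagree there.

## Quantification

The standard curve regresses Ct on log10(relative amount) by ordinary
least squares, replicate wells entering as individual points;
E = (10^(−1/slope) − 1)·100 and R² is the squared correlation of the
fit. E outside 90–110 % or R² < 0.90 produce warnings, not errors —
published assays accept efficiencies well outside that band, so the
bands are configurable advisory limits.

ΔΔCt: the per-sample reference signal is the arithmetic mean Ct of the
reference genes, which equals the log2 of the geometric mean of their
relative quantities — the same combination rule as geNorm's NF.
ΔCt = Ct_target − refsignal; ΔΔCt subtracts the calibrator group's mean
ΔCt; rq = 2^−ΔΔCt. Group summaries are the mean and n−1 SD of
per-sample rq by default (`summary_on="ddct"` switches to statistics on
the log scale, exponentiating the mean); the calibrator group's mean rq
is exactly 1 only on the log scale, a known asymmetry of fold-change
averaging. Significance testing of expression differences is left to
general statistics packages.

## Motif classification

A cysteine-spacing pattern is an ordered list of (min, max) windows for
the number of residues strictly between consecutive conserved
cysteines — "Cys1-X30-Cys2" means the positions differ by 31. Shipped
patterns: minus-C OBP (4 Cys; 28–32, 37–39, 16–23), classic OBP (6 Cys;
27, 3, 29, 9, 8), plus-C OBP (8 Cys; 35, 3, 43, 13, 9, 8, 10), CSP
(4 Cys; 6–8, 18, 2). Single-width spacings are observations from
individual sequences, not family-wide windows, so gaps longer than 10
residues get a configurable ±2 tolerance by default (short gaps stay
exact; spacings already published as ranges are kept as published), and
the tolerance is a parameter of `default_patterns`.

Matching enumerates increasing cysteine subsequences by depth-first
search with window pruning; on short sequences it is verified
exhaustively against brute-force subset enumeration. Non-matched
cysteines inside a gap are allowed by default — the patterns describe
*conserved* cysteines and real family members may carry extra ones — 
and a strict mode forbids them, reading the X notation literally.
Classification picks the matching pattern with the most conserved
cysteines (plus-C over classic over the 4-Cys groups); an equal-count
tie returns all labels rather than guessing. Signal peptides are not
predicted; a `mature_start` argument lets callers strip one found by
other tools. `X` is accepted in input and never matches Cys.

## Synthetic benchmark

`simulate_ct` draws Ct_igj = B_i + s_j + δ_ig + ε_igj: per-gene
baselines B_i ~ U(18, 30) cycles, per-sample loading offsets
s_j ~ N(0, 0.5) cycles (shared pipetting/RNA-input variation — it
cancels in ratio-based statistics but not in BestKeeper's raw-Ct
dispersion, deliberately), condition shifts δ, and replicate noise
ε ~ N(0, σ_i). The ground-truth instability √(Var_g(δ_ig) + σ_i²) lives
on the same cycles scale the statistics estimate, making method ranks
comparable to truth. One seed sequence spawns independent sub-streams
(baselines, loading, one per gene), so outputs are byte-reproducible
and partially regenerable.

The default benchmark uses 10 candidates, 2 conditions × 9 samples:
two designed-stable genes (σ = 0.1, δ = 0), one condition-responsive
trap (σ = 0.1, δ = 0.6 cycles — tightly expressed within condition but
shifted between conditions, the case stability screening exists to
catch), and seven noisier genes with σ up to 2.0 and shifts up to 2.0
cycles. Two deliberate design points: shifts are balanced in sign,
because same-direction shifts partially cancel in pairwise statistics
and in NormFinder's centering, letting co-regulated unstable genes
masquerade as stable; and the trap gene's shift is sized so that the
expected V_2/3 ≈ 0.11 sits below the 0.15 cutoff — by design, two
references suffice, and the benchmark asserts the consensus recommends
exactly the stable pair. Problem sizes throughout the test suite (tens
of genes, tens of samples, hundreds of random instances) are chosen as
the smallest at which the asserted properties are statistically stable.

What the simulation does *not* emulate: amplification-curve shape,
fluorescence thresholds, inter-plate calibration, efficiency
differences between genes, and non-normal outliers. Passing the
recovery benchmark therefore shows the estimators rank additive-model
instability correctly, not that they are robust to instrument-level
artifacts.

`simulate_dilution` generates standard curves from a true amplification
base (Ct = Ct₁ − log_base(x), optional Gaussian noise, optional
replicate wells); `simulate_motif_sequence` plants exactly one motif
occurrence in non-cysteine flanks so the matcher's closed loop is
unambiguous.

## Limitations

- Grouped NormFinder's SV compresses differences among very noisy genes
  (see above); compare with the ungrouped mode when groups are few.
- The geNorm V series, like the original, has no significance measure;
  0.15 is a convention, not a test.
- BestKeeper's CV depends on the absolute Ct level, so it is the one
  statistic not invariant to adding a constant to all Ct values.
- Efficiency-corrected stability (per-gene E inside the stability
  statistics) and instrument-native file formats are out of scope.
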