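# refstab

Reference-gene stability evaluation for RT-qPCR, with standard-curve
efficiency, 2^−ΔΔCt relative quantification, and cysteine-motif
classification of OBP/CSP olfactory proteins.

## The problem

Relative quantification by RT-qPCR normalizes a target gene against one
or more *reference genes* assumed to be uniformly expressed. That
assumption fails often enough — across tissues, sexes, treatments —
that candidate references must themselves be screened for stability
before any expression claim is credible. `refstab` implements the four
classical screening statistics and their standard consensus, all
operating on a genes × samples table of quantification cycles (Ct):

- **Comparative ΔCt** — stability of gene *i* is the mean over genes
  *j ≠ i* of the sample SD of (Ct_i − Ct_j).
- **geNorm** — relative quantities q = E^−ΔCt (E = 2 by default,
  ΔCt = Ct − per-gene min); V_jk = SD(log2 q_j/q_k); M_j = mean_k V_jk.
  The gene with the highest M is excluded iteratively. Genes with
  M > 1.5 are unsuitable. The pairwise variation V_n/n+1 = SD of
  log2(NF_n/NF_n+1), where NF_n is the per-sample geometric mean of the
  n most stable genes' quantities, determines how many references are
  needed: the smallest n with V < 0.15.
- **NormFinder** — variance decomposition of Ct into gene, sample, and
  (optionally) group effects; the stability value SV combines the
  estimated intragroup variance with a shrunken intergroup bias.
- **BestKeeper** — per-gene dispersion of raw Ct: SD (mean absolute
  deviation from the mean) and CV = 100·SD/mean.
- **Consensus** — each method's values become ordinal ranks 1..k; a
  gene's comprehensive value is the geometric mean of its four ranks,
  and the top `optimal_n` genes (from geNorm's V series) are
  recommended.

Around the screening sit the two standard quantification steps —
amplification efficiency E = (10^(−1/slope) − 1) × 100 % from a
dilution-series fit of Ct on log10(template amount), and fold change
rq = 2^−ΔΔCt against a calibrator group — plus a classifier that
assigns protein sequences to the minus-C / classic / plus-C OBP and CSP
families by the spacing of their conserved cysteines, and a seeded
simulator that generates Ct matrices with *known* ground-truth
stability so the whole pipeline is testable end to end.

Each method is exposed both as a scikit-learn style estimator
(`GeNorm().fit(X)` with `stability_`, `ranking_`, …) and as a plain
function on a `CtMatrix`.

## Worked example

Simulate the default benchmark (10 candidates, 2 conditions × 9
samples, two designed-stable genes) and screen it:

```sh
$ refstab simulate --seed 42 --out ct.csv --truth truth.csv
simulated 10 genes x 18 samples (stable: cand01, cand02)
$ refstab stability --input ct.csv --out results
recommended reference genes: cand01, cand02
```

`results/` now holds one table per method, the geNorm V series, the
consensus table, and a JSON summary. The top of `consensus.tsv`:

```text
gene    delta_ct_stability  delta_ct_rank  genorm_stability  genorm_rank  normfinder_stability  normfinder_rank  bestkeeper_stability  bestkeeper_rank  comprehensive_value  comprehensive_rank
cand01  0.966515            2              0.145089          1            0.0                   1                0.483112              1                1.189207             1
cand02  0.965069            1              0.145089          2            0.0                   2                0.509992              2                1.681793             2
```

Reading: the two designed-stable genes top every method (geNorm's final
pair shares one M value, 0.145; NormFinder's clipped variance estimate
is 0 for both), their comprehensive values — geometric means of four
ranks — are the two smallest, and since V_2/3 < 0.15 two references
suffice, so exactly `cand01, cand02` are recommended. The same objects
are available in Python:

```python
from refstab import consensus, simulate_ct, two_condition_preset
m, truth = simulate_ct(two_condition_preset(seed=42))
res = consensus(m)
res.recommended        # ['cand01', 'cand02']
res.optimal_n          # 2
```

The other stages work the same way: `refstab efficiency` fits a
standard curve (a perfect doubling series prints `"e_percent": 100.0`),
`refstab quantify --target cand07 --refs cand01,cand02 --calibrator
group1` writes per-group fold changes, and `refstab classify-motif`
labels FASTA records (`obp  minus_c_obp  11,42,81,102` gives the class
and the matched cysteine positions).

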