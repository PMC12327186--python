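# Methods

## Data model

The unit of analysis is a complete candidates × samples matrix of qPCR
cycle-threshold (Ct) values with a sample → group map and a condition
label. Valid Ct values lie in (0, 45] cycles (40 amplification cycles plus
headroom). Technical replicates are collapsed to one value per
(candidate, sample) pair by arithmetic mean; replicate sets whose max−min
spread exceeds 0.5 cycles (configurable) are flagged for review but never
dropped, because silently changing n would corrupt every downstream SD.
Missing values after collapse are a hard error — all four stability
algorithms assume complete matrices, and no imputation is attempted.

Ct is used directly as the log-scale quantity throughout: Ct is −log2 of
input amount up to an assay constant, and every statistic used here is
invariant to the sign and offset, so no efficiency correction or
calibrator is required. Amplification efficiency is fixed at E = 2
(no dilution-series data are assumed), which makes the geNorm log-ratio SD
reduce exactly to the Ct-difference SD.

## Stability algorithms

**Pairwise kernel.** For every unordered candidate pair (i, j) the sample
SD (n−1 denominator) of {Ct_i(s) − Ct_j(s)} is computed over all samples,
pooled across groups within a condition (the emulated study ranks one list
per condition, not per group). The matrix is symmetric, has zero diagonal
and is invariant to per-sample and per-candidate additive offsets.

**Comparative delta-Ct.** Stability of candidate i = mean over j ≠ i of
the pair SD. Lower is more stable.

**geNorm.** M_i on a subset is the mean pair SD within the subset; at
E = 2 the full-panel M is *identical* to the delta-Ct value, which the
test suite asserts to 1e-12 — the two methods differ only through geNorm's
stepwise exclusion. At each step the candidate with the highest M on the
current subset is removed and that M is recorded as its stability value;
the final two candidates share the final-step M and rank 1 (competition
ranking continues at 3). Ties in M within 1e-12 are broken
lexicographically for determinism. The reported per-candidate geNorm value
is the M at the candidate's exclusion step: a single full-panel pass could
not produce geNorm values different from the delta-Ct values, while the
published listings for this panel clearly differ, so the stepwise
interpretation is adopted. The pairwise-variation companion V_{n/n+1} is
the SD over samples of log2(NF_n/NF_{n+1}), with NF_k the per-sample
geometric mean of relative quantities Q = 2^(minCt−Ct) over the top-k
ranked candidates.

**NormFinder-style decomposition.** With k candidates, G groups and group
sizes n_g: candidates are centered by their grand means; each sample's
across-candidate mean is then subtracted (this removes shared loading
exactly), giving residuals x_igj. Intergroup deviation d̂_ig is the group
mean of x; observed centered variance s²_ig its group variance (n_g−1).
Because the across-candidate centering mixes candidate noises,
Var(x_i) = ((k−1)²/k²)σ²_i + (1/k²)Σ_{i'≠i}σ²_{i'}; inverting this by
method of moments gives the corrected intragroup variance
σ̂²_ig = max(0, (k/(k−2))(s²_ig − S_g/(k(k−1)))) with S_g = Σ_i s²_ig,
whence the k ≥ 3 requirement. The between-candidate variance of group
deviations is estimated as γ̂² = max(0, Var_{i,g}(d̂) − mean_{i,g}(σ̂²/n_g));
the variance over the k·G deviations uses the sample (ddof = 1)
denominator. Deviations are shrunk toward zero by the variance-ratio
factor γ̂²/(γ̂² + σ̂²/n_g), keeping the stability finite and stable when γ̂²
is tiny. Stability ρ_i = (1/G) Σ_g (|d̃_ig| + √(σ̂²_ig/n_g)). A group-free
variant returns ρ_i = √σ̂²_i on the pooled samples. No claim of bit parity
with any existing NormFinder implementation is made; the estimator is
validated against an independent step-by-step oracle in the tests.

**BestKeeper.** The per-candidate dispersion statistic is the mean
absolute deviation (MAD) of raw Ct from its arithmetic mean — the "SD
(± Cp)" of the original descriptive formulation — with CV = 100·MAD/mean.
Candidates are ranked by MAD ascending; a consistency flag marks
MAD ≤ 1 cycle. The BestKeeper index is the per-sample geometric mean over
all candidates (no pre-exclusion), and each candidate's Pearson r and
two-tailed p against the index are reported but do not determine the
ranking. Zero-variance profiles yield an undefined-r flag rather than an
error.

**Consensus.** Each method contributes a competition-rank vector: tied
values (within 1e-12 for computed scores) share the minimum rank and the
next distinct rank skips by the tie size. geNorm contributes its
exclusion-order ranks (final pair both 1); the other three are ranked from
their stability values. The comprehensive score is the geometric mean of
a candidate's per-method ranks, ordered ascending with lexicographic
tie-break (flagged). Display values are floor-truncated, not rounded, to
two decimals — the convention under which the published listings for this
panel are reproduced exactly (1.1892 → 1.18, 2.2360 → 2.23); a 1e-9 guard
absorbs float round-off so an exactly integer geometric mean prints as
itself. When rebuilding ranks from published listings, comma-joined
candidates with identical printed values tie, and a ">" separator always
advances the rank even between equal-looking rounded values; this is the
unique rule that reproduces the published consensus values. The published
morphology consensus for U6 (3.63) is not reproducible from any integer
rank combination consistent with the printed orderings (closest:
180^(1/4) = 3.66); it is reported with a discrepancy flag and deliberately
not forced to agree.

## Cohort-definition rules

Major sperm defects = acrosomal abnormalities + head defects + vacuoles +
proximal cytoplasmic droplet + midpiece damage; minor = detached head +
bent tail; total = major + minor. A sample is non-approved iff
major > 20% or total > 30% (strict inequalities: "exceeding" a limit).
When a record supplies pre-aggregated major/minor values they are treated
as authoritative and not recomputed from components — upstream per-sample
rounding can make a reported aggregate differ from the component sum, as
the packaged cohort-mean table itself shows (reported major 24.00 vs
component sum 23.20 in the failed cohort).

CASA ratios: STR = 100·VSL/VAP, LIN = 100·VSL/VCL, WOB = 100·VAP/VCL;
zero denominators leave the ratio undefined with a flag, and violations of
the VSL ≤ VAP ≤ VCL ordering are flagged but still computed.

Motility quartile grouping assigns values ≤ Q1 to the Low/Moderate cohort
and values > Q3 to the High cohort, leaving the middle unassigned.
Quartiles use linear interpolation between order statistics (numpy
default); the convention matters for membership near the cut points, so it
is fixed and documented rather than configurable per call. Degenerate
inputs (Q1 = Q3) are flagged. Group contrasts use the two-tailed unpaired
Student t-test (equal variance) by default, Welch selectable, with
significance at p < 0.05 and dispersion reported as SEM.

## Synthetic-data model

Ct_igj = B_i + L_gj + δ_i·[g = 2] + ε_igj, with per-candidate baselines
B_i, shared per-sample loading L ~ N(0, τ²) (pipetting / input-amount
variation, identical across candidates within a sample), an optional
group-2 shift δ_i modelling a truly condition-dependent candidate, and
candidate noise ε ~ N(0, σ_i²). Technical replicates add independent
N(0, replicate_sd²) read noise and are collapsed by mean. One seeded
generator drives all draws in a fixed order, so a seed fully determines
the table.

Defaults mirror the emulated study scale and are the package's own
choices: k = 7 candidates, two groups of 5, triplicates, baselines drawn
once in [18, 30] cycles, τ = 0.8, σ_i in [0.1, 1.5], replicate SD 0.15,
δ = 0. The ground-truth disorder score √(σ² + δ²/4) is a documented
convention for ranking truth (δ/2 being the per-group displacement from
the candidate's mean), not a claim about any method's estimand.

What the generator does *not* emulate: amplification-efficiency variation
between assays, missing or censored ("undetermined") wells, non-Gaussian
outliers, and correlated noise between candidates beyond the shared
loading term. Passing tests therefore demonstrate correctness of the
statistics and the expected qualitative behaviour (loading cancels in the
pairwise and model-based methods but inflates BestKeeper MAD; noisy or
shifted candidates rank low), not robustness to those real-data artefacts.

## Recovery experiment

The designed-winner experiment draws fresh cohorts per replicate and asks
where each method, and the consensus, ranked the known most-stable
candidate. The committed design: winner σ = 0.1, δ = 0; competitors
σ = 0.6, 0.8, 1.0, 1.2, 1.5 spanning the default noise range; one
condition-dependent candidate σ = 0.3, δ = 2 cycles; all other parameters
at the generator defaults. At this scale (n = 5+5) the measured consensus
top-1 recovery is ≈ 0.92 over 1000 replicates. The two loss modes are
informative about small-cohort limits: pair-SD estimates carry 9 degrees
of freedom, so the σ = 0.6 competitor overtakes the winner in the
pairwise methods in roughly 9% of draws; and the deviation-variance
estimate γ̂² occasionally clips to zero when the large competitor
variances dominate its subtraction term, whereupon shrinkage discards the
group shift and the shifted low-noise candidate can win the model-based
method. The shifted candidate never wins the model-based ranking when the
background noise is homogeneous (σ = 0.3), where γ̂² is well identified.

## Numerical choices

- SDs and variances use the n−1 denominator throughout (including γ̂²'s
  ddof = 1 over the k·G deviations); BestKeeper MAD uses 1/n by
  definition.
- Negative variance estimates are clipped to zero (σ̂², γ̂²).
- geNorm exclusion ties (ΔM ≤ 1e-12) and equal consensus geometric means
  break lexicographically by candidate id, deterministically.
- Numeric outputs are written at 6 decimals; display truncation to 2
  decimals exists only in the consensus display column.
- CLI exit codes: 0 success, 2 validation error, 3 contract error,
  4 I/O error.

## Known limitations

- The stability values of the original study are not recomputable without
  its raw Ct data; only the consensus arithmetic over the printed
  orderings is reproducible (and is, except for the U6/morphology value
  noted above).
- The group-aware decomposition requires k ≥ 3 candidates and ≥ 2 samples
  per group; with exactly 2 groups of 5 the intergroup deviations are
  estimated from 5 values each and are accordingly noisy.
- No efficiency estimation, amplification-curve processing, or
  instrument-native file parsing; inputs are plain CSV/TSV tables.
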