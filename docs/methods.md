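# Methods

## Scoring model

A participant answers k matched dilemma pairs; each pair has a congruent
(C) version, where utilitarian and deontological reasoning both condemn the
harm, and an incongruent (IC) version, where a utilitarian justification
conflicts with a deontological norm. Responses are binary
(1 = unacceptable). With p_C and p_IC the participant's item-mean
unacceptance rates,

* U = p_C − p_IC ∈ [−1, 1] — utilitarian inclination,
* D = p_IC / (1 − U) ∈ [0, 1] — deontological inclination, undefined
  exactly when U = 1 (all C unacceptable, all IC acceptable),
* TS = p_IC — the traditional bipolar score (higher = more deontological).

Algebraically D·(1 − U) = TS and U + TS = p_C; the implementation asserts
both. Since 1 − U = (1 − p_C) + p_IC, the denominator is computed in that
form, which keeps D exact at the p_C = 1 boundary; the ratio is clipped to
[0, 1] to absorb float roundoff at the edges. Undefined D values propagate
as missing and are deleted pairwise in correlations.

U is affinely equivalent to a plain sum score: over the 2k-item matrix of
C items and reverse-coded IC items, U = 2·mean − 1 per row. This is what
makes item-level internal-consistency machinery (alpha, omega, factor
loadings) applicable to U at all; `build_alt_u_items` materializes that
matrix and a property test holds the identity exactly over random inputs.

## "Realistic" responders

A responder is called realistic when they accept harm in IC dilemmas at
least as readily as in C dilemmas, i.e. U ≥ 0. The threshold is inclusive
by design: for short binary batteries a sizeable mass of responders sits
exactly at U = 0 (17.6% under 10+10 fair-coin responding), and the
subset correlations are visibly sensitive to whether that mass is kept —
with it, the subset reproduces r(TS,U) ≈ −0.53 and r(TS,D) ≈ 0.82 on
random data; dropping it shifts them to ≈ −0.48 / 0.86. Only responders
strictly more accepting of useless than of justified harm (U < 0) are
treated as unrealistic. `filter_realistic(..., strict=True)` exposes the
strict reading for sensitivity analyses.

## Simulation designs

**Random responding.** n×2k independent Bernoulli(p) draws, defaults
n = 10,000, k = 10, p = 0.5. This is the null world: no participant-level
signal. Closed forms fix the expectations the tests check: with
independent equal-variance item means, Cov(TS, U) = −Var(p_IC), so
r(TS, U) → −1/√2 ≈ −0.707, and the strict U > 0 mass equals
P(X > Y) = (1 − P(X = Y))/2 ≈ 0.412 for X, Y ~ Bin(10, ½).

**Constant congruent mean.** As above, but every responder realizes the
same C mean exactly (position-shuffled fixed number of ones per row).
U = c − p_IC and D = p_IC/(1 − c + p_IC) are then monotone in p_IC in
opposite directions, so r(U, D) is strongly negative (≈ −0.97 at c = 0.5)
— demonstrating that the near-zero U–D correlation in the random design
rests entirely on between-responder variance in the congruent set. At
c = 1 every defined D equals 1 and correlations with D are undefined; at
c = 0, D = TS/(1+TS) and Spearman r(TS, D) = 1.

**Correlated latents with ordered cutoffs.** Two independent n×k blocks
of equicorrelated standard gaussians (shared-factor construction
√r·Z + √(1−r)·ε, exact target correlation r = 0.50) represent the C and IC
sets. One cutoff per item: C cutoffs i.i.d. uniform on [−1, 2]; the IC
cutoff of pair j uniform on [−2, C-cutoff j], hence always below its
partner. A response is unacceptable when the latent falls *below* the
cutoff; this direction is forced by the target marginals — it yields
expected unacceptance of 64% (C) and 28% (IC) under the stated cutoff
laws (numeric integration of Φ over the uniform cutoff mixtures), while
the opposite direction yields roughly 36%/71%. Cutoffs are drawn once per
dataset (item-level, not participant-level). A single ten-cutoff draw
moves the realized rates with SD ≈ 8 percentage points, which is why
headline rates are reported as averages over replicate cutoff draws; a
reference value of 35% for the IC set is reachable only by a fortunate
single draw, and the replicate-averaged recomputation honestly lands at
≈ 28%. Dichotomization attenuates the latent correlation: the median
pairwise r among dichotomized C items is ≈ 0.24–0.26.

## Empirical-like synthetic sample

The mimic generator draws each participant×pair outcome from a
four-category joint distribution over (C, IC) response patterns — both
unacceptable, both acceptable, IC acceptable & C unacceptable, and the
perverse IC unacceptable & C acceptable — one distribution per pair.
The default table covers the nine classic dilemma pairs (abortion, animal
research, border crossing, car accident, hard times, relationship, time
machine, torture, vaccine policy) with proportions as observed in a large
online sample (N = 1,010, the default n); columns are renormalized
exactly (printed three-decimal proportions can sum to 0.999–1.005, and
anything further than 0.01 from 1 is rejected as a transcription error).
The per-pair "difference" statistic (sensible-direction switches minus
perverse switches) and the unweighted mean acceptance rates (56.8% IC,
23.9% C) are pure arithmetic on this table and are recomputed, not stored.

Pairs are drawn independently of one another: published tables provide no
cross-pair joint distribution, and real inter-dilemma correlations are
near zero (median absolute ≈ 0.06), so independence is the parsimonious
default. Consequences to keep in mind: within-pair association is
faithful, but any true cross-pair trait consistency is absent, so
split-half reliabilities computed on mimic data sit at their floor (≈ 0)
rather than at the modest positive values a real sample shows. Passing
pipeline tests on mimic data therefore demonstrates that every statistic
is computed correctly, not that real data would show those values. Each
pair's draws come from a substream keyed by (seed, pair label), making the
generator exchangeable under column permutation.

An optional HCMD battery (12 Likert items, 1–7, higher = more
utilitarian — polarity opposite to TS) is generated from a participant
latent correlated `hcmd_link` with the standardized IC-unacceptance
tendency, mixed with item noise at loading 0.7 and discretized at
standard-normal septile thresholds (symmetric marginal). `hcmd_link`
defaults to 0 (independent batteries); the analysis driver uses −0.5,
which reproduces the observed sign pattern (HCMD vs TS negative, vs U
positive, vs D negative) with realistic attenuation.

## Reliability estimation

*Cronbach's alpha* uses the classical variance-ratio formula (sample
variances, ddof = 1). *McDonald's omega* fits a single-factor
maximum-likelihood model to the standardized items
(`sklearn.decomposition.FactorAnalysis`) and computes
ω = (Σλ)² / ((Σλ)² + Σψ) with the factor sign fixed so Σλ ≥ 0. A
hierarchical/bifactor model is unidentifiable with one composite per
parameter, so the one-factor model is the deliberate choice; on
equicorrelated items it recovers the closed form
(Σλ)²/((Σλ)²+Σ(1−λ²)) within ±0.02 at n = 10,000. Both coefficients are
reported for the reversed (per the U formula) and unreversed item sets,
since a general condemnation tendency can make the unreversed variant far
larger.

*Split-half permutation reliability* randomly splits the k pairs into
halves of ⌊k/2⌋ and ⌈k/2⌉ (4 vs 5 at k = 9), computes U and D from each
half, takes the Spearman correlation between half-scores across
participants, and applies the Spearman–Brown step-up 2r/(1+r); the
distribution over (default) 10,000 iterations is summarized by mean and
SD. Participants with undefined D in either half are excluded pairwise
within the iteration. Iterations with a zero-variance half, fewer than
three usable participants, or r = −1 (where the correction is undefined)
are dropped and counted; more than 50% drops flags the report as
unreliable. Negative corrected values are reported as-is, never
truncated. Splits are drawn over the sorted label set, so the report is
invariant to column order and participant order at a fixed seed.

## Correlation tables

Parameter tables use Pearson correlations by default (rank-based analyses
— inter-dilemma correlations and split-half — use Spearman), with
two-sided p-values and the usual star convention (*, **, *** at .05, .01,
.001). Zero variance is detected with a relative tolerance
(σ ≤ 1e−12·(1+max|x|)) so that roundoff-level jitter in analytically
constant scores is not correlated as if it were signal; such cells are
reported as undefined (NaN), never as 0.

## Numerical and design choices

* Seeding: `numpy.random.default_rng` throughout; drivers split one
  user-facing seed into independent `SeedSequence` substreams per stage,
  so stages can be rerun in isolation; derived seeds stay below 2³¹.
* Test and acceptance problem sizes follow the study conditions
  (n = 10,000 for single-run simulation checks; 1,010 for the
  empirical-like sample). Replicate-averaged cutoff quantities use many
  smaller replicates (e.g. 400×2,500 or 30,000×50), chosen so Monte-Carlo
  error is a fraction of the narrowest comparison band.
* Missing input responses are handled by listwise participant exclusion at
  CSV load (the procedures assume complete rows), with a logged count.

## Known limitations

* The mimic generator cannot represent cross-pair dependence (see above);
  its reliability estimates are floors by construction.
* Omega assumes a one-factor structure; for item sets that are themselves
  two-process mixtures its substantive interpretation is limited — which
  is, in part, the methodological point the package illustrates.
* The D parameter admits no item-level consistency coefficient; the
  split-half permutation estimate is the only route implemented and acts
  as a lower bound on reliability.
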