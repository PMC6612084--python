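# Methods

## Design and effect model

The experiment plan is the canonical Taguchi L9(3⁴) orthogonal array: nine
conditions over four three-level factors, every column holding each level
three times and every column pair containing each ordered level pair exactly
once. The array is hard-coded (this package supports exactly this design; a
general orthogonal-array constructor is out of scope) and
`validate_orthogonality` re-checks the pairwise balance by brute-force
census, which is exhaustive and cheap at this size. Level indices are
1-based everywhere, including serialized CSV, to match standard
orthogonal-array tables. Factors bind to columns positionally (A→1 … D→4)
by default.

The outcome is an attribute (count-value) characteristic: each run is
defective or good. The effect of factor F at level ℓ is the pooled defect
proportion over the three conditions with F = ℓ (3 × runs_per_condition
runs, 90 in the reference data). This estimator is unbiased for the
marginal level effect only because the array is balanced; that is the
operational meaning of orthogonality here. Interactions between factors are
assumed negligible — the L9 has no free columns to estimate them, so this
assumption is documented, not tested. Selection is per-factor argmin
("smaller the better") with ties broken to the lowest level index, a purely
deterministic rule; the reference data contain no ties.

## Omega transformation

Defect proportions are combined through Ω(P) = 10·log₁₀((1−P)/P), a logit
expressed in decibels, with inverse P = 1/(1+10^(Ω/10)). The combined
estimate for a selection of m levels is Σ Ω(p̄ᵢ) − (m−1)·Ω(T̄): on the logit
scale each level contributes its deviation from the grand rate T̄, and the
deviations are added to the grand rate's transform. The multiplier (m−1)
generalizes to any factor count.

Two rounding conventions are provided:

* `full` — every proportion and dB value at machine precision; the default
  for new analyses (combined estimate for the reference data: 8.21 dB,
  13.13 %).
* `paper` — proportions rounded to 2 decimals before the transform, each dB
  value rounded to 2 decimals before combining, and the combined dB rounded
  to 2 decimals before back-transformation. This reproduces printed-table
  arithmetic exactly (4.54 + 4.32 + 5.25 + 3.89 − 3·3.27 = 8.19 dB →
  13.17 %). Reproduction of published tables is the only reason to use it.

Degenerate rates (0 or 1) are a hard domain error — never silently clamped,
because Ω diverges there and a silent fix would change reported numbers. An
explicit Haldane-style correction ((x+0.5)/(n+1)) is available behind the
`continuity` flag. Note that with all-zero counts the corrected level rates
(0.5/91) exceed the corrected grand rate (0.5/271), so the additive chain
then predicts *above* the corrected baseline; the correction makes the
arithmetic well-defined, it does not make extrapolation from no events
meaningful.

The confirmation-experiment percentage is printed at 1 decimal by
truncation toward zero (35/270 = 12.963 % → 12.9 %), matching the printing
convention of the source tables; the full-precision rate is carried in the
report alongside it.

## Back-propagation check

The network is a deliberate from-scratch implementation: 4 inputs (the
encoded factors), one hidden layer, 1 output, logistic sigmoid throughout,
online (pattern-by-pattern) delta-rule updates with momentum,

    Δw(t) = −η·∂E/∂w + α·Δw(t−1),   E = ½(y − t)²,

η = 0.1, α = 0.1, 500 epochs by default, weights initialized uniformly in
[−0.5, 0.5]. One seeded generator drives initialization and then the
per-epoch pattern shuffles, so training is bit-reproducible. Correctness is
anchored by a central-finite-difference gradient check (max relative
deviation < 1e−6 at ε = 1e−5), which is the module's core oracle; a sign
flip in the backward pass moves the deviation to order 1.

Hidden-layer sizing follows the classical unit-count heuristics for a
4-input/1-output net — average (in+out)/2 = 3, summation in+out = 5,
doubling 2·(in+out) = 10 — with the summation value 5 as the default.

Input encoding min–max scales numeric factors to [0,1] using their level
values; the categorical access type is ordinal-encoded as level/3 by
default (one-hot optional, widening the input layer to 6). Two target
encodings are supported. The default, `proportion`, gives every run its
condition's empirical defect rate: with only 9 distinct input patterns,
binary 0/1 targets leave an irreducible Bernoulli-variance floor
(≈ 0.19 MSE here) that no network can cross, so very small MSE values are
only attainable against proportion targets. `binary` is retained for
classification-style use.

The 80/10/10 split allocates floor(n·f) records to validation and test and
the remainder to train (270 → 216/27/27), from a seeded shuffle, repaired
so every condition keeps at least one training record.

Convergence detection uses the standard plateau rule: the run converged at
the first epoch opening 10 consecutive epochs during which the monitored
MSE's running minimum improves by less than 1e−4 (validation curve when a
validation split exists, else training). An absolute "stay within 1e−4 of
the minimum" band was considered and rejected: under online updates the
per-epoch MSE of a 27-record validation set jitters by 1e−4–1e−3 around a
flat plateau, so a band that narrow flags jitter, not lack of convergence.
Upward jitter therefore does not reset the window; only a real improvement
does. Training always runs the full epoch budget unless `early_stopping`
is set. On the reference data the detector fires between roughly epoch 2
and epoch 80 depending on the seed, with final training MSE of order 1e−3
to 1e−2. Non-convergence is reported, never fatal: in the workflow it is a
signal to revisit the factor configuration.

## Synthetic data

`generate_runs` draws, for each of the 9 conditions, `runs_per_condition`
independent Bernoulli(p) outcomes; the default profile sets p to the
reference data's empirical rates (7/30 … 5/30) with 30 runs per condition.
A single seed with a fixed stream order (conditions in index order, runs in
index order) makes output platform-reproducible. The generator emulates the
*marginal* structure the analysis assumes — independent runs, fixed
per-condition probabilities — and nothing else: no within-patient
correlation, no session-to-session drift, no covariate-dependent defect
probabilities. Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes, not that real dialysis data satisfy
those assumptions.

Patient covariate tables are sampled per covariate independently from the
packaged category weights (health-status and physiological tables).
Covariates are generated independently of outcomes, since the source data
report them descriptively and never link them to clotting. The printed
physiological percentages are inconsistent with the printed counts for
several bands; counts mode treats counts as authoritative, percent mode
uses the printed percentages verbatim. The "improved" physiological profile
specifies only each normal band's percentage (40.3 / 59.0 / 32.2 / 76.4 /
79.0 %); the remaining mass is split over the other bands in proportion to
the original printed percentages.

## Parameter recovery: a known limitation

The pipeline-closure property — analyze(generate(profile)) returns the
profile's true argmin combination, A1B3C2D2 under the default profile —
holds with probability that grows with runs_per_condition but is limited by
the D factor's narrow margin. The true pooled rates for D2 vs D1 are 26/90
vs 28/90 (Δ ≈ 0.022), while the sampling standard deviation of their
difference at 300 runs per condition (900 per factor-level) is ≈ 0.021, so
the wrong D level is picked in roughly 14 % of replicates; measured overall
recovery at 300 runs per condition is ≈ 0.80–0.84. A ≥ 95 % recovery
frequency is not attainable at these effect sizes and this sample size —
that would require roughly a 4× larger sample for the D margin — and the
corresponding acceptance test documents this honestly by failing. The
generator's default conditions were deliberately left at the reference
rates rather than adjusted to make the check pass.

## Problem sizes used by the test suite

Deterministic reproduction checks run on the packaged 270-run table.
Stochastic checks use: 300 seeds for the binomial-expectation test, 20 000
patients for covariate-frequency convergence, 10 training seeds × 500
epochs for the learning check, and 200 Monte-Carlo replicates at 300 runs
per condition for parameter recovery.
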