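# Methods

## The design and its data

A paired A–Not A study presents each of n participants with k
content-matched stimulus pairs (one A and one Not-A stimulus per pair),
one stimulus at a time, each answered "A" (coded 1) or "Not A" (coded 0).
The response matrix is n × 2k binary; pairs are detected from `_A`/`_NotA`
column suffixes (i-th of each group in file order) or positionally (first
k columns A, last k Not-A). Missing or non-binary cells are rejected, not
imputed. The effective sample size is N = n·k response pairs.

Each pair's joint answer is one of four patterns — a ("A" twice),
b (both wrong), c (both correct), d ("Not A" twice) — and the margins of
the pattern table recover hits (a+c), misses (b+d), false alarms (a+b) and
correct rejections (c+d).

## Testing against chance

Chance-level allocation means the two discordant patterns are equally
likely. The asymptotic McNemar statistic is (b − c)²/(b + c) on 1 df; the
exact test refers c to Binomial(b + c, ½). Conventions adopted:

- **Default and preferred method: exact.** With b + c = 0 (all pairs
  concordant) the exact p is reported as 1; the asymptotic statistic is
  undefined and raises.
- **One-tailed alternative:** the correct pattern dominates (p_c > p_b).
  A one-tailed request when c ≤ b still returns the (large) p but sets
  `direction_ok=False` and warns — reversed allocation indicates swapped
  category understanding, not inability.
- **Two-tailed exact p:** double the smaller tail, capped at 1 (no mid-p).
- **Continuity correction:** the Edwards form (|b − c| − 1)²/(b + c) for
  the two-tailed statistic; the one-tailed approximation uses the signed
  deviate (c − b − 1)/√(b + c), i.e. the half-unit correction on c in
  P(X ≥ c). This one-tailed corrected form tracks the exact binomial p to
  within about 10⁻⁴ at b + c = 200, whereas the uncorrected form deviates
  by up to ~0.03; the convergence test therefore compares the corrected
  form. The two-tailed doubling convention differs from the χ² tail by up
  to ~0.06 near b = c purely through discreteness of the doubling.
- Critical values come from the χ²(1) quantile: 3.84 at a two-tailed .05
  level, 5.02 for the one-tailed convention (half the level, p ≤ .025).

## Effect sizes

- Cohen's w = √(X²/N); benchmarks .1/.3/.5 (small/medium/large).
- Odds ratio b/c of the discordant counts; benchmarks 1.22/1.86/3.0. A
  Haldane (+½) correction is available when c = 0.
- d′ = z(p_hits) − z(p_fas) and criterion c = −½[z(p_hits) + z(p_fas)]
  under the equal-variance Gaussian model. Proportions of exactly 0 or 1
  are replaced by 1/(2k) and 1 − 1/(2k); no blanket (log-linear)
  correction is applied, so interior proportions pass through untouched.
- **Sign convention for the criterion:** c > 0 means a "Not A" tendency
  (miss rate above false-alarm rate). Published descriptions of this sign
  are not always internally consistent; this package fixes the convention
  stated here and the generator (below) is built to match it.
- Benchmark scales for d′ differ by design: A–Not A uses
  0.74/1.81 (rather-small / meaningful / rather-large); the 2-AFC scale is
  0.5/1.0/1.5 (small/medium/large). The √2 conversion
  (d′_2AFC = √2·d′_A–Not A, a 41% increase) does **not** map one benchmark
  set onto the other; both scales are kept verbatim and classification
  treats each boundary as belonging to the larger category.

## Power and sample size

Designs are parameterized by (p_b, p_c), or by the odds ratio OR = p_b/p_c
with the discordant proportion p_D = p_b + p_c
(p_b = p_D·OR/(1+OR), p_c = p_D/(1+OR)). Writing ψ = p_b + p_c and
2Δ = p_c − p_b:

- **Miettinen (closed form).**
  Power = Φ((−z₁₋α·ψ + √(Nψ)·|2Δ|)/√(ψ² − 4Δ²)); the sample size
  N = [z₁₋α·ψ + z₁₋β·√(ψ² − (2Δ)²)]²/(ψ·(2Δ)²), rounded up. The closed
  form is the exact algebraic inverse of the power expression, so the
  returned integer always satisfies power(N) ≥ target > power(N − 1).
- **Bennett–Underwood.** Power = P(χ²₁(λ) > k₁₋α) with noncentrality
  λ = 2NΔ²/p, p = ψ/2, and k₁₋α the central χ²(1) quantile at 1 − 2α
  (2.71 at α = .05) — the one-tailed critical value. N is found by
  bracketing and bisection (power is strictly increasing in N).
- **Unconditional exact.** The discordant count n_D is Binomial(N, p_D);
  conditional on n_D the dominant discordant count is
  Binomial(n_D, max(p_b, p_c)/p_D) and the non-randomized (conservative)
  exact test rejects at the smallest critical count whose Binomial(n_D, ½)
  upper tail is ≤ α. Exact power is a sawtooth in N, so the minimum N is
  found by an upward scan, not bisection. Enumeration is capped
  (default N ≤ 20 000) since cost grows as O(N²).

All three are evaluated with |2Δ|: the (2Δ)² terms are sign-free and the
result is the power to detect the dominant discordant pattern whichever
way the labels point. The printed formulas are one-tailed; a two-tailed
variant substitutes α/2.

Accuracy note: against a full trinomial enumeration of the asymptotic
test's true rejection rate, the Miettinen formula is accurate to ~0.002 at
large N (e.g. the p_b=.12/p_c=.08 design, N = 763) but can deviate by
~0.013 at small N with large OR. The Monte-Carlo cross-validation
therefore uses the large-N cell for the closed form and the exact
computation elsewhere.

## Replication adjustment

With k > 1, participants' response pairs are clustered. The adjustment
factor is the moment design-effect estimator on the per-participant
"A"-answer proportions p̂ᵢ = xᵢ/m (m = 2k trials, pooling both stimulus
classes as the per-participant totals do):

    C_raw = m·Σᵢ(p̂ᵢ − p̄)² / ((n − 1)·p̄·(1 − p̄)),

the estimator of 1 + (m − 1)ρ with ρ the intra-participant correlation.
C is clamped to [1, k]; a degenerate p̄ ∈ {0, 1} yields C = 1. The
effective sample size is N = n·k/C, and the participants needed for a
target N are ⌈C·N/k⌉. The estimator is isolated behind one function so a
different variance-components estimator (e.g. beta-binomial ML) could be
swapped in; that fitting is deliberately out of scope.

A subtlety: for a sensitive observer the binomial reference variance
p̄(1 − p̄)/m overstates the true within-participant variance (the pooled
count mixes hit and false-alarm trials with different success
probabilities), so under zero heterogeneity C_raw sits slightly below 1
(~0.86 at d′ = 1) and clamps to 1 in the large majority of samples —
conservative in the right direction.

## The synthetic observer

The generator implements the equal-variance Gaussian observer: evidence
~ Normal(d′, 1) for A stimuli and Normal(0, 1) for Not-A; the answer is
"A" when evidence exceeds d′/2 + c, so c = 0 is unbiased and the estimators
recover (d′, c) exactly in expectation (p_hit = Φ(d′/2 − c),
p_fa = Φ(−d′/2 − c)). Participant heterogeneity draws each participant's
(d′ᵢ, cᵢ) from normal distributions around the population values. The two
trials of a pair are conditionally independent given the participant;
presentation-order effects, learning, and unequal-variance observers are
not modelled, so passing tests say nothing about sequential dependencies
in real data.

Default condition choices: d′ = 1.0 (a mid-scale "meaningful" effect) and
c = 0; heterogeneity defaults to 0 so that the exchangeable base case is
what one opts out of. Parameter-recovery checks use 10⁵ response pairs
(recovery to ±0.05); Monte-Carlo power uses 20 000 replicates (binomial SE
≈ 0.003 near power .8) at the reference designs N = 75, 99 and 763.

Monte-Carlo power draws each participant's k pattern counts directly from
the multinomial implied by the analytic pattern probabilities
(p_a = p_hit·p_fa, p_b = (1 − p_hit)·p_fa, p_c = p_hit·(1 − p_fa),
p_d = the remainder) — distribution-identical to trial-level simulation
under conditional independence, and fast enough for 2 × 10⁴ replicates in
well under a minute. The trial-level generator is retained for producing
actual response matrices, and a test confirms the two routes agree.

An independent-trials observer cannot reach every (p_b, p_c): solving
p_b = (1 − h)f, p_c = h(1 − f) requires (1 + p_c − p_b)² ≥ 2(p_c − p_b +
p_b + p_c), which fails for high discordance at small odds ratios (e.g.
p_b = .2, p_c = .4). For such designs the design-route Monte-Carlo
(`mc_power_design`) samples pattern counts from the multinomial directly,
with the concordant remainder split evenly between a and d (the test never
sees that split).

## Degenerate inputs and tie-breaks

- b + c = 0: exact p = 1; asymptotic statistic raises.
- Planning with p_b = p_c: power equals α (Miettinen) or 2α-tail (BU);
  sample-size inversion raises (no effect to detect).
- Effect-size classification at a printed boundary takes the larger
  category; d′ (A–Not A scale) exactly 0 is "none".
- `exact_n` scans upward so a sawtooth dip just below an earlier crossing
  cannot produce an N whose power is below target.

## Limitations

- Monadic and mixed sub-designs, rating-scale responses, unequal-variance
  models (d_a, ROC area) and forced-choice power beyond the √2 d′
  conversion are out of scope.
- The discouraged practice of t-testing per-participant d′ values against
  zero is intentionally not offered: the pattern-level McNemar test is the
  appropriate chance-level test, and per-participant d′ is reported for
  description, not inference.
- Confidence intervals for the odds ratio and mid-p exact variants are
  not implemented.
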