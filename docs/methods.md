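# Methods

## The planning problem

The Wilcoxon–Mann–Whitney (WMW) test compares two independent samples
X\_1i ~ F1 (reference) and X\_2j ~ F2 (treatment) through the
nonparametric relative effect

    p = ∫ F1 dF2 = P(X1 < X2) + ½ P(X1 = X2),

with every cdf taken in *normalized* form F = (F⁺ + F⁻)/2, the average of
the right- and left-continuous versions. The normalized cdf makes a single
set of formulas valid for continuous, count, ordinal, and dichotomous data;
its empirical counterpart is the midrank. Planning a study means finding
the total sample size N = n1 + n2 such that a two-sided level-α WMW test
detects a relevant departure p ≠ ½ with probability at least 1 − β, and
possibly choosing the allocation rate t = n1/N as well.

## Synthetic data

The unknown quantities in the power approximation — p and the variances
below — are computed from *synthetic data*: the prior-information sample
for the reference group, plus an artificial sample for the treatment group
constructed so that its empirical distribution equals the conjectured
alternative. Both samples are then treated as fixed theoretical
distributions, not random draws. Consequently:

* every variance uses **population divisors** (N, n_i), never N − 1 or
  n_i − 1;
* duplicating both samples any whole number of times changes nothing
  (replication invariance) — the samples only carry relative frequencies;
* the estimates are exact functionals of (F1*, F2*), not noisy estimates.

The alternative is generated from an interpretable effect rather than a
model assumption (`alternatives` module):

* **scale** — x ↦ q·x, optionally floored to integers, e.g. "a 50 %
  reduction of seizure counts" (q = 0.5, floor). Floor is toward −∞; for
  the nonnegative data this is the usual integer part.
* **shift** — x ↦ x + δ with δ given directly or as a fraction of the
  reference mean, optionally rounded to the measurement precision
  (`round_decimals`), e.g. "a shift of 5 % of the mean, on a scale read to
  2 decimals".
* **category shift** — for ordinal frequency rows, a fraction of each
  affected category's mass moves one category up or down. All moves are
  computed simultaneously from the original weights (mass moved in is not
  moved on), total mass is conserved exactly, and a move off the end of
  the scale is an error rather than a silent clamp.

`expand_to_integer_counts` realizes a probability row as the smallest
integer-count sample (brute-force search over multipliers, absolute
tolerance 1e-9), mirroring the common trick of augmenting a data set by a
constant factor to make fractional targets whole.

## Estimation from ranks and placements

With overall midranks R\*\_ik over the pooled N synthetic values, internal
midranks R\*\_ik^(i) within each group, and placements
P\*\_ik = R\*\_ik − R\*\_ik^(i):

    p*    = (R̄*_2· − R̄*_1·)/N + ½
    σ²*   = N⁻³ Σ_{i,k} (R*_ik − (N+1)/2)²             (pooled null variance)
    σ1²*  = (n1 n2²)⁻¹ Σ_k (P*_1k − P̄*_1·)²            = Var(F2(X1))
    σ2²*  = (n1² n2)⁻¹ Σ_k (P*_2k − P̄*_2·)²            = Var(F1(X2))

These are algebraic identities for ∫F1 dF2, ∫(F\*)² dF\* − ¼,
∫F2² dF1 − (1−p)², and ∫F1² dF2 − p², where F\* is the normalized cdf of
the combined synthetic sample. The package carries both routes:
`effect_and_variances` (ranks, O(N log N)) and `integral_oracle` (direct
summation over normalized ecdfs), cross-checked to 1e-10 in the tests; the
oracle never reuses the rank identities, so the check is a genuine dual
route.

For ordered-categorical input, `effect_from_frequency_table` evaluates the
same functionals directly on relative frequencies using the mid-cdf values
H_i(j) = Σ_{l<j} f_il + f_ij/2, which is exact for arbitrary (non-integer)
weights and provably equal to the rank route on any integer expansion.
The pooled null variance depends on how the two groups are weighted in the
pool; `pool_weight` (default ½, matching equal synthetic group sizes)
makes that dependence explicit.

An open modelling point: the continuous-theory null variance is
∫F1² dF1 − ¼ (reference distribution only), while the computational
definition used here pools both synthetic samples. The pooled form is the
default everywhere; `null_variance="reference"` exposes the F1-only
variant for sensitivity checks. For tie-free pooled data
σ²\* = (N² − 1)/(12 N²) exactly, approaching 1/12.

## Sample size and allocation

    N(t) = [σ* u_{1−α/2} + u_{1−β} √(t σ2²* + (1−t) σ1²*)]²
           ─────────────────────────────────────────────────
                        t (1−t) (p* − ½)²

Rounding: n1 = ⌈t·N(t)⌉ and n2 = ⌈(1−t)·N(t)⌉, each group separately
(per-group ceiling). This is the only rule consistent with all four worked
examples at once, including the case where the "optimal" rounded design is
one subject larger than the balanced one. A tolerance of 1e-9 prevents
exact integers from being bumped up.

The Noether comparator replaces the alternative variance by the
continuous-data null variance 1/12:
N = (u_{1−α/2} + u_{1−β})² / (12 t(1−t)(p−½)²). It is included because it
is the field's default formula; with heavily tied data it can oversize a
study by a factor of 3 (the albumin example: 5334 vs 1754).

**Optimal allocation.** N(t) has a unique minimizer t0 on (0, 1), found by
bounded derivative-free minimization (scipy's bounded Brent) on
[1e-3, 1 − 1e-3] with xatol 1e-6, tie-breaking toward ½ when the balanced
size is within 1e-9. The sign rule t0 < ½ ⇔ σ1 < σ2 (and mirror) holds
because only the weighting of σ1², σ2² inside the square root depends
on t.

**Bracketing interval.** At the minimizer, w = 1 − 2t satisfies
w = C(s)·(1 − w²)/4 with

    C(s) = u_{1−β}(σ2² − σ1²) / [s·(u_{1−α/2} σ* + u_{1−β} s)],
    s(t) = √(t σ2² + (1−t) σ1²),

whose positive root w = C/(2 + √(4 + C²)) is increasing in C. Since
s(t0) ≤ s(½) for σ1 < σ2, substituting s(½) yields a closed-form upper
bound; the lower bound is the variance-ratio allocation
I1 = σ1/(σ1 + σ2) = 1/(κ + 1), κ = σ2/σ1, which is also the exact limit
of t0 as the power → 1 (convergence is slow, O(σ*/u_{1−β})). For σ1 = 0
the lower bound degenerates and is replaced by
(u_{1−α/2}σ*/2)/(u_{1−α/2}σ* + u_{1−β}σ2), which follows from the reduced
stationarity relation t0 = 1/(2 + r), r = u_{1−β}σ2√t0/(u_{1−α/2}σ*).
Larger α or larger power pushes the bounds away from ½. The interval is
advisory only: `allocation_interval` always computes the numeric t0 and
raises if the closed form ever fails to bracket it, rather than returning
a silently wrong interval. κ-equality is decided at relative tolerance
1e-12 to route the σ1 = σ2 branch.

**Balance diagnostics.** t0 = ½ ⇔ σ1 = σ2 ⇔ ∫F1² dF2 = ∫(1−F2)² dF1.
A sufficient condition is the mirror relation F1(a + x) = 1 − F2(a − x)
for some a (the treatment distribution is the reference flipped about a);
`balance_diagnostics` reports both integral sides and searches for the
mirror point — the only support-compatible candidate is
a = (min x1 + max x2)/2 — while F1 = F2 with a skewed shape shows the
integral equality can hold without the mirror. Note the mirror check
compares floating-point values exactly (tolerance 1e-9 on the cdfs), so
decimal data whose mirror is not binary-representable will honestly
report "no mirror".

## Monte-Carlo verification

The implemented test is the classical tie-corrected asymptotic WMW test:
p̂ from midranks of the observed data and

    T = √N (p̂ − ½) / √(σ̂² / (t̂(1−t̂))),
    σ̂² = Σ_k (R_k − (N+1)/2)² / (N²(N−1)),

rejecting when |T| > u_{1−α/2}. σ̂² is the exact permutation variance of
the rank sum given the observed tie pattern — for observed *random* data
the N − 1 divisor is the standard finite-sample form, in contrast to the
population divisor used for fixed synthetic distributions in the planning
step. No continuity correction is applied. All-tied data yield T = 0 and
no rejection.

`simulate_power` draws each replicate's groups with replacement from the
two synthetic distributions (multinomially, for frequency tables) and
reports the rejection fraction with its binomial standard error
√(p̂(1−p̂)/nsim). Replicate k uses a child generator spawned from the
global seed with spawn key (k,), so increasing nsim extends the replicate
stream without reshuffling earlier replicates; results are bit-identical
for a fixed seed. Replicates are ranked in vectorized batches of 512 for
speed.

What the resampling model does *not* emulate: sampling variability of the
prior information itself (the synthetic distributions are treated as
known), covariates, dropout, or any sequential element. A power estimate
of 0.80 here means: *if* future data really follow the synthetic
distributions, the planned design achieves 80 % power for this test.
Agreement with an independent implementation of the same procedure is
expected within Monte-Carlo error only, since RNG streams differ.

`allocation_curve` reproduces the allocation-rate sweeps at desk scale:
for each α (or power) on a grid it draws `ndraw` values per group from
Beta distributions as stand-ins for F1, F2 and records t0, N(t0), N(½).
The default ndraw = 1e5 (4e4 in the test suite) keeps runtimes in seconds
while leaving t0 stable to ~1e-3; monotonicity checks therefore allow
5e-3 Monte-Carlo slack.

## Numerical choices, in brief

- midranks via `scipy.stats.rankdata(method="average")`; normalized ecdfs
  via binary search on the sorted sample ((#< + #≤)/2n).
- normal quantiles via `scipy.stats.norm.ppf` in double precision.
- p = ½ is rejected as "no effect" at absolute tolerance 1e-12; all-tied
  pooled data (σ²* = 0) are rejected as degenerate before that check.
- variances are clipped at 0 to remove negative rounding dust in the
  grouped route.
- powers ≤ 0.5 trigger a warning at construction (the interval theory
  requires 1 − β > ½; `allocation_interval` refuses them outright).

## Known limitations

- Two groups only; no confidence intervals for p; no exact/permutation
  test and no studentized (Brunner–Munzel) variant of the test.
- The sample-size formula is a normal approximation; for very small
  computed N (< ~10 per group) the achieved power should be checked by
  simulation, which is exactly what `simulate_power` is for.
- The closed-form allocation bounds are derived under σ1 ≠ σ2 (or the
  σ_i = 0 special cases); near-equal variances are routed to the exact
  point ½ by the 1e-12 relative threshold.
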