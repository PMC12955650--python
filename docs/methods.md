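# Methods

## Model

`uvsdt` implements the unequal-variance Gaussian signal detection (UV-SDT)
rating model for yes/no detection. Internal evidence on target-absent
trials is X₀ ~ N(0, 1) (the fixed reference) and on target-present trials
X₁ ~ N(μ, σ). A strictly increasing set of 2n − 1 criteria partitions the
evidence axis into 2n ordered response categories — n rating levels crossed
with the yes/no decision, whose criterion is the middle cutpoint. The model
therefore predicts, for each stimulus class, a multinomial distribution
over the categories via Gaussian-CDF differences.

Derived indices:

- **d′ = z(hit) − z(fa)** from a single ROC point — valid as a sensitivity
  measure only if σ = 1.
- **d_a = μ·√(2/(1+σ²))** — mean separation standardized by the
  root-mean-square of the two SDs; reduces to d′ when σ = 1 and is
  invariant to criterion placement.
- **c = −(z(hit)+z(fa))/2** — response bias; positive = conservative.
- **AUC = Φ(d_a/√2)** — model-implied area under the type-1 ROC.

Because detection ROCs are asymmetric when σ > 1, single-point d′ is
criterion-dependent: it overestimates sensitivity for conservative
criteria and underestimates it for lenient ones. The point where the ROC
crosses the chance diagonal is k = μ/(1−σ); for σ > 1 the curve dips
*below* the diagonal at the lenient extreme, so an observer with
above-chance d_a can produce d′ ≤ 0. The **misevaluation index** d′ − d_a
quantifies this bias per subject and correlates with c across subjects.

## Pipeline

1. **Evidence strength.** Confidence ratings are used as ordinal strength
   directly, or discretized per subject into n quantile levels when the
   scale is continuous (type-7 quantiles; ties at a cutpoint go to the
   lower level). Response times are binned per subject into n quantile
   bins, fastest = strongest evidence for the chosen option; by default
   the cutpoints pool both responses ("pooled"), with a per-response
   variant ("within_response") available. Ties at an RT cutpoint go to
   the slower (weaker) bin.
2. **Rating table.** Trials are tabulated into a 2 × 2n frequency table
   ordered from strongest-yes to strongest-no. A constant 1/N (N = total
   trials) is added to every cell before fitting to keep boundary rates
   off 0 and 1. Padding is applied before the below-chance screen.
3. **Screening.** Subjects whose collapsed yes/no performance satisfies
   z(hit) − z(fa) ≤ 0 on the padded midpoint are excluded (the boundary
   counts as excluded; configurable). Subjects whose fit fails to
   converge under any requested evidence source are excluded afterwards.
4. **Fitting.** The multinomial log-likelihood Σ freq·log p is maximized
   over θ = (μ, log σ, c₁, log-gaps), an unconstrained parameterization
   that enforces σ > 0 and strict criterion ordering (minimum gap 1e-4).
   Predicted probabilities are floored at 1e-300 inside the log.
   Optimization is Nelder-Mead (fatol 1e-8, max 5000 evaluations) from a
   zROC-based initializer (σ₀ = 1/slope clipped to [0.2, 5],
   μ₀ = intercept·σ₀, criteria at −z(cumulative FA)) plus 3 restarts with
   N(0, 0.1²) jitter on θ; the best optimum wins. A fit counts as
   converged only if the optimizer reports success and σ̂ ∈ [0.05, 20] —
   estimates outside that band signal a degenerate table, not a usable σ.
5. **Group summaries.** Paired two-sided t-tests and Pearson correlations
   compare RT-based and confidence-based μ, σ, d_a across subjects
   (p-values uncorrected); percent differences use the confidence-based
   mean as denominator. The bias analysis correlates per-subject c with
   d′ − d_a.

The zROC least-squares slope (1/σ̂) is reported descriptively only; the
MLE is authoritative for σ. Empirical AUC uses the trapezoid rule with
(0,0)/(1,1) anchors; the model AUC identity is evaluated by adaptive
quadrature of hit dFA, which is what attains 1e-6 agreement with
Φ(d_a/√2) (a finite trapezoid grid cannot).

## Synthetic observers

`simulate` generates the data structure the analysis assumes: evidence
drawn from the two Gaussians, response = yes iff x > c₀, confidence level
given by the criterion interval containing x (criteria default to
symmetric placement around c₀ at gaps of 0.5), p(present) = 0.5. The RT
mechanism is this package's own choice — detection analyses assume only
that faster responses indicate stronger evidence for the choice made — and
is realized log-linearly:

    rt = exp(a − b·|x − c₀| + ε),  ε ~ N(0, τ²),  b > 0,

with defaults a = 0 (≈1 s at the criterion), b = 0.4, τ = 0.2. With τ = 0
the within-response RT order equals the evidence order exactly, so RT
quantile bins coincide with quantile bins of |x − c₀|; τ > 0 selectively
degrades the RT route, which is the mechanism behind RT-based σ estimates
being attenuated relative to confidence-based ones. Cohorts scatter μ and
c₀ normally and σ and the RT slope log-normally between subjects; the
confidence criteria shift rigidly with each subject's c₀.

What the generator does **not** emulate: sequential-sampling RT dynamics
(no drift-diffusion shape, no speed–accuracy trade-off), staircase
difficulty titration (which inflates σ by pooling difficulty levels),
lapses, base-rate or payoff manipulations, and any task-design effects on
RT precision. Passing tests therefore demonstrate correctness of the
estimator under its own assumptions and the direction of the RT-noise
attenuation — not that real RT data carry as much graded evidence as
confidence.

## Numerical and design choices

- Type-7 (linear-interpolation) quantiles everywhere, for determinism and
  order stability.
- Column order: index 0 = strongest yes, matching the left-to-right
  cumulative ROC construction; the midpoint (n-th point) is the overall
  yes rate by construction.
- z at rates exactly 0 or 1 is a hard error in the index functions;
  padding is the sanctioned remedy.
- RT binning pools both responses by default: faster-is-stronger is
  applied on a common clock; the within-response scheme is available
  where yes and no responses have different speed baselines.
- Degenerate inputs: identical RTs error by default (config:
  single-level fallback); all-equal confidence errors naming the subject;
  diagonal/degenerate zROCs fall back to a null-model initializer.
- Unit-test cohort sizes are chosen for stable sign-level behavior:
  recovery and RT/confidence agreement use 100 subjects × 1000 trials,
  replicate-level mechanism checks 10 × 30 subjects, the grid oracle 50
  random tables against a 21³ grid. Cohort fixtures include
  between-subject SD(μ) = 0.3 alongside SD(c₀) = 0.5: with criterion
  scatter alone the true d_a is constant across subjects and the
  RT-vs-confidence correlation of d̂_a reflects only shared estimation
  noise; sensitivity variance is what makes that correlation a meaningful
  agreement measure, and is what real cohorts have.

## Limitations

- Only the bi-Gaussian rating model is fit; no threshold or dual-process
  ROC variants, no equal-vs-unequal model comparison, and no standard
  errors on parameter estimates.
- Single-subject fits with few rating levels (n = 2) leave 1 residual
  degree of freedom; σ̂ is then noisy and the convergence band matters.
- The below-chance screen and the padding interact at very small N;
  padding shifts cumulative rates by O(1/N) (fitted μ moves < 0.05 for
  N ≥ 200 on simulated data).
- Type-2 (metacognitive) analyses such as meta-d′ are out of scope.
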