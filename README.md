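# uvsdt

Unequal-variance signal detection analysis of yes/no detection data,
using **response times or confidence ratings** as graded evidence.

## The problem

Detection studies routinely summarize performance with d′ = z(hit) −
z(fa), which assumes the target-present and target-absent evidence
distributions have equal variance. Detection ROCs are, however, typically
asymmetric: the target-present distribution is wider (σ > 1 in zROC
terms). Under that asymmetry, single-point d′ depends on where the
observer places their criterion — it **overestimates** sensitivity for
conservative criteria and **underestimates** it for lenient ones, and can
even read zero for an observer with genuinely above-chance sensitivity.
The bias-robust alternative is the unequal-variance index

    d_a = μ · √( 2 / (1 + σ²) ),      c = −( z(hit) + z(fa) ) / 2,

with μ, σ the mean and SD of the target-present evidence distribution
(target-absent fixed at N(0,1)). Estimating μ and σ requires a rating
ROC — and when no confidence ratings were collected, **response times can
stand in for them**: a faster response is a stronger indication of the
choice made, so per-subject RT quantile bins play the role of confidence
levels.

`uvsdt` implements the full pipeline: trial records → 2 × 2n rating
tables (confidence levels or RT bins, with 1/N cell padding and a
below-chance subject screen) → maximum-likelihood fit of the
unequal-variance Gaussian rating model → d_a, d′, c, AUC per subject →
group-level comparisons of the RT and confidence routes and the
criterion-vs-misevaluation (d′ − d_a) analysis. A synthetic UV-SDT
observer (`uvsdt.simulate`) generates trial data with the assumed
structure for validation and power exploration.

It is intended for psychophysicists and consciousness/metacognition
researchers analyzing yes/no detection tasks.

## Worked example

```python
import uvsdt as u

cfg = u.SimConfig(mu=1.5, sigma=1.5, c0=1.0, n_levels=3, n_trials=2000, seed=42)
trials = u.simulate_observer(cfg)          # stimulus, response, rt, confidence
trials = u.bin_rt(trials, 3)               # RT quantile bins, fastest = strongest
tab = u.pad_table(u.build_table(trials, 3, evidence="rt"))
fit = u.fit_uvsdt(tab)                     # unequal-variance MLE
ev = u.fit_evsdt_midpoint(tab)             # conventional midpoint indices
print(f"mu_hat    = {fit.params.mu:.3f}")
print(f"sigma_hat = {fit.params.sigma:.3f}")
print(f"d_a       = {fit.report.d_a:.3f}")
print(f"d_prime   = {ev.d_prime:.3f}")
print(f"c         = {ev.criterion_c:.3f}")
print(f"misevaluation (d' - d_a) = {u.misevaluation_index(fit, ev):.3f}")
```

prints

```
mu_hat    = 1.422
sigma_hat = 1.468
d_a       = 1.132
d_prime   = 1.362
c         = 0.296
misevaluation (d' - d_a) = 0.230
```

The generating observer has μ = 1.5, σ = 1.5 (true d_a = 1.18) and a
conservative criterion at +1. The RT-based fit recovers μ and σ from RT
bins alone; conventional d′ (1.36) overestimates the fitted d_a (1.13)
because the criterion is conservative (c > 0) — the misevaluation the
unequal-variance analysis corrects.

A command-line front end covers the same pipeline on CSV files
(`subject,stimulus,response,rt[,confidence]`):

```bash
uvsdt simulate --out run/ --seed 1 --n-subjects 20 --n-trials 1000
uvsdt fit run/trials.csv --out run/ --seed 1      # per-subject results CSV
uvsdt cohort run/trials.csv --out run/ --seed 1   # + group summary JSON
```

See `docs/methods.md` for the model, the RT generative mechanism, the
optimizer settings, and known limitations.

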