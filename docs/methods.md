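# Methods

## The unit of analysis

The package analyses a *closed* corpus: a fixed set of coded
publications whose within-corpus reference lists define a citation
digraph.  The unit of analysis is the **potential citation path**, the
ordered pair (citing *j*, cited *i*) such that *i* was available when
*j* was written.  Every realized citation is one path with outcome 1;
all other admissible pairs are paths with outcome 0.  Analysing paths
rather than citation counts lets cited-side characteristics enter a
binary regression while conditioning on what was actually available to
each citing author.

### Temporal admissibility

True submission dates are unobservable in bibliographic exports, so
admissibility is a configurable `TemporalRule`:

* default — compare online dates at the finest precision both ends
  share (months if available, else years); pairs equal at that
  precision are admitted in **both** directions, because neither order
  can be excluded and same-year citation demonstrably occurs;
* `admit_ties=False` — strict ordering (a stricter sensitivity rule);
* `lag_months=L` — the cited publication must precede the citing one by
  at least L months, emulating a submission-to-online lag (applied only
  when both ends carry month precision).

Realized citations that the rule would exclude are **force-included**
with a warning, never dropped: an observed citation proves its path was
possible.  All results record the rule used.

## Determinants of the cited publication

* **Study outcome** — statistical significance (yes / no / mixed / not
  reported; reviews present no new data and are always "not reported")
  and the authors' conclusion relative to the harm hypothesis (in line /
  not in line / mixed / unclear).
* **Tertile-categorized continuous determinants** — sample size,
  journal impact factor, affiliation count, reference count.  Cutoffs
  are empirical 1/3 and 2/3 type-1 (inverse-CDF) quantiles over
  publications; ties at a cutoff go to the lower category, so category
  sizes differ by at most one absent ties.  Reviews have no sample size
  and are excluded from the sample-size model (an eligibility flag, not
  a silent drop).
* **Authority** — per (author, year), the cumulative number of
  within-network citations received by that author's publications up to
  the end of the year, credited in full to every co-author; a
  publication's authority for a path is the maximum over its co-authors
  evaluated at the citing year minus one (only information available
  before the citing publication appeared; the offset and a per-year
  variant are configurable).  Authority varies per path and is
  tertile-categorized at path level.
* **Self-citation** — at least one normalized author key (lowercase
  ASCII "surname, initials"; diacritics stripped; no disambiguation
  beyond string match) shared by citing and cited publications.
* **Funding** — modelled as "not reported vs reported"; publications
  with no applicable funding are excluded from that model.
  **Corresponding-author sector** is modelled as private (industry or
  other) vs public (university or government).  **Gender** excludes
  unknown.
* **Concordance** — eligible only when both citing and cited
  conclusions are definite (in line / not in line); concordant iff
  equal.  How mixed/unclear conclusions should enter has no canonical
  answer; restricting to definite categories is the conservative
  choice.

Categorical covariates are treatment-coded against fixed reference
levels (significance = no, conclusion = not in line, design = narrative
review, lowest tertile, self-citation = no).

## The statistical model

With paths nested under citing publications,

  logit P(y_ij = 1 | u_j) = x_ij'β + u_j,  u_j ~ N(0, σ²).

The marginal log-likelihood per citing group is a one-dimensional
integral over the random effect, evaluated by K-node Gauss–Hermite
quadrature.  Numerical choices:

* **Adaptive centering** (default for fitting, K = 15): nodes are
  re-centred at each group's posterior mode with a Laplace scale,
  found by a vectorized Newton iteration.  This matters for the large
  citing groups of a 169-publication network, where fixed-node
  quadrature at K = 15 is only accurate to ~1e-5; the adaptive rule is
  accurate to ~1e-10 on the same fixtures.  Fixed-node quadrature is
  available (`adaptive=False`) and converges monotonically in K.
* **Optimization** is quasi-Newton (L-BFGS-B) over (β, log σ) from
  β = 0, log σ = 0, with the analytic gradient of the frozen-node
  objective; node centres are refreshed between rounds until the
  estimates stabilize, then Newton polishing drives the gradient norm
  below 1e-5 (the `converged` flag reports the actually achieved norm;
  log σ is bounded in [-10, 3] and a fit at the lower bound is reported
  as σ ≈ 0).
* **Standard errors** come from the numerically differentiated observed
  information (central differences of the analytic gradient); the σ
  standard error is delta-method-transformed from log σ.  Intervals are
  per-term Wald 95% (±1.96 SE, exponentiated); no multiplicity
  adjustment is applied.
* **Degenerate inputs** are diagnosed before fitting: constant
  outcomes, empty categories ("NA" rows, e.g. a funding category with
  no publications), zero-event indicator levels (monotone likelihood),
  zero-event reference cells in single-block designs, and rank-deficient
  designs (named collinear columns).  The analysis suite records these
  per determinant and continues.

The **crude** model per determinant contains only that determinant's
block; the **adjusted** model adds the four study-design indicators.
The **concordance** model is an ordinary (single-level) logistic
regression on eligible paths, fitted by IRLS (statsmodels GLM) — it
also serves as an independent cross-check: the random-intercept fit
with σ fixed at 0 reproduces it to 1e-6.  The **sensitivity analysis**
removes publications receiving more than a threshold number of
citations (default 50) in both roles, re-enumerates paths, rebuilds the
authority ledger and refits everything.

## The synthetic corpus generator

The generator emulates the reference network's shape so that every
pipeline stage, and the estimator itself, can be exercised without the
(undeposited) study data.  It is *not* fitted to the real corpus; it
copies printed descriptive marginals and encodes printed crude odds
ratios as generative truth.

* **Corpus shape** — 169 publications over 2002–2017 with geometric
  per-year intensity (factor 1.5, final year partial), month-resolution
  online dates, and a 6-month admissibility lag.  These choices were
  set once so that a corpus yields ~12k potential paths, a majority of
  publications after 2010, and ≥25% zero-citation publications on
  average — the printed corpus scale.  Attribute marginals (design,
  significance, conclusion, health outcome, funding, gender,
  affiliation, continent, suggestive titles) are iid draws from the
  printed category proportions; reviews get no sample size and unscored
  significance by construction.  Continuous determinants are lognormal
  with parameters placing the printed tertile cutoffs near the 1/3 and
  2/3 quantiles.  Authors are drawn uniformly from a 300-author pool
  (2 + Poisson(3) per publication), which yields a ~7–9% self-citation
  opportunity share; real co-authorship is more clustered, so the
  generator understates the clustering of self-citation paths.
* **Citation process** — simulated forward in time.  Each citing
  publication draws u_j ~ N(0, σ²) (default σ = 1.0 on the logit scale;
  no empirical variance component is published, so σ-dependent results
  are framed as recovery properties, not as reproductions) and
  realizes each admissible earlier publication with probability
  expit(β₀ + u_j + x'β_true).  The authority component is computed from
  citations realized in *earlier simulated years* — endogenous
  feedback, using the printed fixed category bounds (<3 / 3–26 / >26).
  Self-citation comes from actual author overlap.
* **Intercept calibration** — β₀ is calibrated to a target marginal
  rate (default 6.5%) by a fixed-point iteration (pilot pass →
  root-find → re-simulate), necessary because authority feedback makes
  the achieved rate depend on the intercept itself.  The same
  underlying uniforms are reused across passes, so output is a
  deterministic function of the seed; a single seed expands into
  per-stage substreams.
* **Preset effects** — the `bpa` preset sets every determinant's true
  log odds to the printed crude estimate.  Nuisance levels with no
  printed estimate (significance mixed / not reported, conclusion
  mixed / unclear) were fixed once at OR 1.57 / 1.3 / 1.25 / 1.5,
  loosely guided by the descriptive realized fractions; they enter
  models as extra indicator levels and are never recovery targets.
  The concordance effect defaults to zero (the published concordance
  analysis found none).
* A **TruthLedger** stored with every corpus holds the effects, the
  calibrated intercept, each group's random intercept and each path's
  linear predictor and relational covariates — sufficient to recompute
  every outcome probability exactly (property-tested).

## What recovery experiments do and do not show

`recovery_experiment` generates replicate corpora, fits the crude
random-intercept model per determinant, and aggregates bias, RMSE and
Wald coverage against the generative truth.  At full network scale
(100 replicates) the significance and conclusion effects are recovered
essentially unbiased (mean log-OR bias < 0.02).  Two deliberate,
verified caveats:

1. **Non-collapsibility of large odds ratios.**  With a 6.5% marginal
   rate, a true OR-5.14 exposure has ~20% event probability in the
   exposed cell.  The crude model marginalizes over the other
   (independently generated) cited-side effects, which attenuates the
   crude log-OR for self-citation by ≈0.06 — the same regime in which
   an odds ratio overstates a relative risk.  With all other effects
   switched off the estimator is unbiased for the same term, so this is
   a property of the crude estimand, not an estimator defect.  For the
   modest headline effects (OR ≈ 1.6) the fitted OR and the simulated
   relative risk agree within a few percent.
2. **Cited-side clustering.**  Omitted cited-side effects are shared by
   every path pointing at the same cited publication.  The model's only
   cluster term is the citing-side random intercept (as in the analysis
   the package implements), so Wald standard errors understate the
   replicate-to-replicate variance of crude estimates (observed spread
   ≈ 2× the reported SE under the full preset) and 95% intervals cover
   the truth in only ~77–90% of replicates, term-dependent.  Coverage
   is nominal when the other effects are absent.  The endogenous
   authority feedback further makes part of each determinant's crude
   association replicate-specific (mediation through who becomes an
   authority).  Real-data crude intervals produced by this model share
   the limitation.

Because the generator draws determinants independently (no printed
correlation structure exists to copy), passing recovery tests show the
estimator and pipeline are correct under the stated generative model;
they do not certify the published point estimates, which depend on the
real corpus's unobserved correlation structure.

## Other limitations

* Author-name normalization cannot split distinct authors sharing
  "surname, initials", nor merge variant spellings; the self-citation
  and authority determinants inherit this.
* Year-only dates make same-year ordering ambiguous; the both-directions
  default slightly over-counts potential paths relative to true
  submission-time availability, the strict rule under-counts.
* The plain-logistic concordance model ignores citing-side clustering,
  exactly as in the analysis it mirrors.
* No Bayesian fitting, GEE alternative, citing-side covariates or
  random slopes; graph layout/visualization is out of scope beyond
  GraphML export.
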