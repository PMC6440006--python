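# citebias

Citation-network analysis of **selective citation**: which
characteristics of a publication drive its chance of being cited within
a closed literature network?  The package was built around the coded
network of human-health studies on bisphenol A (BPA) — 169 publications,
12,432 potential citation paths, 808 realized citations — and is aimed
at meta-researchers studying citation bias and at statisticians who want
a tested, reproducible implementation of the dyadic citation model.

## The model

Every ordered pair (citing *j*, cited *i*) in which publication *i* was
available before *j* is a **potential citation path**; the outcome
*y<sub>ij</sub>* = 1 if *j*'s reference list contains *i*.  Paths
leading out of the same citing publication are not independent, so they
share a random intercept:

```
logit P(y_ij = 1 | u_j) = β₀ + x_ij'β + u_j ,   u_j ~ N(0, σ²)
```

where *x<sub>ij</sub>* describes only the **cited** publication: study
outcome (statistical significance; authors' conclusion in line with the
harm hypothesis), study design, sample-size / impact-factor /
affiliation / reference-count tertiles, funding reporting,
corresponding-author attributes, the time-varying **authority** of its
most-cited co-author, and **self-citation** (an author shared between
citing and cited).  The marginal likelihood integrates the random
effect by adaptive Gauss–Hermite quadrature; effects are reported as
odds ratios with Wald 95% intervals, crude and adjusted for study
design.  A plain logistic model tests whether *concordance* of
conclusions between citing and cited publications predicts citation,
and a sensitivity analysis re-runs everything after removing
highly cited hub publications.

Because the real coded corpus is not publicly deposited, the package
ships a **synthetic corpus generator** whose generative model is
exactly the model above, with configurable true effects, endogenous
year-by-year authority accumulation, and a preset (`bpa_preset()`)
encoding the published network's marginals and crude odds ratios — so
estimator correctness and parameter recovery are testable end to end.

## Worked example

```python
from citebias import run_analysis_suite
from citebias.synthetic import bpa_preset, generate
from citebias.reporting import suite_tables

cfg = bpa_preset(seed=42)          # study-shaped generator, known truth
corpus, truth = generate(cfg)      # 169 publications + ground-truth ledger
suite = run_analysis_suite(
    corpus, rule=cfg.rule,
    determinants=("significance", "conclusion", "self_citation"))
print(suite_tables(suite)[1].to_string(index=False))
```

prints (abridged)

```
169 publications, 11794 potential paths, 795 realized (6.7%)
  determinant        level            crude         adjusted
 significance          yes 1.45 (1.18-1.77) 1.47 (1.20-1.80)
   conclusion      in_line 1.48 (1.18-1.87) 1.35 (1.07-1.71)
self_citation          yes 5.09 (4.18-6.19) 5.24 (4.30-6.39)
concordance: 1.25 (1.01-1.54)
```

Each row is the odds ratio for citation of a cited publication with
that attribute versus the reference level ("crude" from a univariate
model, "adjusted" adding study-design indicators).  Here the generator
truth was OR 1.57 for a significant outcome, 1.57 for an in-line
conclusion and 5.14 for self-citation, so a single replicate recovers
the effects to within sampling error.

The same pipeline runs from the shell on real or simulated corpora:

```sh
citebias simulate --preset bpa --seed 7 --out-dir out/sim
citebias analyze  --input out/sim/corpus.json --lag-months 6 --out-dir out/ana
citebias recover  --replicates 100 --seed 7 --out out/recovery.json
```

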