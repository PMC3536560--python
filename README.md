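# nccpv

Predictive values — post-test probabilities — and their confidence
intervals from **nested case–control** diagnostic accuracy studies, plus a
Monte-Carlo engine that measures how well six competing interval
constructions actually cover.

## The problem

A diagnostic cohort cross-classifies subjects by true disease status and a
dichotomous index-test result (cells *a* = TP, *b* = FP, *c* = FN,
*d* = TN). When the index test is expensive (a biomarker assayed from
banked material, say), a nested case–control design measures it only in
all cases and in a random fraction of the cohort's controls. Because the
cohort is fully enumerated, the predictive values are still estimable by
re-inflating the sampled control cells with the inverse sampling fraction
*sf* = (b₁+d₁)/(b+d):

```
PPV = a / (a + b₁/sf)          NPV = (d₁/sf) / (c + d₁/sf)
```

These equal the Bayes expressions
PPV = Se·p / (Se·p + (1−Sp)(1−p)) and
NPV = Sp(1−p) / (Sp(1−p) + (1−Se)p) with the plug-in sensitivity,
specificity and cohort prevalence — an exact algebraic identity. The hard
part is the **standard error**: the inflated denominator pretends more
subjects were observed than actually were, so a naive binomial SE on the
weighted counts is too small. This package implements six interval
constructions for this situation:

1. **Naive Wald** — binomial SE of the uncorrected observed proportion on
   the observed denominator.
2. **Corrected Wald** — binomial SE of the corrected predictive value,
   still on the observed denominator.
3. **Stratified percentile bootstrap** — resample cases within cases and
   sampled controls within controls, recompute the weighted estimate,
   take empirical percentiles.
4. **Delta method (probability scale)** — propagate the binomial errors of
   Se and Sp through the Bayes formula at the (known) cohort prevalence.
5. **Weighted logistic regression** — logit P(D|x) = α + βx with case
   weight N₁/N and control weight (N₁/N)/sf; interval on the logit scale
   from the model-based covariance.
6. **Delta method (logit scale)** — approach 4 on the log-odds scale:
   Var(logit PPV) = (1−Se)/(Se·n₁) + Sp/((1−Sp)·n₀).

All six share the same point estimate; they differ only in the interval.
The simulation engine replays the two-stage design (source population →
multinomial cohort → nested sample) and reports per-approach empirical
coverage and mean interval width against the acceptability band
`level ± 2·sqrt(level·(1−level)/B)`.

Intended users: biostatisticians and clinical epidemiologists planning or
analysing two-phase / nested case–control diagnostic accuracy studies.

## Worked example

A cohort of 440 subjects (TP=30, FP=100, FN=10, TN=300); the nested sample
keeps all 40 cases and 40 of the 400 controls, so sf = 0.1:

```sh
nccpv estimate --a 30 --c 10 --b1 10 --d1 30 \
               --cohort-controls 400 --cohort-size 440 --seed 7 --round 4
```

```
approach,target,estimate,lower,upper,se,scale,level,truncated,continuity_corrected
1,ppv,0.2308,0.0966,0.365,0.0685,natural,0.95,False,False
1,npv,0.9677,0.8336,1.0,0.0685,natural,0.95,True,False
2,ppv,0.2308,0.1002,0.3613,0.0666,natural,0.95,False,False
2,npv,0.9677,0.913,1.0,0.0279,natural,0.95,True,False
3,ppv,0.2308,0.1566,0.3827,,percentile,0.95,False,False
3,npv,0.9677,0.9474,0.9841,,percentile,0.95,False,False
4,ppv,0.2308,0.1303,0.3312,0.0512,natural,0.95,False,False
4,npv,0.9677,0.9501,0.9854,0.009,natural,0.95,False,False
5,ppv,0.2308,0.1033,0.4385,0.4882,logit,0.95,False,False
5,npv,0.9677,0.8725,0.9925,0.7539,logit,0.95,False,False
6,ppv,0.2308,0.1456,0.3457,0.2887,logit,0.95,False,False
6,npv,0.9677,0.9446,0.9814,0.2887,logit,0.95,False,False
```

Every approach returns PPV = 30/130 ≈ 0.23 and NPV = 300/310 ≈ 0.97 — the
same values the full cohort would give — but the intervals differ
substantially: the naive Wald interval (approach 1) is the widest, the
delta-method intervals (4, 6) the narrowest. `se` is reported on the scale
named in `scale` (approaches 5 and 6 quote the SE of the logit).

The same counts work through the library API:

```python
from nccpv import NestedSample, EstimatorConfig, estimate_all

sample = NestedSample(a=30, c=10, b1=10, d1=30,
                      cohort_controls=400, cohort_size=440)
for est in estimate_all(sample, cfg=EstimatorConfig(seed=7)):
    print(est.approach, est.target.value, round(est.estimate, 2),
          (round(est.lower, 3), round(est.upper, 3)))
```

Coverage simulations run from a built-in DVT (deep-vein-thrombosis)
source-population catalogue, e.g. the D-dimer test at cohort prevalence
0.1 with one control per case:

```sh
nccpv simulate --test d_dimer --prevalence 0.1 --ratio 1 \
               --replicates 200 --boot-reps 200 --seed 7 \
               --targets ppv --out-prefix demo
```

which writes a tidy `demo.csv` (per approach: coverage, mean width, mean
estimate, excluded replicates), a `demo.json` summary and a run manifest.
A grid of tests × prevalences × ratios can be given in one YAML config via
`--config`.

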