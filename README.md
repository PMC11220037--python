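# eeanet

Tools for linking working-memory task behavior to large-scale brain-network
activation through a computational lens: Bayesian diffusion-model estimation
of the **efficiency of evidence accumulation (EEA)** from n-back trial data,
cross-validated prediction of EEA from cortical activation maps, and
network-level association statistics with cluster-aware inference — plus a
synthetic cohort generator with known ground truth that validates the whole
chain end to end.

It is written for cognitive neuroscientists and methodologists who analyze
task-fMRI studies with behavioral computational models (multi-site
developmental cohorts with family structure are the motivating design) and
for anyone who wants a tested, reusable reference implementation of the
individual pieces.

## The model at the core

Each n-back trial is modeled as a two-boundary Wiener diffusion: evidence
accumulates at drift rate *v* (unit diffusion) between absorbing boundaries
0 and *a*, starting at *z·a*; the upper boundary is the correct response for
every stimulus class. Per load condition (0-back, 2-back) the model has
eight free parameters — class drifts *v*<sub>target</sub>,
*v*<sub>novel</sub>, *v*<sub>lure</sub>, boundary separation *a*,
non-decision time *t₀* with uniform variability *st₀*, start point *z*, and
a contaminant-omission probability — with non-responses modeled as a mixture
of contaminants and responses censored by the 2-s window:

P(omission) = p_contam + (1 − p_contam) · P(T_decision + T_nondecision > 2 s).

Per-subject posteriors are sampled by blockwise differential-evolution MCMC
under truncated-normal informative priors, iterating until split-chain
rhat < 1.1. **EEA** for a condition is the mean of the posterior medians of
the three class drifts; the headline index averages the two conditions.
EEA is then predicted from parcel-level activation by principal-components
regression whose out-of-sample performance is a *cross-validated partial
correlation* (components and outcome residualized on age, age², sex,
race/ethnicity, motion and motion² with training-fold betas; K chosen by
nested 5-fold CV), and related to 7-network activation means with clustered
bootstrap confidence intervals.

## Worked example

```python
import numpy as np
from eeanet import (DriftDiffusionModel, load_default_priors,
                    simulate_trials, table1_preset, generate_cohort,
                    CrossValidatedPCR)
from eeanet.cohort import build_task_schedule, true_parameters_for_subject

# --- fit one synthetic subject ------------------------------------------
cohort = generate_cohort(table1_preset(n_subjects=50), seed=11)
row = cohort.truth.iloc[0]
trials = simulate_trials(true_parameters_for_subject(row),
                         build_task_schedule(row.subject_id, seed=1), seed=2)
res = DriftDiffusionModel(trials, load_default_priors()).fit(seed=3)
print(res.eea())
print(res.summary().loc[["0-back.v_novel", "2-back.v_novel"]].round(3))
```

```
EEARecord(subject_id='sub00000', eea_0back=1.5925719469379873,
          eea_2back=1.6183989204830738, eea_mean=1.6054854337105304,
          converged=True)
                median     sd   rhat
0-back.v_novel   2.146  0.365  1.086
2-back.v_novel   2.614  0.392  1.062
```

The record holds the drift-based EEA index per load condition and their
average, in evidence units per second; `converged` certifies max rhat < 1.1.
(This subject's generating drifts for novel stimuli were 2.43 and 2.71, well
inside the posterior intervals.)

```python
# --- predict true EEA from the 2-0 activation contrast ------------------
import pandas as pd
cohort = generate_cohort(table1_preset(n_subjects=2000), seed=5)
y = pd.Series(cohort.truth.eea_mean.to_numpy(),
              index=cohort.truth.subject_id.to_numpy())
X = cohort.activation["2-0"]
model = CrossValidatedPCR(y, X, cohort.covariates, scheme="loso")
results = model.fit(seed=3)
print(f"mean out-of-fold partial r = {results.mean_r:.3f}")
```

```
mean out-of-fold partial r = 0.532
```

The preset plants a population R² of 0.36 for EEA given the full 2-0 map, so
a perfectly estimated model would approach r = 0.6 out of sample; 0.53
reflects the estimation noise of PCA + OLS at n = 2000 under
leave-one-site-out folding.

A command-line interface mirrors the library:

```bash
eeanet simulate-cohort --n-subjects 1000 --seed 7 --out cohort/
eeanet predict --activation cohort/activation_2minus0.tsv --eea eea.tsv \
       --covariates cohort/covariates.tsv --scheme loso --out pred/
eeanet networks --activation-dir cohort/ --eea eea.tsv \
       --covariates cohort/covariates.tsv --stats corr --out networks.tsv
```

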