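# emoconn

Effective connectivity of emotional face processing in depression
remission, re-implemented as a fully synthetic, fully tested pipeline.

## The problem

Remitted depression (rMDD) shows few regional activation differences from
health in classic fMRI contrasts, yet mood-congruent processing biases
persist. The hypothesis this pipeline operationalizes is that the
difference lives in *connectivity*: in a right-hemisphere face-processing
network — V1, fusiform gyrus (FG), amygdala (AMY), lateral orbitofrontal
cortex (OFC) — the pattern of emotion-induced coupling changes is
*reversed* between groups across valence. Healthy controls viewing sad
faces (and rMDD viewing happy faces) show modulation of bidirectional
OFC↔AMY and OFC↔FG connections; healthy controls viewing happy faces (and
rMDD viewing sad faces) show modulation of a single FG–OFC connection
(backward OFC→FG in controls, forward FG→OFC in rMDD).

`emoconn` is for methods researchers who want a self-contained,
reproducible testbed for this style of analysis: every stage — simulation,
subject inclusion, model inversion, model selection, seed-based
connectivity — is importable, seeded, and exercised end-to-end on
synthetic cohorts whose ground truth encodes the reversal.

## What it implements

- **Task design** — the 22-block order `NHNSNFNRSNHNFNRFNSNHNR` (21-s
  blocks, 462 s, TR 2.1 s, 218 volumes), boxcar inputs and HRF-convolved
  GLM regressors.
- **Generative model** — bilinear neural dynamics
  `dx/dt = (A + Σ u_j B_j)x + Cu` with a balloon–windkessel BOLD
  observation per region (1.5 T coefficients), integrated by exact
  matrix-exponential propagators for the neural states (numba-compiled).
- **Synthetic cohorts** — ~21 HC and ~22 rMDD subjects with
  subject-level parameters drawn around stable population means, observation
  noise at a stated SNR, drift, MADRS-like symptom scores, and optional
  weak-OFC subjects for the inclusion rule to reject.
- **ROI stage** — DCT high-pass filter (cutoff = 2× the longest
  same-condition onset interval, 378 s here), faces-vs-rest activation
  t-test, the "p < .05 within 14 mm of every group maximum" inclusion rule,
  and first-eigenvariate extraction from voxel spheres.
- **Model space** — 7 structural candidates, then 21 emotion-modulation
  profiles on the fully interconnected winner, partitioned into 7 families
  (family 1 = six single edges incl. models 2 and 5; family 7 = three
  double-bidirectional models incl. model 21).
- **Inversion** — variational Laplace: Gauss-Newton ascent on the free
  energy F (accuracy − complexity) with Levenberg damping, EM noise-
  precision updates, shrinkage priors; F is exact on linear-Gaussian
  reductions and monotone over accepted steps.
- **BMS** — fixed-effects group log evidence, family-level inference with
  equal within-family prior splitting, within-family winners; RFX
  (variational Dirichlet) as an option.
- **PPI** — amygdala-seed psychophysiological interactions (seed ×
  task-contrast regressor), group comparison over an FG+OFC composite with
  Bonferroni correction, symptom-score correlations.

## Worked example

```python
from emoconn import RunConfig, run_all

config = RunConfig(n_hc=8, n_rmdd=8, weak_ofc_fraction=0.0,
                   out_dir="runs/demo", master_seed=7)
report = run_all(config)
print(report.to_markdown())
```

This simulates both cohorts on the published design, applies the inclusion
rule, fits all 21 models per subject and emotion (~20 min on one CPU),
runs family-level BMS per group × emotion, and the amygdala PPI. Output:

```
| Group | Emotion | Winning family | Winning model | Family posterior | Model posterior |
|---|---|---|---|---|---|
| HC | happy | F1 | Model 5 | 0.526 | 0.998 |
| HC | sad | F7 | Model 21 | 1.000 | 1.000 |
| rMDD | happy | F7 | Model 21 | 1.000 | 0.509 |
| rMDD | sad | F6 | Model 14 | 0.931 | 1.000 |

- HC: 6 of 8 subjects included
- rMDD: 6 of 8 subjects included
- PPI happy, amygdala->FG: HC > rMDD (n.s.)
- PPI happy, amygdala->OFC: rMDD > HC (n.s.)
- PPI sad, amygdala->FG: HC > rMDD (n.s.)
- PPI sad, amygdala->OFC: HC > rMDD (significant)
```

Reading the table: each row is one group × emotion Bayesian model
selection. Three of the four winners express the built-in reversal
directly — the HC-sad pattern (family F7, model 21: bidirectional OFC↔AMY
+ OFC↔FG modulation) recurs as the rMDD-happy winner, and HC-happy selects
the single backward OFC→FG connection (family F1, model 5). The rMDD-sad
cell selects model 14, a superset neighbour of its true model 2 (the
forward FG→OFC edge plus one spurious FG→AMY edge): at this cohort size
one subject whose true-model fit lands in a wrong optimization basin can
tip the fixed-effects sum toward such a neighbour — the known accuracy
limit of local free-energy optimization discussed in `docs/methods.md`.
Posteriors are family posteriors and within-family model posteriors. The
PPI directions on the OFC target agree with the reversal — amygdala–OFC
connectivity is higher in HC for sad faces and higher in rMDD for happy
faces — while the amygdala–FG direction for happy faces is noise (neither
group's happy truth modulates an AMY–FG edge directly; the composite
FG+OFC difference carries the effect). The excluded subjects failed the
activation inclusion rule at this noise level (SNR 1), which is the rule
working, not an error.

The same stages are scriptable from a shell (`emoconn design`,
`emoconn simulate`, `emoconn fit`, `emoconn bms`, `emoconn ppi`,
`emoconn run --seed 7 --out runs/demo`).

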