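# Methods

`morphdbn` implements a generative deep-learning analysis of regional
brain morphometry for schizophrenia case-control studies: a deep belief
network (DBN) is pretrained on confound-adjusted FreeSurfer features,
fine-tuned into a binary classifier, evaluated by nested repeated
cross-validation against a linear SVM, probed generatively to rank
class-discriminative brain regions, and finally applied to an
intermediate first-episode psychosis (FEP) cohort.

## Data model and preprocessing

The unit of analysis is a subject x 113 feature table: 68 mean cortical
thickness values (34 Desikan-Killiany regions per hemisphere) and 45
`aseg.stats` structure volumes (FreeSurfer v5-era structure list).  The
column order is pinned in `morphdbn.schema` — thickness (lh then rh,
atlas row order) followed by volumes (aseg row order) — so that model
weights and reports are column-stable across runs.  FreeSurfer stats
parsers are column-position based, matching FreeSurfer's own layout
(`aseg.stats`: Volume_mm3 in column 4, StructName in column 5;
`aparc.stats`: StructName in column 1, ThickAvg in column 5).

Each feature is regressed on age and sex in one joint OLS fit
(`feature ~ 1 + age + sex`, sex coded 0 = female / 1 = male) and
replaced by its residual, then z-scored with the sample (n-1) standard
deviation.  By default both transforms are estimated **across all
subjects**, which mirrors the single-sample analysis this package
reproduces; `fit_rows` restricted to a training fold gives a
leakage-free mode, and tests verify that in that mode the fitted
transforms are bit-identical under arbitrary perturbation of held-out
rows.

## RBMs and pretraining

Layer one is a Gaussian-Bernoulli RBM with unit conditional variance —
the standard choice for z-scored inputs — and all higher layers are
Bernoulli.  Training is contrastive divergence with one alternating
Gibbs step (CD-1): weights initialized N(0, 0.01^2), biases zero,
minibatches of 10, ten epochs, one data shuffle per epoch.  The
negative-phase reconstruction uses conditional means rather than
samples (a common variance-reduction convention), and the last short
minibatch is used with gradients averaged over its actual size.
Momentum defaults to 0 during pretraining and weight decay to 0; both
are configurable.

For models with at most 20 units the partition function is enumerable;
`exact_log_likelihood` (free-energy marginalization + brute-force
partition sum) and `exact_loglik_gradient` (data-expected minus
model-expected sufficient statistics) serve as independent oracles.
The test-suite checks the free-energy path against a second, direct
enumeration of the (v, h) joint, matches the analytic gradient to
central finite differences at 1e-5 relative error, and requires CD-1
to raise the exact likelihood of tiny models over initialization in at
least 8 of 10 seeds.

## Fine-tuning

The pretrained stack initializes a feedforward classifier (logistic
hidden units, weights copied verbatim) topped by a two-unit softmax
initialized at zero.  Fine-tuning minimizes cross-entropy plus an L2
penalty of 5e-5 on weights (not biases) for 200 epochs of minibatch-10
SGD with Nesterov momentum and RMSPROP per-parameter scaling.  Choices
the recipe leaves open, fixed here:

- momentum ramps linearly 0.5 -> 0.9 over the first 10% of epochs, then
  stays at the 0.9 maximum (ramping is the standard companion of
  Nesterov momentum in this literature);
- RMSPROP decay 0.9, epsilon 1e-6;
- no dropout and no early stopping;
- prediction ties (exactly equal softmax outputs) break toward HC.

The minibatch loop is compiled with numba for throughput; a pure-numpy
forward/backward pass (`loss_and_gradients`) is retained as the
reference implementation, and tests assert that one full-batch compiled
update equals the reference RMSPROP + Nesterov update to ~1e-9 relative
and that the reference gradients match finite differences at 1e-6
relative.  Every stochastic operation takes an explicit seed and is
bit-reproducible on one platform.

## Generative probe

The probe attaches an associative top RBM whose visible layer
concatenates the penultimate activation probabilities with a one-hot
(HC, SCZ) label block, trained by CD-1.  Clamping the two label units
and running 1000 alternating Gibbs updates draws from the model's
class-conditional distribution; a single deterministic down-pass
(activation probabilities through Bernoulli layers, conditional means
at the Gaussian bottom) maps the final state to morphometry space in
z-score units.  The per-feature |SCZ - HC| prototype difference, ranked
descending, is the region attribution; an optional back-transform via
the stored preprocessing model restores mm / mm^3 units.

Design choices: the default averages 100 independent chains per class
(a single chain — the literal procedure — is seed-noise dominated;
`n_chains=1` restores it); chains initialize from a uniform random
penultimate state with the label clamped; the probe samples through the
**pretraining** generative weights — fine-tuned recognition weights are
never written back into the generative stack.  The clamped sampler is
validated against exact enumeration on a 14-unit associative RBM
(20,000 chains within 4 standard errors), which is the module's
load-bearing oracle.

The probe's generative stack is pretrained for 100 epochs rather than
the 10-epoch classifier default.  On cohorts of a few hundred subjects,
ten epochs (~150 CD updates per layer) leave a 3-layer stack too close
to its initialization for class structure to reach the penultimate
layer, and the probe then ranks noise; the classifier is unaffected
because supervised fine-tuning follows.  This is a deliberate
divergence between the discriminative recipe and the generative probe
and only affects how well-fit the sampled model is.

## Evaluation design

Nested repeated cross-validation: 5 repeats of stratified 3-fold CV
(stratification avoids degenerate folds at a ~226-subject scale; a
non-stratified mode exists).  Per fold, two folds train; the held-out
fold is split 50/50 at random (stratified, odd remainders balanced)
into a validation half that drives the hyperparameter search and a test
half scored exactly once by the retrained best configuration.  SCZ is
the positive class; reports carry sensitivity, specificity, balanced
accuracy, error rate (all %, undefined rates reported as None, never
0) and AUC as the normalized Mann-Whitney U with ties counting 1/2.

The search mixes three proposal strategies per iteration — 70% a
Tree-of-Parzen-Estimators-style density-ratio proposal (top-25% /
rest split, per-dimension Gaussian KDE, best ratio among 20 candidate
draws), 20% annealing-style Gaussian perturbation of the incumbent with
a shrinking scale, 10% uniform random — over units per hidden layer
(quantized uniform [10, 200]) and the two learning rates (uniform
[1e-4, 1e-1]).  The Parzen proposal is deliberately simple; its
fidelity target, asserted in tests, is beating pure random search on
smooth objectives at equal budget, not equivalence with any external
optimizer.  The linear baseline is an SVC (libsvm) with C chosen on the
validation half from {0.001, 0.1, 1, 10, 100, 1000}; ties resolve to
C = 1.  The FEP cohort is excluded from all training and search and is
preprocessed with the transforms fitted on the HC/SCZ sample; both the
fraction classified SCZ and the complementary HC fraction are reported,
since "error rate" is ambiguous for a cohort with no assumed label.

## Synthetic cohorts

`generate_cohort` draws tables from the linear-Gaussian model

    x_ij = mu_j + beta_age_j (age_i - mean age) + beta_sex_j sex_i
           + delta_j g_i + eps_ij,

g = 0 (HC), 1 (SCZ), lambda (FEP, default 0.5), with delta_j = d *
sigma_j on the planted regions so d is a standardized mean difference
(default d = 1.0, a conventional large effect chosen for testability).
Residuals have equicorrelation 0.2 by default (one shared subject-level
factor) — region-wise morphometry shares substantial global variance,
and a diagonal model would be unrealistically easy.  Default group
sizes (83 HC / 143 SCZ / 32 FEP), age distributions (35.49 +/- 11.08,
37.12 +/- 10.99, 27.09 +/- 7.97 years) and male fractions (67%, 66%,
46%) copy the target cohort's demographics so confounding is realistic;
the default planted regions are the ten regions the analysis is built
to surface (cerebellar white matter, lateral ventricle, entorhinal,
rostral anterior cingulate, inferior parietal, insula, transverse
temporal, inferior temporal, lateral orbitofrontal, putamen).
Thickness baselines sit near 2.5 mm (sd 0.15 mm, -0.005 mm/yr age
slope, no sex effect) and volumes take structure-typical magnitudes
(sd 10%, -0.3%/yr, +4% male) so back-transformed reports are
plausible.

What the generator does **not** emulate: scanner/site effects,
non-Gaussian or heteroscedastic residuals, nonlinear age effects,
anatomically structured covariance beyond equicorrelation, and
segmentation failures.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes — not that the
effect sizes or rankings would transfer to real clinical data.

## Problem sizes

Tests run the full experimental design at reduced budgets chosen for a
desk-scale machine: the headline end-to-end check uses the default
cohort at d = 1.5 with 5x 3-fold CV and a 50-iteration search; the
permuted-label null uses 2 repeats with a 5-iteration search (the
search budget cannot manufacture test-set signal on a null cohort);
`scripts/acceptance.py` uses a 15-iteration search for the main run.
The full 2000-iteration search of the original design remains available
through `n_iter`.

## Known limitations

- CD-1 is a biased maximum-likelihood surrogate; the equilibrium
  distribution of a CD-1-trained RBM can visibly distort marginals at
  high learning rates (quantified in the label-marginal test).
- The probe reports prototype differences, not effect sizes; its
  ranking is meaningful only relative to the model's own fit.
- With 113 features and a few hundred subjects the network operates far
  from the regime where depth demonstrably helps; the depth sweep
  harness reproduces the design of that comparison, not its outcome.
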