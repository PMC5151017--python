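# morphdbn

Deep-belief-network analysis of regional brain morphometry for
schizophrenia case-control studies.

Structural MRI studies of schizophrenia report widespread but variable
differences in cortical thickness and subcortical volume.  `morphdbn`
implements, as a reusable and tested pipeline, a generative
deep-learning approach to this problem: region-wise FreeSurfer features
(68 Desikan-Killiany mean thicknesses + 45 `aseg` structure volumes)
are adjusted for age and sex and z-scored; a deep belief network — a
stack of restricted Boltzmann machines trained greedily by contrastive
divergence — is pretrained on the features and fine-tuned into a
HC-vs-SCZ classifier; nested repeated cross-validation with a
mixed-strategy hyperparameter search scores it against a linear SVM;
and, because the DBN is generative, clamping class labels in an
associative top layer and Gibbs sampling yields class-conditional
morphometry prototypes whose per-region differences rank the brain
regions the model finds most discriminative.  A first-episode psychosis
(FEP) cohort can then be classified by the trained model to ask whether
early-stage patients look more like chronic patients or controls.

The clinical data such a study uses are not publicly deposited, so the
package ships a synthetic cohort generator that reproduces the
statistical structure of the analysis — group-dependent region means,
age/sex confounds, correlated Gaussian noise, and an intermediate third
group — with known ground truth, making every stage testable.

## Model summary

- **Gaussian-Bernoulli RBM** (first layer, z-scored inputs):
  p(h_j = 1 | v) = sigma(W_j v + c_j), v | h ~ N(W^T h + b, I).
- **CD-1 pretraining**: ΔW ∝ ⟨h v^T⟩_data − ⟨h v^T⟩_recon, minibatch 10,
  10 epochs, weights N(0, 0.01²), biases 0.
- **Fine-tuning**: 2-unit softmax head; cross-entropy + 5·10⁻⁵ L2;
  200 epochs of minibatch-10 SGD with Nesterov momentum (max 0.9) and
  RMSPROP scaling.
- **Search**: units per layer ~ quantized-uniform [10, 200], both
  learning rates ~ uniform [10⁻⁴, 10⁻¹]; proposals 70% Parzen-style /
  20% annealing / 10% random, maximizing validation AUC-ROC in
  stratified 3-fold CV repeated 5 times (validation/test = random
  halves of the held-out fold).
- **Generative probe**: clamp the one-hot label units of the
  associative top RBM, run 1000 alternating Gibbs steps, down-pass to
  feature space, rank regions by |SCZ − HC| prototype difference.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a synthetic cohort with a planted effect (standardized mean
difference d = 1.5 in ten regions), preprocess it, and run the
generative probe:

```sh
morphdbn simulate --config sim.yaml --out cohort.csv --truth truth.json --seed 1
morphdbn preprocess --in cohort.csv --out cohort_z.csv
morphdbn probe --table cohort_z.csv --out probe.json --seed 0
```

with `sim.yaml` containing `effect_size_d: 1.5`.  The probe prints:

```
rank	feature	|SCZ - HC| (z units)
1	Right-Cerebellum-White-Matter	0.9751
2	lh_inferiorparietal	0.9326
3	rh_rostralanteriorcingulate	0.9206
4	rh_entorhinal	0.9015
5	lh_lateralorbitofrontal	0.8969
6	rh_inferiortemporal	0.8660
7	Left-Putamen	0.8643
8	lh_transversetemporal	0.8348
9	rh_insula	0.7896
10	Right-Lateral-Ventricle	0.7651
```

All ten planted regions (listed in `truth.json`) head the ranking: the
difference between the class-conditional prototypes the generative
model produces is concentrated on exactly the regions that carry the
planted group effect, in z-score units of the preprocessed features.

A cross-validated accuracy estimate for the same table
(`morphdbn evaluate --table cohort_z.csv --config run.yaml --out report.json`)
prints a summary row with balanced accuracy, sensitivity, specificity,
error rate and AUC-ROC aggregated over the 15 fold evaluations, e.g.
balanced accuracy ≈ 90% on this strongly separated synthetic cohort,
and ≈ 50% when the labels are shuffled.

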