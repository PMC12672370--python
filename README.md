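# cyclebrain

Whole-brain spatiotemporal analysis of structural brain dynamics across the
menstrual cycle, for dense-sampling ("precision imaging") studies: a few
individuals scanned near-daily for a month with serum estradiol and
progesterone assayed at every session.

The pipeline answers three questions for such a study:

1. **How does the brain change day to day?**  All individuals' per-session
   gray-matter volume maps (or cortical-thickness vectors) are concatenated,
   centered per individual, and decomposed with a singular value
   decomposition, `X = U diag(sigma) V'`.  Each component is a
   *spatiotemporal pattern*: unit-norm spatial weights `v_k` over voxels and
   session-wise temporal scores `u_k`, with variance fraction
   `f_k = sigma_k^2 / sum sigma_j^2`.  Components explaining at least ~10%
   of the variance are retained, and a penalized cubic-spline GAM
   (`score = beta0 + f(test day)`, basis dimension k = 10) tests whether
   each pattern fluctuates over the sampled month.
2. **Are the fluctuations hormonal?**  Each retained pattern's standardized
   scores are regressed on the square-root hormone level
   (`score = beta0 + beta1 * sqrt(hormone)`), cross-checked with Spearman
   rank correlation (exact p for n <= 7), with Benjamini-Hochberg FDR within
   each individual; an association counts only when both routes are
   FDR-significant.  Voxel-wise, the same question is asked per location
   with a GLM whose t map is enhanced by threshold-free cluster enhancement
   (TFCE, E = 0.5, H = 2) and tested against a within-individual permutation
   null of the map-wide maximum at FWE P < 0.01.
3. **Do endocrine profiles differ between individuals?**  One-way MANOVA on
   (estradiol, progesterone, progesterone-to-estradiol ratio) with Pillai's
   trace and Roy's largest root, post hoc ANOVAs and Bonferroni-corrected
   pairwise t-tests; cycles are classified ovulatory when peak progesterone
   exceeds 15.9 nmol/l.  The ratio uses both hormones in pmol/l:
   `R = 1000 * P[nmol/l] / E[pmol/l]`.

Because real studies of this kind have tiny n and non-shareable raw MRI, the
package ships first-class synthetic generators: parametric hormone-cycle
templates (typical, short estradiol-dominant endometriosis cycle,
progesterone-suppressed oral-contraceptive cycle, male control) and phantom
image stacks with planted, hormone-coupled spatiotemporal components.  Every
stage of the pipeline is verified against these known ground truths and
against independent oracles (Gram-matrix eigendecomposition, exhaustive rank
permutation, closed-form TFCE integrals, flood-fill labeling, Monte-Carlo
calibration).

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import numpy as np
from cyclebrain import default_study_design, SpatioTemporalSVD, associate_all

# four simulated individuals: 25/30/24/25 sessions, three planted components
hormones, stacks, planted = default_study_design(seed=7)

model = SpatioTemporalSVD().fit(stacks)
print("variance fractions:", np.round(model.variance_fractions_[:5], 3))

scores = {ind: {p.index: p.temporal_std[sl] for p in model.retained_}
          for ind, sl in model.blocks_}
for r in associate_all(scores, hormones):
    if r.component == 1 and r.significant:
        print(f"{r.individual_id:16s} comp1 ~ {r.predictor:12s} "
              f"beta1={r.beta1:+.4f} p_fdr={r.p_beta_fdr:.4f} rho={r.rho:+.2f}")
```

prints

```
variance fractions: [0.502 0.201 0.102 0.003 0.003]
typical          comp1 ~ estradiol    beta1=+0.0969 p_fdr=0.0302 rho=+0.70
typical          comp1 ~ progesterone beta1=+0.4934 p_fdr=0.0000 rho=+1.00
typical          comp1 ~ ratio        beta1=+0.2997 p_fdr=0.0000 rho=+0.85
typical_28andme  comp1 ~ estradiol    beta1=+0.1038 p_fdr=0.0263 rho=+0.53
typical_28andme  comp1 ~ progesterone beta1=+0.5114 p_fdr=0.0000 rho=+1.00
typical_28andme  comp1 ~ ratio        beta1=+0.2938 p_fdr=0.0000 rho=+0.91
endometriosis    comp1 ~ estradiol    beta1=+0.1959 p_fdr=0.0000 rho=+1.00
endometriosis    comp1 ~ progesterone beta1=+0.6953 p_fdr=0.0000 rho=+0.63
oc               comp1 ~ estradiol    beta1=+0.5758 p_fdr=0.0000 rho=+1.00
oc               comp1 ~ ratio        beta1=-2.3616 p_fdr=0.0000 rho=-0.84
```

Three components are retained (50.2/20.1/10.2% of variance, matching the
planted 50/20/10), and the headline dissociation is recovered: the dominant
pattern tracks **progesterone** in the two typical cycles (rho = 1.00 at the
planted coupling) but **estradiol** in the estradiol-dominant endometriosis
and OC cycles.  Correlated predictors flag alongside the coupled one — the
ratio is progesterone-driven, so it accompanies progesterone in typical
cycles and moves oppositely under OC — exactly the structure such studies
report.

## Command line

```bash
cyclebrain simulate-study --seed 7 --out study/          # phantom study on disk
cyclebrain run-all --manifest study/study.yaml --out results/
cyclebrain endocrine --hormones study/hormones.tsv --out results/
cyclebrain masswise --manifest study/study.yaml --hormone progesterone \
    --scope pooled --n-perm 1000 --alpha 0.01 --seed 42 --out results/
```

`run-all` writes the component summary, per-session scores, GAM table,
association table, spatial maps (raw and display-thresholded NIfTI) and a
run log with the config hash; reruns with the same seed and config are
byte-identical.

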