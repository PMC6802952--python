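# schemarsa

Spatiotemporally resolved representational similarity analysis (RSA) of
*schema-based coding*: do visual cortex responses to isolated scene
fragments sort themselves by where each fragment typically sits within a
natural scene?

The package is built for the paradigm in which six natural scenes (three
indoor, three outdoor) are each cut into a 3 (vertical) × 2 (horizontal)
grid, yielding 36 fragment conditions viewed at central fixation. It takes
multivariate neural responses to those fragments — fMRI voxel patterns per
ROI, or epoched EEG — and carries them to the conclusion-bearing
statistics: predictor-RDM regression weights, their group-level
significance across ROIs and time, and covariate residualization against
feature-model RDMs. A synthetic-data generator with planted
representational structure stands in for recorded data, so the entire
pipeline is testable end to end.

## The method

1. **Neural RDMs.**
   *fMRI:* the dissimilarity of conditions *i, j* is the split-half
   cross-validated correlation difference. Runs are split into halves *A*,
   *B*; with Fisher-transformed Pearson correlations *z(r)* between
   half-averaged patterns,

   d(i,j) = ½[z(r<sub>iA,iB</sub>) + z(r<sub>jA,jB</sub>)] − ½[z(r<sub>iA,jB</sub>) + z(r<sub>jA,iB</sub>)],

   averaged over all 10 equal splits of 6 runs. Expected 0 when the
   conditions are indistinguishable; above 0 when discriminable.
   *EEG:* d(i,j) at each time point is the leave-one-trial-out accuracy of
   a two-class LDA (pooled covariance, shrinkage toward identity) on the
   17 posterior channels at that sample; chance 0.5.

2. **Predictor RDMs.** Binary model matrices over the 630 condition pairs:
   vertical location (0 iff same vertical level; 198 zero pairs),
   horizontal location (306 zero pairs), and category/scene (0 iff same
   scene; 90 zero pairs), plus a graded |Δvertical| variant and a
   cross-scene-type pair mask (324 indoor×outdoor pairs) under which
   category cannot be modelled.

3. **GLM.** Each neural RDM is vectorized (lower triangle), z-scored, and
   regressed on the three predictors (OLS + intercept), one beta per
   predictor per subject and ROI/time point. Feature-model control
   ("residualization") partials a bank of layer RDMs (1 − correlation over
   unit activations) out of the analysis before re-estimating the betas.

4. **Inference.** fMRI: one-tailed one-sample t-tests on betas,
   Bonferroni-corrected across ROIs. EEG: threshold-free cluster
   enhancement (E = 0.5, H = 2) of the group t time course, corrected by a
   10,000-iteration sign-permutation max-statistic null, thresholded at
   Z > 1.64; onset/peak latencies with bootstrap CIs. A sliding-window MDS
   movie visualizes the emerging representational geometry.

## Worked example

```python
import schemarsa as sr

sset = sr.build_stimulus_set()                      # 36 fragments
truth = sr.GroundTruth(weights={"vertical": 1.0, "horizontal": 0.0, "category": 1.0})
ds = sr.simulate_fmri(sset, n_subjects=20, n_voxels=100, n_runs=6, truth=truth, seed=1)
rdms = sr.dataset_rdms(ds)                          # (20, 36, 36) cross-validated RDMs
res = sr.run_glm_suite(rdms, sset, analysis="full")
stat = sr.group_ttest(res.betas[:, 0, :])
for name, t, p in zip(res.predictor_names, stat.t, stat.p_uncorrected):
    print(f"{name:<10s} t(19) = {t:6.2f}   p = {p:.2g}")
```

```
vertical   t(19) =  35.15   p = 4.7e-19
horizontal t(19) =  -2.43   p = 0.99
category   t(19) =  36.33   p = 2.5e-19
```

The planted vertical-location and scene-category structure is recovered as
strongly positive group betas, while the absent horizontal effect stays at
(here, slightly below) zero — the same logic the pipeline applies to
recorded data, where a positive vertical beta in a scene-selective ROI is
the signature of schema-based sorting.

The same flow runs from the shell:

```bash
schemarsa all --config config.yaml          # simulate → RDMs → GLM → stats
schemarsa simulate --seed 3 out/bundle.h5   # or stage by stage
schemarsa rdm-eeg out/bundle.h5
```

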