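# latentcortex

Nonlinear latent representations of developmental resting-state surface fMRI.

Resting-state fMRI of fetuses and newborns is usually analysed with linear
decompositions (group-ICA maps, cortical parcellations), but the perinatal
brain changes so rapidly that linear bases capture its activity poorly.
`latentcortex` implements an alternative: a β-variational autoencoder whose
encoder compresses each cortical activity frame into 256 latent variables and
whose decoder maps latent vectors back to the cortex.  Around that core the
package provides the full analysis pipeline:

- **Geometric reformatting** (`latentcortex.grid`) — an invertible, injective
  assignment of every cortical vertex to a cell of a regular 2-D grid (one
  image channel per hemisphere), so that image convolutions apply to surface
  data.  Because the assignment is injective, inverse∘forward is the identity
  on cortical vertices.
- **The β-VAE** (`latentcortex.vae`) — five strided convolutions and a dense
  head to the posterior N(μ_z, σ_z), a mirror decoder, and training by

  &nbsp;&nbsp;&nbsp;&nbsp;L(x) = ‖x − x′‖² + β · D_KL( N(μ_z, σ_z) ‖ N(0, I) )

  with the reparameterization trick and Adam.  Implemented directly in NumPy
  (im2col convolutions, explicit backpropagation, gradients verified against
  finite differences).
- **Linear baselines** (`latentcortex.linear`) — spatial-ICA and parcellation
  bases A with pseudoinverse encoding Y = A⁺X and reconstruction X̃ = AY.
- **Reconstruction evaluation** (`latentcortex.recon`) — reconstruction
  degree (per-frame Pearson r over cortical vertices, Fisher-z aggregated),
  geodesic Gaussian surface smoothing, FWHM similarity profiles that measure
  a model's implicit smoothing, covariate-adjusted correlations, and
  inter-session consistency (partial r and ICC(2,1)).
- **Age prediction** (`latentcortex.agepred`) — latent functional
  connectivity (covariance of every latent pair, 32,640 edges), FDR feature
  selection, linear support-vector regression, affine bias adjustment on a
  validation split, repeated tenfold cross-validation, the single-feature
  global-network-strength model, and cross-acquisition transfer.
- **Network mapping** (`latentcortex.networks`) — temporal ICA (extended
  Infomax) on concatenated latent timecourses, projection of each latent
  basis to the cortex by random-scaling covariance through the decoder, sign
  fixing, display thresholding, and cross-group basis matching with
  reproducibility curves.
- **Group contrasts** (`latentcortex.contrast`) — component-variance vs age
  correlations with FDR, young/median/old splits, dual-regression group
  bases, and group-difference maps computed by subtracting in *latent* space
  before decoding.
- **Synthetic cohorts** (`latentcortex.synthetic`) — two-hemisphere icosphere
  meshes and surface-fMRI cohorts with known ground truth: K smooth spatial
  networks, network covariance varying linearly with age at scan, AR(1)
  timecourses, additive noise, and acquisition profiles emulating a fast
  multiband protocol versus a conventional one.  The generator manifest is
  the recovery oracle for the whole test suite — real infant cohorts are
  access-restricted.

## Worked example

`examples/` contains one narrative script per capability.  For instance:

```bash
python examples/02_train_vae_and_reconstruct.py
```

trains a desk-scale model on 2,000 reformatted frames from a 40-network
synthetic cohort and prints

```
epoch-mean loss: 1249.5 (first) -> 241.3 (last)
held-out reconstruction degree: VAE=0.916, spatial ICA (k=30)=0.893
effective smoothing of the VAE reconstruction: 6 mm FWHM
```

the training curve, the Fisher-averaged per-frame correlation between
held-out scans and their reconstructions (the 256-latent model beats the
rank-30 linear basis), and the FWHM at which the reconstruction is most
similar to explicitly smoothed data — the model's implicit smoothing level.
`examples/03_age_prediction.py` then prints, for a 120-scan cohort,

```
MAE = 1.75 +/- 0.40 weeks (chance 5.37)
r^2 = 0.88, pooled correlation = 0.93
```

mean absolute error of cross-validated age prediction from latent FC against
the error of always predicting the mean age, and
`examples/04_network_mapping_and_group_contrast.py` recovers the generative
networks through the decoder:

```
best |r| of each generative network among the 30 component maps: [0.94 0.78 0.79 0.82 0.85]
```

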