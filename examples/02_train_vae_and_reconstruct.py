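"""Train a small beta-VAE on grid-reformatted frames and score reconstruction.

Trains on 1,200 frames from a synthetic cohort, then compares held-out
reconstruction degree (per-frame Pearson r between original and
reconstructed cortical patterns, Fisher-averaged) against a rank-30
spatial-ICA linear basis, and diagnoses the model's implicit smoothing with
the FWHM similarity profile.
"""

import numpy as np

from latentcortex.grid import GridSequence, build_grid_mapping, from_grid, to_grid
from latentcortex.linear import fit_linear_basis, linear_encode, linear_reconstruct
from latentcortex.recon import fisher_mean, reconstruction_degree, smoothing_profile
from latentcortex.synthetic import default_truth, make_mesh, simulate_cohort
from latentcortex.vae import VAEConfig, build_vae, decode, encode, train_vae

mesh = make_mesh(3)
mapping = build_grid_mapping(mesh, (32, 32))
truth = default_truth(mesh, K=40, seed=0)  # dozens of networks, like real data
train, _, _ = simulate_cohort(mesh, truth, 10, T=200, tr_seconds=0.8, seed=1)
test, _, _ = simulate_cohort(mesh, truth, 1, T=100, tr_seconds=0.8, seed=99)

frames = np.concatenate([to_grid(ts, mapping).frames for ts in train])
config = VAEConfig(epochs=20, learning_rate=1e-3, beta=0.2, seed=0)
model = build_vae(config, mapping.grid_shape)
model, curve = train_vae(model, GridSequence(frames=frames,
                                             validity=mapping.validity), config)
print(f"epoch-mean loss: {curve[0]:.1f} (first) -> {curve[-1]:.1f} (last)")

ts = test[0]
rec = decode(model, encode(model, to_grid(ts, mapping)).mu)
back = from_grid(GridSequence(frames=rec, validity=mapping.validity), mapping)
am = mesh.analysis_mask
vae_score = fisher_mean(reconstruction_degree(ts.values, back.values, mask=am))

basis = fit_linear_basis([t.values for t in train], "spatial_ica", k=30, seed=0)
lin = linear_reconstruct(linear_encode(ts.values, basis), basis)
lin_score = fisher_mean(reconstruction_degree(ts.values, lin, mask=am))
print(f"held-out reconstruction degree: VAE={vae_score:.3f}, "
      f"spatial ICA (k=30)={lin_score:.3f}")

_, effective_fwhm, _ = smoothing_profile(ts.values, back.values, mesh)
print(f"effective smoothing of the VAE reconstruction: {effective_fwhm:.0f} mm FWHM")
print("Higher reconstruction degree at comparable smoothing means the latent "
      "code captures pattern structure, not just blur.")
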