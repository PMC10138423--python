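# idpgen

Generative conformational sampling for intrinsically disordered and
ordered proteins.

Intrinsically disordered proteins (IDPs) have no fixed tertiary
structure; they exist as broad conformational ensembles that neither
crystallography nor cryo-EM can capture, and sampling them exhaustively
with molecular dynamics (MD) is computationally expensive. `idpgen`
implements a variational-autoencoder (VAE) route around that cost: train
a generative model on the conformations visited by a *short* stretch of
simulation, then sample the model's latent space to reconstruct and
extend the ensemble a *longer* simulation would have produced.

The package is aimed at computational structural biologists who have a
multi-model PDB trajectory (or want a synthetic stand-in) and want to
train, sample, evaluate and cluster with a few commands or a short
script.

## Model

Each trajectory frame is superposed onto the first frame (backbone
Kabsch fit), reduced to heavy atoms, flattened to a 3N-vector and
MinMax-normalized per feature over the training frames,
c_norm = (c − min c)/(max c − min c) — an exactly invertible transform.
The VAE encoder (dense ReLU stack, default 1024–256–64–16) maps x to a
diagonal Gaussian posterior N(μ(x), σ²(x)) over a 2-D latent space; the
reparameterized draw z′ = μ + σ·ε is decoded by the mirrored stack into
a reconstruction x′. Training minimizes

    L = E[‖x′ − x‖²] − ½ E[ Σ_j (1 + log σ_j² − μ_j² − σ_j²) ]

reconstruction error plus the KL divergence from the posterior to the
unit-Gaussian prior. A plain autoencoder baseline (linear bottleneck of
width ⌈⅔·N_res⌉, reconstruction loss only, latent sampling via a fitted
multivariate Gaussian) is included for comparison.

Ensembles are judged frame-by-frame against the held-out part of the
trajectory: heavy-atom RMSD √(1/N Σ‖r⁰_i − r_i‖²) and Spearman ρ between
the paired flattened coordinate vectors, plus radius-of-gyration
profiles, PCA co-projection, backbone (φ, ψ) dihedrals, a Wilcoxon
rank-sum comparison between models, and k-medoid clustering on the
all-against-all RMSD matrix to pick representative structures. See
`docs/methods.md` for conventions and caveats.

## Worked example

```python
import idpgen as ig

# a 2,000-frame synthetic MD stand-in: 50-residue CA chain drifting
# from extended (Rg ~ 20 A) to compact (Rg ~ 9 A) conformations
ensemble = ig.generate_trajectory(ig.ChainSpec(n_residues=50, n_frames=2000, seed=7))

# align to frame 1, flatten heavy atoms, split first 50% / last 50%
model, test = ig.ConformationalAutoencoder.from_ensemble(
    ensemble, train_fraction=0.5,
    config=ig.ModelConfig.vae_default(epochs=200, seed=0),
)
result = model.fit()
print(result.summary())

# one generated conformation per held-out frame
generated = result.generate(source=test, mode="paired", seed=1)
reference = ig.Ensemble(result.topology, ig.unflatten(test.raw()))
report = ig.evaluate_pairs(reference, generated)
print(report.summary())
```

Output (numbers from the run above):

```
VAE conformational generator
  architecture : 150 -> 1024 -> 256 -> 64 -> 16 -> 2 -> 16 -> 64 -> 256 -> 1024 -> 150
  latent dim   : 2
  input dim    : 150 (3 x heavy atoms)
  epochs       : 200  batch 64  lr 0.001
  final losses : reconstruction 3.701661  kl 0.458141  total 4.159802

paired evaluation over 1000 conformation pairs (unfitted RMSD)
  RMSD [A]     : mean 8.675  min 5.081  median 8.430  max 25.524
  Spearman rho : mean 0.898  min 0.767  median 0.903  max 0.976
  Rg [A]       : reference mean 10.799  generated mean 11.535
```

Reading this: each held-out compact conformation is regenerated from its
latent encoding with an average heavy-atom deviation of ~8.7 Å (a
faithful-but-coarse reconstruction, not a copy — these are disordered
50-residue chains), the coordinate ranks correlate strongly (mean ρ
0.90, well above chance), and the generated ensemble's mean radius of
gyration tracks the reference within ~7%. Unconditional sampling from
the prior (`mode="prior"`) gives a markedly higher mean RMSD of 11.6 Å
on the same test set — the latent encoding, not chance, carries the
conformational information.

The same workflow is available from the shell:

```sh
idpgen simulate --n-residues 50 --n-frames 2000 --seed 7 --outdir sim/
idpgen train --input sim/trajectory.pdb --train-fraction 0.5 --epochs 200 --outdir run/
idpgen generate --checkpoint run/checkpoint.npz --data run/test_split.npz --outdir gen/
idpgen evaluate --reference run/test_reference.pdb --generated gen/generated.pdb --outdir eval/
idpgen cluster --input gen/generated.pdb --outdir clusters/
idpgen scan --input sim/trajectory.pdb --axis latent_dim --values 2,7,12,17,22 --outdir scan/
```

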