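# Methods

## Problem and model

`idpgen` treats enhanced conformational sampling of proteins — above all
intrinsically disordered proteins (IDPs), which exist as broad
conformational ensembles rather than a single fold — as a generative
modelling problem. A molecular-dynamics (MD) trajectory is an ordered
set of conformations; the early part of a trajectory tends to contain
more extended and diverse states, the later part relatively compact
ones. The package trains a generative model on the chronologically first
fraction of an ensemble and asks whether it can reproduce the held-out
remainder, i.e. whether a short simulation plus a generator can stand in
for a long simulation.

Each aligned frame is reduced to its heavy-atom Cartesian coordinates,
flattened to a vector of length 3N (atom-major, axis-minor) and
MinMax-normalized per feature over the training frames:

    c_norm = (c − min(c)) / (max(c) − min(c))

The stored minima/maxima make the transform exactly invertible;
normalized values of held-out or generated frames may leave [0, 1] and
are deliberately not clipped so the back-transform stays exact. Constant
features map to 0 and invert to their stored constant.

The variational autoencoder (VAE) encodes x through a stack of dense
ReLU layers (default 1024–256–64–16) into a diagonal Gaussian posterior
q(z|x) = N(μ(x), σ²(x)) over a 2-dimensional latent space, draws
z′ = μ + σ·ε with ε ∼ N(0, I), and decodes z′ through the mirrored
stack (linear output layer) into a reconstruction x′. Training
minimizes

    L = E[‖x′ − x‖²]  +  E[ −½ Σ_j (1 + log σ_j² − μ_j² − σ_j²) ]

i.e. the squared reconstruction error summed over the 3N features and
averaged over the batch, plus the closed-form KL divergence from the
posterior to the unit-Gaussian prior. Two scaling conventions in this
loss deserve a note because they decide whether the model works at all:

* The KL term follows the standard closed form with the −½ factor and
  conventional sign; the variant occasionally quoted without the −½ and
  with the sign flipped would be unbounded below under minimization.
* The reconstruction term is the *per-sample squared norm* averaged
  over the batch (the E[‖x′−x‖] form with n = sample size), not the
  per-feature mean. With a per-feature mean the KL term outweighs
  reconstruction by a factor ≈ 3N and the posterior collapses onto the
  prior — we verified this empirically (KL → ~10⁻⁴, encoded means carry
  no information, paired and prior sampling become indistinguishable).
  The norm form is exactly the Gaussian-decoder evidence lower bound
  (decoder variance ½) and trains non-degenerately.

The plain autoencoder (AE) baseline uses the same encoder/decoder idea
with a linear bottleneck (default width ⌈⅔·n_residues⌉) and the
reconstruction term only. Because its latent space carries no prior, new
conformations are sampled by fitting a maximum-likelihood multivariate
Gaussian to the encoded training data and decoding draws from it; a
singular covariance is jitter-regularized with a warning.

The networks are implemented directly on numpy (hand-written backward
pass, Adam). At these layer sizes that trains in seconds to minutes on
one CPU core and is bit-reproducible under a seed on a given platform;
cross-platform bit-equality is not promised.

### Sampling modes

* **paired** — one generated conformation per source frame: encode,
  perturb (z′ = μ + σ·ε; a `noise_scale` of 0 gives the deterministic
  reconstruction), decode, back-transform. This underlies all per-pair
  statistics.
* **prior** — decode z′ ∼ N(0, I) (VAE only; the AE raises and points
  to the latent-Gaussian route).
* **latent_gaussian** — the AE sampling route described above.

## Evaluation

* **Per-pair RMSD** (heavy atoms): √(1/N Σ‖r⁰_i − r_i‖²), computed by
  default *without* re-superposition, because generated and reference
  coordinates already live in the common frame established by aligning
  the trajectory to its first frame, and the decoder reconstructs
  absolute coordinates in that frame. A fitted variant (per-pair Kabsch)
  is available and is the default for clustering, where generated
  structures may drift in the global frame.
* **Per-pair Spearman ρ** over the two flattened 3N coordinate vectors,
  using the exact 1 − 6Σd²/(n(n²−1)) form for tie-free ranks and
  Pearson-on-average-ranks when ties occur (the closed form is exact
  only without ties). Zero-variance input yields NaN (undefined), not an
  exception, so one degenerate pair cannot abort a report.
* **Model comparison** via the two-sided Wilcoxon rank-sum
  (Mann–Whitney) test on two per-pair RMSD samples — exact null for
  group sizes ≤ 20, normal approximation with continuity correction
  above (scipy's implementation; an exhaustive permutation oracle
  cross-checks it in the tests).
* **Radius of gyration** (mass-weighted) per frame, **PCA
  co-projection** (basis fitted on the reference ensemble only, both
  ensembles projected), and **backbone dihedrals** (φ = C–N–CA–C,
  ψ = N–CA–C–N, IUPAC sign convention, NaN at termini/missing
  atoms/degenerate geometry) for Ramachandran-style checks.

## Clustering and representatives

All-against-all heavy-atom RMSD (fitted by default) feeds a seeded
PAM-style k-medoids: D²-weighted seeding, then alternating
nearest-medoid assignment (ties to the lowest cluster index; each medoid
anchors its own cluster) and medoid updates (member minimizing summed
within-cluster distance), until stable or 100 iterations. The objective
never increases. Representative structures are the medoids of the three
largest clusters at the smallest k ∈ [3, k_max] whose top-3 coverage
reaches 80%. Note that at k = 3 the top-3 clusters are all clusters, so
that rule is satisfied trivially at k = 3 whenever clustering succeeds;
the search and the warning branch exist for degenerate configurations
and for callers that raise the lower bound.

Energy-minimization refinement of generated structures is out of scope;
`geometry_report` provides the corresponding sanity check instead
(consecutive CA–CA distances outside [2.9, 4.1] Å; non-bonded heavy-atom
pairs closer than 2.0 Å, where non-bonded means residue separation ≥ 2).

## Synthetic trajectories

Real MD data for this protocol is large and not redistributable, so the
package ships a generator whose output has the statistical properties
the pipeline relies on, with known ground truth:

* Chains are correlated random walks with *exact* bond lengths
  (default 3.8 Å CA–CA). Bond direction i mixes the previous direction
  (weight = persistence p), an isotropic random direction (1 − p) and,
  as p drops, a bias toward the chain centroid (attraction, default
  0.15). The first bond is deterministic (+x), so p = 1 yields
  identical straight rods.
* A per-frame persistence schedule (default 0.6 → 0.1 across the
  trajectory) produces the extended→compact drift. The defaults were
  chosen against physical anchors for a 50-residue disordered chain:
  early frames Rg ≈ 19–26 Å (expanded-coil regime; the experimental
  IDP scaling R₀·N^0.588 gives ≈ 25 Å), late frames Rg ≈ 9.4 Å
  (the dense-packing/globule limit for 50 residues is ≈ 9–10 Å).
* In the freely-jointed limit (p = 0, attraction 0) the ensemble obeys
  the ideal-chain law ⟨Rg²⟩ ≈ N·b²/6, which anchors the Rg machinery to
  a closed form.
* Multi-basin ensembles scatter frames (iid Gaussian noise, default
  0.5 Å) around k independently generated seed conformations and return
  ground-truth labels; construction requires the seeds' pairwise fitted
  RMSD to exceed 5·σ·√3 and errors otherwise, stating the requirement.
* One master seed spawns a separate substream per frame, so frame i is
  reproducible independent of the total frame count.
* `ideal_helix` builds an exact N/CA/C/O backbone from internal
  coordinates (NeRF placement) at prescribed (φ, ψ) — the fixture for
  validating the torsion code.

What the generator does *not* emulate: excluded volume, secondary
structure, side chains, solvent, thermodynamic weights, or realistic
kinetics. Passing tests on these fixtures therefore demonstrates that
the pipeline's machinery is correct and that the learning signal exists
under the stated statistical conditions — not that the model
reproduces real IDP thermodynamics.

## Numerical choices

* Scaling is fitted on the training split only (leak-free); whether the
  source work normalized before or after splitting is unstated.
* Encoder parameterizes log σ² (clipped to ±15 for stability);
  σ = exp(½ log σ²).
* Optimizer Adam (β₁ 0.9, β₂ 0.999), lr 10⁻³, batch 64, He
  initialization from the run seed; defaults exposed in `ModelConfig`.
* `ModelConfig` defaults to 10 epochs. The *reference study runs* in
  the test suite and acceptance script train 200 epochs: their fixture
  has only 1,000 training frames, and what transfers across dataset
  sizes is the optimization step count, not the epoch count — 200
  epochs ≈ 3,200 Adam steps, comparable to a few epochs at the dataset
  sizes the protocol was designed around.
* Kabsch rotations are proper by construction (SVD sign correction);
  < 3 selected atoms or collinear selections raise.
* PDB coordinates outside the fixed-width %8.3f range raise instead of
  truncating.
* k-medoids ties: nearest-medoid ties go to the lowest cluster index;
  degenerate D² seeding (all mass on chosen points) falls back to a
  uniform draw among the rest.

## Known limitations

* Flattened Cartesian input loses bonded/chemical structure; generated
  conformations can violate local geometry (hence `geometry_report`)
  and are meant to be refined externally before structural
  interpretation.
* Reconstruction of held-out frames that lie outside the training
  envelope is biased toward the training distribution; on the drifting
  synthetic fixture the paired-generated mean Rg typically exceeds the
  test-set mean by ≈ 4–17% depending on the random seed — generated
  ensembles err on the extended side, as is also observed when this
  protocol is applied to real MD data.
* Same-platform, not cross-platform, bit reproducibility.
* The evaluation RMSD convention (no per-pair refit) and the per-pair
  Spearman over coordinate vectors follow the protocol this package
  implements; both have fitted/alternative variants exposed where the
  original choice is ambiguous.
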