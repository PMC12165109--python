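# Methods

## Model overview

`diffmcgen` couples two denoising diffusion chains on one timestep clock
`t = 1..T`:

* a categorical chain on the one-hot node tensor `X` (atom types) and edge
  tensor `E` (bond types; channel 0 is the explicit "none" category, the
  diagonal is fixed to "none", and `E` is kept symmetric by noising only the
  upper triangle and mirroring);
* a variance-preserving Gaussian chain on 3D coordinates, restricted to the
  zero-center-of-mass (CoM) subspace because translations of a free-floating
  molecule are unidentifiable.

Molecules are heavy-atom graphs with implicit hydrogens over the alphabet
{C, N, O, F} (max valences 4/3/2/1), the convention of small-organic
generative benchmarks; an explicit-hydrogen mode is available by declaring
"H" in the alphabet. One canonical SMILES dialect (the toolkit default) is
used for every identity comparison package-wide.

## Noise processes

**Discrete.** `Q_t = alpha_t I + (1 - alpha_t) 1 m^T` with `m` the training
marginal over categories ("marginal noise"), so `m Q_t = m` exactly and fully
noised graphs resemble random graphs with realistic type frequencies. The
cumulative retention follows the cosine schedule (`s = 0.008`); a linear
schedule and a uniform-noise variant sit behind config flags. The exact
posterior `q(x_{t-1} | x_t, x0)`, marginalized over a soft predicted `x0`, is
computed per candidate clean category and renormalized; it reduces to a delta
at `x0` for `t = 1` and to the `x0`-projected prior when the chain is
uninformative.

**Continuous.** Per-step coefficients satisfy `alpha_t^2 + sigma_t^2 = 1`,
sharing the cosine family with the discrete chain (the squared cumulative
retention equals the discrete chain's `alpha_bar`). Noise is projected to the
zero-CoM subspace at every draw; a full reverse trajectory stays in the
subspace to 1e-9. Reverse steps go through the implied clean coordinates
`x0_hat = (x_t - sigma_bar_t eps_hat)/alpha_bar_t`, which are clipped to a
15 Å sphere: with an imperfect noise prediction the unclipped recursion
multiplies by `1/alpha_t` per step and inflates exponentially, while for
molecule-sized geometries and a competent predictor the clip is inactive (the
step is then algebraically the standard VP posterior mean).

## Denoisers

**Discrete (graph transformer).** Node, edge and global streams. Attention
logits get an additive per-head bias from the edge stream; the H-vector of
head scores at each node pair is recombined by a static `H x H` map
(identity-initialized) plus a rank-`r` query/key-dependent map
(zero-initialized), both before and after the softmax; the composed maps also
drive the edge-stream update. Conditioning (property targets, dynamic
weights, sinusoidal timestep, global features `y`) enters twice: concatenated
into the node input/global stream, and through adaptive instance
normalization (zero-initialized affines, so conditioning starts as plain
instance norm). Two per-node structural scalars — degree and valence sum
derived from the current edge state — are appended to the node input; they
make valence violations directly visible and were decisive for sampling
validity. Default: 2 layers, 4 heads, rank 2, widths 64/32/32. Edge output
logits are symmetrized by averaging `(i,j)` and `(j,i)`.

The global features `y` are: cycle counts of lengths 3–6, the 5 smallest
nonzero Laplacian eigenvalues (zero-padded), the number of connected
components, formal-charge and valence histograms, and the heavy-atom weight
sum / 100. All are permutation-invariant; the weight sum deliberately avoids
toolkit sanitization so `y` is defined for invalid intermediate graphs.

**Continuous (equivariant).** Geometry enters only as rigid-motion invariant
scalars — radial basis distances, the cosine of the angle to the nearest
reference neighbor, mean neighbor angles, distances from the CoM — plus
per-edge orthonormal frames from Gram–Schmidt on (edge vector, reference
neighbor vector, cross product). Learned invariant coefficients multiply the
frame axes and are attention-averaged over neighbors; the result is projected
to zero CoM. Equivariance is therefore exact by construction (verified to
float precision), and frames/invariants are computed outside the autodiff
graph: parameter gradients flow only through the scalar networks. Degenerate
(collinear or neighbor-less) edges are flagged and contribute only their
radial axis. Radius graph cutoff 5 Å; 2 message-passing rounds; the
frame-transition block can be ablated to a radial-only field. The continuous
model conditions only on the pharmacophore coefficient.

**Parameter sharing.** The conditional and unconditional models are separate
networks (the unconditional one sees only the timestep), and the two
denoisers are separate models evaluated on the shared state at each step.

## Training

Adam (lr 2e-3, linear decay to 10%), gradient-norm clip 5. The discrete loss
is masked cross-entropy on nodes plus `lambda_E = 5` times the upper-triangle
edge term; the continuous loss is per-entry MSE on the noise; the regressor
loss is MSE against clean-molecule property labels from noised states at
uniform random `t`. Conditioning targets during training are each molecule's
own property values. Minibatches of 32 graphs are drawn per step when the
dataset is larger.

## Guidance

At each reverse step with strength `lambda > 0`, the regressor (pooled
category fractions, the atom-bond-atom co-occurrence tensor `X^T E_k X`, size
and timestep, through a small MLP with sigmoid heads) is evaluated **at the
denoiser's predicted clean graph**, where it is calibrated; evaluating at the
raw noisy state gave unreliable gradient directions. Its input gradients give
per-category first-order property estimates, and each node-category posterior
is tilted by `exp(-lambda * G * sum_p w_p |phi_p,c - target_p|)` and
renormalized. Two deliberate choices:

* **Node-only modulation.** Tilting edge categories directly destroyed
  valence patterns and validity; steering atom composition and letting the
  denoiser re-adapt bonds preserved both.
* **Internal gain `G = 10`.** The pooled featurization dilutes single-entry
  sensitivities by roughly the graph size; the gain maps guidance strengths
  of order 1 onto the regime where per-entry tilts are `exp(O(0.1))` — strong
  enough to steer, weak enough not to override the denoiser. Strengths beyond
  `lambda ~ 20` visibly degrade sample quality.

Dynamic weights (`adaptive` rule) renormalize to the current property gaps
`|phi_p - target_p|` each step, focusing on the worst-satisfied constraint; a
constant-weight mode is available. The unconditional model runs every `k`-th
step (default `k = 5`; `k = 1` means fully unconditional sampling). With
`lambda = 0` the guidance path is skipped entirely, so unguided sampling is
exactly the plain posterior chain. Node counts are drawn from the training
histogram; `g_T` from the stationary marginals and an isotropic zero-CoM
Gaussian. At decode the discrete edge state wins; with coordinates present,
pairs the discrete chain left unbonded whose distance is well inside the
covalent cutoff (tolerance 0.25 Å) are filled with single bonds and flagged.

## Constraint scorers

All four map to [0, 1] with explicit orientation (pharm/QED high is good,
SA/toxicity low): 

* **Pharmacophore.** Features (donor, acceptor, aromatic, hydrophobic,
  positive, negative) are perceived with a versioned SMARTS family asset;
  positions are match centroids. A hypothesis is built from actives grouped
  by Murcko scaffold: features of the feature-richest reference active that
  recur (same type, pairwise distances within `delta = 1 Å`) in at least half
  the class become nodes of a complete graph with class-averaged distances.
  Matching maximizes (mapped fraction) x (fraction of mapped pairs with
  distance deviation < `delta`) over partial injective same-type assignments —
  exact enumeration up to 6 hypothesis features, greedy beyond. Molecules
  without coordinates fall back to topological distances (shortest path x
  1.5 Å). The score formula is validated only against its own brute-force
  oracle; the literature source for the original does not print one.
* **QED.** Own implementation of the published asymmetric-double-sigmoid
  desirability functions and weighted geometric mean over the eight
  descriptors (perceived with the toolkit); agrees with the toolkit's
  reference implementation to 1e-6.
* **SA.** The fragment-contribution/complexity-penalty score on the published
  1–10 scale (computed via the toolkit's contributed implementation and its
  fragment frequency table), normalized as `(raw - 1)/9`.
* **Toxicity.** Ridge regression on 1024-bit Morgan fingerprints (radius 2)
  against log10 LD50 [mg/kg], with 5-fold CV R² reported; predictions are
  mapped to [0, 1] between the 95th (favorable) and 5th (toxic) percentiles
  of the training predictions.

## Evaluation metrics

Uniqueness is computed over valid molecules and novelty over valid unique
molecules (benchmark convention); internal diversity uses 2048-bit radius-2
Morgan fingerprints. The Fréchet metric defaults to a standardized
9-descriptor embedding (a hook accepts learned embeddings for true
ChemNet-style FCD); the trace term is computed by symmetric eigen
decompositions with numerically-zero eigenvalues chopped, keeping
`d(A,A) = 0` and symmetry to 1e-8 even for rank-deficient covariances. The
energy ratio references strain against the molecule's own relaxed minimum
(raw force-field energies are signed, so a raw "7x" multiple would be
ill-posed): a conformer passes if its strain is at most 7x the mean strain of
50 freshly embedded conformers; anyone comparing to published tables should
note the referencing convention is declared here, not printed in the
original.

## Synthetic data

The fixture generator emulates small-organic benchmark statistics: 4–7 heavy
atoms over {C, N, O, F} (element draw weighted 0.70/0.12/0.14/0.04), random
valence-respecting trees with occasional ring closures and double-bond
upgrades, sanitized and deduplicated through canonical SMILES, ETKDG-embedded
and UFF-relaxed conformers, QED/SA labels, an anilide-scaffold actives subset
for pharmacophore construction, and an LD50 table with a planted linear
signal in the three most variable fingerprint bits plus Gaussian noise
(sd 0.1 log units). Everything derives from one seed and is byte-reproducible
across processes. What it does **not** emulate: benchmark-scale size
distributions (9+ heavy atoms), aromatic ring systems at realistic frequency,
charged species, stereochemistry, or quantum-property labels — so passing
tests show the machinery is correct at desk scale, not that the model
reproduces published benchmark numbers.

## Study conditions and problem sizes

* Overfit study: 20 molecules, `T = 100`, `n_max = 10`, 3000/2500 discrete
  steps (conditional/unconditional), 200 samples. Unguided sampling uses the
  unconditional model at every step.
* Conformer recovery: the largest fixture molecule, 10k steps, deterministic
  reverse from `t = T/4`, best-fit (rotation-aligned) RMSD — orientation is a
  gauge freedom of the zero-CoM chain.
* Guidance study: 160 molecules (2D), minibatch 32, QED-only constant
  weights, targets (0.5, 1.0, 0.0, 0.0), 200 samples per strength. The
  20-molecule set is too small for the regressor to rank molecules within a
  size class, which is why the guidance study uses the larger set.
* Memorization oracle: one acyclic multi-element molecule, `T = 100`;
  short chains (`T = 25`) commit structure in too few steps and fail.

## Numerical choices and degenerate inputs

Posterior normalizers are guarded against zero (impossible transitions
raise); padding rows are given a dummy category before posterior computation
and re-masked after sampling. Softmaxes subtract the row max; cross-entropy
adds 1e-12 inside the log. Instance norms use eps 1e-5, so constant features
stay finite. Isolated atoms send no messages and receive zero noise
contribution before CoM projection. Bond-order assignment after distance
inference upgrades single bonds only when both endpoints have free valence
and the distance shows the typical contraction (double < r_sum - 0.10 Å,
triple < r_sum - 0.22 Å), visiting pairs by decreasing summed
electronegativity with index tie-breaks.

## Known limitations

* Training is pure numpy on one CPU: minutes for the study models, far from
  benchmark scale.
* The guidance regressor generalizes only as far as its training set;
  guidance gains are a few hundredths of QED at desk scale.
* The frame-ablation experiment showed no measurable recovery penalty at
  matched budgets on single-conformer overfitting; multi-molecule 3D training
  may behave differently.
* Hydrogen counts are carried for parsed molecules but not through the
  diffusion state; decoded molecules rely on valence-based implicit
  hydrogens.
* The "atomic weights" channel of the continuous chain is not implemented:
  atom identity lives entirely in the discrete chain, since a continuous
  atomic-weight channel has no defined decoding back to a category.
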