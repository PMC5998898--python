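# Methods

## Angle representation

All public interfaces use degrees on the half-open interval [−180, 180);
+180 canonicalises to −180 so each angle has one representative. A dihedral
that does not exist structurally (φ of the first residue, ψ of the last) is
carried as an explicit mask flag plus NaN, never as a sentinel angle, and is
excluded from every training and evaluation sum.

The working representation is the embedding v = (cos φ, sin φ, cos ψ, sin ψ).
Euclidean distance on v is a monotone proxy for toroidal distance, which is
what makes ordinary k-means usable for angle pairs. Raw averages of
embeddings (k-means centers, probability-weighted mixtures) leave the torus;
they are projected back by renormalising each (cos, sin) pair to unit
length. A pair norm below 10⁻⁸ means the directions cancelled and the angle
is undefined; the clustering re-seeds such a center from a member point,
while prediction falls back to the most probable cluster's center and flags
the record.

## Clustering and labels

k-means (k-means++ initialisation, 10 restarts, seeded, best inertia) runs
on the 4-D embeddings; K defaults to 20, the value appropriate for
PDB-scale training sets, while the desk-scale synthetic studies use K = 5
matching the generator. "True" labels are assigned by nearest *normalized*
center — not the raw k-means center — so labels are consistent with the
centers later used for mixing. Clusters are relabelled in order of
decreasing population, so label 1 is always the dominant basin and runs are
comparable across seeds.

Per cluster the model stores: the background probability (label frequency),
circular means, and variances defined as the mean squared
periodicity-corrected deviation about the circular mean, in degrees². The
angle-space (rather than trig-component) variance was chosen deliberately:
it makes the derived confidence σ(θ) directly comparable to angular errors
in degrees.

## Bivariate von Mises mixture

Each cluster also carries a cosine-model bivariate von Mises component.
The normalizing integral over the torus equals
(2π)²{I₀(κ₁)I₀(κ₂)I₀(κ₃) + 2Σ_{p≥1} I_p(κ₁)I_p(κ₂)I_p(κ₃)}; the density
divides by this constant (and tests confirm unit mass by quadrature).
The series is evaluated with exponentially scaled Bessel functions in log
space, truncated when a term's relative contribution falls below 10⁻¹⁴
(cap p ≤ 10⁴), and uses I_p(−κ) = (−1)ᵖ I_p(κ) for negative interaction.
Concentrations are capped at 700, beyond which the density is numerically a
point mass.

Parameters are estimated by the method of moments: circular means for
(μ, ν); κ₁, κ₂ by Newton inversion (tolerance 10⁻¹⁰) of A(κ) = I₁(κ)/I₀(κ)
on the marginal mean resultant lengths; |κ₃| by the same inversion on the
resultant length of the deviation differences (φ−μ) − (ψ−ν), signed by the
circular correlation of deviations. **Known limitation:** this κ₃ recipe is
upward-biased when the marginals are concentrated and the true interaction
is weak, because the difference of two concentrated deviations is itself
concentrated. Location and marginal-concentration recovery is accurate (to
fractions of a degree and a few percent at n = 5·10⁴) and the mixture
log-likelihood comparisons it feeds are insensitive to the bias, but κ₃
estimates should not be interpreted quantitatively. Test sampling uses
exact rejection from the product-of-univariate proposal with acceptance
ratio exp(κ₃cos δ − |κ₃|), which is efficient for the moderate |κ₃| used
throughout.

## Classifier

The reference classifier is a 1-D convolutional residual network written
directly in numpy with explicit backpropagation: input convolution, then
`n_blocks` residual blocks (convolution → ReLU → convolution, identity
skip, ReLU), then a softmax output layer. Convolutions use zero padding
outside the chain and a receptive half-window of 3 (window 7). The default
architecture is 5 blocks × 100 filters; tests and the acceptance run use
2 × 32, which reaches the same qualitative behaviour on synthetic data at a
fraction of the cost. The objective is mean cross-entropy over labelled
residues plus λΣW² (λ = 10⁻⁴ default; biases are deliberately exempt, so
that extreme regularisation collapses predictions to the class background
frequencies rather than to uniform). Optimisation is Adam
(β₁ = 0.9, β₂ = 0.999, lr 10⁻³, minibatches of 8 proteins padded to a
common length), at most 20 epochs, fully deterministic given the seed.
The full-dataset objective is recorded after every epoch.

Ensembling averages member probability matrices and renormalises rows; any
object exposing `predict_probs` can replace the built-in network.

Feature columns are fixed as 20 PSSM, 20 PSFM, 20 one-hot amino acid
(alphabetical one-letter order A, C, D, …, Y), 3 ACC and 3 SS
probabilities. Profile values are consumed as provided — PSI-BLAST
log-odds integers are not squashed — and unknown residues get a zero
one-hot with a logged warning.

## Prediction and confidence

Real-valued angles come from v̂ = Σₖ pₖC̃ₖ with pairwise renormalisation;
the top-R variant zeroes all but the R largest probabilities (ties to the
lower label) and renormalises before mixing; R = K is exactly full mixing.
Confidence is σ(θ) = √(Σₖ pₖ σₖ²(θ)), reported as a standard deviation in
degrees. It is a within-cluster quantity by construction: it ignores
between-cluster dispersion, so it is a lower-style bound that is
informative through its correlation with realised error rather than as an
absolute error estimate.

## Evaluation

MAE uses min(d, 360−d). Correlations are Pearson on cos- or
sin-transformed angles, pooled over all residues of a dataset (not
per-protein averaged). Reports stratify by 3-state secondary structure
(8-state input is reduced H,G,I→H; E,B→E; else C) and amino-acid type.
The error-versus-std analysis fits ordinary least squares of MAE on mean
predicted std; both the 8-point region-mean mode ({all, H, E, C} × {φ, ψ})
and the all-residue mode are available. Zero total variance returns R² = 0
with an explicit flag. Spearman correlation uses average ranks for ties.

## Synthetic data

The generator is the package's study harness, not a claim about empirical
basin statistics. Five basins (weights, locations, concentrations fixed in
`default_basins`): α-helix (−60, −45) at weight 0.35, β-sheet (−120, 135)
at 0.25, PPII (−75, 150) at 0.15, left-handed helix (60, 45) at 0.10, and
a broad coil basin (−100, 60) at 0.15. The weights mirror typical globular
secondary-structure composition; concentrations are set so basins are
visually distinct on a Ramachandran plot and k-means can localise every
center to within a few degrees. Secondary structure follows a first-order
Markov chain with strong self-transitions (mean helix segment ≈ 8
residues); each residue's basin is drawn among the basins of its SS state
and its angles from that basin's von Mises density.

Features are informative of basin membership by construction: the PSSM and
PSFM blocks are per-basin template vectors plus Gaussian noise of scale
`noise`, the SS block is a noise-softened encoding of the true state, the
ACC block is uninformative, and the one-hot block encodes a uniformly
random sequence. Templates derive from a fixed internal generator rather
than the bundle seed, so bundles with different seeds remain
feature-compatible. What passing tests therefore show is that the
pipeline's machinery — clustering, classification, mixing, confidence —
recovers a known generative structure; they do not show real-data accuracy,
which depends on evolutionary profiles, sequence-structure correlations
and disorder that the generator does not emulate.

## Problem sizes and numerical choices

The acceptance run uses 100 proteins of length 50–150 at feature noise 0.3,
an 80/20 split, K = 5, and the 2 × 32 classifier for 10 epochs — sizes at
which every stage's behaviour is already stable across seeds. Cluster-model
JSON serialisation round-trips bit-exactly (full-repr floats); feature TSVs
do the same. k-means ties in label assignment break to the lowest label;
top-R ties at the cut rank keep the lower label. The entropy and
entropy-loss computations use natural logarithms (nats) with 0·log 0 = 0.
The plateau rule for selecting K takes the smallest K within ε (default
0.05 nats) of the best entropy loss; on shallow curves the choice is
sensitive to ε, which is why the cluster count for downstream work is
fixed (K = 20 at PDB scale, K = 5 in the synthetic studies) rather than
re-derived per run.
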