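# ramamix

Real-valued prediction of protein backbone dihedral angles (φ, ψ) by a
hybrid of clustering and per-residue classification, with a per-residue
confidence bound.

## The problem and the method

Backbone dihedral angles describe a protein's local conformation: predicted
(φ, ψ) restrain the conformational search in tertiary-structure prediction,
help angle-based structure alignment, and act as a continuous alternative to
discrete secondary-structure states. Direct regression of angles is awkward
because angles are periodic — a prediction of −179° for a true 179° is 2°
off, not 358° — and because the Ramachandran distribution is multimodal.

`ramamix` splits the problem into a discrete part and a continuous part:

1. **Clustering.** Every angle pair is embedded as
   **v** = (cos φ, sin φ, cos ψ, sin ψ), which removes the periodic seam.
   k-means in this 4-D space partitions the training pairs into K basins
   (default K = 20; the synthetic demonstrations use K = 5). Each raw
   center **C**ₖ is renormalized pairwise into a valid angle representation
   **C̃**ₖ, and each residue's "true" label is its nearest normalized
   center.
2. **Classification.** A 1-D convolutional residual network (blocks of two
   convolutions with ReLU and an identity skip, softmax output; reference
   size 5 blocks × 100 filters, window 7) maps 66 per-residue features —
   20 PSSM + 20 PSFM + 20 one-hot amino acid + 3 predicted solvent
   accessibility + 3 predicted secondary structure probabilities — to the
   marginal cluster probabilities P = (p₁ … p_K). Training maximizes the
   penalized log-likelihood max_θ log P_θ(Y|X) − λ‖θ‖² (default λ = 10⁻⁴)
   with Adam, converging within 20 epochs.
3. **Mixing back to real values.** The predicted angles come from the
   probability-weighted mean embedding v̂ = Σₖ pₖ **C̃**ₖ, renormalized
   (cos φ̂ = v₀/√(v₀²+v₁²), …) and converted back to degrees. A top-R
   variant mixes only the R most probable clusters.
4. **Confidence.** Each cluster stores in-cluster circular variances
   σₖ²(θ); the per-residue confidence is σ(θ) = √(Σₖ pₖ σₖ²(θ)) for
   θ ∈ {φ, ψ}. Realised errors track this bound approximately linearly.

Choosing K uses two criteria computed on held-out data: the entropy loss
EL = (1/N) Σᵢ (H(P₀) − H(Pᵢ)) against the background cluster distribution
P₀, and the mean log-likelihood LL = (1/N) Σᵢ log Σₖ p_ik f_k(φᵢ, ψᵢ) of a
mixture of bivariate von Mises (cosine model) densities

f_k(φ, ψ) ∝ exp{κ₁cos(φ−μ) + κ₂cos(ψ−ν) + κ₃cos(φ−μ−ψ+ν)},

whose normalization constant is evaluated through its Bessel-function
series. Evaluation uses the periodicity-corrected MAE min(d, 360−d) and
Pearson correlation of cos/sin-transformed angles, stratified by secondary
structure and amino-acid type.

A seeded synthetic-data generator emulates proteins whose (φ, ψ) come from
secondary-structure-conditional Ramachandran basins with features noisily
informative of basin membership, so the entire pipeline is testable without
any structure database.

## Worked example

`examples/04_train_and_predict.py` generates 60 synthetic proteins, fits a
5-cluster model, trains a desk-scale classifier (2 blocks × 32 filters) and
evaluates held-out predictions:

```
held-out MAE phi:  14.01 deg
held-out MAE psi:  15.64 deg
circular-mean baseline MAE phi:  34.29 deg
```

The mixture prediction roughly halves the error of always predicting the
global circular mean: the classifier places each residue in the right
Ramachandran basin and the probability-weighted mean refines the angle
inside it. The other examples cover clustering
(`01_cluster_ramachandran.py`), the von Mises density and its moment
estimators (`02_von_mises_density.py`), cluster-number selection
(`03_select_cluster_number.py`) and confidence calibration
(`05_confidence_calibration.py`).

A thin CLI mirrors the pipeline (`ramamix simulate | fit-clusters | scan-k |
train | predict | evaluate`); run `ramamix --help`.

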