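# Methods

## Overview

`protembed` implements two E(3)-invariant graph-transformer networks over
protein structures and the full training, curation and evaluation
machinery around them:

* **ResidueNet** — a residue-level network. Each residue is a node with a
  learned amino-acid embedding, a 15-value dihedral block
  (sin, cos, mask for φ, ψ, χ1–χ3) and the distance of its Cα to the
  protein center of mass. Directed edges connect residues whose Cα atoms
  are within 15 Å; the scalar distance d_ij = ‖p_i − p_j‖ is expanded on
  K = 300 Gaussian basis functions with centers linearly spaced on
  [0, 15] Å and width equal to the spacing (15/299 ≈ 0.05017 Å). Six
  message-passing layers of width 150 (one attention head) produce node
  embeddings; readout heads predict the six global targets (ΔG_sol, R_g,
  R_h, D_t, D_r, V), molecular SASA, residue SASA and residue pKa.
* **LocalChargeNet** — an atomic, locally charge-aware network for pKa.
  Nodes are the C/H/N/O/S atoms within 10 Å of the target residue's Cα
  (inclusive), carrying the parent residue's amino-acid embedding, an
  atom-type embedding and the PQR partial charge; edges connect atoms
  within 5 Å, smeared on 300 Gaussians over [0, 5] Å. Three layers of
  width 75 with three attention heads.

Every node and edge feature is a function of internal coordinates
(distances, torsions), so all predictions are invariant under rigid
rotations and translations by construction; the test suite verifies this
to 1e−6 over random rigid motions.

## Message passing

Edge features e_ij (300-d) are first transformed to the node width by
W₂ σ(W₁ e_ij + b₁) + b₂ with σ the shifted softplus
σ(x) = ln(1 + eˣ) − ln 2. Attention follows the graph-transformer
convention: per head, logits are q_i · (k_j + e_c,ij) / √d_head over each
node's in-neighbors, softmax-normalized; messages are α_ij (v_j + e_c,ij),
and heads are concatenated. The edge term is added to both keys and
values; there is no gating. The node update is the gated residual

    h_i^(l+1) = h_i^(l) + ReLU(LayerNorm(W_R σ(ĥ_i^(l)) + b_R)).

A node with no in-edges receives a zero message, so the residual path
carries its state unchanged through the nonlinearity — this keeps single-
atom selections and disconnected fragments well-defined.

## Readouts

* Global properties and molecular SASA: the component-wise mean μ over all
  node embeddings, through an output MLP of four linear layers (1024
  hidden channels, three shifted-softplus activations).
* Residue SASA: the target residue's own embedding h_i through an
  architecturally identical head.
* Residue pKa (residue-level network): concat(h_i, μ6, μ8, μ10, μ12, μ15, μ),
  a 1050-d feature, where μ_r averages embeddings of residues whose Cα is
  within r Å of the target's Cα (inclusive of the target; Cα–Cα distances).
  The head has six linear layers (1024 hidden), five activations and 20%
  dropout at each layer input; dropout is active only in training mode.
* Residue pKa (atomic network): concat(h_Cα, μ_aa, μ), a 225-d feature,
  where μ_aa averages the target residue's own atoms.

A radius subset always contains at least the target residue; if membership
degenerates the target embedding itself is the documented fallback.

## Encoders and initialization

The main architecture constants (widths 150/75, layer and head counts,
K = 300, cutoffs, head shapes) are fixed. The input encoders are
configurable design choices recorded in the model's config snapshot:
amino-acid embeddings are 64-d, atom-type embeddings 32-d, and each
continuous input (dihedral block, center-of-mass distance, partial
charge) passes through a two-layer shifted-softplus encoder to 32-d
before a linear reduction to the node width. Continuous inputs are
standardized by fixed nominal scales (charges divided by 0.25 e, the
typical spread of protein partial charges; center-of-mass distances by
10 Å) so all encoder inputs are O(1); without this the charge signal is
numerically dominated by the discrete embeddings and is very slow to
learn. Weights use Glorot-uniform initialization from the model seed;
all computation is in float64.

## Training protocol

Targets are normalized per task by the mean and *population* standard
deviation of the training rows only; the stats are stored in the model
state and applied to every split. The loss is mean squared error over
normalized targets with a binary mask that removes examples lacking a
solvation-energy reference — masked entries contribute exactly zero
gradient (verified against a loss with the column dropped).

The reference schedule is Adam (β = 0.9/0.999, ε = 1e−8) at learning rate
1e−4, stepped to 1e−5 after 50 epochs, batch size 64, early stopping
after 10 epochs without validation improvement, best-epoch checkpointing,
and NaN-abort. Transfer regimes freeze parameter blocks: the "frozen"
regimes update only the readout head (trunk parameters are bit-identical
before and after, which the suite audits); the "optimized" regimes
fine-tune everything. Multi-run selection trains n independent seeds and
keeps either the single best run by validation MSE or the top-k by
validation RMSE, ties broken by seed order.

**Desk scale.** The published schedule presumes ~10⁵ training structures,
i.e. thousands of optimizer steps per epoch. The in-package experiments
run on a few hundred synthetic examples, where an epoch at batch 64 is
under ten steps; `TrainConfig.desk_scale()` therefore uses batch 16 and
initial learning rate 3e−4 (same step-decay shape) so the optimization
budget stays meaningful. Problem sizes used by the tests and the
reproduction script: 200 mini-proteins (12–28 residues) for the
radius-of-gyration run — trained single-task on the exact Rg oracle
(batch 8, ≤ 30 epochs, step decay at 25; at n = 200 the surrogate
co-targets measurably drag the Rg head, and the smaller batch keeps the
step count meaningful) — and 500 atomic environments for the pKa run
(batch 16, ≤ 15 epochs), with 100 random rigid motions for the
invariance check. Multi-run experiments fix the train/validation split
(`split_seed`) so runs are compared on one validation set. These are the
package's desk-scale study conditions.

## Synthetic data

The generators are pure functions of (spec, seed).

* **Mini-proteins**: chains of 12–28 residues built in internal
  coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, trans ω), with a
  contiguous helical block (φ, ψ ≈ −57°, −47° ± 2°) over a per-structure
  helix fraction drawn uniformly, coil torsions jittered around the
  extended region, Cβ and a one-atom side-chain stub at a sampled χ1.
  Cα–Cα spacing is ≈ 3.80 Å and all torsions round-trip from coordinates.
* **Atomic environments**: one ionizable residue fragment with ideal local
  geometry plus 20–200 surrounding atoms grouped into pseudo-residues of
  ~5 atoms whose charges sum to integer formal charges; placement is
  clash-free (≥ 2 Å) by rejection sampling within 12 Å.
* **Property tables**: R_g and SASA come from the exact oracles below.
  R_h, D_t, D_r, V and ΔG_sol are documented deterministic *surrogates*
  (e.g. R_h = 2.0 + 0.9 R_g, D_t = 218/R_h, a Stokes–Einstein shape);
  they have realistic units and correlations but are not physical
  reference values, and are never presented as such. ΔG_sol is available
  for 20% of rows by default, emulating sparse references, which
  exercises the masked loss.
* **pKa records**: pKa = model-compound value + α·(net charge within
  10 Å of the target Cα) + β·(burial proxy − 0.5) + noise, with
  α = 0.75 pK/e, β = 1.5 pK, noise σ = 0.25 pK. The planted signal is a
  function the atomic network's inputs determine, so recovery is a
  meaningful end-to-end check.

What passing at desk scale does and does not show: the synthetic
structures have ideal geometry, stub side chains and random sequence, so
success demonstrates that the architecture, featurization, optimization
and evaluation machinery are correct and can extract a physically shaped
local-charge/burial signal — not that the networks reach the accuracy
obtainable with large structure databases and physics-derived references.

## Reference oracles

* **Radius of gyration**: mass-weighted RMS distance from the
  mass-weighted center of mass (standard atomic masses; heavy atoms for
  PDB input, all atoms for PQR).
* **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points), probe 1.4 Å, Bondi van der Waals radii (C 1.70,
  N 1.55, O 1.52, S 1.80, H 1.20 Å). Per-residue values partition the
  total exactly; an isolated atom reproduces 4π(r+1.4)² within 0.5%, and
  the implementation agrees with MDTraj's independent implementation
  within 2% at equal point counts (MDTraj is used only as a cross-check).
* **Null pKa model**: returns the residue type's model-compound pKa
  (Asp 3.7, Glu 4.2, His 6.6, Lys 10.4, Cys 8.5, Tyr 9.8 by default;
  overridable, and the table identity is recorded in every report). Its
  predicted shift is identically zero, so the fitted slope of predicted
  vs. experimental shifts is exactly 0.

## Evaluation

RMSE in task units; MAPE in percent (flagged undefined if any observation
is zero); Pearson r; and for pKa the least-squares slope m of predicted
shifts regressed on experimental shifts (shift = value − model-compound
value). Computing m on shifts makes the null model score m = 0 exactly
and an ideal predictor m = 1. For conformational ensembles (disordered
peptides), per-conformer predictions are arithmetically averaged per
residue, with the conformer count reported.

## Dataset curation

Residue-level records leak between splits whenever the same position in
homologous proteins appears on both sides. Two records are *similar* when
their parent sequences share a cluster at > 0.5 identity, the residues
occupy the same column of the cluster's multiple alignment, and the
amino-acid types match. Clustering is greedy and length-sorted with
identity defined as matches over the global-alignment length
(gap-inclusive denominator); multiple alignments are center-star
(pairwise global alignments to the longest member, gap regions merged,
giving injective and strictly monotone position→column maps). The split
deduplicates validation and test internally (first record in input order
wins), then removes any held-out record similar to a training record; a
brute-force all-pairs audit over the final split is part of the public
API and of the acceptance checks. Adapters ingest CD-HIT `.clstr` files
and aligned FASTA so externally produced clusterings can be used
verbatim.

## Numerical choices and edge cases

* Distances are computed in double precision; cutoff boundaries are
  inclusive ("within 15 Å" means d ≤ 15.0), which makes the last RBF
  center attainable. No self-edges; self-information flows through the
  residual path.
* Alternate locations resolve to highest occupancy; non-standard residues
  map to their parent type via a fixed table (MSE→MET, etc.); residues
  without a Cα are excluded from graphs with a warning; missing atoms or
  chain termini degrade dihedral entries to mask = 0, never to an error.
* Torsion angles are undefined for collinear triples (raised as a typed
  error, converted to mask = 0 during featurization).
* The engine underneath is a reverse-mode tape over NumPy float64 arrays;
  every operation's gradient is verified against central finite
  differences in the test suite, and training is bit-reproducible given
  (seed, config, data).

## Known limitations

* No mmCIF input, no structure repair, no protonation-state placement;
  PQR files are consumed, not produced.
* The attention variant is the cited mechanism's core form (edge term in
  keys and values, no gating); alternatives exist and the choice is
  recorded in the config snapshot.
* Hydrodynamic reference values are surrogates at desk scale; training
  against physical hydrodynamics requires external reference software
  that is deliberately out of scope.
* The bundled aligner is a center-star progressive scheme, not a full
  MSA program; for exact reproduction of an external pipeline, use the
  `.clstr` / aligned-FASTA adapters.
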