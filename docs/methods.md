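# Methods

This note documents the models and procedures implemented in `meftop`, the
parameters that matter, the design choices made where the design was open,
and what the generated benchmark does and does not establish.

## Structural annotation

All geometry operates on the CA trace plus one side-chain centroid (SCM)
pseudo-atom per residue. For parsed PDB models the SCM is the mean of the
side-chain heavy atoms (CA for glycine or when no side-chain atoms are
present); models built or rebuilt from a CA trace place the SCM along the
pseudo-CB direction (negated bisector of the two chain bonds) at a
per-residue-type distance.

**Secondary structure** is assigned from CA geometry alone, deterministically:

- *Helix*: 4-residue windows whose virtual CA torsion lies in [30°, 80°] and
  whose CA(i)–CA(i+3) distance lies in [4.2, 6.5] Å are helical; residues
  covered by at least two consecutive helical windows are H.
- *Strand*: a residue is locally extended if it sits in a window with
  |torsion| ≥ 140° and CA(i)–CA(i+2) ≥ 6.0 Å. An extended residue becomes E
  only if it is spatially paired with another extended residue (separation
  ≥ 3, CA distance ≤ 5.5 Å) and an adjacent rung of the ladder also pairs —
  so an isolated extended chain with no partner strand stays coil.
- Residues flanking a chain break (CA–CA > 4.5 Å) are forced to coil.

A CA-only assigner was chosen over a backbone H-bond energy scheme because
decoys are generated and rebuilt as CA traces, and because it applies
unchanged to backbone-incomplete PDB input. It reproduces the intended
3-state labels on ideal helices, paired sheets, and extended or broken
chains, and is rigid-motion invariant by construction.

**Relative solvent accessibility** uses a neighbour-count burial proxy:
`rsa_i = max(0, 1 − n_i/14)` where `n_i` counts other SCMs within 10 Å.
A residue is exposed iff `rsa_i ≥ threshold` (default 0.25, so a threshold
of 0 marks everything exposed). The constant 14 was calibrated once on the
generated folds so that compact natives show a realistic (~25–40%) buried
fraction; it is a proxy, not an accessible-surface-area computation.

**Contact maps** are strict-inequality SCM contacts, `N_ij = 1` iff
`|i−j| ≥ 6` and `‖scm_i − scm_j‖ < t`, at the two classes t = 8 and 12 Å.

## Features (37 = 14 + 10 + 6 + 7)

Zero conventions are uniform: cosine of a zero vector is 0, Pearson
correlation with a constant side is 0, a per-residue contact order with no
contacts is 0, SSE features without any corresponding SSE pair are 0. These
conventions keep every feature finite on degenerate inputs.

- `f_res` is the mean of `C·N + (1−C)(1−N)` over eligible pairs (i < j,
  separation ≥ 6), hence in [0, 1] and equal to 1 exactly when the model's
  binary contacts reproduce a binary prediction. Normalization is by the
  eligible-pair count, chosen for boundedness.
- SSE segmentation takes maximal runs of ≥ 4 identical H/E states.
  Model↔sequence SSE correspondence is a greedy, order-preserving matching
  by minimal start-position difference; ties take the earlier sequence-side
  SSE. Only corresponding SSEs enter the SSE features.
- SSE contact strength is the count of model SCM pairs under 8 Å
  (sequence side: the sum of predicted probabilities from the 8 Å-class
  map). The same 8 Å class is used on both sides so that a prediction that
  matches the model geometry exactly yields `f_SSE = 1`; a looser model-side
  cut (e.g. 8.5 Å) is available as a parameter. `f_SSE` compares
  row-length-normalized strengths over ordered SSE pairs:
  `1 − Σ|C_S − N_S| / Σ max(C_S, N_S)`; a single corresponding SSE gives 0
  (no pair information), two all-zero strength matrices give 1.
- Predicted SSE-pair distance interpolates linearly in the maximum predicted
  contact probability p of the pair: `D = D0 + k(Dm − D0)(P0 − p)` with
  D0 = 3.8 Å, Dm = 8 Å, P0 = 1, k = 1, clipped to [3.8, 20]; the model-side
  distance is the minimum SCM distance of the pair. Distances are compared
  by a Gaussian similarity with σ = 4 Å. Length agreement uses
  Σmin/Σmax and the mean per-pair min/max ratio.
- Radius-of-gyration agreement uses the globular power law
  `R_pred = 2.2·L^0.38` (Å); features are a Gaussian similarity with
  σ = 0.2·R_pred and the min/max ratio.
- The hydrophobic core is the largest single-linkage cluster (6.5 Å cutoff,
  equivalently a connected component of the thresholded graph) of the SCMs
  of {A, V, L, I, M, F, W, C}; size ties go to the cluster containing the
  lowest residue index. Its radius, member count and number of contributing
  SSEs are compared as min/max ratios against sequence-side expectations:
  0.9 of the sequence's hydrophobic residues in the core (calibrated on the
  idealized folds, where a single core collects nearly all inward-facing
  hydrophobic side chains), the power-law radius for that count, and the
  number of predicted SSEs holding ≥ 2 hydrophobic residues. This comparison
  side is the least externally constrained part of the feature set and is
  deliberately parameter-exposed.
- Fragment potentials scan 5-residue windows, take the majority secondary
  structure state (H/E ties toward H; majority-coil windows skipped), and
  measure (a) `exp(−msd/4)` of the CA(i)–CA(i+4) distance against the
  state ideal (H: 6.2 Å, E: 12.4 Å) and (b) the fraction of windows whose
  virtual CA torsion is canonical (H: 45–65°; E: |τ| ≥ 150°, the symmetric
  band around ±180°).

## Scores

- **Z-score**: per-pool standardization of the raw threading score
  (population sd; constant pools map to zero).
- **P-score**: ε-SVR with RBF kernel on min–max scaled features
  (scaling learned on the training split only), per-instance weight equal
  to the TM-score label — the simplest monotone map from quality to weight.
  Defaults C = 10, γ = 0.25, ε = 0.05 fit the generated benchmark well;
  a cost function `F = mean(native rank) − n·mean(Z_svm) + λ·missed`
  (λ = 1) is provided for hyperparameter selection when natives are
  included in training pools. Predictions are clipped to [0, 1] for
  reporting.
- **M-score**: `M = Z + n·P`, with n ≥ 0 selected on validation targets by
  maximizing Top1% over the grid 0.5–10 (step 0.5, ties toward smaller n).

**TM-score** is computed for equal-length correspondences by maximizing
`mean(1/(1 + (d_i/d0)²))` with `d0 = max(0.5, 1.24(L−15)^⅓ − 1.8)` over
Kabsch superpositions seeded from contiguous fragments and refined by
re-superposing on residues within the inclusion cutoff (relaxed when fewer
than four qualify) until the aligned set is stable. Chains of ≤ 40 residues
are seeded from every contiguous fragment; longer chains use fragment
lengths {L, L/2, L/4, 4} with half-length steps, which agrees with the
exhaustive search to well under 0.01 on this benchmark's pool sizes.
Tied TM values in ranking metrics receive average ranks.

## The generated benchmark

`build_native` packs ideal secondary-structure elements — parametric helices
(2.3 Å radius, 1.5 Å rise, 100°/residue) and pleated strands (3.1 Å rise,
±1.1 Å pleat, paired at 4.9 Å) — along an arc in the plane, consecutive
elements running antiparallel in z, joined by short loops relaxed to 3.8 Å
CA spacing. Consecutive strands form rigidly placed sheets. Residue types
are assigned by burial: SSE positions whose side-chain direction faces the
fold centre cycle through hydrophobic types, the rest through polar ones.
The folds are globular (model radius of gyration within ~10% of the
power-law prediction) and their assigned secondary structure reproduces the
layout.

Decoys perturb the native's internal coordinates: Gaussian noise of a grade
magnitude (radians) on the virtual torsions, and a quarter of that on bond
angles, at a random 35% of positions, then rebuild the trace. The default
grade mix (0.1–1.7 rad) makes native-like decoys (TM > 0.4) a minority
(~25–35%) of each pool, spanning TM ≈ 0.2–0.95.

Synthetic predictor noise defaults emulate a realistic sequence-based
pipeline: 20% of SS and RSA states flipped, true contacts attenuated by
15%, a 3% background on non-contacts, and Gaussian jitter (sd 0.05) on
contact probabilities. Raw threading scores are `10·TM + N(0, 9)`: at that
noise level picking models by Z-score alone finds a native-like top model
for well under 60% of targets, emulating the low-confidence regime the
re-ranking is designed for.

What the benchmark does **not** emulate: real side-chain packing and
H-bonding, sequence-profile information, alignment-induced (rather than
torsion-noise) decoy errors, multi-domain targets, and predictor errors
correlated with structural context. Passing results therefore demonstrate
internal correctness and the qualitative rescue effect, not expected
accuracy on experimental structures.

## Default problem sizes

The bundled experiment uses 30 training, 10 validation and 50 held-out test
targets with 50 decoys each (folds of ~31–57 residues). These sizes give
stable metrics (Top1% resolution of 2 points on 50 targets) while the whole
experiment, including TM labelling of 4,500 decoys and SVR training on
1,500 weighted instances, completes in minutes on one CPU.

## Known limitations

- The SS assigner does not distinguish 3-10/π helices or isolated bridges;
  labels are 3-state by design.
- RSA is a burial proxy; do not interpret it as accessible surface area.
- TM-score requires equal-length, identity-corresponded chains
  (no alignment search), which is exactly the decoy-labelling use case.
- The SVR hyperparameter defaults were chosen for the generated benchmark's
  feature distributions; retune (grid search under the provided cost
  function) before applying to models from real pipelines.
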