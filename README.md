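# meftop

Topology-focused single-model quality assessment for protein structure
models, and re-ranking of template-based-modeling candidates by a combined
threading/quality score.

## The problem

Template-based modeling produces, for each target sequence, a pool of
candidate structure models ranked by a threading score. For low-homology
targets — the "dawn region", where the best threading Z-score is weak — that
ranking is unreliable: native-like models exist in the pool but are not
ranked first. `meftop` scores each candidate model by how well its
*topology* agrees with what the target sequence itself predicts, and uses
that score to re-rank the pool.

For a model with contact map `N_ij` and a sequence-side predicted contact
probability map `C_ij` (both restricted to residue pairs with separation
`|i−j| ≥ 6`), the package extracts **37 features in four groups**:

1. **1D composition (14)** — helix/strand/coil and exposed/buried fractions
   on both sides, plus cosine, Pearson correlation, Gaussian-kernel and dot
   products of the two composition vectors.
2. **2D contact map (10)** — cosine and correlation of per-residue contact
   order and contact number profiles at the <8 Å and <12 Å classes, plus the
   overall residue contact match score at each class,
   `f_res = mean over eligible pairs of [C·N + (1−C)(1−N)]`.
3. **SSE contacts (6)** — secondary-structure elements (runs of ≥4 helix or
   strand residues) are matched one-to-one between model and sequence; the
   features compare SSE-pair contact strengths (`f_SSE`), SSE contact-number
   vectors, SSE pair distances and SSE lengths.
4. **3D topology (7)** — radius-of-gyration agreement with the globular
   power law `R = 2.2·L^0.38`, three hydrophobic-core descriptors (radius,
   residue count, SSE count of the largest spatial cluster of hydrophobic
   side-chain centroids), and two local fragment-conformation potentials.

A weighted ε-SVR (RBF kernel, per-model weight = TM-score label) maps the
feature vector to a **P-score**, an estimate of the model's TM-score to the
(unknown) native structure. The threading raw score `S` is standardized over
the pool, `Z_k = (S_k − mean S)/sd S`, and the final selection metric is

```
M = Z + n·P
```

with the weight `n` chosen on validation targets to maximize Top1% (the
fraction of targets whose top-ranked model is native-like, TM > 0.4).

Everything runs on generated data: `meftop.synthetic_fixtures` builds
idealized globular folds, graded torsion-space decoys with exact TM labels,
noisy sequence-side predictions, and corrupted raw threading scores, so the
whole train/rank/evaluate loop is reproducible from a single seed with no
external downloads.

## Worked example

```sh
python examples/tm_score_basics.py
```

```
native: 54 residues; TM(native, native) = 1.000
torsion noise sd 0.05 rad -> mean TM 0.888 (native-like)
torsion noise sd 0.20 rad -> mean TM 0.607 (native-like)
torsion noise sd 0.60 rad -> mean TM 0.374 (non-native)
torsion noise sd 1.50 rad -> mean TM 0.265 (non-native)
```

The TM-score (in (0, 1], computed by iteratively refined Kabsch
superpositions with the length-dependent scale `d0 = 1.24·(L−15)^⅓ − 1.8`)
degrades smoothly as backbone torsions are perturbed; 0.4 is the
native-like topology threshold used throughout.

```sh
python examples/rank_decoys.py
```

```
metric   top pick      its true TM
z        decoy_020           0.705
p        decoy_000           0.735
m        decoy_020           0.705
oracle   (true best)         0.735
```

Here the P-score's top pick is the truly best model in the pool, while the
noisy threading Z-score settles for a slightly worse one.

Other examples: `examples/extract_features.py` (prints all 37 features with
their group structure) and `examples/dawn_region_experiment.py` (a
scaled-down version of the full re-ranking experiment).

A thin CLI mirrors the library for shell use:
`meftop fixtures`, `meftop extract`, `meftop train`, `meftop score
--metric {z,p,m}`, `meftop evaluate` (see `meftop --help`).

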