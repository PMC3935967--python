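"""Extract the 37-feature agreement vector for one structure model.

Builds an idealized mixed alpha/beta fold, synthesizes the sequence-side
predictions a real pipeline would obtain from a secondary-structure /
contact predictor, and prints every feature.  Values near 1 mean the model
agrees with what the sequence predicts (similarity scores); composition
entries are plain state fractions.
"""

from meftop import FEATURE_GROUPS, assemble_features, build_native, profile_from_structure

native = build_native(["H10", "E6", "E6", "H10", "H8"], seed=1)
profile = profile_from_structure(native, seed=0)  # realistic predictor noise

vec = assemble_features(profile, native)
names = [n for group in FEATURE_GROUPS.values() for n in group]

print(f"fold: {native.length} residues, SS {native.ss_string}")
i = 0
for group, group_names in FEATURE_GROUPS.items():
    print(f"\n[{group}] ({len(group_names)} features)")
    for name in group_names:
        print(f"  {name:24s} {vec[i]: .4f}")
        i += 1
print(f"\ntotal features: {len(vec)}")
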