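"""Simulate a multi-tissue expression matrix with planted structure.

Builds a quarter-scaled five-tissue dataset (group sizes 15/24/3/10/5,
1000 genes, 50 signature genes per tissue), prints its shape and the
planted ground truth, and shows the measurable signal: the mean expression
of one tissue's signature genes inside vs outside that tissue.
"""

import numpy as np

import bicbench as bb

cfg = bb.desk_config(seed=1)
matrix, labels, truth = bb.generate_multitissue_dataset(cfg)

print(f"matrix: {matrix.shape[0]} genes x {matrix.shape[1]} samples")
print(f"sample types (t={labels.t}):")
for lab in labels.types:
    print(f"  {lab:<16} {len(labels.samples_of_type(lab)):>3} samples")
print(f"planted biclusters: {len(truth.planted)}")
for p in truth.planted:
    print(f"  {p.pattern_kind:<15} {len(p.genes)} genes x {len(p.samples)} samples")

# the constant-shift tissues are up-shifted by effect_size in their samples
lab = labels.types[-1]  # last type uses the constant-shift archetype
sig = sorted(truth.type_signatures[lab])
inside = matrix.data.loc[sig, sorted(labels.samples_of_type(lab))].to_numpy()
other = sorted(set(matrix.sample_ids) - labels.samples_of_type(lab))
outside = matrix.data.loc[sig, other].to_numpy()
print(f"\n{lab} signature genes: mean inside type = {inside.mean():.2f}, "
      f"outside = {outside.mean():.2f}")
print(f"(difference ~ effect_size = {cfg.effect_size}; "
      "background is Normal(0, 1) noise)")
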