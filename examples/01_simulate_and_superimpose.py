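"""Generate a synthetic wing-landmark study and superimpose it.

Builds the default two-species study (77/70/67/57 specimens plus replicated
digitizations), validates it, and runs generalized Procrustes analysis on the
female wings.  The printed centroid sizes are in the generator's image units;
the consensus is the unit-size mean shape all specimens were aligned to.
"""

import numpy as np

from wingmorph import SyntheticSpec, generate_study, gpa, validate_dataset

dataset = generate_study(SyntheticSpec(seed=42))
report = validate_dataset(dataset)
print(f"generated {len(dataset)} configurations "
      f"({dataset.landmark_count} landmarks each); validation: "
      f"{'clean' if report.ok and not report.issues else report}")

meta = dataset.metadata_frame()
females = dataset.subset(((meta.sex == "female") & (meta.replicate == 1)).to_numpy())
res = gpa(females)
print(f"GPA converged in {res.iterations} iterations "
      f"(residual Q = {res.q_trace[-1]:.4f})")
print(f"centroid size: mean {res.centroid_sizes.mean():.1f}, "
      f"range {res.centroid_sizes.min():.1f}-{res.centroid_sizes.max():.1f}")
rms = np.sqrt(np.mean(np.sum((res.aligned - res.consensus) ** 2, axis=(1, 2))))
print(f"root-mean-square Procrustes deviation from consensus: {rms:.4f}")
print("-> sizes vary by tens of percent while shapes deviate by ~4% of "
      "centroid size: size and shape carry separate information.")
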