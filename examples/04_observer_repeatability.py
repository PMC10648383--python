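"""Observer effect: does who clicks the landmarks change the results?

Uses the replicated-digitization subset (each selected wing measured once by
each of three observers).  Compares digitization noise (within-specimen
Procrustes variance) against biological variation (within-species PV), tests
the observer effect on centroid size, and re-runs the species classification
on the replicated measurements.
"""

from wingmorph import (
    SyntheticSpec,
    generate_study,
    gpa,
    loocv_classify,
    observer_repeatability,
    observer_size_effect,
)

dataset = generate_study(SyntheticSpec(seed=42))
meta = dataset.metadata_frame()

for sex in ("female", "male"):
    mask = ((meta.sex == sex) & (meta.replicate == 2)).to_numpy()
    sub = dataset.subset(mask)
    sub_meta = meta[mask]
    res = gpa(sub)

    anova = observer_size_effect(
        res.centroid_sizes,
        sub_meta["observer"].to_numpy(),
        specimens=sub_meta["id"].to_numpy(),
        n_permutations=500,
        seed=42,
    )
    rep = observer_repeatability(
        res.shape_vectors(),
        sub_meta["id"].to_numpy(),
        sub_meta["observer"].to_numpy(),
        sub_meta["species"].to_numpy(),
    )
    cls = loocv_classify(res.shape_vectors(), sub_meta["species"].to_numpy())
    print(f"== {sex} ({rep.n_specimens} wings x 3 observers) ==")
    print(f"observer size ANOVA: F = {anova.statistic_F:.3f}, "
          f"Z = {anova.z_score:.2f}, P = {anova.p_value:.3f}")
    print(f"within-specimen PV = {rep.within_specimen_pv:.6f} vs "
          + ", ".join(f"within-{g} PV = {v:.6f}"
                      for g, v in sorted(rep.within_species_pv.items())))
    print(f"replicate-measurement LOOCV accuracy: {cls.accuracy:.1%}")

print("-> digitization noise is several-fold smaller than biological shape "
      "variation and the classification survives a change of observer.")
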