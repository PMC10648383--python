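"""Centroid-size ANOVA and the allometry permutation test, per sex.

Wing size is compared between species with a one-way ANOVA on centroid size;
the shape-size relationship (allometry) is tested by regressing all 36
superimposed coordinates on size with a 1000-permutation null.  A small R²
with a small p means size explains a real but tiny share of shape variation.
"""

from wingmorph import (
    SyntheticSpec,
    allometry_regression,
    generate_study,
    gpa,
    size_anova,
)

dataset = generate_study(SyntheticSpec(seed=42))
meta = dataset.metadata_frame()

for sex in ("female", "male"):
    mask = ((meta.sex == sex) & (meta.replicate == 1)).to_numpy()
    res = gpa(dataset.subset(mask))
    species = meta[mask]["species"].to_numpy()

    anova = size_anova(res.centroid_sizes, species)
    allo = allometry_regression(
        res.shape_vectors(), res.centroid_sizes, n_permutations=1000, seed=42
    )
    print(f"{sex}: size ANOVA F{anova.df_model},{anova.df_resid} = "
          f"{anova.statistic_F:.2f}, P = {anova.parametric_p:.3f}")
    print(f"{sex}: allometry F{allo.df_model},{allo.df_resid} = "
          f"{allo.statistic_F:.2f}, R2 = {allo.r_squared:.3f}, "
          f"P = {allo.p_value:.3f}")

print("-> a significant size difference does not make size a usable species "
      "marker (distributions overlap heavily), and allometry, though "
      "significant, explains only ~2-5% of shape variation.")
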