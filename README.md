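# wingmorph

Landmark-based geometric morphometrics for discriminating the invasive bush
mosquitoes *Aedes japonicus japonicus* and *Aedes koreicus* from their wings.

The two species are close relatives, occur in sympatry in Europe, and are
hard to tell apart morphologically — yet they may differ in vector capacity,
so surveillance programs need a cheap, robust identification method.
`wingmorph` implements the full wing-morphometrics workflow on 18
two-dimensional landmarks digitized at wing-vein intersections:

1. **Superimposition** — generalized Procrustes analysis (GPA): every
   configuration is centered, scaled to unit centroid size
   CS = √Σᵢ‖xᵢ − x̄‖², and rotated (proper rotations only, det R = +1) onto an
   iteratively re-estimated consensus; optional projection onto the tangent
   space at the consensus.
2. **Size** — one-way ANOVA of centroid size between species, per sex, with
   parametric and permutation p-values.
3. **Allometry** — Procrustes regression of all 2k shape coordinates on size:
   R² = SS_model/SS_total, F = (SS_model/1)/(SS_resid/(n−2)), significance by
   permuting the specimen-to-size assignment (p = (c+1)/(N+1), Z score from
   the permutation distribution of F).
4. **Classification** — PCA of the superimposed coordinates, two-class linear
   discriminant w = W⁻¹(μ₁ − μ₂) on full-rank PC scores, validated by
   leave-one-out cross-validation; per-landmark mean-shape contrasts.
5. **Disparity & observer effect** — morphological disparity as Procrustes
   variance PV_g = (1/n_g)Σᵢ‖vᵢ − v̄_g‖², and repeatability of replicated
   digitizations (within-specimen vs within-species PV, observer size ANOVA,
   replicate-set classification).

Because no public landmark coordinate tables exist for this study system
(only wing images), the package ships a fully parameterized synthetic study
generator (`SyntheticSpec` / `generate_study`) that emulates the data
structure — species/sex mean-shape fields, lognormal sizes, weak allometry,
individual and observer noise — so every stage is testable end to end.

## Worked example

```sh
wingmorph simulate --out demo --seed 42     # writes demo/study.csv (511 wings)
wingmorph analyze --input demo/study.csv --seed 42 --out demo_out
```

prints (abridged):

```
== female ==
  n: japonicus=77, koreicus=67
  size ANOVA: F1,142 = 10.11, P = 0.002
  allometry: F1,142 = 3.43, R² = 0.024, P = 0.001
  LOOCV accuracy: 88.9% (confusion [[70, 7], [9, 58]])
  Procrustes variance [japonicus]: 0.001520
  Procrustes variance [koreicus]: 0.001458
  observer size ANOVA: F = 0.03, Z = -0.98, R² = 0.000, P = 0.976
  within-specimen PV: 0.000376 (ratio to within-species: 0.20)
  observer-replicate LOOCV accuracy: 90.8%
```

Reading: female *Ae. koreicus* wings are significantly larger on average but
the size distributions overlap too much to identify species by size; shape,
in contrast, assigns 128 of 144 females correctly under leave-one-out
validation. Allometry is statistically real but explains only ~2% of shape
variation. Digitization noise (within-specimen PV ≈ 0.0004) is a factor ~5
below biological shape variation (within-species PV ≈ 0.0015), and the
classification accuracy survives a change of observer.

The `examples/` directory holds one short script per capability
(superimposition, size/allometry, classification, observer repeatability);
each builds a small input, runs the method, and explains its printout.

## Layout

- `wingmorph.io` — TPS / wide-CSV reading, writing, validation
- `wingmorph.gpa` — centroid size, pairwise Procrustes alignment, GPA
- `wingmorph.stats` — size ANOVA, allometry, disparity, repeatability
- `wingmorph.classify` — PCA, LDA, LOOCV, landmark contrasts
- `wingmorph.simulate` — synthetic study generator and parameter recovery
- `wingmorph.pipeline` / `wingmorph.cli` — per-sex orchestration, reports, CLI

See `docs/methods.md` for the statistical model, parameter defaults, and the
limits of what the synthetic study can show.
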