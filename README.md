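# qsmref

Reference-region analysis for quantitative susceptibility mapping (QSM).

In QSM the dipole kernel `D(k) = 1/3 − k_z²/|k|²` has a zero at the k-space
origin, so the mean (DC) susceptibility of a reconstructed map is
undetermined: maps are only ever *relative*. Clinical studies therefore
"reference" their maps by subtracting the mean (or median) susceptibility of
a chosen region — CSF, white matter, the whole brain, or a data-driven
region — from every voxel. This package implements the machinery to study
what that choice does to group statistics:

- a **synthetic phantom and cohort generator** built on the dipole forward
  model `ΔB = χ * D`, with TKD (thresholded k-space division) and Tikhonov
  inversion emulators, multi-echo magnitude simulation, and an
  epilepsy-style three-group cohort sampler (27 HC / 19 LTLE / 17 RTLE);
- **five referencing strategies**: anatomical ROI, whole brain, the lowest
  percentile of the across-subject relative susceptibility variance map
  `Var(χ)[r] / mean(χ)[r]`, and an R2\*-threshold region (voxels with
  R2\* < 4 Hz from an ARLO-style autoregressive fit — fluid-like tissue,
  segmentation-free);
- the **ROI pipeline** (spherical-kernel erosion ×3, 1st–99th percentile
  trimming, mean/sd) and the **group statistics**: Welch t
  (`t_d = (x̄_n − ȳ_m)/S_d`, `S_d² = S_X²/n + S_Y²/m`), one-way ANOVA with
  post-hoc Tukey–Kramer gated on ANOVA significance, pooled linear age
  correction, and ground-truth accuracy classification;
- **variance diagnostics** based on Bienaymé's identity
  `Var(X−R) = Var(X) + Var(R) − 2 Cov(X,R)`: for equal variances σ² and
  correlation ρ the referenced variance is `(2−2ρ)σ² ∈ [0, 4σ²]`, so an
  uncorrelated reference *doubles* the variance (weakening the test) while
  a correlated one can sharpen it — or, if the reference region itself
  carries a group effect, silently bias the hypothesis being tested.

## Worked example

```python
import qsmref as q

# null cohort: identical group means, unbiased references
table = q.cohort_to_frame(q.simulate_cohort(q.default_cohort_design(seed=7)))
report = q.run_group_pipeline(table, strategy="csf", alpha=0.05)
print(report.anova[["roi", "F", "p", "var_change_pct"]].head(4).to_string(index=False))
```

```
             roi        F        p  var_change_pct
             CSF 0.000000 1.000000     -100.000000
 corpus_callosum 1.620480 0.206340       29.727747
internal_capsule 2.615639 0.081444       57.721931
        amygdala 4.515358 0.014903       50.844348
```

Reading this: the CSF row is referenced to itself, so its variance change is
exactly −100% and the ANOVA is degenerate (F = 0, p = 1). The other rows
show positive variance changes: referencing removed the shared per-subject
offset (τ = 0.005 ppm) and the age trend, but added the CSF reference's own
independent noise (σ = 0.01 ppm), and since σ² > τ² the net effect is
variance inflation — exactly the `Var(X) + Var(R) − 2 Cov(X,R)` trade-off.
One of nine null ROIs coming out significant at α = 0.05 (amygdala,
p ≈ 0.015) is ordinary false-positive behaviour; over many seeds the
pipeline's rejection rate is calibrated at ~5% (see
`tests/test_acceptance.py`).

The same study can be run from the shell:

```sh
qsmref simulate cohort --seed 7 --out run/
qsmref group-stats --cohort run/cohort.csv --strategy csf --out run/report.csv
qsmref theory scan --out run/scan.csv   # Var(X−R)/Var(X) vs correlation
```

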