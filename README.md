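# mandifrac

Texture and radiomorphometric analysis of mandibular trabecular bone on
dental panoramic radiographs, with the three-group statistics used to
relate those measurements to serum total-cholesterol strata.

The package is aimed at dental/oral-radiology researchers who quantify
trabecular microarchitecture from plain panoramic images. It implements,
as a tested and scriptable pipeline:

* **ROI preprocessing** (Rudolph–White chain): a 64×64 px trabecular
  region of interest is flattened by subtracting a Gaussian-blurred
  background (σ = 35 px) and re-centring at grey 128, thresholded at
  128, opened with a 3×3 structuring element to remove radiographic
  noise, inverted, and thinned to a 1-px-wide skeleton of the
  trabecular pattern.
* **Box-counting fractal dimension (FD)**: the slope of
  log N(ε) vs log(1/ε), where N(ε) is the number of ε×ε boxes containing
  skeleton pixels, over the box-size ladder
  ε ∈ {2, 3, 4, 6, 8, 12, 16, 32, 64}, with counts averaged over four
  deterministic grid origins (single-origin mode available).
* **Lacunarity (Λ)**: the squared coefficient of variation of per-box
  foreground mass, λ(ε) = (σ/μ)², averaged over grids and box sizes —
  a gap-structure complement to FD.
* **Radiomorphometry**: mandibular cortical width (MCW, the cortical
  thickness *a* perpendicular to the inferior border through the lower
  edge of the mental foramen) and the panoramic mandibular index
  (PMI = *a*/*b*, with *b* the foramen-to-border distance), from
  operator-supplied landmark coordinates.
* **Group statistics**: Kruskal–Wallis H across the normal
  (< 5.2 mmol/L), borderline (5.2–6.2 mmol/L) and high (> 6.2 mmol/L)
  cholesterol groups; Dunn's post-hoc z tests with Bonferroni
  correction; the effect-size chain η² = H/(N−1),
  f = √(η²/(1−η²)), and achieved power from the noncentral
  F(k−1, N−k; λ = f²N) approximation; and an age/sex OLS confounding
  check.
* **Synthetic ground truth**: Sierpinski-carpet and other phantoms with
  closed-form FD, illumination-biased grey patches, landmark fixtures
  built from known (a, b), and three-group cohorts with a configurable
  anterior-FD effect size — everything needed to validate the pipeline
  without patient data.

## Worked example

```python
import mandifrac as mf

# a radiograph-like phantom: carpet texture + 60-grey-level ramp + noise
patch = mf.make_grey_patch(mf.SynthParams(
    seed=7, texture_model="ifs_fractal",
    illumination_amplitude=60, noise_sd=3))
res = mf.analyze_patch(patch)
print(f"fd={res.fd:.4f} r2={res.fit_r2:.4f} lacunarity={res.lacunarity:.4f}")
# fd=1.5075 r2=0.9752 lacunarity=1.4104

# morphometry on a fixture constructed with a=12 px, b=40 px
landmarks, a, b = mf.make_landmark_fixture(3, mcw=12, foramen_height=40)
m = mf.pmi(landmarks)
print(f"mcw={m.mcw:.2f} b={m.foramen_border_distance:.2f} pmi={m.pmi:.4f}")
# mcw=12.00 b=40.00 pmi=0.3000

# three-group comparison on a synthetic cohort (35/33/24 patients)
cohort = mf.make_cohort(mf.CohortParams(seed=1))
anterior = next(c for c in mf.compare_all(cohort)
                if c.variable == "fd" and c.region_or_side == "anterior")
print(f"H={anterior.h:.3f} p={anterior.p:.3f} eta2={anterior.eta2:.4f} "
      f"f={anterior.cohens_f:.3f} power={anterior.power:.3f}")
# H=2.547 p=0.280 eta2=0.0280 f=0.170 power=0.279
```

The phantom FD of 1.51 is the dimension of the *skeletonized* carpet
texture after the full chain (thinning lowers the filled pattern's
dimension); the fit R² of 0.98 indicates clean log–log scaling. The
morphometry block recovers the construction values exactly, and
PMI = 12/40 = 0.30. In the cohort block the generator draws every
metric around its group medians, so H, the Dunn-adjusted p-values and
the η² → f → power chain summarize one simulated replicate of the
three-group design.

The same steps are available from the shell:

```
mandifrac simulate cohort --seed 1 --out cohort.csv
mandifrac stats --cohort cohort.csv --out tables/
mandifrac run --config study.yaml      # full images-to-tables replay
```

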