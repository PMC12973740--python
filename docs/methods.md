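# Methods

This note documents the models, conventions and numerical choices
behind the package, what the synthetic generators do and do not
emulate, and the known limitations.

## Preprocessing chain

A trabecular ROI is a 64×64 px 8-bit patch containing only trabecular
bone. The chain is:

1. **Background estimation.** Gaussian blur with σ = 35 px. At this
   scale the filter passes only the smooth brightness bias contributed
   by soft-tissue and bone-thickness variation; the trabecular texture
   (period of a few pixels) is completely suppressed. Boundary mode is
   *reflective*: σ exceeds the patch side, and zero or constant padding
   would darken the borders of a 64 px patch and leak a spurious
   gradient back into the flattened image.
2. **Flattening.** `original − blurred + 128`, rounded
   half-away-from-zero to integer grey and clamped to [0, 255]. The
   +128 re-centres the texture so flat regions sit exactly at mid-grey.
3. **Binarization at 128.** Values ≥ 128 are white. The tie value 128
   is assigned to white by convention: after flattening, textureless
   background sits exactly at 128, and either assignment is defensible,
   but one must be fixed or constant patches would be phase-ambiguous.
4. **Opening.** One binary erosion then one dilation with a 3×3 square
   on the white phase, removing isolated noise pixels thinner than
   3 px. Erosion pads with white and dilation with black, so an
   all-white patch survives unchanged.
5. **Inversion.** The originally dark phase becomes foreground; it is
   the phase subsequently analysed. The per-stage foreground fractions
   are recorded so users can audit phase identity.
6. **Skeletonization.** Zhang–Suen-type thinning followed by a
   block-breaking pass, iterated to a fixed point. Zhang–Suen alone can
   leave 2×2 staircase blocks; the extra pass deletes one
   topologically simple pixel (crossing number 1) per remaining block.
   The composite is idempotent by construction, never adds pixels, and
   guarantees the thinness invariant (no 2×2 all-foreground block).

A patch whose thresholded stage is constant carries no texture; it is
flagged `degenerate` and the fractal estimator refuses to produce a
number for it. Stage tags are enforced: running a stage on a patch in
the wrong state raises an error rather than silently continuing.

## Box counting and lacunarity

For box size ε, the patch is partitioned into ⌈H/ε⌉×⌈W/ε⌉ cells
(trailing cells partial, included by default). N(ε) is the number of
cells containing foreground; FD is the OLS slope of log N(ε) against
log(1/ε), unweighted over the configured sizes, with no automatic
scale-range pruning. The default ladder {2, 3, 4, 6, 8, 12, 16, 32, 64}
is the conventional one for 64 px trabecular ROIs. Estimates outside
[0, 2] (possible with partial-box noise on near-degenerate patterns)
are clamped with a warning, never silently.

**Grid offsets.** Counts are averaged over four deterministic grid
origins per size — (0,0), (⌊ε/2⌋,0), (0,⌊ε/2⌋), (⌊ε/2⌋,⌊ε/2⌋) —
implemented as *toroidal* (cyclic) shifts of the pattern against a
fixed covering grid. This choice was made after measuring the
alternative: bounded offset grids change the number of covering boxes
with the offset (at ε = patch side, 1 box vs 4), which breaks the
closed forms (filled square → 2.0, line → 1.0) whenever offsets are
averaged and *increases* the variance of FD across translations of the
same pattern (measured ratio ≈ 2.1). With toroidal shifts every grid
has the same box layout and total mass, the closed forms hold at any
offset count, and translation variance drops (measured ratio ≈ 0.38).
`n_offsets=1` reproduces the classic single-origin count exactly.

**Lacunarity.** Per grid, λ(ε) = (σ/μ)² over per-box masses with empty
boxes included (gappiness is the point); Λ(ε) averages λ over offsets,
and the summary scalar averages Λ(ε) over sizes. A uniform full
pattern has λ = 0 at every scale; a single pixel among four ε = 32
boxes on a 64 px patch has λ = 3. Lacunarity is phase-sensitive: a
pattern and its complement generally differ. Because published
lacunarity values depend on unstated aggregation conventions
(grid count, empty-box treatment, summary statistic), absolute
lacunarity is validated only against the package's own closed-form
oracles, not against external tables.

## Radiomorphometry

Landmarks are operator-supplied pixel coordinates: an inferior-border
polyline, the mental foramen's lower edge, and the endosteal (inner
cortical) margin polyline. The border tangent is the principal
direction of the k = 7 border vertices nearest the foramen's projection
(total least squares, so steep borders are handled); the measurement
axis is the normal through the projection foot, oriented toward the
foramen. MCW (*a*) is the axis distance from the border to the first
intersection with the endosteal margin; *b* is the axis distance to the
foramen; PMI = a/b. Both are invariant under rigid motions, and PMI
under uniform scaling — the property that makes it robust to panoramic
magnification. Whether *b* should be an along-axis or point-to-curve
distance is not settled; the along-axis convention is used (for a
locally straight border they coincide) and k is configurable. Units
are pixels throughout; no millimetre calibration is attempted.

## Group statistics

Kruskal–Wallis uses mid-ranks with the standard tie correction,
referred to χ²(k−1). An all-constant dataset (tie correction
denominator zero) is defined as H = 0, p = 1. Dunn's post-hoc z uses
pooled mid-ranks with tie term T = Σ(t³−t); adjusted p = min(1, 3·p)
for the three pairwise tests. The effect-size chain is
η² = H/(N−1) → f = √(η²/(1−η²)) → power from the noncentral
F(k−1, N−k; λ = f²N) beyond the central-F critical value. The
η² = H/(N−1) convention is the default because it is the one commonly
paired with this power approximation; the bias-adjusted
(H−k+1)/(N−k) variant is available via `convention="adjusted"` and is
systematically smaller (for H = 6.104, N = 92: 0.046 vs 0.067). The
power path rounds f to two decimals when reproducing published chains
computed from a rounded f; `anova_power` itself takes any f. The
age/sex check is an OLS of the regional metric on age and a sex
indicator, with rank-deficiency detected explicitly.

## Synthetic data: what it emulates, and what it does not

**Textures.** The depth-d Sierpinski carpet (8^d pixels on a 3^d grid)
has box-counting dimension log 8/log 3 ≈ 1.8928 on aligned dyadic-of-3
grids — the only desk-scale ground truth available for an FD
estimator. Spectral surfaces (1/f^β noise thresholded at the median)
and strut lattices provide irregular and regular line-network
phantoms; uniform, single-line and single-point patterns are
degenerate controls.

**Grey patches.** A texture is mapped to two grey levels (dark 90 on
bright 160 — the analysed phase is dark, because the chain inverts
before skeletonizing), then a linear illumination ramp of configurable
peak-to-peak amplitude and Gaussian pixel noise are added, rounded and
clamped. The ramp is a low-order stand-in for soft-tissue brightness
bias; it is what the σ = 35 step must remove. In grey phantoms the
carpet's struts default to 3 px wide: real trabeculae span several
pixels, and any structure thinner than the 3×3 opening would be erased
by the noise-removal step itself. The recovery oracle compares the
recovered skeleton's FD with the FD of the *skeletonized* clean
pattern — skeletonization thins any finite-width texture, so comparing
against the filled pattern's dimension would conflate thinning with
recovery error. Under zero noise the recovery is exact; with a
≤ 60-level ramp plus noise it stays within 0.15.

These phantoms do not emulate projection geometry, anatomical
context, focal-plane blur, scatter, or detector response; passing
tests demonstrates the correctness of the measurement chain on
patterns with known answers, not clinical validity on radiographs.

**Cohorts.** Per-patient metrics are drawn from Gaussians located at
the published group medians (FD, lacunarity per region; MCW, PMI per
side), with within-group SDs chosen from the published ranges
(range ≈ 4 SD): FD 0.12, lacunarity 0.05, MCW 9 px, PMI 0.10. Ages are
clipped Gaussians and sexes Bernoulli draws matching the study's
group-wise demographics; total cholesterol is drawn uniformly inside
each stratum's band so group labels are always consistent with the
5.2/6.2 mmol/L thresholds. The Gaussian location-shift form is a
modelling convention — the study reports only medians and ranges, not
distributions. `with_anterior_effect(f)` spaces the anterior-FD group
means monotonically so the size-weighted dispersion hits an exact
population Cohen's f, which is how the sensitivity analysis is
connected to simulation: at f = 0.27 with sizes (35, 33, 24) the
simulated Kruskal–Wallis rejection rate is ≈ 0.59, slightly below the
ANOVA-approximation power 0.62 because the rank test pays a Pitman
efficiency factor (≈ 0.955 under normality).

## Problem sizes used in the validation suite

Closed-form checks run on single 64×64 or 81×81 patches. Monte-Carlo
checks use 4000–5000 label permutations for the permutation oracle,
2000 replicates for the type-I-error and family-wise-error
calibrations, and 10000 seeded cohort replicates for the power-recovery
check (the estimate's Monte-Carlo error, ≈ 0.005, is then well below
the ±0.04 acceptance band). All stochastic tests are seeded and
deterministic.

## Known limitations

* ROI placement and landmark digitization are inputs, not outputs: the
  package measures what the operator marks.
* Absolute lacunarity values are convention-dependent (grid scan,
  empty-box handling, aggregation); only relative comparisons made
  under one configuration are meaningful.
* The achieved-power figure is an ANOVA approximation applied to a
  rank test; simulation shows it is mildly optimistic (0.62 vs ≈ 0.59).
* The preprocessing chain destroys structures thinner than its 3×3
  opening; single-pixel textures cannot be recovered by design.
* FD estimates on 64 px patches use at most nine scales spanning 1.5
  decades; they are comparative indices, not asymptotic dimensions.
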