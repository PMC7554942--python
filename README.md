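# qfib

Periportal-aware collagen quantification for dual-channel (SHG/TPEF)
liver-biopsy images, and the two-stage Wilcoxon screen that derives an
F1-vs-F2 fibrosis discriminant parameter panel.

## The problem

Non-alcoholic steatohepatitis (NASH) trials typically enroll patients with
stage 2–3 fibrosis. The histological boundary between stage 1 (F1,
perisinusoidal fibrosis only) and stage 2 (F2, perisinusoidal **plus**
periportal fibrosis) is subtle, and in-house pathology reads frequently
mis-stage it. Label-free second-harmonic generation (SHG) microscopy images
fibrillar collagen directly, and two-photon excited fluorescence (TPEF)
images the surrounding tissue, which makes the F1/F2 boundary quantifiable —
provided the analysis actually looks at the periportal zone.

`qfib` implements that refinement:

1. **Periportal region.** Around every annotated portal tract *P* the
   package builds the periportal region
   `PP = { x ∈ tissue : 0 < d(x, P) ≤ m }` with an exact Euclidean distance
   transform and margin *m* = 100 µm (boundary inclusive). What remains of
   the tissue is the *reduced perisinusoidal* (RPS) region, so
   portal ∪ periportal ∪ RPS tiles the tissue exactly.
2. **Fiber morphometry.** Each 8-connected component of the collagen mask is
   one *fiber string* with area *A* (pixel count × µm²/px), skeleton arc
   length *L*, and mean width *W = A/L*; dichotomous classes
   long/short (*L* ≥ 20 µm), thick/thin (*W* ≥ 3 µm) and
   aggregated/distributed (*A* ≥ 200 µm²), all boundary-inclusive and
   configurable.
3. **56-parameter vector.** Per region (periportal, RPS) and stratum (all /
   aggregated / distributed): collagen area percentage of the region, five
   fiber counts (#Str, #ShortStr, #LongStr, #ThinStr, #ThickStr) and three
   totals (StrArea, StrLength, StrWidth), plus one intersection count per
   region — 28 periportal + 28 RPS parameters.
4. **Screen and panel.** Parameters are compared between two sample groups
   with the two-sided Wilcoxon rank-sum test (exact permutation null for
   small tie-free samples, normal approximation with tie and continuity
   correction otherwise), significance strict *p* < 0.05, no multiplicity
   correction by default (Benjamini–Hochberg behind a flag). A two-stage
   screen — discovery contrast, then true-F1 vs true-F2 validation —
   retains the parameters that stay significant: applied to the published
   clinical p-values this reproduces the 26-parameter discriminant panel.

A synthetic-fixture generator (`qfib.synth`) produces calibrated SHG/TPEF
slides with exact ground truth for F0-, F1- and F2-like fibrosis patterns,
so the full pipeline is testable without clinical data.

## Worked example

```python
import dataclasses
from qfib import quantify_slide, compare_groups
from qfib.synth import F2LIKE, generate_slide

profile = dataclasses.replace(F2LIKE, noise_sd=0.0)   # noise-free fixture
slide, truth = generate_slide(profile, seed=7)        # 1024 px = 400 um field
vec = quantify_slide(slide, truth.regions.portal)

print(f"#StrPeriportal = {vec['#StrPeriportal']:.0f}  "
      f"(truth {sum(1 for f in truth.fibers if f.region == 'periportal')})")
print(f"#StrRPS        = {vec['#StrRPS']:.0f}  "
      f"(truth {sum(1 for f in truth.fibers if f.region == 'rps')})")
print(f"%Periportal    = {vec['%Periportal']:.2f}")
```

prints

```
#StrPeriportal = 27  (truth 27)
#StrRPS        = 29  (truth 29)
%Periportal    = 9.50
```

i.e. on a noise-free synthetic F2-like section the pipeline recovers every
ground-truth fiber in both regions, and periportal collagen occupies 9.5 %
of the periportal region's area. The same objects drive a cohort screen:

```python
from qfib.synth import F1LIKE, generate_cohort, truth_cohort_table

samples = generate_cohort(15, (F1LIKE, F2LIKE), seed=11)
results = compare_groups(truth_cohort_table(samples), "F1like", "F2like")
print(sum(r.significant for r in results), "of 56 parameters significant")
# -> 50 of 56 parameters significant
```

From the shell, the same workflow is `qfib simulate` → `qfib quantify` →
`qfib compare` → `qfib panel`; `qfib schema` prints the 56 parameter names.

## Documentation

`docs/methods.md` describes the model, the parameter schema and naming
grammar, every configurable threshold with its default and rationale, the
synthetic-data model and what passing tests do and do not show about
clinical data, and the numerical choices (tie rules, degenerate inputs,
windowed distance transforms).
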