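# floracue

Spectral-reflectance **marker points** for pollination ecology: detect
sharp reflectance transitions in 300–700 nm spectra, assemble
Monte-Carlo simulated natural backgrounds from material samples, and
test marker-point distributions for multimodality — the toolkit a visual
ecologist needs to ask *where in the spectrum do flower colour signals
sit relative to the rocks, bark and leaves behind them?*

## The science in brief

A surface's reflectance spectrum R(λ) (percent of incident light
reflected, measured against a white Lambertian standard) matters to a
bee or bird mostly through its sharp transitions. A **marker point** is
the midpoint of any change of at least a threshold *t* percentage points
occurring within less than 50 nm:

> marker at λ\*, where R crosses (R(λ₁)+R(λ₂))/2 on a window
> [λ₁, λ₂] with |R(λ₂) − R(λ₁)| ≥ t and λ₂ − λ₁ < 50 nm

with *t* = 20 for flower petals (the conventional salience threshold)
and *t* = 5 for unevolved background materials — calibrated so both
yield a similar mean number of markers per sample.

A **simulated background** is a with-replacement resample of 195
members from a stratified subset (65 green leaves + 65 dry materials +
65 rocks/minerals drawn without replacement), its members' markers
pooled and binned at 5 nm — the hue-discrimination limit of pollinator
vision. Repeating this 100 000 times gives the marker-point distribution
of the visual world a flower must stand out against.

Distributions are compared with:

* the **Hartigan–Hartigan dip** D = min over unimodal CDFs G of
  sup|F̂ₙ − G| (exact greatest-convex-minorant algorithm; uniform
  bootstrap null for p-values);
* the **critical bandwidth** h\*(k): the smallest Gaussian-KDE bandwidth
  at which the sample shows at most k modes (Silverman's monotonicity +
  bisection), with mode positions read off the KDE at h\*(k);
* **cumulative left-of-reference fractions**, e.g. the share of marker
  mass below the 500 nm centre line.

Everything is seeded and reproducible; a synthetic-spectra generator
with planted logistic steps provides ground truth so the whole pipeline
is testable without field data.

## Worked example

```python
import numpy as np, floracue as fc

pool, truth = fc.gen_pool(fc.GeneratorConfig(seed=7))

detector = fc.MarkerDetector(threshold=20.0)
flowers = detector.transform(pool.subset(fc.FLOWER_CLASSES))
insect = flowers.query("material_class == 'flower_insect'")["marker_nm"].to_numpy()

an = fc.ModalityAnalyzer(k=3, n_bootstrap=2000, random_state=0).fit(insect)

bg = pool.subset(fc.BACKGROUND_CLASSES)
bg_markers = fc.MarkerDetector(threshold=5.0).transform(bg)
sim = fc.BackgroundSimulator(n_iterations=10_000, random_state=1)
sim.fit(bg, markers=bg_markers)
```

which prints (via the obvious `print` statements):

```
pool: 728 samples, classes: {'dry_material': 96, 'flower_bird': 68,
  'flower_insect': 153, 'green_leaf': 65, 'rock_mineral': 346}
insect-pollinated flowers: 182 markers at the 20% threshold
dip D = 0.129 (p = 0.0000), critical bandwidth = 3.1 nm
modes: [401.9 514.6 652.8] nm
simulated backgrounds: median 215 markers (95% interval 189-242)
background marker mass left of 500 nm: 32%  (insect flowers: 54%)
```

Reading the numbers: the insect-flower marker distribution is strongly
multimodal (dip p ≈ 0 rejects unimodality), with modes near 402, 515 and
653 nm — the planted signal positions. A typical simulated background
contains ~215 markers, and insect-pollinated flowers concentrate more of
their marker mass below 500 nm (54 %) than the backgrounds do (32 %):
the short-wavelength shift that makes them conspicuous to trichromatic
bees.

The same stages are available as a CLI for field data
(`floracue synth | markers | simulate | modality | compare | run`); input
spectra are delimited text (wavelength column + replicate reflectance
columns) with a `sample_id, material_class, file` manifest CSV.

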