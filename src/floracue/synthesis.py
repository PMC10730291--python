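"""Synthetic reflectance spectra with planted transitions.

The generator emulates the material classes the analysis assumes so the
whole pipeline is testable without field data: smooth class-specific
baselines, planted logistic reflectance steps (the features marker
detection should recover), and smooth correlated measurement noise.
White noise would litter the spectra with spurious micro-extrema that a
real spectrophotometer's optical averaging does not produce, so noise is
generated with a ~20 nm correlation length.

Default templates (amplitudes in percentage points, centres in nm):

* green leaf — low UV/blue base rising into the ~550 nm green peak
  (step up near 524, step down near 580) and the chlorophyll red edge
  (a large rise near 696);
* dry material — a gentle monotone long-wavelength rise with moderate
  steps near 431 and 617;
* rock/mineral — flat-to-tilted bases of widely varying brightness with
  sparse steps (presence probability < 1) near 329, 421 and 558;
* flowers — one or two large (>= 25 point) sigmoid steps: near 404 and
  513 for insect-pollinated, near 439 and 606 for bird-pollinated.

Step centres, amplitudes and presence are jittered per sample; every
planted step is returned as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator

from .spectra import (CANONICAL_GRID, DRY_MATERIAL, FLOWER_BIRD,
                      FLOWER_INSECT, GREEN_LEAF, ROCK_MINERAL, SamplePool,
                      Spectrum)

#: logistic 10-90% rise spans 2*ln(9) ~ 4.394 scale units
_LOGISTIC_1090 = 2.0 * np.log(9.0)


@dataclass(frozen=True)
class StepSpec:
    """One planted sigmoid step: half-height at ``centre``, 10-90% rise
    within ``width`` nm; negative ``amplitude`` steps downward."""

    centre: float
    amplitude: float
    width: float = 20.0
    presence: float = 1.0      # probability the step is present
    centre_jitter: float = 0.0  # sd of Gaussian jitter on the centre
    amplitude_jitter: float = 0.0

    def __post_init__(self):
        if not (310.0 <= self.centre <= 690.0):
            raise ValueError(f"step centre {self.centre} outside [310, 690]")
        if not (0 < self.width < 50.0):
            raise ValueError(f"step width {self.width} must be in (0, 50)")
        if self.amplitude == 0:
            raise ValueError("step amplitude must be non-zero")


@dataclass(frozen=True)
class ClassTemplate:
    """Per-class recipe: baseline family + planted steps + noise."""

    material_class: str
    baseline: str = "flat"            # flat | tilt | green_leaf
    base_level: float = 10.0
    base_slope: float = 0.0           # %% per nm, for "tilt"
    base_level_jitter: float = 0.0
    steps: tuple = ()
    noise_sd: float = 0.0             # percentage points
    noise_correlation_length: float = 20.0  # nm


def _baseline(template: ClassTemplate, level: float) -> np.ndarray:
    w = CANONICAL_GRID
    if template.baseline == "flat":
        return np.full(w.size, level)
    if template.baseline == "tilt":
        return level + template.base_slope * (w - w[0])
    if template.baseline == "green_leaf":
        # gentle broad curvature under the planted green-peak steps
        return level + 1.5 * np.exp(-0.5 * ((w - 550.0) / 60.0) ** 2)
    raise ValueError(f"unknown baseline family {template.baseline!r}")


def _logistic_step(w, centre, amplitude, width):
    scale = width / _LOGISTIC_1090
    return amplitude / (1.0 + np.exp(-(w - centre) / scale))


def _correlated_noise(rng, sd, corr_len):
    # pad so the cropped interior is stationary (no boundary variance
    # inflation), and scale by the theoretical filtered sd so the noise
    # level does not depend on the realisation
    n = CANONICAL_GRID.size
    sigma = max(corr_len, 1e-6)
    pad = int(np.ceil(4 * sigma))
    white = rng.standard_normal(n + 2 * pad)
    smooth = gaussian_filter1d(white, sigma=sigma,
                               mode="constant")[pad:pad + n]
    theoretical_sd = (2.0 * sigma * np.sqrt(np.pi)) ** -0.5
    return smooth * (sd / theoretical_sd)


def gen_spectrum(template: ClassTemplate, rng, sample_id="synthetic"):
    """One spectrum from a template.  Returns (Spectrum, planted steps):
    the realised steps after jitter/presence, as a list of StepSpec."""
    level = template.base_level
    if template.base_level_jitter > 0:
        level = max(0.5, level + template.base_level_jitter
                    * rng.standard_normal())
    y = _baseline(template, level)
    realised = []
    for st in template.steps:
        if st.presence < 1.0 and rng.random() >= st.presence:
            continue
        centre = st.centre + st.centre_jitter * rng.standard_normal()
        centre = float(np.clip(centre, 310.0, 690.0))
        amp = st.amplitude
        if st.amplitude_jitter > 0:
            amp = amp * float(np.exp(st.amplitude_jitter
                                     * rng.standard_normal() - 0.5
                                     * st.amplitude_jitter ** 2))
        y = y + _logistic_step(CANONICAL_GRID, centre, amp, st.width)
        realised.append(replace(st, centre=centre, amplitude=amp,
                                presence=1.0, centre_jitter=0.0,
                                amplitude_jitter=0.0))
    if template.noise_sd > 0:
        y = y + _correlated_noise(rng, template.noise_sd,
                                  template.noise_correlation_length)
    y = np.clip(y, 0.0, None)
    spec = Spectrum(sample_id=sample_id,
                    material_class=template.material_class,
                    wavelengths=CANONICAL_GRID.copy(), reflectance=y)
    return spec, realised


def default_templates(noise_sd: float = 1.0) -> dict:
    """Study-condition templates keyed by material class.

    Step presence probabilities put the expected markers per sample near
    the field collection's per-class means (~1.4 leaf, ~1.3 dry, ~0.7
    rock, ~1.2 insect flower, ~0.7 bird flower).  Small sub-threshold
    troughs between candidate step positions mimic the local dips of real
    spectra; they never qualify as markers themselves but keep
    co-occurring steps in separate monotone segments.
    """
    return {
        GREEN_LEAF: ClassTemplate(
            material_class=GREEN_LEAF, baseline="green_leaf",
            base_level=4.0, base_level_jitter=1.0,
            steps=(
                StepSpec(524.0, 8.0, width=26.0, presence=0.55,
                         centre_jitter=6.0, amplitude_jitter=0.25),
                StepSpec(580.0, -6.5, width=20.0, presence=0.5,
                         centre_jitter=6.0, amplitude_jitter=0.25),
                StepSpec(690.0, 30.0, width=22.0, presence=0.45,
                         centre_jitter=3.0, amplitude_jitter=0.2),
            ),
            noise_sd=noise_sd,
        ),
        DRY_MATERIAL: ClassTemplate(
            material_class=DRY_MATERIAL, baseline="tilt",
            base_level=8.0, base_slope=0.01, base_level_jitter=3.0,
            steps=(
                StepSpec(431.0, 7.5, width=28.0, presence=0.65,
                         centre_jitter=9.0, amplitude_jitter=0.3),
                StepSpec(520.0, -3.0, width=12.0),   # segmenting trough
                StepSpec(617.0, 9.0, width=32.0, presence=0.65,
                         centre_jitter=9.0, amplitude_jitter=0.3),
            ),
            noise_sd=noise_sd,
        ),
        ROCK_MINERAL: ClassTemplate(
            material_class=ROCK_MINERAL, baseline="tilt",
            base_level=18.0, base_slope=0.008, base_level_jitter=8.0,
            steps=(
                StepSpec(329.0, 7.0, width=24.0, presence=0.25,
                         centre_jitter=8.0, amplitude_jitter=0.35),
                StepSpec(375.0, -2.5, width=12.0),   # segmenting trough
                StepSpec(421.0, 8.0, width=26.0, presence=0.25,
                         centre_jitter=8.0, amplitude_jitter=0.35),
                StepSpec(490.0, -2.5, width=12.0),   # segmenting trough
                StepSpec(558.0, 7.5, width=28.0, presence=0.25,
                         centre_jitter=8.0, amplitude_jitter=0.35),
            ),
            noise_sd=noise_sd,
        ),
        FLOWER_INSECT: ClassTemplate(
            material_class=FLOWER_INSECT, baseline="flat",
            base_level=6.0, base_level_jitter=2.0,
            steps=(
                StepSpec(404.0, 30.0, width=22.0, presence=0.65,
                         centre_jitter=7.0, amplitude_jitter=0.2),
                StepSpec(460.0, -10.0, width=14.0),  # segmenting trough
                StepSpec(513.0, 38.0, width=24.0, presence=0.45,
                         centre_jitter=7.0, amplitude_jitter=0.2),
                StepSpec(654.0, 28.0, width=22.0, presence=0.15,
                         centre_jitter=7.0, amplitude_jitter=0.2),
            ),
            noise_sd=noise_sd,
        ),
        FLOWER_BIRD: ClassTemplate(
            material_class=FLOWER_BIRD, baseline="flat",
            base_level=6.0, base_level_jitter=2.0,
            steps=(
                StepSpec(439.0, 26.0, width=22.0, presence=0.30,
                         centre_jitter=7.0, amplitude_jitter=0.2),
                StepSpec(520.0, -10.0, width=14.0),  # segmenting trough
                StepSpec(606.0, 42.0, width=24.0, presence=0.42,
                         centre_jitter=7.0, amplitude_jitter=0.2),
            ),
            noise_sd=noise_sd,
        ),
    }


#: field collection sizes: 65 green leaves, 96 dry samples, 346 rocks,
#: 153 insect-pollinated and 68 bird-pollinated flowers
DEFAULT_CLASS_SIZES = {
    GREEN_LEAF: 65,
    DRY_MATERIAL: 96,
    ROCK_MINERAL: 346,
    FLOWER_INSECT: 153,
    FLOWER_BIRD: 68,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Pool recipe: per-class sample counts and templates, plus a seed."""

    class_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    templates: dict = field(default_factory=default_templates)
    seed: object = None

    def __post_init__(self):
        for cls, n in self.class_sizes.items():
            if n < 1:
                raise ValueError(f"class {cls!r}: n must be >= 1")
            if cls not in self.templates:
                raise ValueError(f"no template for class {cls!r}")


def gen_pool(config: GeneratorConfig):
    """Generate a pool of spectra plus the planted-step ground truth.

    Returns ``(SamplePool, DataFrame)``; the ground truth has one row per
    realised step with columns sample_id, material_class, centre_nm,
    amplitude_pct, width_nm, direction.
    """
    root = np.random.SeedSequence(config.seed)
    pool = SamplePool()
    truth_rows = []
    classes = sorted(config.class_sizes)  # deterministic order
    streams = root.spawn(len(classes))
    for cls, stream in zip(classes, streams):
        rng = np.random.default_rng(stream)
        template = config.templates[cls]
        for i in range(config.class_sizes[cls]):
            sid = f"{cls}_{i:04d}"
            spec, steps = gen_spectrum(template, rng, sample_id=sid)
            pool.add(spec)
            for st in steps:
                truth_rows.append((sid, cls, st.centre, st.amplitude,
                                   st.width,
                                   "rise" if st.amplitude > 0 else "fall"))
    truth = pd.DataFrame(truth_rows, columns=[
        "sample_id", "material_class", "centre_nm", "amplitude_pct",
        "width_nm", "direction"])
    return pool, truth


def write_pool(pool: SamplePool, out_dir, truth: pd.DataFrame = None) -> None:
    """Emit a pool in the delimited-text exchange format: one CSV per
    sample, a manifest.csv, and optionally ground_truth.csv."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    records = []
    for spec in pool:
        fname = f"{spec.sample_id}.csv"
        pd.DataFrame({"wavelength_nm": spec.wavelengths,
                      "reflectance_pct": spec.reflectance}).to_csv(
            os.path.join(out_dir, fname), index=False)
        records.append((spec.sample_id, spec.material_class, fname))
    pd.DataFrame(records, columns=["sample_id", "material_class", "file"]) \
        .to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    if truth is not None:
        truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)


class SpectrumGenerator(BaseEstimator):
    """Estimator-style front end to the pool generator.

    ``sample(n_overrides=None)`` returns ``(SamplePool, ground_truth)``
    using the configured templates, class sizes and random_state.
    """

    def __init__(self, class_sizes=None, templates=None, noise_sd=1.0,
                 random_state=None):
        self.class_sizes = class_sizes
        self.templates = templates
        self.noise_sd = noise_sd
        self.random_state = random_state

    def _config(self) -> GeneratorConfig:
        return GeneratorConfig(
            class_sizes=dict(self.class_sizes) if self.class_sizes
            else dict(DEFAULT_CLASS_SIZES),
            templates=dict(self.templates) if self.templates
            else default_templates(self.noise_sd),
            seed=self.random_state,
        )

    def sample(self):
        return gen_pool(self._config())
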