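import numpy as np
import pytest

import floracue as fc


@pytest.fixture
def grid():
    return fc.CANONICAL_GRID


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_spectrum(y, sample_id="s", material_class="other"):
    return fc.Spectrum(sample_id, material_class, fc.CANONICAL_GRID,
                       np.asarray(y, dtype=float))


def ramp_spectrum(lo=10.0, hi=40.0, start=495.0, stop=505.0,
                  sample_id="ramp", material_class="other"):
    """Flat at lo, linear ramp between start and stop, flat at hi."""
    y = np.interp(fc.CANONICAL_GRID, [300.0, start, stop, 700.0],
                  [lo, lo, hi, hi])
    return make_spectrum(y, sample_id, material_class)


def random_piecewise_linear(rng, n_knots=None, lo=0.0, hi=80.0):
    """A random piecewise-linear spectrum on the canonical grid."""
    if n_knots is None:
        n_knots = int(rng.integers(4, 12))
    knots = np.sort(rng.choice(np.arange(300.0, 701.0), size=n_knots,
                               replace=False))
    knots[0], knots[-1] = 300.0, 700.0
    vals = rng.uniform(lo, hi, size=n_knots)
    y = np.interp(fc.CANONICAL_GRID, knots, vals)
    return make_spectrum(y)


@pytest.fixture
def tiny_pool():
    """One sample per background class, each with a single planted step."""
    specs = []
    for cls, centre in ((fc.BACKGROUND_CLASSES[0], 450.0),
                        (fc.BACKGROUND_CLASSES[1], 520.0),
                        (fc.BACKGROUND_CLASSES[2], 600.0)):
        y = np.interp(fc.CANONICAL_GRID,
                      [300.0, centre - 5, centre + 5, 700.0],
                      [10.0, 10.0, 30.0, 30.0])
        specs.append(fc.Spectrum(f"{cls}_demo", cls, fc.CANONICAL_GRID, y))
    return fc.SamplePool(specs)
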