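"""Multimodality statistics for marker-point distributions.

Implements the modality toolkit the background/flower comparison needs:

* the Hartigan–Hartigan dip test of unimodality, with a uniform(0, 1)
  bootstrap null for the p-value (the standard calibration: the uniform
  is the asymptotically least favourable unimodal distribution);
* critical bandwidths in the sense of Silverman: the smallest Gaussian
  kernel bandwidth h at which the KDE of the sample has at most k local
  maxima (mode count is non-increasing in h for Gaussian kernels, so
  bisection applies);
* mode location: positions of the k density maxima at the critical
  bandwidth, parabolically refined between grid points;
* a Silverman-type bootstrap sequence to choose the mode count k;
* cumulative left-of-reference fractions for distribution comparisons.

All routines accept optional non-negative weights so the 5 nm-binned
output of large background simulations (bin centres + counts) can be
analysed without expanding millions of marker points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._dip import dip_statistic

__all__ = [
    "DipResult", "ModalityReport", "dip_statistic", "dip_test",
    "critical_bandwidth", "count_modes", "locate_modes",
    "select_mode_count", "cumulative_left_fraction", "kde_density",
    "ModalityAnalyzer",
]


@dataclass(frozen=True)
class DipResult:
    D: float
    p_value: float
    n: int
    n_bootstrap: int


@dataclass(frozen=True)
class ModalityReport:
    k: int
    critical_bandwidth: float
    mode_positions: tuple
    dip: DipResult | None


# ---------------------------------------------------------------------------
# dip test
# ---------------------------------------------------------------------------

def dip_test(sample, n_bootstrap: int = 2000, seed=None) -> DipResult:
    """Dip test of the null of unimodality.

    The p-value is the proportion of uniform(0, 1) samples of the same
    size whose dip is at least the observed dip.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    d_obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_bootstrap):
        if dip_statistic(rng.random(n)) >= d_obs:
            exceed += 1
    return DipResult(D=d_obs, p_value=exceed / n_bootstrap, n=n,
                     n_bootstrap=n_bootstrap)


# ---------------------------------------------------------------------------
# Gaussian KDE mode machinery
# ---------------------------------------------------------------------------

def _check_weights(x, weights):
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape:
            raise ValueError("weights must match the sample shape")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    return x, w


def _kde_on(grid, x, w, h):
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z) @ w
    return dens / (w.sum() * h * np.sqrt(2.0 * np.pi))


def _eval_grid(x, h):
    lo = x.min() - 4.0 * h
    hi = x.max() + 4.0 * h
    step = min(h / 5.0, 1.0)
    n = int(np.ceil((hi - lo) / step)) + 1
    return np.linspace(lo, hi, min(max(n, 16), 100_001))


def _local_maxima(dens, grid):
    """Indices of local maxima, merging flat plateaus (centre reported)."""
    s = np.sign(np.diff(dens))
    # propagate the previous non-zero slope sign through exact plateaus
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    out = []
    for i in range(1, s.size):
        if s[i - 1] > 0 and s[i] < 0:
            out.append(i)
    if s.size and s[0] < 0:
        out.insert(0, 0)
    if s.size and s[-1] > 0:
        out.append(s.size)
    return out


def count_modes(x, h, weights=None) -> int:
    """Number of local maxima of the Gaussian KDE at bandwidth h."""
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    x, w = _check_weights(x, weights)
    grid = _eval_grid(x, h)
    return len(_local_maxima(_kde_on(grid, x, w, h), grid))


def critical_bandwidth(sample, k: int = 1, weights=None, tol: float = 0.01):
    """Smallest Gaussian bandwidth with at most k KDE modes (bisection).

    The bracket is refined until its width is below both ``tol`` (nm) and
    0.5% of the bandwidth, so a 1% perturbation of the returned value is
    guaranteed to sit on the other side of the true critical point.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, w = _check_weights(sample, weights)
    if x.size < 2:
        raise ValueError("critical bandwidth needs n >= 2")
    span = x.max() - x.min()
    if span == 0 or np.unique(x).size <= k:
        return tol  # too few distinct points ever to exceed k modes
    lo = 1e-3 * span
    while count_modes(x, lo, w) <= k and lo > 1e-8 * span:
        lo /= 4.0
    if count_modes(x, lo, w) <= k:
        return lo  # sample has no bandwidth with more than k modes
    hi = span / 2.0
    while count_modes(x, hi, w) > k:
        hi *= 2.0
    while hi - lo > min(tol, 0.005 * hi):
        mid = 0.5 * (lo + hi)
        if count_modes(x, mid, w) > k:
            lo = mid
        else:
            hi = mid
    return hi


def kde_density(markers, bandwidth, weights=None, grid=None):
    """Gaussian KDE on the 1 nm wavelength grid, renormalised to integrate
    to 1 over [300, 700] nm.  Returns ``(grid, density)``."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    x, w = _check_weights(markers, weights)
    if grid is None:
        from .spectra import CANONICAL_GRID
        grid = CANONICAL_GRID
    dens = _kde_on(np.asarray(grid, dtype=float), x, w, bandwidth)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return np.asarray(grid, dtype=float), dens


def _refine_parabolic(grid, dens, i):
    if i == 0 or i == grid.size - 1:
        return float(grid[i])
    y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(grid[i])
    shift = 0.5 * (y0 - y2) / denom
    step = grid[i + 1] - grid[i]
    return float(grid[i] + np.clip(shift, -1, 1) * step)


def locate_modes(sample, k: int, weights=None, dip: DipResult | None = None,
                 tol: float = 0.01) -> ModalityReport:
    """Critical bandwidth for k modes and the k mode positions there."""
    x, w = _check_weights(sample, weights)
    if x.size < 4:
        raise ValueError("locate_modes requires n >= 4")
    h = critical_bandwidth(x, k, weights=w, tol=tol)
    grid = _eval_grid(x, h)
    dens = _kde_on(grid, x, w, h)
    maxima = _local_maxima(dens, grid)
    if len(maxima) < k:
        raise RuntimeError(
            f"expected {k} modes at the critical bandwidth, found "
            f"{len(maxima)} (bisection inconsistency)"
        )
    positions = sorted(_refine_parabolic(grid, dens, i) for i in maxima)
    lo, hi = float(x.min()), float(x.max())
    positions = [min(max(p, lo), hi) for p in positions]
    return ModalityReport(k=k, critical_bandwidth=float(h),
                          mode_positions=tuple(positions), dip=dip)


def select_mode_count(sample, max_k: int = 6, alpha: float = 0.05,
                      n_bootstrap: int = 200, seed=None,
                      weights=None) -> int:
    """Smallest k not rejected by a Silverman-type bootstrap mode test.

    For each k in 1..max_k: h_k is the critical bandwidth for k modes;
    smooth-bootstrap samples are drawn from the KDE at h_k (resample the
    data, add Gaussian noise of sd h_k, rescale to preserve the sample
    variance) and the test p-value is the proportion of bootstrap samples
    whose KDE at h_k has more than k modes.  Returns the first k with
    p >= alpha, else max_k.
    """
    x, w = _check_weights(sample, weights)
    if x.size < 4:
        raise ValueError("select_mode_count requires n >= 4")
    rng = np.random.default_rng(seed)
    n = x.size
    p = w / w.sum()
    var = np.average((x - np.average(x, weights=w)) ** 2, weights=w)
    for k in range(1, max_k + 1):
        h = critical_bandwidth(x, k, weights=w)
        scale = 1.0 / np.sqrt(1.0 + h * h / var) if var > 0 else 1.0
        exceed = 0
        for _ in range(n_bootstrap):
            boot = rng.choice(x, size=n, p=p) + h * rng.standard_normal(n)
            boot = np.average(x, weights=w) + scale * (
                boot - np.average(x, weights=w))
            if count_modes(boot, h) > k:
                exceed += 1
        if exceed / n_bootstrap >= alpha:
            return k
    return max_k


def cumulative_left_fraction(markers, reference: float,
                             weights=None) -> float:
    """Fraction of marker mass strictly below the reference wavelength."""
    x, w = _check_weights(markers, weights)
    return float(w[x < reference].sum() / w.sum())


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ModalityAnalyzer(BaseEstimator):
    """Fit the full modality analysis to a set of marker wavelengths.

    Parameters
    ----------
    k : int or "auto"
        Number of modes; "auto" selects it with the Silverman-type
        bootstrap sequence.
    max_k, alpha, n_bootstrap_modes : mode-count selection settings.
    n_bootstrap : bootstrap replicates for the dip p-value.
    run_dip : set False to skip the dip test (e.g. weighted binned input,
        where the dip is computed upstream on raw markers).
    random_state : seed for both bootstraps.

    Attributes (after ``fit``)
    --------------------------
    dip_, dip_pvalue_ : dip statistic and bootstrap p-value (or None).
    k_ : chosen/fixed mode count.
    critical_bandwidth_ : nm.
    mode_positions_ : ndarray of the k mode wavelengths, ascending.
    report_ : the bundled :class:`ModalityReport`.
    """

    def __init__(self, k="auto", max_k=6, alpha=0.05, n_bootstrap=2000,
                 n_bootstrap_modes=200, run_dip=True, random_state=None):
        self.k = k
        self.max_k = max_k
        self.alpha = alpha
        self.n_bootstrap = n_bootstrap
        self.n_bootstrap_modes = n_bootstrap_modes
        self.run_dip = run_dip
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None):
        x, w = _check_weights(X, sample_weight)
        seed_seq = np.random.SeedSequence(
            self.random_state if self.random_state is not None else None)
        s_dip, s_modes = seed_seq.spawn(2)
        dip = None
        if self.run_dip:
            if sample_weight is not None:
                raise ValueError(
                    "dip test needs raw (unweighted) markers; pass "
                    "run_dip=False for weighted input"
                )
            dip = dip_test(x, n_bootstrap=self.n_bootstrap, seed=s_dip)
        if self.k == "auto":
            k = select_mode_count(x, max_k=self.max_k, alpha=self.alpha,
                                  n_bootstrap=self.n_bootstrap_modes,
                                  seed=s_modes, weights=w)
        else:
            k = int(self.k)
        report = locate_modes(x, k, weights=w, dip=dip)
        self.dip_ = dip.D if dip is not None else None
        self.dip_pvalue_ = dip.p_value if dip is not None else None
        self.k_ = report.k
        self.critical_bandwidth_ = report.critical_bandwidth
        self.mode_positions_ = np.asarray(report.mode_positions)
        self.report_ = report
        self.n_features_in_ = 1
        return self
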