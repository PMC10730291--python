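"""Marker-point detection in reflectance spectra.

A marker point is the midpoint of a sharp reflectance transition: a
change of at least ``threshold`` percentage points of reflectance
occurring within a window narrower than ``max_span`` (50 nm).  Detection
runs on a lightly smoothed spectrum, segments it at confirmed local
extrema, and emits at most one marker per monotone segment:

1. centred moving-average smoothing (window truncates symmetrically at
   the spectrum ends, no padding);
2. lookahead extremum confirmation: a running extremum candidate is
   confirmed when, within ``lookahead`` subsequent grid points, the curve
   departs from it by at least ``min_delta`` in the opposing direction;
   the first and last grid points are appended as virtual extrema so
   boundary transitions are scanned too;
3. within each segment between consecutive extrema, the shortest window
   [λ1, λ2] with |R(λ2) − R(λ1)| ≥ threshold and λ2 − λ1 < max_span
   qualifies the segment (ties: steeper change, then shorter wavelength);
   the window is then extended outward while reflectance keeps changing
   strictly in the same direction, so the marker describes the full
   transition from base to peak;
4. the marker wavelength is where the smoothed curve crosses the
   half-height (R(λ1)+R(λ2))/2, linearly interpolated between grid
   points; magnitude is the full |ΔR| of the extended window and span its
   width.

Thresholds are absolute percentage points of reflectance (the study
convention: 5 for natural background materials, 20 for flowers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import MARKER_COLUMNS, SamplePool, Spectrum, to_canonical

RISE = "rise"
FALL = "fall"

DEFAULT_MAX_SPAN = 50.0
DEFAULT_SMOOTHING_WINDOW = 21
DEFAULT_LOOKAHEAD = 5


@dataclass(frozen=True)
class MarkerPoint:
    """A detected sharp-transition location."""

    sample_id: str
    wavelength: float      # nm, half-height midpoint of the transition
    magnitude: float       # percentage points, full change of the transition
    span: float            # nm, width of the extended transition window
    direction: str         # "rise" or "fall"


@dataclass(frozen=True)
class DetectionConfig:
    """Marker detection parameters (defaults follow the study settings)."""

    threshold: float = 5.0
    max_span: float = DEFAULT_MAX_SPAN
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    lookahead: int = DEFAULT_LOOKAHEAD
    min_delta: float | None = None   # None -> threshold / 4
    directions: tuple = (RISE, FALL)

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.max_span <= 0:
            raise ValueError("max_span must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.lookahead < 1:
            raise ValueError("lookahead must be >= 1")
        bad = set(self.directions) - {RISE, FALL}
        if bad or not self.directions:
            raise ValueError(f"directions must be a non-empty subset of "
                             f"{{'{RISE}', '{FALL}'}}, got {self.directions}")

    @property
    def effective_min_delta(self) -> float:
        return self.threshold / 4.0 if self.min_delta is None else self.min_delta


def smooth_spectrum(spectrum: Spectrum, window: int) -> Spectrum:
    """Centred moving average; the window truncates symmetrically at the
    boundaries to the available points (no padding)."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    n = len(spectrum)
    if window > n:
        raise ValueError(f"smoothing window {window} exceeds spectrum length {n}")
    from dataclasses import replace
    return replace(spectrum,
                   reflectance=_moving_average(spectrum.reflectance, window))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return y.astype(float).copy()
    n = y.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(y, dtype=float)))
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))  # symmetric truncation
    lo = idx - k
    hi = idx + k
    return (csum[hi + 1] - csum[lo]) / (2 * k + 1)


def detect_extrema(spectrum: Spectrum, lookahead: int, min_delta: float):
    """Alternating confirmed minima/maxima of a (smoothed) spectrum.

    Returns a list of ``(wavelength, reflectance, kind)`` with kind in
    {"min", "max"}; interior extrema only (no virtual endpoints).
    """
    y = np.asarray(spectrum.reflectance, dtype=float)
    idx = _extrema_indices(y, lookahead, min_delta)
    w = spectrum.wavelengths
    return [(float(w[i]), float(y[i]), kind) for i, kind in idx]


def _extrema_indices(y: np.ndarray, lookahead: int, min_delta: float):
    """Confirmed alternating extrema as (index, kind) pairs.

    Classic delta/lookahead peak detection: a running extremum candidate
    is confirmed once the curve has departed from it by ``min_delta`` in
    the opposing direction, provided no better candidate appears within
    the next ``lookahead`` points at confirmation time.  Extrema at the
    first/last grid point are not reported (those are the virtual
    endpoints of the segment scan).
    """
    n = y.size
    out = []
    mxpos = mnpos = 0
    state = 0            # 0 unknown, -1 seeking a min next, +1 seeking a max
    for j in range(1, n):
        v = y[j]
        if v > y[mxpos]:
            mxpos = j
        if v < y[mnpos]:
            mnpos = j
        if state >= 0 and v < y[mxpos] - min_delta:
            ahead = y[j + 1:j + 1 + lookahead]
            if ahead.size == 0 or ahead.max() < y[mxpos]:
                out.append((mxpos, "max"))
                state = -1
                mnpos = mxpos + int(np.argmin(y[mxpos:j + 1]))
                mxpos = j
                continue
        if state <= 0 and v > y[mnpos] + min_delta:
            ahead = y[j + 1:j + 1 + lookahead]
            if ahead.size == 0 or ahead.min() > y[mnpos]:
                out.append((mnpos, "min"))
                state = 1
                mxpos = mnpos + int(np.argmax(y[mnpos:j + 1]))
                mnpos = j
    return [(i, kind) for i, kind in out if 0 < i < n - 1]


def _segment_bounds(n: int, extrema_idx) -> list:
    """Segment index ranges between consecutive extrema, with the first and
    last grid points as virtual extrema."""
    knots = [0] + [i for i, _ in extrema_idx] + [n - 1]
    knots = sorted(set(knots))
    return [(a, b) for a, b in zip(knots[:-1], knots[1:]) if b > a]


def _best_window(y: np.ndarray, w: np.ndarray, a: int, b: int,
                 threshold: float, max_span: float, directions):
    """Shortest qualifying window in segment [a, b] (grid indices).

    Returns (i, j, signed_change) or None.  Ties: shortest span, then
    larger |change|, then smaller start wavelength.
    """
    best = None
    signs = []
    if RISE in directions:
        signs.append(1.0)
    if FALL in directions:
        signs.append(-1.0)
    length = b - a + 1
    for span_pts in range(1, length):
        widths = w[a + span_pts:b + 1] - w[a:b + 1 - span_pts]
        if widths.min() >= max_span:
            break  # every window at this index span is already too wide
        found = None
        for i in range(a, b + 1 - span_pts):
            j = i + span_pts
            if w[j] - w[i] >= max_span:
                continue
            d = y[j] - y[i]
            for s in signs:
                if s * d >= threshold:
                    cand = (i, j, d)
                    if found is None or abs(d) > abs(found[2]):
                        found = cand
                    break
        if found is not None:
            best = found
            break
    return best


def _extend_window(y: np.ndarray, a: int, b: int, i: int, j: int,
                   sign: float):
    """Grow [i, j] within [a, b] while the curve keeps changing strictly in
    the transition's direction, capturing the full base-to-peak jump."""
    while i > a and sign * (y[i] - y[i - 1]) > 0:
        i -= 1
    while j < b and sign * (y[j + 1] - y[j]) > 0:
        j += 1
    return i, j


def _half_height_crossing(y: np.ndarray, w: np.ndarray, i: int, j: int,
                          sign: float) -> float:
    """First crossing of the half-height level inside [i, j], linearly
    interpolated between grid points."""
    mid = 0.5 * (y[i] + y[j])
    for t in range(i, j):
        y0, y1 = y[t], y[t + 1]
        if (sign > 0 and y0 <= mid <= y1) or (sign < 0 and y0 >= mid >= y1):
            if y1 == y0:
                return float(w[t])
            frac = (mid - y0) / (y1 - y0)
            return float(w[t] + frac * (w[t + 1] - w[t]))
    return float(0.5 * (w[i] + w[j]))  # unreachable for monotone windows


def extract_markers(spectrum: Spectrum, config: DetectionConfig) -> list:
    """Detect all marker points of one spectrum (canonical grid)."""
    spectrum = to_canonical(spectrum)
    if len(spectrum) < config.smoothing_window:
        raise ValueError(
            f"{spectrum.sample_id!r}: spectrum shorter than smoothing window"
        )
    sm = smooth_spectrum(spectrum, config.smoothing_window)
    y = sm.reflectance
    w = sm.wavelengths
    extrema = _extrema_indices(y, config.lookahead, config.effective_min_delta)
    markers = []
    for a, b in _segment_bounds(y.size, extrema):
        win = _best_window(y, w, a, b, config.threshold, config.max_span,
                           config.directions)
        if win is None:
            continue
        i, j, d = win
        sign = 1.0 if d > 0 else -1.0
        i, j = _extend_window(y, a, b, i, j, sign)
        magnitude = abs(y[j] - y[i])
        markers.append(MarkerPoint(
            sample_id=spectrum.sample_id,
            wavelength=_half_height_crossing(y, w, i, j, sign),
            magnitude=float(magnitude),
            span=float(w[j] - w[i]),
            direction=RISE if sign > 0 else FALL,
        ))
    return markers


def markers_for_pool(pool: SamplePool, config: DetectionConfig) -> pd.DataFrame:
    """Marker table for every sample of a pool (``MARKER_COLUMNS`` schema).

    Samples with no markers simply contribute no rows; detection errors
    are re-raised with the sample id attached.
    """
    rows = []
    for spec in pool:
        try:
            found = extract_markers(spec, config)
        except Exception as exc:
            raise RuntimeError(
                f"marker detection failed for sample {spec.sample_id!r}: {exc}"
            ) from exc
        for m in found:
            rows.append((m.sample_id, spec.material_class, m.wavelength,
                         m.magnitude, m.span, m.direction))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


class MarkerDetector(TransformerMixin, BaseEstimator):
    """Transformer from spectra to a marker-point table.

    Parameters mirror :class:`DetectionConfig`; ``transform`` accepts a
    :class:`~floracue.spectra.SamplePool`, a single Spectrum, or an
    iterable of Spectrum and returns a tidy ``DataFrame`` with one row per
    detected marker.  Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, threshold=5.0, max_span=DEFAULT_MAX_SPAN,
                 smoothing_window=DEFAULT_SMOOTHING_WINDOW,
                 lookahead=DEFAULT_LOOKAHEAD, min_delta=None,
                 directions=(RISE, FALL)):
        self.threshold = threshold
        self.max_span = max_span
        self.smoothing_window = smoothing_window
        self.lookahead = lookahead
        self.min_delta = min_delta
        self.directions = directions

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            threshold=self.threshold, max_span=self.max_span,
            smoothing_window=self.smoothing_window, lookahead=self.lookahead,
            min_delta=self.min_delta, directions=tuple(self.directions),
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X) -> pd.DataFrame:
        config = self._config()
        if isinstance(X, Spectrum):
            X = SamplePool([X])
        elif not isinstance(X, SamplePool):
            X = SamplePool(list(X))
        return markers_for_pool(X, config)
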