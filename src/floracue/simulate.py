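"""Monte-Carlo assembly of simulated natural flower backgrounds.

A simulated background is built in two stages from the pool of natural
material samples (green leaves, dry plant material, rocks/minerals):

1. a stratified subset of ``n_per_class`` (default 65) samples per
   background class is drawn uniformly *without* replacement — the green
   leaf class, being the smallest in the field collection, sets the
   stratum size;
2. ``background_size`` (default 195 = 3 x 65) members are then drawn
   *with* replacement from that subset, so a background may contain
   duplicate samples and unequal class representation, like a real patch
   of habitat behind a flower.

The marker points of all drawn members are pooled per background, and
across iterations accumulated into 5 nm bins over 300-700 nm.  Each
iteration uses an RNG sub-stream spawned from the root seed by iteration
index, so results are reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .spectra import BACKGROUND_CLASSES, WAVE_MAX, WAVE_MIN

DEFAULT_N_PER_CLASS = 65
DEFAULT_BACKGROUND_SIZE = 3 * DEFAULT_N_PER_CLASS
DEFAULT_N_ITERATIONS = 100_000
BIN_WIDTH = 5.0

#: left edges of the 5 nm analysis bins: 300, 305, ..., 695
BIN_EDGES = np.arange(WAVE_MIN, WAVE_MAX + BIN_WIDTH / 2, BIN_WIDTH)


@dataclass(frozen=True)
class BackgroundDraw:
    """One simulated background and its pooled marker multiset."""

    iteration: int
    member_sample_ids: tuple
    pooled_markers: np.ndarray

    @property
    def marker_count(self) -> int:
        return int(self.pooled_markers.size)


@dataclass(frozen=True)
class BinnedMarkers:
    """Marker counts per 5 nm bin (left edges 300, 305, ..., 695)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.size != BIN_EDGES.size - 1:
            raise ValueError(f"expected {BIN_EDGES.size - 1} bins, got {c.size}")
        object.__setattr__(self, "counts", c)

    @property
    def bin_left_edges(self) -> np.ndarray:
        return BIN_EDGES[:-1]

    @property
    def bin_centres(self) -> np.ndarray:
        return BIN_EDGES[:-1] + BIN_WIDTH / 2.0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregate of a full background simulation."""

    n_iterations: int
    seed: object
    marker_count_median: float
    marker_count_ci: tuple          # (2.5th, 97.5th percentile)
    marker_counts: np.ndarray       # one count per iteration
    binned: BinnedMarkers

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "marker_count_median": self.marker_count_median,
            "marker_count_ci": list(self.marker_count_ci),
            "total_markers": self.binned.total,
            "binned_counts": self.binned.counts.tolist(),
        }


def bin_markers(markers, width: float = BIN_WIDTH) -> BinnedMarkers:
    """Bin marker wavelengths into half-open [edge, edge+width) bins.

    The bin label is the greatest multiple of ``width`` at or below the
    wavelength (426.11 nm falls in the 425 nm bin); 700.0 exactly joins
    the final bin.  Total count is conserved.
    """
    x = np.asarray(markers, dtype=float).ravel()
    if x.size and (x.min() < WAVE_MIN or x.max() > WAVE_MAX):
        raise ValueError("marker wavelength outside [300, 700] nm")
    edges = np.arange(WAVE_MIN, WAVE_MAX + width / 2, width)
    n_bins = edges.size - 1
    if x.size == 0:
        counts = np.zeros(n_bins, dtype=np.int64)
    else:
        idx = np.clip(((x - WAVE_MIN) // width).astype(np.int64), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
    if width == BIN_WIDTH:
        return BinnedMarkers(counts=counts)
    out = BinnedMarkers.__new__(BinnedMarkers)  # non-default width variant
    object.__setattr__(out, "counts", counts)
    return out


def _markers_by_sample(markers: pd.DataFrame) -> dict:
    by = {}
    for sid, grp in markers.groupby("sample_id"):
        by[str(sid)] = np.asarray(grp["marker_nm"], dtype=float)
    return by


def stratified_subsample(pool_manifest: pd.DataFrame, n_per_class: int,
                         rng) -> np.ndarray:
    """Draw n_per_class sample ids per background class, without
    replacement.  ``pool_manifest`` needs columns sample_id and
    material_class."""
    chosen = []
    for cls in BACKGROUND_CLASSES:
        ids = pool_manifest.loc[pool_manifest["material_class"] == cls,
                                "sample_id"].to_numpy()
        if ids.size < n_per_class:
            raise ValueError(
                f"class {cls!r} has {ids.size} samples, needs >= {n_per_class}"
            )
        chosen.append(rng.choice(ids, size=n_per_class, replace=False))
    return np.concatenate(chosen)


def resample_background(subset_ids, markers_by_sample: dict, rng,
                        background_size: int | None = None,
                        iteration: int = 0) -> BackgroundDraw:
    """Draw one simulated background from a stratified subset.

    ``background_size`` members are drawn with replacement (default: the
    subset size); the pooled markers are the multiset union over drawn
    members, duplicates contributing repeatedly.
    """
    subset_ids = np.asarray(subset_ids)
    size = subset_ids.size if background_size is None else background_size
    members = rng.choice(subset_ids, size=size, replace=True)
    arrays = [markers_by_sample.get(str(sid), _EMPTY) for sid in members]
    pooled = np.concatenate(arrays) if arrays else _EMPTY
    return BackgroundDraw(iteration=iteration,
                          member_sample_ids=tuple(str(s) for s in members),
                          pooled_markers=pooled)


_EMPTY = np.zeros(0, dtype=float)


def simulate_backgrounds(pool_manifest: pd.DataFrame, markers: pd.DataFrame,
                         n_iterations: int = DEFAULT_N_ITERATIONS,
                         seed=None, n_per_class: int = DEFAULT_N_PER_CLASS,
                         background_size: int | None = None,
                         ) -> SimulationSummary:
    """Run the full background simulation.

    Parameters
    ----------
    pool_manifest : DataFrame with sample_id and material_class for every
        pool sample (including samples without markers).
    markers : marker table for the pool (background threshold), with
        columns sample_id and marker_nm.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    by_sample = _markers_by_sample(markers)
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = root.spawn(n_iterations)
    counts = np.empty(n_iterations, dtype=np.int64)
    agg = np.zeros(BIN_EDGES.size - 1, dtype=np.int64)
    if background_size is None:
        background_size = 3 * n_per_class
    # integer-index the pool once: per-class id arrays and, per sample,
    # its markers' bin indices and count
    all_ids = pool_manifest["sample_id"].astype(str).to_numpy()
    id_to_int = {sid: i for i, sid in enumerate(all_ids)}
    class_idx = []
    for cls in BACKGROUND_CLASSES:
        mask = (pool_manifest["material_class"] == cls).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size < n_per_class:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples, needs >= {n_per_class}"
            )
        class_idx.append(idx)
    n_bins = BIN_EDGES.size - 1
    per_sample_bins = np.zeros((all_ids.size, n_bins), dtype=np.int64)
    for sid, arr in by_sample.items():
        if sid not in id_to_int:
            raise ValueError(f"marker table sample {sid!r} not in manifest")
        per_sample_bins[id_to_int[sid]] = bin_markers(arr).counts
    per_sample_total = per_sample_bins.sum(axis=1)
    for it in range(n_iterations):
        rng = np.random.default_rng(children[it])
        subset = np.concatenate([
            rng.choice(ci, size=n_per_class, replace=False)
            for ci in class_idx
        ])
        members = subset[rng.integers(0, subset.size, size=background_size)]
        counts[it] = per_sample_total[members].sum()
        agg += per_sample_bins[members].sum(axis=0)
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return SimulationSummary(
        n_iterations=n_iterations, seed=seed,
        marker_count_median=float(np.median(counts)),
        marker_count_ci=(float(lo), float(hi)),
        marker_counts=counts,
        binned=BinnedMarkers(counts=agg),
    )


class BackgroundSimulator(BaseEstimator):
    """Estimator wrapper around the background simulation.

    ``fit(X, markers=...)`` takes the pool manifest as X (DataFrame with
    sample_id and material_class) and the precomputed marker table for
    the pool, and exposes the summary through fitted attributes.

    Attributes (after ``fit``)
    --------------------------
    summary_ : :class:`SimulationSummary`
    median_markers_, markers_ci_ : per-background marker count statistics.
    binned_ : aggregate :class:`BinnedMarkers` over all iterations.
    """

    def __init__(self, n_iterations=DEFAULT_N_ITERATIONS,
                 n_per_class=DEFAULT_N_PER_CLASS, background_size=None,
                 random_state=None):
        self.n_iterations = n_iterations
        self.n_per_class = n_per_class
        self.background_size = background_size
        self.random_state = random_state

    def fit(self, X, y=None, markers: pd.DataFrame = None):
        if markers is None:
            raise ValueError("fit requires the pool marker table: "
                             "fit(manifest, markers=markers)")
        manifest = X.manifest() if hasattr(X, "manifest") else X
        self.summary_ = simulate_backgrounds(
            manifest, markers, n_iterations=self.n_iterations,
            seed=self.random_state, n_per_class=self.n_per_class,
            background_size=self.background_size,
        )
        self.median_markers_ = self.summary_.marker_count_median
        self.markers_ci_ = self.summary_.marker_count_ci
        self.binned_ = self.summary_.binned
        return self
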