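"""Reflectance spectra: containers, reading, averaging, regridding, tables.

Spectra are percent reflectance relative to a white (Lambertian) standard,
sampled over 300–700 nm.  Values above 100% are legitimate (a surface can
out-reflect the standard at some wavelengths); negative values are not.
All downstream analysis runs on a canonical 1 nm grid over [300, 700]
(401 points), fine enough that the 5 nm analysis bins and sub-nm marker
interpolation are unaffected by the input grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WAVE_MIN = 300.0
WAVE_MAX = 700.0
GRID_STEP = 1.0
#: canonical wavelength grid: 300, 301, ..., 700 nm
CANONICAL_GRID = np.arange(WAVE_MIN, WAVE_MAX + GRID_STEP / 2, GRID_STEP)

GREEN_LEAF = "green_leaf"
DRY_MATERIAL = "dry_material"
ROCK_MINERAL = "rock_mineral"
FLOWER_INSECT = "flower_insect"
FLOWER_BIRD = "flower_bird"
OTHER = "other"

MATERIAL_CLASSES = (
    GREEN_LEAF, DRY_MATERIAL, ROCK_MINERAL, FLOWER_INSECT, FLOWER_BIRD, OTHER,
)
#: the three non-floral classes used to assemble simulated backgrounds
BACKGROUND_CLASSES = (GREEN_LEAF, DRY_MATERIAL, ROCK_MINERAL)
FLOWER_CLASSES = (FLOWER_INSECT, FLOWER_BIRD)

MARKER_COLUMNS = [
    "sample_id", "material_class", "marker_nm", "magnitude_pct",
    "span_nm", "direction",
]


@dataclass(frozen=True)
class Spectrum:
    """One sample's reflectance curve.

    ``reflectance`` is percent reflectance on the (strictly increasing)
    ``wavelengths`` grid, restricted to [300, 700] nm.
    """

    sample_id: str
    material_class: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)
        if self.material_class not in MATERIAL_CLASSES:
            raise ValueError(
                f"{self.sample_id!r}: unknown material class "
                f"{self.material_class!r}; expected one of {MATERIAL_CLASSES}"
            )
        if w.ndim != 1 or r.ndim != 1 or w.size != r.size:
            raise ValueError(
                f"{self.sample_id!r}: wavelengths and reflectance must be "
                "1-D and equal length"
            )
        if w.size < 2:
            raise ValueError(f"{self.sample_id!r}: fewer than 2 grid points")
        if np.any(np.diff(w) <= 0):
            raise ValueError(
                f"{self.sample_id!r}: wavelengths not strictly increasing"
            )
        if w[0] < WAVE_MIN - 1e-9 or w[-1] > WAVE_MAX + 1e-9:
            raise ValueError(
                f"{self.sample_id!r}: wavelengths outside [300, 700] nm "
                "(clip rows before constructing a Spectrum)"
            )
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError(
                f"{self.sample_id!r}: reflectance must be finite and >= 0"
            )

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SamplePool:
    """A collection of spectra with unique sample ids."""

    spectra: list = field(default_factory=list)

    def __post_init__(self):
        ids = [s.sample_id for s in self.spectra]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_ids: {sorted(dupes)}")
        self._by_id = {s.sample_id: s for s in self.spectra}

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, sample_id: str) -> Spectrum:
        return self._by_id[sample_id]

    def add(self, spectrum: Spectrum) -> None:
        if spectrum.sample_id in self._by_id:
            raise ValueError(f"duplicate sample_id: {spectrum.sample_id!r}")
        self.spectra.append(spectrum)
        self._by_id[spectrum.sample_id] = spectrum

    @property
    def class_counts(self) -> dict:
        counts: dict = {}
        for s in self.spectra:
            counts[s.material_class] = counts.get(s.material_class, 0) + 1
        return counts

    def ids_by_class(self, material_class: str) -> list:
        return [s.sample_id for s in self.spectra
                if s.material_class == material_class]

    def subset(self, classes) -> "SamplePool":
        classes = set(classes)
        return SamplePool([s for s in self.spectra
                           if s.material_class in classes])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": [s.sample_id for s in self.spectra],
             "material_class": [s.material_class for s in self.spectra]}
        )


def average_replicates(wavelengths, replicates) -> np.ndarray:
    """Pointwise arithmetic mean of k aligned replicate reflectance columns.

    ``replicates`` is a sequence of k arrays (k >= 1), each the same length
    as ``wavelengths``.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    reps = [np.asarray(r, dtype=float) for r in replicates]
    if not reps:
        raise ValueError("at least one replicate required")
    for r in reps:
        if r.shape != wavelengths.shape:
            raise ValueError(
                f"replicate length {r.size} does not match wavelength grid "
                f"length {wavelengths.size}"
            )
    return np.mean(reps, axis=0)


def regrid(spectrum: Spectrum, step: float = GRID_STEP) -> Spectrum:
    """Linearly interpolate onto 300, 300+step, ..., 700 nm.

    No extrapolation: beyond the observed endpoints the endpoint values
    are held constant.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    grid = np.arange(WAVE_MIN, WAVE_MAX + step / 2, step)
    r = np.interp(grid, spectrum.wavelengths, spectrum.reflectance)
    return replace(spectrum, wavelengths=grid, reflectance=r)


def to_canonical(spectrum: Spectrum) -> Spectrum:
    """Regrid onto the canonical 1 nm grid (identity if already there)."""
    if spectrum.wavelengths.size == CANONICAL_GRID.size and np.array_equal(
        spectrum.wavelengths, CANONICAL_GRID
    ):
        return spectrum
    return regrid(spectrum, GRID_STEP)


def _read_delimited(path_or_buf):
    """Read one spectrum file: column 1 wavelength (nm), columns 2..k
    replicates (%).  Comma or tab separated, optional header row."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    # optional header: first row not numeric
    first = df.iloc[0]
    try:
        first.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:]
    df = df.astype(float)
    return df


def read_spectrum_file(path, sample_id: str, material_class: str) -> Spectrum:
    """Read, clip to [300, 700] nm, average replicates, and regrid."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError(f"{sample_id!r}: file {path} has no reflectance column")
    w = df.iloc[:, 0].to_numpy()
    keep = (w >= WAVE_MIN) & (w <= WAVE_MAX)
    df = df.loc[keep]
    w = df.iloc[:, 0].to_numpy()
    if w.size < 2:
        raise ValueError(
            f"{sample_id!r}: fewer than 2 rows inside [300, 700] nm in {path}"
        )
    if np.any(np.diff(w) <= 0):
        raise ValueError(f"{sample_id!r}: non-monotone wavelengths in {path}")
    reps = [df.iloc[:, j].to_numpy() for j in range(1, df.shape[1])]
    r = average_replicates(w, reps)
    spec = Spectrum(sample_id=sample_id, material_class=material_class,
                    wavelengths=w, reflectance=np.clip(r, 0.0, None))
    return to_canonical(spec)


def read_spectra(path, manifest) -> SamplePool:
    """Read a directory (or single file) of spectra driven by a manifest.

    The manifest CSV has columns ``sample_id``, ``material_class`` and
    ``file`` (path relative to ``path`` if that is a directory).  Every
    spectrum named in the manifest must resolve; a sample with no manifest
    entry is an error naming the sample.
    """
    mf = pd.read_csv(manifest) if not isinstance(manifest, pd.DataFrame) \
        else manifest
    required = {"sample_id", "material_class", "file"}
    if not required.issubset(mf.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    blank = mf["material_class"].isna() | (mf["material_class"] == "")
    if blank.any():
        missing = mf.loc[blank, "sample_id"].tolist()
        raise ValueError(f"missing manifest material_class for samples: {missing}")
    pool = SamplePool()
    for rec in mf.itertuples(index=False):
        fp = rec.file if os.path.isabs(str(rec.file)) else os.path.join(
            str(path) if os.path.isdir(str(path)) else os.path.dirname(str(path)),
            str(rec.file),
        )
        if not os.path.exists(fp):
            raise FileNotFoundError(
                f"sample {rec.sample_id!r}: spectrum file not found: {fp}"
            )
        pool.add(read_spectrum_file(fp, str(rec.sample_id),
                                    str(rec.material_class)))
    return pool


def write_markers(markers: pd.DataFrame, path) -> None:
    """Write a marker table CSV (schema: ``MARKER_COLUMNS``)."""
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table missing columns {missing}")
    markers.loc[:, MARKER_COLUMNS].to_csv(path, index=False)


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table missing columns {missing}")
    return df
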