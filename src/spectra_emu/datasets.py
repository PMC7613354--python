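"""Labeled spectral datasets: containers, CSV I/O and split protocol.

A labeled spectral dataset pairs per-sample biophysical variables (leaf
chlorophyll content, leaf area index, ...) with a reflectance spectrum
sampled on a fixed band grid.  The on-disk format is a plain CSV with one
row per sample: an optional ``sample_id`` column, one column per variable,
and one column per band named ``R_<wavelength_nm>``.  An optional JSON
sidecar (same basename, ``.meta.json``) carries sensor label, reflectance
scale and variable units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BandGrid",
    "LabeledSpectralDataset",
    "SplitSpec",
    "read_labeled_csv",
    "write_labeled_csv",
    "split_dataset",
]

REFLECTANCE_PREFIX = "R_"


class DatasetFormatError(ValueError):
    """Raised when a labeled-dataset file violates the expected format."""


@dataclass(frozen=True)
class BandGrid:
    """Ordered band-center wavelengths of a (possibly hypothetical) sensor.

    Parameters
    ----------
    wavelengths
        Band centers in nanometres, strictly increasing.
    sensor_label
        Free-text sensor identifier (e.g. ``"chris62"``).
    reflectance_scale
        Value representing unit reflectance: 1.0 means reflectance stored
        in [0, 1], 10000.0 means scaled integer-style units.
    """

    wavelengths: np.ndarray
    sensor_label: str = "custom"
    reflectance_scale: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelengths must be a non-empty 1-D sequence")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths must be finite")
        if not self.reflectance_scale > 0:
            raise ValueError("reflectance_scale must be positive")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandGrid):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and self.sensor_label == other.sensor_label
            and self.reflectance_scale == other.reflectance_scale
        )


@dataclass
class LabeledSpectralDataset:
    """n samples of D biophysical variables paired with K-band spectra."""

    variable_names: list[str]
    X: np.ndarray  # n x D
    Y: np.ndarray  # n x K
    band_grid: BandGrid
    sample_ids: list[str] = field(default_factory=list)
    variable_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        n = self.X.shape[0]
        if n < 1:
            raise ValueError("dataset needs at least one sample")
        if self.Y.shape[0] != n:
            raise ValueError(
                f"X has {n} rows but Y has {self.Y.shape[0]}"
            )
        if self.X.shape[1] != len(self.variable_names):
            raise ValueError("X column count does not match variable_names")
        if self.Y.shape[1] != len(self.band_grid):
            raise ValueError("Y column count does not match band grid length")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in X")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("non-finite values in Y")
        scaled = self.Y / self.band_grid.reflectance_scale
        if scaled.min() < -1e-9 or scaled.max() > 1.5:
            raise ValueError(
                "reflectance outside [0, 1.5] after dividing by "
                f"reflectance_scale={self.band_grid.reflectance_scale}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def n_bands(self) -> int:
        return self.Y.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledSpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledSpectralDataset(
            variable_names=list(self.variable_names),
            X=self.X[idx],
            Y=self.Y[idx],
            band_grid=self.band_grid,
            sample_ids=[self.sample_ids[i] for i in idx],
            variable_units=dict(self.variable_units),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Configuration of a random train/validation split."""

    fraction_train: float = 0.8
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_train < 1.0:
            raise ValueError("fraction_train must lie in the open interval (0, 1)")


def _format_wavelength(wl: float) -> str:
    # repr() keeps full float precision for the round trip
    return repr(float(wl))


def read_labeled_csv(path: str | Path) -> LabeledSpectralDataset:
    """Read a labeled spectral dataset from CSV (plus optional sidecar).

    Columns prefixed ``R_`` are reflectance bands (suffix parsed as the
    band-center wavelength in nm); all other columns except ``sample_id``
    are biophysical variables.  Bands are reordered by wavelength.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DatasetFormatError(f"{path}: missing header row") from exc
    if df.shape[0] == 0:
        raise DatasetFormatError(f"{path}: no samples (header only)")

    refl_cols: list[str] = []
    wavelengths: list[float] = []
    var_cols: list[str] = []
    for col in df.columns:
        if col.startswith(REFLECTANCE_PREFIX):
            try:
                wl = float(col[len(REFLECTANCE_PREFIX):])
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{path}: cannot parse wavelength from column {col!r}"
                ) from exc
            refl_cols.append(col)
            wavelengths.append(wl)
        elif col != "sample_id":
            var_cols.append(col)
    if not refl_cols:
        raise DatasetFormatError(f"{path}: no reflectance (R_*) columns")
    if len(set(wavelengths)) != len(wavelengths):
        raise DatasetFormatError(f"{path}: duplicate wavelength column")

    for col in var_cols + refl_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) if not bad.any() else int(bad.idxmax())
            raise DatasetFormatError(
                f"{path}: non-numeric or missing value at row {row}, column {col!r}"
            )
        df[col] = numeric

    order = np.argsort(wavelengths, kind="stable")
    wavelengths_sorted = [wavelengths[i] for i in order]
    refl_sorted = [refl_cols[i] for i in order]

    meta_path = path.with_name(path.stem + ".meta.json")
    sensor_label, scale, units = "custom", 1.0, {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        sensor_label = meta.get("sensor_label", sensor_label)
        scale = float(meta.get("reflectance_scale", scale))
        units = dict(meta.get("variable_units", {}))

    grid = BandGrid(np.asarray(wavelengths_sorted), sensor_label, scale)
    sample_ids = (
        [str(s) for s in df["sample_id"]] if "sample_id" in df.columns else []
    )
    return LabeledSpectralDataset(
        variable_names=var_cols,
        X=df[var_cols].to_numpy(dtype=float) if var_cols else np.empty((len(df), 0)),
        Y=df[refl_sorted].to_numpy(dtype=float),
        band_grid=grid,
        sample_ids=sample_ids,
        variable_units=units,
    )


def write_labeled_csv(ds: LabeledSpectralDataset, path: str | Path) -> Path:
    """Write a dataset to CSV plus its ``.meta.json`` sidecar.

    The written file round-trips through :func:`read_labeled_csv` with
    matrices, names and wavelengths preserved to full stored precision.
    """
    path = Path(path)
    cols: dict[str, object] = {"sample_id": ds.sample_ids}
    for j, name in enumerate(ds.variable_names):
        cols[name] = ds.X[:, j]
    for k, wl in enumerate(ds.band_grid.wavelengths):
        cols[REFLECTANCE_PREFIX + _format_wavelength(wl)] = ds.Y[:, k]
    df = pd.DataFrame(cols)
    # repr of float64 keeps the round trip lossless (17 significant digits)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(df.columns) + "\n")
        for i in range(len(df)):
            row = [str(df.iloc[i, 0])]
            row += [repr(float(v)) for v in df.iloc[i, 1:]]
            fh.write(",".join(row) + "\n")
    meta = {
        "sensor_label": ds.band_grid.sensor_label,
        "reflectance_scale": ds.band_grid.reflectance_scale,
        "variable_units": ds.variable_units,
    }
    meta_path = path.with_name(path.stem + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2))
    return path


def split_dataset(
    ds: LabeledSpectralDataset, spec: SplitSpec
) -> tuple[LabeledSpectralDataset, LabeledSpectralDataset]:
    """Randomly partition a dataset into train and validation parts.

    Part-a size is round-half-up of ``fraction_train * n`` (so a 130-sample
    set at 0.8 yields 104 + 26); the permutation is a deterministic
    function of the seed.
    """
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_a = int(math.floor(spec.fraction_train * n + 0.5))
    if n_a == 0 or n_a == n:
        raise ValueError(
            f"fraction_train={spec.fraction_train} produces an empty part for n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n) if spec.shuffle else np.arange(n)
    return ds.subset(perm[:n_a]), ds.subset(perm[n_a:])
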