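"""Synthetic hyperspectral scenes: ENVI cubes, map stacks, pixel-wise emulation.

A scene run applies a trained emulator (or any ``predict(X) -> Y``
callable) to every valid pixel of a stack of biophysical-variable maps,
producing a rows x cols x K reflectance cube.  Cubes and map stacks are
stored in the ENVI band-sequential (BSQ) dialect: a text ``.hdr`` header
next to a raw little-endian float32 binary.  Computation is float64;
storage float32.

No georeferencing is interpreted; an ENVI ``map info`` line, if present,
is carried through verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import BandGrid

__all__ = [
    "VariableMapStack",
    "HyperspectralCube",
    "SceneErrorReport",
    "read_envi_cube",
    "write_envi_cube",
    "read_envi_maps",
    "write_envi_maps",
    "emulate_scene",
    "compare_scenes",
]

DEFAULT_NODATA = -999.0


class EnviFormatError(ValueError):
    """Raised for malformed or unsupported ENVI files."""


@dataclass
class VariableMapStack:
    """rows x cols x D stack of biophysical-variable maps with a validity mask."""

    data: np.ndarray
    variable_names: list[str]
    nodata_value: float = DEFAULT_NODATA
    mask: np.ndarray | None = None
    map_info: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be rows x cols x D")
        if self.data.shape[2] != len(self.variable_names):
            raise ValueError("variable_names length does not match band count")
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValueError("variable names must be unique")
        if self.mask is None:
            finite = np.all(np.isfinite(self.data), axis=2)
            not_nodata = np.all(self.data != self.nodata_value, axis=2)
            self.mask = finite & not_nodata
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape does not match map shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class HyperspectralCube:
    """rows x cols x K reflectance cube on a band grid, with validity mask."""

    data: np.ndarray
    band_grid: BandGrid
    nodata_value: float = DEFAULT_NODATA
    mask: np.ndarray | None = None
    map_info: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be rows x cols x bands")
        if self.data.shape[2] != len(self.band_grid):
            raise ValueError("band count does not match band grid length")
        if self.mask is None:
            finite = np.all(np.isfinite(self.data), axis=2)
            not_nodata = np.all(self.data != self.nodata_value, axis=2)
            self.mask = finite & not_nodata
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape does not match cube shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SceneErrorReport:
    """Band-per-band scene comparison against a reference cube."""

    nrmse_per_band_pct: np.ndarray
    relative_difference_maps: dict[float, np.ndarray] = field(default_factory=dict)
    n_valid_pixels: int = 0
    degenerate_bands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def nrmse_mean_pct(self) -> float:
        ok = np.isfinite(self.nrmse_per_band_pct)
        return float(np.mean(self.nrmse_per_band_pct[ok]))


# ---------------------------------------------------------------------------
# ENVI BSQ I/O

_MANDATORY_KEYS = ("samples", "lines", "bands", "data type", "interleave", "byte order")


def _parse_envi_header(text: str, path: Path) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError(f"{path}: missing ENVI magic line")
    # collapse brace-delimited multi-line values into single logical lines
    body = text.lstrip()[4:]
    entries: dict[str, str] = {}
    buf = ""
    for line in body.splitlines():
        buf += line.strip() + " "
        if buf.count("{") > buf.count("}"):
            continue
        if "=" in buf:
            key, _, value = buf.partition("=")
            entries[key.strip().lower()] = value.strip()
        buf = ""
    for key in _MANDATORY_KEYS:
        if key not in entries:
            raise EnviFormatError(f"{path}: missing mandatory header key {key!r}")
    return entries


def _parse_brace_list(value: str) -> list[str]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:]
    if inner.endswith("}"):
        inner = inner[:-1]
    return [item.strip() for item in inner.split(",") if item.strip()]


def _read_envi(path: str | Path):
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    entries = _parse_envi_header(hdr_path.read_text(), hdr_path)

    if entries["interleave"].lower() != "bsq":
        raise EnviFormatError(
            f"{path}: unsupported interleave {entries['interleave']!r}; "
            "supported dialects: bsq"
        )
    if entries["data type"] != "4":
        raise EnviFormatError(
            f"{path}: unsupported data type {entries['data type']!r}; "
            "only 4 (32-bit float) is supported"
        )
    if entries["byte order"] != "0":
        raise EnviFormatError(f"{path}: only little-endian (byte order = 0) supported")

    lines = int(entries["lines"])
    samples = int(entries["samples"])
    bands = int(entries["bands"])
    raw = np.fromfile(path, dtype="<f4")
    if raw.size != lines * samples * bands:
        raise EnviFormatError(
            f"{path}: binary size {raw.size} values does not match header "
            f"{lines}x{samples}x{bands}"
        )
    data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    return data, entries


def _write_envi(path: str | Path, data: np.ndarray, extra: dict[str, str]) -> Path:
    path = Path(path)
    lines, samples, bands = data.shape
    payload = np.ascontiguousarray(
        data.transpose(2, 0, 1), dtype="<f4"
    )  # BSQ: band, line, sample
    payload.tofile(path)
    hdr = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
    ]
    for key, value in extra.items():
        hdr.append(f"{key} = {value}")
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    hdr_path.write_text("\n".join(hdr) + "\n")
    return path


def write_envi_cube(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write a reflectance cube as ENVI BSQ float32 (+ text header)."""
    data = np.where(cube.mask[:, :, None], cube.data, cube.nodata_value)
    extra = {
        "wavelength units": "nanometers",
        "wavelength": "{ " + ", ".join(repr(float(w)) for w in cube.band_grid.wavelengths) + " }",
        "data ignore value": repr(float(cube.nodata_value)),
        "sensor type": cube.band_grid.sensor_label,
        "reflectance scale factor": repr(float(cube.band_grid.reflectance_scale)),
    }
    if cube.map_info:
        extra["map info"] = cube.map_info
    return _write_envi(path, data, extra)


def read_envi_cube(path: str | Path) -> HyperspectralCube:
    """Read an ENVI BSQ float32 reflectance cube."""
    data, entries = _read_envi(path)
    if "wavelength" not in entries:
        raise EnviFormatError(f"{path}: missing wavelength list")
    wavelengths = np.array([float(w) for w in _parse_brace_list(entries["wavelength"])])
    if wavelengths.size != data.shape[2]:
        raise EnviFormatError(f"{path}: wavelength count does not match bands")
    grid = BandGrid(
        wavelengths,
        entries.get("sensor type", "custom"),
        float(entries.get("reflectance scale factor", 1.0)),
    )
    nodata = float(entries.get("data ignore value", DEFAULT_NODATA))
    return HyperspectralCube(
        data=data,
        band_grid=grid,
        nodata_value=nodata,
        map_info=entries.get("map info"),
    )


def write_envi_maps(maps: VariableMapStack, path: str | Path) -> Path:
    """Write a variable-map stack as ENVI BSQ with band names = variable names."""
    data = np.where(maps.mask[:, :, None], maps.data, maps.nodata_value)
    extra = {
        "band names": "{ " + ", ".join(maps.variable_names) + " }",
        "data ignore value": repr(float(maps.nodata_value)),
    }
    if maps.map_info:
        extra["map info"] = maps.map_info
    return _write_envi(path, data, extra)


def read_envi_maps(path: str | Path) -> VariableMapStack:
    """Read an ENVI BSQ variable-map stack (band names = variable names)."""
    data, entries = _read_envi(path)
    if "band names" not in entries:
        raise EnviFormatError(f"{path}: missing band names (variable names)")
    names = _parse_brace_list(entries["band names"])
    nodata = float(entries.get("data ignore value", DEFAULT_NODATA))
    return VariableMapStack(
        data=np.asarray(data, dtype=float),
        variable_names=names,
        nodata_value=nodata,
        map_info=entries.get("map info"),
    )


# ---------------------------------------------------------------------------
# Scene emulation and comparison


def emulate_scene(
    emulator,
    maps: VariableMapStack,
    chunk_size: int = 256,
    deduplicate: bool = True,
) -> HyperspectralCube:
    """Apply an emulator pixel-wise to a variable-map stack.

    ``emulator`` is anything exposing ``variable_names``, ``band_grid``
    and ``predict_spectra(X) -> Y`` (a trained :class:`~.emulation.Emulator`
    or an interpolation adapter).  Maps are matched to the emulator's
    variables by name.  Pixels are processed in row chunks; identical
    variable vectors are optionally deduplicated — both are exact
    optimizations, the output is invariant to them.  Invalid pixels get
    the nodata value across all bands.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    em_names = list(emulator.variable_names)
    missing = [n for n in em_names if n not in maps.variable_names]
    extra = [n for n in maps.variable_names if n not in em_names]
    if missing or extra:
        raise ValueError(
            f"variable mismatch between maps and emulator; missing={missing}, "
            f"extra={extra}"
        )
    col_order = [maps.variable_names.index(n) for n in em_names]
    rows, cols, _ = maps.data.shape
    K = len(emulator.band_grid)
    out = np.full((rows, cols, K), maps.nodata_value, dtype=float)

    for r0 in range(0, rows, chunk_size):
        r1 = min(r0 + chunk_size, rows)
        sub_mask = maps.mask[r0:r1]
        if not sub_mask.any():
            continue
        vectors = maps.data[r0:r1][sub_mask][:, col_order]
        if deduplicate:
            uniq, inverse = np.unique(vectors, axis=0, return_inverse=True)
            spectra = emulator.predict_spectra(uniq)[inverse]
        else:
            spectra = emulator.predict_spectra(vectors)
        block = out[r0:r1]
        block[sub_mask] = spectra
        out[r0:r1] = block

    return HyperspectralCube(
        data=out,
        band_grid=emulator.band_grid,
        nodata_value=maps.nodata_value,
        mask=maps.mask.copy(),
        map_info=maps.map_info,
    )


def compare_scenes(
    emulated: HyperspectralCube,
    reference: HyperspectralCube,
    bands_for_maps: list[float] | None = None,
    normalizer: str = "range",
) -> SceneErrorReport:
    """Band-per-band NRMSE (%) of an emulated cube against a reference.

    NRMSE uses the validation-module formula over jointly valid pixels,
    normalized by the reference band range over the scene.  For each
    wavelength in ``bands_for_maps`` a signed relative-difference map is
    produced: 100 * (emulated - reference) / reference-range, positive
    where the emulator overestimates.
    """
    from .validation import nrmse_per_band

    if emulated.data.shape != reference.data.shape:
        raise ValueError("cube shapes differ")
    if len(emulated.band_grid) != len(reference.band_grid) or np.any(
        np.abs(emulated.band_grid.wavelengths - reference.band_grid.wavelengths) > 1e-6
    ):
        raise ValueError("band grids differ")
    joint = emulated.mask & reference.mask
    if not joint.any():
        raise ValueError("no jointly valid pixels")

    pred = np.asarray(emulated.data, dtype=float)[joint]
    ref = np.asarray(reference.data, dtype=float)[joint]
    nrmse = nrmse_per_band(pred, ref, normalizer=normalizer)
    degenerate = np.flatnonzero(~np.isfinite(nrmse))

    diff_maps: dict[float, np.ndarray] = {}
    wl = reference.band_grid.wavelengths
    for target in bands_for_maps or []:
        k = int(np.argmin(np.abs(wl - target)))
        band_ref = np.asarray(reference.data[:, :, k], dtype=float)
        band_emu = np.asarray(emulated.data[:, :, k], dtype=float)
        rng = band_ref[joint].max() - band_ref[joint].min()
        dmap = np.full(band_ref.shape, np.nan)
        if rng > 0:
            dmap[joint] = 100.0 * (band_emu[joint] - band_ref[joint]) / rng
        diff_maps[float(wl[k])] = dmap

    return SceneErrorReport(
        nrmse_per_band_pct=nrmse,
        relative_difference_maps=diff_maps,
        n_valid_pixels=int(joint.sum()),
        degenerate_bands=degenerate,
    )
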