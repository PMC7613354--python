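"""Accuracy protocol: per-band RMSE/NRMSE, timing, multi-method comparison.

The benchmark statistic is the root-mean-square error between predicted
and reference spectra, computed per wavelength over the validation
samples, normalized (by default by the per-band reference range) and
expressed in percent, then averaged over the spectral range.  Prediction
wall-clock time is recorded per method — model construction excluded —
so that accuracy and speed can be compared across interpolators and
emulators in one table.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledSpectralDataset
from .emulation import Emulator, EmulatorConfig, train_emulator
from .interpolation import (
    IDWConfig,
    InterpolationModel,
    hybrid_predict,
    idw_predict,
    nearest_predict,
)

__all__ = [
    "ValidationReport",
    "rmse_per_band",
    "nrmse_per_band",
    "compare_methods",
    "METHOD_LABELS",
]

#: Canonical benchmark method order (interpolators first, then emulators).
METHOD_LABELS = ("nearest", "linear+idw", "idw", "KRR", "GPR", "NN")


@dataclass
class ValidationReport:
    """Per-band and spectrally averaged validation errors for one method."""

    method_label: str
    rmse_per_band: np.ndarray
    nrmse_per_band_pct: np.ndarray
    rmse_mean: float
    nrmse_mean_pct: float
    prediction_seconds: float
    n_validation: int
    degenerate_bands: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    normalizer: str = "range"


def rmse_per_band(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-band root-mean-square error over samples (reflectance units)."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.shape[0] < 1:
        raise ValueError("need at least one sample")
    return np.sqrt(np.mean((pred - ref) ** 2, axis=0))


def _normalizer_per_band(ref: np.ndarray, normalizer: str) -> np.ndarray:
    if normalizer == "range":
        return ref.max(axis=0) - ref.min(axis=0)
    if normalizer == "mean":
        return ref.mean(axis=0)
    if normalizer == "std":
        return ref.std(axis=0)
    raise ValueError(f"unknown normalizer {normalizer!r}")


def nrmse_per_band(
    pred: np.ndarray, ref: np.ndarray, normalizer: str = "range"
) -> np.ndarray:
    """Normalized RMSE per band in percent.

    NRMSE_k = 100 * RMSE_k / N_k where N_k is the per-band normalizer of
    the reference (range by default; mean and std are alternatives).
    Bands with a zero normalizer are returned as NaN (degenerate) and
    must be excluded from averages by the caller.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    rmse = rmse_per_band(pred, ref)
    norm = _normalizer_per_band(ref, normalizer)
    out = np.full(rmse.shape, np.nan)
    ok = norm > 0
    if not ok.any():
        raise ValueError("all bands degenerate (zero reference normalizer)")
    out[ok] = 100.0 * rmse[ok] / norm[ok]
    return out


def _summarize(
    label: str,
    pred: np.ndarray,
    ref: np.ndarray,
    seconds: float,
    normalizer: str,
) -> ValidationReport:
    rmse = rmse_per_band(pred, ref)
    nrmse = nrmse_per_band(pred, ref, normalizer=normalizer)
    ok = np.isfinite(nrmse)
    return ValidationReport(
        method_label=label,
        rmse_per_band=rmse,
        nrmse_per_band_pct=nrmse,
        rmse_mean=float(rmse.mean()),
        nrmse_mean_pct=float(nrmse[ok].mean()),
        prediction_seconds=seconds,
        n_validation=ref.shape[0],
        degenerate_bands=np.flatnonzero(~ok),
        normalizer=normalizer,
    )


def compare_methods(
    train: LabeledSpectralDataset,
    val: LabeledSpectralDataset,
    methods: list[str] | None = None,
    seed: int = 0,
    idw_config: IDWConfig | None = None,
    emulator_configs: dict[str, EmulatorConfig] | None = None,
    normalizer: str = "range",
) -> list[ValidationReport]:
    """Fit every requested method on ``train`` and score it on ``val``.

    Interpolators use the training samples directly as nodes; emulators
    are trained with their default (or supplied) configuration.  Only the
    prediction call is timed.  Reports come back in the requested order.
    """
    if methods is None:
        methods = ["nearest", "linear+idw", "KRR", "GPR", "NN"]
    if train.variable_names != val.variable_names:
        raise ValueError("train and val variable names differ")
    if train.band_grid != val.band_grid:
        raise ValueError("train and val band grids differ")
    emulator_configs = emulator_configs or {}
    reports: list[ValidationReport] = []
    for label in methods:
        if label not in METHOD_LABELS:
            raise ValueError(f"unknown method {label!r}")
        if label in ("nearest", "linear+idw", "idw"):
            method_key = {"nearest": "nearest", "linear+idw": "linear_idw", "idw": "idw"}[
                label
            ]
            model = InterpolationModel(
                train.X, train.Y, method=method_key, idw_config=idw_config
            )
            predictor = {
                "nearest": nearest_predict,
                "linear+idw": hybrid_predict,
                "idw": idw_predict,
            }[label]
            if label == "linear+idw":
                model.triangulation()  # build outside the timed call
            t0 = time.perf_counter()
            pred = predictor(model, val.X)
            seconds = time.perf_counter() - t0
        else:
            config = emulator_configs.get(
                label, EmulatorConfig(method=label, seed=seed)
            )
            em = train_emulator(train, config)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t0 = time.perf_counter()
                pred = em.predict_spectra(val.X)
                seconds = time.perf_counter() - t0
        reports.append(_summarize(label, pred, val.Y, seconds, normalizer))
    return reports


def report_table(reports: list[ValidationReport]) -> "pd.DataFrame":
    """Summary table (one row per method), in benchmark order."""
    import pandas as pd

    return pd.DataFrame(
        {
            "method": [r.method_label for r in reports],
            "rmse_mean": [r.rmse_mean for r in reports],
            "nrmse_mean_pct": [r.nrmse_mean_pct for r in reports],
            "prediction_seconds": [r.prediction_seconds for r in reports],
            "n_val": [r.n_validation for r in reports],
        }
    )
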