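"""Statistical emulation of reflectance spectra from biophysical variables.

An emulator is a trained surrogate for the mapping ``x in R^D -> f(x) in
R^K`` defined by labeled samples (field spectra or radiative-transfer
runs).  The K-dimensional spectral output is first compressed with a
principal-component analysis (typically 20 components); a machine
learning regression algorithm then maps standardized input variables to
component scores, and predictions are decompressed back to full spectra:

    predict(x) = mu + g(standardize(x)) @ loadings.T

Three back-ends are supported:

* ``KRR`` — kernel ridge regression with an isotropic squared-exponential
  kernel; one independent model per component, hyperparameters (kernel
  width, ridge) selected per component by k-fold cross-validation over a
  shared log-spaced grid.
* ``GPR`` — Gaussian process regression with an anisotropic
  squared-exponential kernel plus a white-noise term, one process per
  component, hyperparameters by marginal-likelihood maximization with
  seeded restarts.
* ``NN`` — a single multi-output feed-forward network (one hidden layer)
  with early stopping.

All fitted state is held as plain arrays, so predictions are bit-equal
before and after a save/load round trip, and training is deterministic
given (data, config, seed).
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .datasets import BandGrid, LabeledSpectralDataset

__all__ = [
    "PCABasis",
    "KRRConfig",
    "GPRConfig",
    "NNConfig",
    "EmulatorConfig",
    "Emulator",
    "fit_pca",
    "pca_project",
    "pca_reconstruct",
    "train_emulator",
    "predict_spectra",
    "save_emulator",
    "load_emulator",
]

FORMAT_VERSION = 1


class CorruptModelError(ValueError):
    """Raised when a serialized emulator archive is inconsistent."""


# ---------------------------------------------------------------------------
# PCA compression of the spectral output


@dataclass
class PCABasis:
    """Mean-centered orthonormal principal-component basis of spectra.

    ``eigenvalues`` are per-component sample variances (divisor n-1,
    sorted non-increasing); the mean squared reconstruction error of the
    training spectra over all n*K entries equals
    ``(n-1)/(n*K) * sum(discarded eigenvalues)``.
    """

    mean_spectrum: np.ndarray  # K
    loadings: np.ndarray  # K x C, orthonormal columns
    eigenvalues: np.ndarray  # C
    n_components: int

    def __post_init__(self) -> None:
        K, C = self.loadings.shape
        if self.mean_spectrum.shape != (K,):
            raise ValueError("mean_spectrum length does not match loadings rows")
        if self.eigenvalues.shape != (C,) or self.n_components != C:
            raise ValueError("eigenvalue count does not match component count")
        if np.any(np.diff(self.eigenvalues) > 1e-10) or np.any(
            self.eigenvalues < -1e-12
        ):
            raise ValueError("eigenvalues must be non-increasing and non-negative")


def fit_pca(Y: np.ndarray, C: int) -> PCABasis:
    """Fit a principal-component basis to n x K training spectra.

    C is clipped to min(n-1, K) with a warning; constant spectra yield a
    single zero-variance component.
    """
    Y = np.asarray(Y, dtype=float)
    n, K = Y.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if C < 1:
        raise ValueError("n_components must be >= 1")
    max_c = min(n - 1, K)
    if C > max_c:
        warnings.warn(
            f"n_components={C} clipped to {max_c} (rank limit)", stacklevel=2
        )
        C = max_c
    if np.all(Y == Y[0]):
        # zero-variance spectra: a single arbitrary (unit) component
        warnings.warn("constant spectra: n_components clipped to 1", stacklevel=2)
        loadings = np.zeros((K, 1))
        loadings[0, 0] = 1.0
        return PCABasis(
            mean_spectrum=Y[0].copy(),
            loadings=loadings,
            eigenvalues=np.zeros(1),
            n_components=1,
        )
    pca = PCA(n_components=C, svd_solver="full")
    pca.fit(Y)
    return PCABasis(
        mean_spectrum=pca.mean_.copy(),
        loadings=pca.components_.T.copy(),
        eigenvalues=np.maximum(pca.explained_variance_.copy(), 0.0),
        n_components=C,
    )


def pca_project(basis: PCABasis, Y: np.ndarray) -> np.ndarray:
    """Project n x K spectra onto the basis -> n x C scores."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != basis.mean_spectrum.size:
        raise ValueError("spectrum length does not match basis")
    return (Y - basis.mean_spectrum) @ basis.loadings


def pca_reconstruct(basis: PCABasis, scores: np.ndarray) -> np.ndarray:
    """Decompress n x C scores back to n x K spectra: mu + s @ L.T."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != basis.n_components:
        raise ValueError("score length does not match basis")
    return basis.mean_spectrum + scores @ basis.loadings.T


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class KRRConfig:
    ridge_grid: tuple[float, ...] = tuple(np.logspace(-8, 2, 11))
    width_grid: tuple[float, ...] = tuple(np.logspace(-2, 2, 9))
    cv_folds: int = 5


@dataclass(frozen=True)
class GPRConfig:
    anisotropic: bool = True
    n_restarts: int = 3
    noise_floor: float = 1e-10


@dataclass(frozen=True)
class NNConfig:
    hidden_layer_sizes: tuple[int, ...] = (50,)
    activation: str = "relu"
    max_epochs: int = 2000
    early_stopping_fraction: float = 0.2


@dataclass(frozen=True)
class EmulatorConfig:
    """Training configuration for an emulator."""

    method: str = "KRR"
    n_components: int = 20
    seed: int = 0
    krr: KRRConfig = field(default_factory=KRRConfig)
    gpr: GPRConfig = field(default_factory=GPRConfig)
    nn: NNConfig = field(default_factory=NNConfig)

    def __post_init__(self) -> None:
        if self.method not in ("KRR", "GPR", "NN"):
            raise ValueError(f"unknown emulation method {self.method!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.krr.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.gpr.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")


# ---------------------------------------------------------------------------
# Regressor back-ends (fitted state as plain arrays)


def _rbf_kernel(sqdist: np.ndarray, width: float) -> np.ndarray:
    return np.exp(-sqdist / (2.0 * width**2))


def _rowwise_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """A @ B computed one row at a time.

    Batched BLAS matmul chooses blocking (and hence summation order) by
    matrix shape, so the same query row can yield results differing by a
    few ulp depending on its batch.  Evaluating each row independently
    makes predictions bit-equal regardless of batching — required for the
    chunk- and deduplication-invariance of scene emulation.
    """
    out = np.empty((A.shape[0], B.shape[1] if B.ndim == 2 else 1))
    row = np.empty(A.shape[1])
    for i in range(A.shape[0]):
        row[:] = A[i]  # fixed buffer: identical alignment for every row
        out[i] = row @ B
    return out


def _fit_krr(Xs: np.ndarray, S: np.ndarray, cfg: KRRConfig, seed: int) -> dict:
    """Per-component kernel ridge regression with joint grid CV.

    For every (width, ridge) grid point the dual problem is solved for all
    components at once via a per-fold eigendecomposition of the kernel, so
    the cross-validation sweep costs one eigh per fold and width.
    """
    n, _ = Xs.shape
    C = S.shape[1]
    widths = np.asarray(cfg.width_grid, dtype=float)
    ridges = np.asarray(cfg.ridge_grid, dtype=float)
    D2 = cdist(Xs, Xs, "sqeuclidean")
    folds = list(
        KFold(n_splits=min(cfg.cv_folds, n), shuffle=True, random_state=seed).split(
            np.arange(n)
        )
    )
    sse = np.zeros((widths.size, ridges.size, C))
    for tr, va in folds:
        D2_tr = D2[np.ix_(tr, tr)]
        D2_va = D2[np.ix_(va, tr)]
        for wi, w in enumerate(widths):
            evals, evecs = np.linalg.eigh(_rbf_kernel(D2_tr, w))
            evals = np.maximum(evals, 0.0)
            B = evecs.T @ S[tr]  # (n_tr, C)
            K_va = _rbf_kernel(D2_va, w)
            for ai, a in enumerate(ridges):
                dual = evecs @ (B / (evals + a)[:, None])
                resid = K_va @ dual - S[va]
                sse[wi, ai] += (resid**2).sum(axis=0)
    # per-component best grid point; ties go to the first (smallest width,
    # then smallest ridge) for determinism
    flat = sse.reshape(-1, C)
    best = flat.argmin(axis=0)
    best_w = widths[best // ridges.size]
    best_a = ridges[best % ridges.size]

    duals = np.zeros((n, C))
    for w, a in sorted({(float(w), float(a)) for w, a in zip(best_w, best_a)}):
        comps = np.flatnonzero((best_w == w) & (best_a == a))
        K_full = _rbf_kernel(D2, w) + a * np.eye(n)
        duals[:, comps] = np.linalg.solve(K_full, S[:, comps])
    return {
        "krr_widths": best_w,
        "krr_ridges": best_a,
        "krr_duals": duals,
        "krr_cv_mse": flat[best, np.arange(C)] / n,
    }


def _predict_krr(state: dict, Xs: np.ndarray) -> np.ndarray:
    Xtr = state["X_train"]
    D2 = cdist(Xs, Xtr, "sqeuclidean")
    widths = state["krr_widths"]
    duals = state["krr_duals"]
    out = np.empty((Xs.shape[0], widths.size))
    for w in np.unique(widths):
        comps = np.flatnonzero(widths == w)
        out[:, comps] = _rowwise_matmul(_rbf_kernel(D2, w), duals[:, comps])
    return out


def _fit_gpr(Xs: np.ndarray, S: np.ndarray, cfg: GPRConfig, seed: int) -> dict:
    """One Gaussian process per component; fitted state kept as arrays.

    Kernel: amplitude * RBF(length scales, anisotropic) + white noise.
    The mean prediction only needs the amplitude, length scales and dual
    coefficients (the white term vanishes off-diagonal), so those are
    extracted from the fitted sklearn object.
    """
    n, D = Xs.shape
    C = S.shape[1]
    ls0 = np.ones(D) if cfg.anisotropic else 1.0
    amplitudes = np.empty(C)
    length_scales = np.empty((C, D if cfg.anisotropic else 1))
    duals = np.empty((n, C))
    for c in range(C):
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            ls0, (1e-2, 1e3)
        ) + WhiteKernel(1e-4, (cfg.noise_floor, 1e1))
        gp = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=cfg.n_restarts,
            normalize_y=False,
            random_state=seed + c,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter from LBFGS
            gp.fit(Xs, S[:, c])
        k = gp.kernel_
        amplitudes[c] = k.k1.k1.constant_value
        ls = np.atleast_1d(k.k1.k2.length_scale)
        length_scales[c] = ls
        duals[:, c] = gp.alpha_
    return {
        "gpr_amplitudes": amplitudes,
        "gpr_length_scales": length_scales,
        "gpr_duals": duals,
    }


def _predict_gpr(state: dict, Xs: np.ndarray) -> np.ndarray:
    Xtr = state["X_train"]
    amps = state["gpr_amplitudes"]
    ls = state["gpr_length_scales"]
    duals = state["gpr_duals"]
    C = amps.size
    out = np.empty((Xs.shape[0], C))
    for c in range(C):
        D2 = cdist(Xs / ls[c], Xtr / ls[c], "sqeuclidean")
        out[:, c] = _rowwise_matmul(
            amps[c] * np.exp(-0.5 * D2), duals[:, c : c + 1]
        )[:, 0]
    return out


def _fit_nn(Xs: np.ndarray, S: np.ndarray, cfg: NNConfig, seed: int) -> dict:
    net = MLPRegressor(
        hidden_layer_sizes=cfg.hidden_layer_sizes,
        activation=cfg.activation,
        max_iter=cfg.max_epochs,
        early_stopping=True,
        validation_fraction=cfg.early_stopping_fraction,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(Xs, S)
    state: dict = {"nn_n_layers": np.array([len(net.coefs_)], dtype=float)}
    for i, (W, b) in enumerate(zip(net.coefs_, net.intercepts_)):
        state[f"nn_W{i}"] = np.asarray(W, dtype=float)
        state[f"nn_b{i}"] = np.asarray(b, dtype=float).ravel()
    return state


def _predict_nn(state: dict, Xs: np.ndarray) -> np.ndarray:
    n_layers = int(state["nn_n_layers"][0])
    h = Xs
    for i in range(n_layers):
        h = _rowwise_matmul(h, state[f"nn_W{i}"]) + state[f"nn_b{i}"]
        if i < n_layers - 1:
            h = np.maximum(h, 0.0)
    return np.atleast_2d(h)


_FIT = {"KRR": _fit_krr, "GPR": _fit_gpr, "NN": _fit_nn}
_PREDICT = {"KRR": _predict_krr, "GPR": _predict_gpr, "NN": _predict_nn}


# ---------------------------------------------------------------------------
# Emulator


@dataclass
class Emulator:
    """Trained spectral emulator (see module docstring for the pipeline)."""

    config: EmulatorConfig
    variable_names: list[str]
    band_grid: BandGrid
    input_mean: np.ndarray  # D
    input_std: np.ndarray  # D
    input_min: np.ndarray  # D, training hyper-rectangle (extrapolation check)
    input_max: np.ndarray  # D
    pca: PCABasis
    score_mean: np.ndarray  # C
    score_std: np.ndarray  # C
    regressor_state: dict[str, np.ndarray]
    training_fingerprint: dict

    def predict_spectra(self, Xq: np.ndarray, clip_to_unit: bool = False) -> np.ndarray:
        return predict_spectra(self, Xq, clip_to_unit=clip_to_unit)


def train_emulator(
    train: LabeledSpectralDataset, config: EmulatorConfig = EmulatorConfig()
) -> Emulator:
    """Train an emulator on a labeled dataset.

    Inputs are standardized per variable on the training data; spectra are
    compressed to ``config.n_components`` principal components (clipped to
    the data rank); component scores are standardized and regressed on the
    standardized inputs with the configured back-end.  Training is a
    deterministic function of (data, config).
    """
    n = train.n_samples
    if n < 5:
        raise ValueError("need at least 5 training samples")
    X, Y = train.X, train.Y

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    zero_var = std == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance input variable(s) "
            f"{[train.variable_names[i] for i in np.flatnonzero(zero_var)]}; "
            "scale set to 1",
            stacklevel=2,
        )
        std = np.where(zero_var, 1.0, std)
    Xs = (X - mean) / std

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        basis = fit_pca(Y, config.n_components)
    scores = pca_project(basis, Y)
    s_mean = scores.mean(axis=0)
    s_std = scores.std(axis=0)
    s_std = np.where(s_std == 0, 1.0, s_std)
    Ss = (scores - s_mean) / s_std

    sub_cfg = {"KRR": config.krr, "GPR": config.gpr, "NN": config.nn}[config.method]
    state = _FIT[config.method](Xs, Ss, sub_cfg, config.seed)
    state["X_train"] = Xs

    fingerprint = {
        "n_train": int(n),
        "data_sha256": hashlib.sha256(
            X.tobytes() + Y.tobytes()
        ).hexdigest(),
    }
    return Emulator(
        config=config,
        variable_names=list(train.variable_names),
        band_grid=train.band_grid,
        input_mean=mean,
        input_std=std,
        input_min=X.min(axis=0),
        input_max=X.max(axis=0),
        pca=basis,
        score_mean=s_mean,
        score_std=s_std,
        regressor_state=state,
        training_fingerprint=fingerprint,
    )


def predict_spectra(
    em: Emulator, Xq: np.ndarray, clip_to_unit: bool = False
) -> np.ndarray:
    """Predict q x K spectra for q variable vectors (deterministic).

    Queries outside the training hyper-rectangle are allowed — emulators,
    unlike piece-wise linear interpolation, can extrapolate — but trigger
    a warning.  With ``clip_to_unit`` the output is clipped to
    [0, reflectance_scale].
    """
    Xq = np.asarray(Xq, dtype=float)
    if Xq.ndim == 1:
        Xq = Xq[None, :]
    D = len(em.variable_names)
    if Xq.shape[1] != D:
        raise ValueError(f"expected {D} variables, got {Xq.shape[1]}")
    if Xq.shape[0] == 0:
        return np.empty((0, len(em.band_grid)))
    if not np.all(np.isfinite(Xq)):
        raise ValueError("queries must be finite")
    if np.any(Xq < em.input_min - 1e-12) or np.any(Xq > em.input_max + 1e-12):
        warnings.warn(
            "query outside the training hyper-rectangle; emulator is "
            "extrapolating",
            stacklevel=2,
        )
    Xs = (Xq - em.input_mean) / em.input_std
    Ss = _PREDICT[em.config.method](em.regressor_state, Xs)
    scores = Ss * em.score_std + em.score_mean
    # row-wise decompression keeps predictions bit-equal across batchings
    out = em.pca.mean_spectrum + _rowwise_matmul(scores, em.pca.loadings.T)
    if clip_to_unit:
        out = np.clip(out, 0.0, em.band_grid.reflectance_scale)
    return out


# ---------------------------------------------------------------------------
# Serialization (.semu: zip of manifest.json + arrays/*.bin)


def _config_to_dict(config: EmulatorConfig) -> dict:
    return asdict(config)


def _config_from_dict(d: dict) -> EmulatorConfig:
    return EmulatorConfig(
        method=d["method"],
        n_components=d["n_components"],
        seed=d["seed"],
        krr=KRRConfig(
            ridge_grid=tuple(d["krr"]["ridge_grid"]),
            width_grid=tuple(d["krr"]["width_grid"]),
            cv_folds=d["krr"]["cv_folds"],
        ),
        gpr=GPRConfig(**d["gpr"]),
        nn=NNConfig(
            hidden_layer_sizes=tuple(d["nn"]["hidden_layer_sizes"]),
            activation=d["nn"]["activation"],
            max_epochs=d["nn"]["max_epochs"],
            early_stopping_fraction=d["nn"]["early_stopping_fraction"],
        ),
    )


def save_emulator(em: Emulator, path: str | Path) -> Path:
    """Serialize an emulator to a ``.semu`` archive.

    The archive is a zip holding ``manifest.json`` plus one raw
    little-endian float64 row-major ``.bin`` per array.  Writing is fully
    deterministic (fixed entry order and timestamps), so identical models
    produce byte-identical files.
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {
        "input_mean": em.input_mean,
        "input_std": em.input_std,
        "input_min": em.input_min,
        "input_max": em.input_max,
        "pca_mean": em.pca.mean_spectrum,
        "pca_loadings": em.pca.loadings,
        "pca_eigenvalues": em.pca.eigenvalues,
        "score_mean": em.score_mean,
        "score_std": em.score_std,
        "wavelengths": em.band_grid.wavelengths,
    }
    for name, arr in em.regressor_state.items():
        arrays[f"state.{name}"] = np.asarray(arr, dtype=float)

    manifest = {
        "format_version": FORMAT_VERSION,
        "method": em.config.method,
        "config": _config_to_dict(em.config),
        "variable_names": em.variable_names,
        "sensor_label": em.band_grid.sensor_label,
        "reflectance_scale": em.band_grid.reflectance_scale,
        "n_components": em.pca.n_components,
        "training_fingerprint": em.training_fingerprint,
        "arrays": {
            name: list(arr.shape) for name, arr in sorted(arrays.items())
        },
    }
    epoch = (1980, 1, 1, 0, 0, 0)  # fixed timestamp: byte-identical archives
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo("manifest.json", date_time=epoch)
        zf.writestr(info, json.dumps(manifest, sort_keys=True, indent=1))
        for name in sorted(arrays):
            arr = np.ascontiguousarray(arrays[name], dtype="<f8")
            info = zipfile.ZipInfo(f"arrays/{name}.bin", date_time=epoch)
            zf.writestr(info, arr.tobytes())
    return path


def load_emulator(path: str | Path) -> Emulator:
    """Load a ``.semu`` archive; predictions are bit-equal to pre-save."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        try:
            manifest = json.loads(zf.read("manifest.json"))
        except KeyError as exc:
            raise CorruptModelError(f"{path}: missing manifest.json") from exc
        arrays: dict[str, np.ndarray] = {}
        for name, shape in manifest["arrays"].items():
            try:
                raw = zf.read(f"arrays/{name}.bin")
            except KeyError as exc:
                raise CorruptModelError(f"{path}: missing array {name!r}") from exc
            expected = int(np.prod(shape)) * 8
            if len(raw) != expected:
                raise CorruptModelError(
                    f"{path}: array {name!r} has {len(raw)} bytes, "
                    f"manifest says {expected}"
                )
            arrays[name] = np.frombuffer(raw, dtype="<f8").reshape(shape).copy()

    config = _config_from_dict(manifest["config"])
    K = arrays["pca_mean"].size
    loadings = arrays["pca_loadings"]
    if loadings.shape[0] != K or loadings.shape[1] != manifest["n_components"]:
        raise CorruptModelError(f"{path}: loadings shape mismatch with manifest")
    basis = PCABasis(
        mean_spectrum=arrays["pca_mean"],
        loadings=loadings,
        eigenvalues=arrays["pca_eigenvalues"],
        n_components=manifest["n_components"],
    )
    grid = BandGrid(
        arrays["wavelengths"],
        manifest["sensor_label"],
        manifest["reflectance_scale"],
    )
    state = {
        name[len("state."):]: arr
        for name, arr in arrays.items()
        if name.startswith("state.")
    }
    return Emulator(
        config=config,
        variable_names=list(manifest["variable_names"]),
        band_grid=grid,
        input_mean=arrays["input_mean"],
        input_std=arrays["input_std"],
        input_min=arrays["input_min"],
        input_max=arrays["input_max"],
        pca=basis,
        score_mean=arrays["score_mean"],
        score_std=arrays["score_std"],
        regressor_state=state,
        training_fingerprint=manifest["training_fingerprint"],
    )
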