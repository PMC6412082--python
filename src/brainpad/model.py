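"""Similarity-kernel Gaussian-process age regression and brain-PAD scoring.

Subjects' concatenated GM+WM voxel vectors enter only through their pairwise
dot products (a linear similarity kernel), so the model scales with cohort
size rather than voxel count. Age is regressed on the kernel by GP regression
with a constant mean fixed at the training-age mean; for fixed hyperparameters
the predictive mean coincides with kernel ridge regression,

    f(x*) = mu + k*' (s K + sigma_n^2 I)^{-1} (y - mu),

which is the module's primary numerical oracle. Accuracy is assessed by
k-fold cross-validation (Pearson r, R^2, MAE, RMSE) and significance by
permuting ages and repeating the full cross-validation.

brain-PAD (brain-predicted age difference) = predicted age - chronological
age; positive values mean an older-appearing brain.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .volumes import DimensionError, FeatureVector

logger = logging.getLogger(__name__)

SCALE_MODES = ("none", "by_voxel_count", "trace_normalized")


@dataclass
class SimilarityKernel:
    """Symmetric PSD N x N matrix of pairwise feature dot products."""

    matrix: np.ndarray
    subject_ids: list[str]
    scale_mode: str = "by_voxel_count"
    mask_id: str | None = None
    feature_dim: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise DimensionError(f"kernel must be square, got {self.matrix.shape}")
        scale = max(np.abs(self.matrix).max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-10 * scale:
            raise ValueError("kernel matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


def _stack_features(features: Sequence[FeatureVector]) -> tuple[np.ndarray, list[str], str]:
    if len(features) == 0:
        raise ValueError("no feature vectors given")
    lengths = {len(f) for f in features}
    if len(lengths) != 1:
        raise DimensionError(f"feature lengths differ: {sorted(lengths)}")
    mask_ids = {f.mask_id for f in features}
    if len(mask_ids) != 1:
        raise ValueError(f"feature vectors built from different masks: {mask_ids}")
    X = np.stack([f.values for f in features])
    ids = [f.subject_id or f"subj_{i:04d}" for i, f in enumerate(features)]
    return X, ids, mask_ids.pop()


def _scale_gram(K: np.ndarray, scale_mode: str, feature_dim: int) -> np.ndarray:
    if scale_mode == "none":
        return K
    if scale_mode == "by_voxel_count":
        return K / max(feature_dim, 1)
    if scale_mode == "trace_normalized":
        tr = np.trace(K)
        return K * (K.shape[0] / tr) if tr > 0 else K
    raise ValueError(f"unknown scale_mode {scale_mode!r}; choose from {SCALE_MODES}")


def build_kernel(
    features: Sequence[FeatureVector], scale_mode: str = "by_voxel_count"
) -> SimilarityKernel:
    """Gram matrix K_ij = x_i . x_j of the subjects' feature vectors."""
    if len(features) < 2:
        raise ValueError(f"need at least 2 subjects for a kernel, got {len(features)}")
    X, ids, mask_id = _stack_features(features)
    K = X @ X.T
    K = _scale_gram(K, scale_mode, X.shape[1])
    K = (K + K.T) / 2.0  # exact symmetry against float round-off
    return SimilarityKernel(K, ids, scale_mode, mask_id, X.shape[1])


def build_cross_kernel(
    test_features: Sequence[FeatureVector],
    train_features: Sequence[FeatureVector] | SimilarityKernel,
    scale_mode: str | None = None,
    train_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """N_test x N_train matrix of test-vs-training dot products.

    ``train_features`` is the training feature list; scaling follows the
    training kernel's ``scale_mode``.
    """
    Xte, _, mask_te = _stack_features(test_features)
    Xtr, _, mask_tr = _stack_features(train_features)  # type: ignore[arg-type]
    if mask_te != mask_tr:
        raise ValueError(
            f"test features use mask {mask_te}, training used {mask_tr}: "
            "all subjects entering one model must share the mask"
        )
    if Xte.shape[1] != Xtr.shape[1]:
        raise DimensionError(
            f"feature length mismatch: test {Xte.shape[1]} vs train {Xtr.shape[1]}"
        )
    scale_mode = scale_mode or "by_voxel_count"
    C = Xte @ Xtr.T
    if scale_mode == "trace_normalized":
        # the same multiplicative factor the training Gram received
        tr = np.trace(Xtr @ Xtr.T)
        C = C * (Xtr.shape[0] / tr) if tr > 0 else C
    else:
        C = _scale_gram(C, scale_mode, Xtr.shape[1])
    return C


# ---------------------------------------------------------------------------
# Gaussian-process regression (constant mean, linear similarity kernel)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRHyperparams:
    """Kernel multiplier, observation noise variance (years^2), mean offset."""

    signal_scale: float
    noise_var: float
    mean_offset: float

    def __post_init__(self) -> None:
        if self.signal_scale <= 0 or self.noise_var <= 0:
            raise ValueError("signal_scale and noise_var must be positive")


@dataclass
class GPRModel:
    hyper: GPRHyperparams
    alpha: np.ndarray  # dual weights (sK + sigma^2 I)^{-1} (y - mu)
    subject_ids: list[str]
    scale_mode: str = "by_voxel_count"
    mask_id: str | None = None
    # kernel centering statistics (training column means and grand mean);
    # None means the model was fit on the raw, uncentered Gram matrix
    center_col_means: np.ndarray | None = None
    center_grand_mean: float | None = None
    log_marginal_likelihood: float | None = None

    @property
    def n_train(self) -> int:
        return self.alpha.size

    @property
    def centered(self) -> bool:
        return self.center_col_means is not None


def center_gram(K: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Double-center a Gram matrix (subtract the mean training image).

    Returns (centered K, column means, grand mean). Centering removes the
    shared-anatomy component that otherwise dominates the dot products and
    masks the age signal; the centered matrix is the Gram matrix of the
    mean-subtracted feature vectors, hence still PSD.
    """
    col = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col[None, :] - col[:, None] + grand
    return (Kc + Kc.T) / 2.0, col, grand


def center_cross(
    C: np.ndarray, col_means: np.ndarray, grand_mean: float
) -> np.ndarray:
    """Apply training-based centering to a test-vs-training cross kernel:
    (x* - xbar).(x_j - xbar) = k*_j - mean_i k*_i - colmean_j + grand."""
    row = C.mean(axis=1, keepdims=True)
    return C - col_means[None, :] - row + grand_mean


def _neg_lml_eigen(log_s: float, log_sn2: float, lam: np.ndarray, yt2: np.ndarray) -> float:
    d = np.exp(log_s) * lam + np.exp(log_sn2)
    return 0.5 * float(np.sum(yt2 / d) + np.sum(np.log(d)) + lam.size * np.log(2 * np.pi))


def optimize_hyperparams(
    K: np.ndarray, ages: np.ndarray, n_restarts: int = 3
) -> GPRHyperparams:
    """Maximize the Gaussian log marginal likelihood over (signal, noise).

    Because the kernel is fixed, C = s K + sigma_n^2 I shares K's
    eigenvectors, so each likelihood evaluation costs O(n) after one
    eigendecomposition. L-BFGS-B on log parameters from fixed restarts.
    """
    y = np.asarray(ages, dtype=float)
    mu = y.mean()
    yc = y - mu
    vy = float(yc.var())
    if vy < 1e-12:
        # zero-variance target: any noise floor gives constant predictions
        return GPRHyperparams(1.0, 1e-6, mu)
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yt2 = (U.T @ yc) ** 2
    mean_lam = max(float(lam.mean()), 1e-300)
    s0 = vy / mean_lam
    # the flat "all noise" solution (s -> 0, sigma^2 -> var y) is a known
    # local optimum; one restart starts from a deliberately large signal scale
    starts = [
        (np.log(s0), np.log(0.1 * vy)),
        (np.log(s0), np.log(0.5 * vy)),
        (np.log(1e3 * s0), np.log(0.01 * vy)),
    ][: max(1, n_restarts)]
    lo_sn2 = np.log(1e-8 * vy)
    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        res = optimize.minimize(
            lambda x: _neg_lml_eigen(x[0], x[1], lam, yt2),
            np.asarray(x0),
            method="L-BFGS-B",
            bounds=[(x0[0] - 40, x0[0] + 40), (lo_sn2, np.log(1e4 * vy))],
        )
        if not res.success:
            logger.warning("hyperparameter optimizer did not converge: %s", res.message)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    assert best is not None
    log_s, log_sn2 = best[1]
    return GPRHyperparams(float(np.exp(log_s)), float(np.exp(log_sn2)), mu)


def _solve_spd(C: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cholesky solve with one diagonal-jitter retry."""
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-8 * np.trace(C) / C.shape[0]
        logger.warning("kernel factorization failed; adding jitter %.3g", jitter)
        cf = linalg.cho_factor(C + jitter * np.eye(C.shape[0]), lower=True)
    return linalg.cho_solve(cf, b)


def fit_gpr(
    K: SimilarityKernel | np.ndarray,
    ages: Sequence[float],
    hyper: GPRHyperparams | str = "optimize",
    subject_ids: Sequence[str] | None = None,
    scale_mode: str = "by_voxel_count",
    mask_id: str | None = None,
    center: bool = True,
) -> GPRModel:
    """Fit the GP age-regression model on a training kernel.

    ``hyper="optimize"`` maximizes the log marginal likelihood; passing a
    :class:`GPRHyperparams` fixes the hyperparameters (the mean offset is
    always reset to the training-age mean). ``center=True`` (default)
    double-centers the Gram matrix — equivalent to subtracting the mean
    training image from every feature vector — which removes the dominant
    shared-anatomy component; prediction applies the matching correction to
    cross kernels automatically. ``center=False`` gives the textbook
    uncentered model (used by the closed-form oracles).
    """
    if isinstance(K, SimilarityKernel):
        mat = K.matrix
        subject_ids = subject_ids or K.subject_ids
        scale_mode = K.scale_mode
        mask_id = mask_id or K.mask_id
    else:
        mat = np.asarray(K, dtype=float)
    y = np.asarray(ages, dtype=float)
    if y.size != mat.shape[0]:
        raise DimensionError(f"{y.size} ages for a {mat.shape[0]}-subject kernel")
    if not np.all(np.isfinite(y)):
        raise ValueError("ages must be finite")
    n = mat.shape[0]
    col_means = grand = None
    if center:
        mat, col_means, grand = center_gram(mat)
    min_eig = float(np.linalg.eigvalsh(mat)[0])
    if min_eig < -1e-8 * max(np.trace(mat) / n, 1.0):
        raise ValueError(f"kernel is not PSD (min eigenvalue {min_eig:.3g})")
    if isinstance(hyper, str):
        if hyper != "optimize":
            raise ValueError(f"hyper must be GPRHyperparams or 'optimize', got {hyper!r}")
        hp = optimize_hyperparams(mat, y)
    else:
        hp = GPRHyperparams(hyper.signal_scale, hyper.noise_var, float(y.mean()))
    C = hp.signal_scale * mat + hp.noise_var * np.eye(n)
    alpha = _solve_spd(C, y - hp.mean_offset)
    ids = list(subject_ids) if subject_ids is not None else [f"subj_{i:04d}" for i in range(n)]
    return GPRModel(hyper=hp, alpha=alpha, subject_ids=ids,
                    scale_mode=scale_mode, mask_id=mask_id,
                    center_col_means=col_means, center_grand_mean=grand)


def predict_mean(model: GPRModel, cross_kernel: np.ndarray) -> np.ndarray:
    """Predictive mean ages: mu + s * K_cross alpha (centering applied if the
    model was fit on a centered kernel)."""
    C = np.atleast_2d(np.asarray(cross_kernel, dtype=float))
    if C.shape[1] != model.n_train:
        raise DimensionError(
            f"cross kernel has {C.shape[1]} training columns, model expects {model.n_train}"
        )
    if model.centered:
        C = center_cross(C, model.center_col_means, model.center_grand_mean)
    return model.hyper.mean_offset + model.hyper.signal_scale * (C @ model.alpha)


@dataclass(frozen=True)
class PredictionRecord:
    """Predicted vs chronological age for one subject; brain_pad = difference."""

    subject_id: str
    chronological_age: float
    predicted_age: float

    @property
    def brain_pad(self) -> float:
        return self.predicted_age - self.chronological_age


def brain_pad(predicted_age, chronological_age):
    """brain-PAD = predicted age - chronological age (years)."""
    return np.asarray(predicted_age, dtype=float) - np.asarray(chronological_age, dtype=float)


def predict_gpr(
    model: GPRModel,
    cross_kernel: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    chronological_ages: Sequence[float] | None = None,
) -> list[PredictionRecord]:
    """Apply a trained model through a test-vs-training cross kernel."""
    pred = predict_mean(model, cross_kernel)
    n = pred.size
    ids = list(subject_ids) if subject_ids is not None else [f"test_{i:04d}" for i in range(n)]
    chron = (
        np.asarray(chronological_ages, dtype=float)
        if chronological_ages is not None
        else np.full(n, np.nan)
    )
    return [PredictionRecord(ids[i], float(chron[i]), float(pred[i])) for i in range(n)]


def predictions_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.chronological_age for r in records],
            "predicted_age": [r.predicted_age for r in records],
            "brain_pad": [r.brain_pad for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Cross-validation and permutation significance
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    predicted_age: np.ndarray
    r: float
    r2: float
    mae: float
    rmse: float
    seed: int | None = None
    perm_p: float | None = None
    subject_ids: list[str] | None = None


def cv_metrics(predicted: np.ndarray, ages: np.ndarray) -> tuple[float, float, float, float]:
    """(Pearson r, R^2 = r^2, MAE, RMSE) of predictions against true ages."""
    predicted = np.asarray(predicted, dtype=float)
    ages = np.asarray(ages, dtype=float)
    err = predicted - ages
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(predicted) == 0 or np.std(ages) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(predicted, ages)[0, 1])
    return r, r * r, mae, rmse


def assign_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation chunked into near-equal folds (sizes differ <=1)."""
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def _cv_predict_kernel(
    K: np.ndarray,
    ages: np.ndarray,
    folds: np.ndarray,
    hyper: GPRHyperparams | str,
    center: bool = True,
) -> np.ndarray:
    """Out-of-fold GPR predictions using submatrices of the full Gram matrix.

    Any hyperparameter optimization happens inside the training fold only.
    """
    pred = np.empty_like(ages, dtype=float)
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        Ktr = K[np.ix_(tr, tr)]
        model = fit_gpr(Ktr, ages[tr], hyper=hyper, center=center)
        pred[te] = predict_mean(model, K[np.ix_(te, tr)])
    return pred


def crossvalidate(
    features: Sequence[FeatureVector] | SimilarityKernel,
    ages: Sequence[float],
    seed: int = 0,
    n_folds: int = 10,
    hyper: GPRHyperparams | str = "optimize",
    scale_mode: str = "by_voxel_count",
    center: bool = True,
) -> CVResult:
    """k-fold cross-validated age prediction (default 10 folds).

    Folds are a seeded uniform random partition into near-equal parts; each
    subject is predicted exactly once by a model fit on the other folds. With
    fewer subjects than folds the fold count is reduced with a warning.
    """
    kern = features if isinstance(features, SimilarityKernel) else build_kernel(features, scale_mode)
    y = np.asarray(ages, dtype=float)
    n = kern.n
    if y.size != n:
        raise DimensionError(f"{y.size} ages for {n} subjects")
    if n < n_folds:
        warnings.warn(f"only {n} subjects: reducing folds from {n_folds} to {n}")
        n_folds = n
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    folds = assign_folds(n, n_folds, rng)
    pred = _cv_predict_kernel(kern.matrix, y, folds, hyper, center=center)
    r, r2, mae, rmse = cv_metrics(pred, y)
    return CVResult(folds, pred, r, r2, mae, rmse, seed=seed, subject_ids=kern.subject_ids)


@dataclass
class PermutationResult:
    p: float
    r_observed: float
    null_r: np.ndarray
    n_perm: int


def permutation_test(
    features: Sequence[FeatureVector] | SimilarityKernel,
    ages: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    n_folds: int = 10,
    hyper: GPRHyperparams | str = "optimize",
    scale_mode: str = "by_voxel_count",
    center: bool = True,
) -> PermutationResult:
    """Permutation significance of the cross-validated age correlation.

    Ages are permuted uniformly; the full cross-validation (same folds) is
    repeated per permutation; one-sided upper-tail p with +1 smoothing,
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    kern = features if isinstance(features, SimilarityKernel) else build_kernel(features, scale_mode)
    y = np.asarray(ages, dtype=float)
    rng_folds = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    n = kern.n
    nf = min(n_folds, n)
    folds = assign_folds(n, nf, rng_folds)
    pred = _cv_predict_kernel(kern.matrix, y, folds, hyper, center=center)
    r_obs = cv_metrics(pred, y)[0]
    rng_perm = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    null_r = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng_perm.permutation(y)
        pp = _cv_predict_kernel(kern.matrix, yp, folds, hyper, center=center)
        null_r[b] = cv_metrics(pp, yp)[0]
    p = (1.0 + np.sum(null_r >= r_obs)) / (1.0 + n_perm)
    return PermutationResult(float(p), float(r_obs), null_r, n_perm)


# ---------------------------------------------------------------------------
# Optional age-bias correction (NOT part of the published procedure)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeBiasCorrection:
    """Linear recalibration of predicted ages against chronological age.

    Kernel regression on noisy features attenuates predictions toward the
    training mean (regression dilution), which biases brain-PAD group
    differences by (1 - slope) x offset. Fitting ``pred = a + b * age`` on
    out-of-sample training predictions and applying ``(pred - a) / b``
    removes that attenuation. This mode is OFF by default everywhere: the
    published analysis applies no such correction, so using it changes the
    estimand relative to the original procedure.
    """

    intercept: float
    slope: float

    @classmethod
    def fit(cls, predicted: np.ndarray, ages: np.ndarray) -> "AgeBiasCorrection":
        b, a = np.polyfit(np.asarray(ages, float), np.asarray(predicted, float), 1)
        if abs(b) < 1e-12:
            raise ValueError("cannot correct: predictions do not depend on age")
        return cls(intercept=float(a), slope=float(b))

    def apply(self, predicted) -> np.ndarray:
        return (np.asarray(predicted, dtype=float) - self.intercept) / self.slope


# ---------------------------------------------------------------------------
# Serialization (single .npz archive; bit-exact reload)
# ---------------------------------------------------------------------------


def save_model(model: GPRModel, path) -> None:
    meta = {
        "signal_scale": model.hyper.signal_scale,
        "noise_var": model.hyper.noise_var,
        "mean_offset": model.hyper.mean_offset,
        "scale_mode": model.scale_mode,
        "mask_id": model.mask_id or "",
        "subject_ids": model.subject_ids,
        "centered": model.centered,
        "center_grand_mean": model.center_grand_mean,
    }
    arrays = {"alpha": model.alpha,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if model.centered:
        arrays["center_col_means"] = model.center_col_means
    np.savez(path, **arrays)


def load_model(path) -> GPRModel:
    with np.load(path) as data:
        alpha = data["alpha"]
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        col = data["center_col_means"] if meta.get("centered") else None
    return GPRModel(
        hyper=GPRHyperparams(meta["signal_scale"], meta["noise_var"], meta["mean_offset"]),
        alpha=alpha,
        subject_ids=list(meta["subject_ids"]),
        scale_mode=meta["scale_mode"],
        mask_id=meta["mask_id"] or None,
        center_col_means=col,
        center_grand_mean=meta.get("center_grand_mean"),
    )
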