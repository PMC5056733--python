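"""C-SVC training, latent-variable evaluation and Platt probability calibration.

The estimator :class:`ExplainableSVC` delegates the quadratic program to
``sklearn.svm.SVC`` and then *discards* the solver object: the fitted model is
fully described by its support vectors, signed dual coefficients ``α_i y_i``,
intercept ``b``, kernel specification and feature-scaling record.  Every
downstream quantity (decision values, decomposition, nomogram) is recomputed
from these, so a serialized model round-trips exactly.

The latent variable is ``ℓ(x) = Σ_i α_i y_i K(x_i, x) + b``; the class label is
``sign(ℓ)`` with ``sign(0) = +1``; the calibrated risk is Platt's sigmoid
``h(ℓ) = 1 / (1 + exp(A ℓ + B))`` fitted on pooled out-of-fold latent values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .datasets import Dataset
from .kernels import KernelSpec

__all__ = [
    "ExplainableSVC",
    "PlattCalibration",
    "fit_svm",
    "latent_variable",
    "fit_platt",
    "predict",
    "model_to_json",
    "model_from_json",
]


@dataclass
class PlattCalibration:
    """Two-parameter sigmoid ``h(ℓ) = 1/(1+exp(A ℓ + B))`` mapping latent to risk."""

    slope_A: float
    offset_B: float

    def risk(self, latent: np.ndarray) -> np.ndarray:
        return expit(-(self.slope_A * np.asarray(latent, dtype=float) + self.offset_B))

    def to_dict(self) -> dict:
        return {"slope_A": self.slope_A, "offset_B": self.offset_B}

    @classmethod
    def from_dict(cls, d: dict) -> "PlattCalibration":
        return cls(slope_A=float(d["slope_A"]), offset_B=float(d["offset_B"]))


def _platt_sigmoid_fit(latent: np.ndarray, y: np.ndarray) -> PlattCalibration:
    """Fit (A, B) by maximizing Platt's regularized likelihood.

    Uses Platt's smoothed targets ``t+ = (N+ + 1)/(N+ + 2)``,
    ``t- = 1/(N- + 2)`` and an L-BFGS search on the convex cross-entropy.
    """
    latent = np.asarray(latent, dtype=float)
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt calibration requires both classes")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(ab):
        A, B = ab
        z = A * latent + B  # h = expit(-z)
        nll = -(t * log_expit(-z) + (1.0 - t) * log_expit(z)).sum()
        p = expit(-z)
        grad_z = t - p  # d nll / d z
        return nll, np.array([(grad_z * latent).sum(), grad_z.sum()])

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(objective, x0, jac=True, method="L-BFGS-B")
    return PlattCalibration(slope_A=float(res.x[0]), offset_B=float(res.x[1]))


class ExplainableSVC(ClassifierMixin, BaseEstimator):
    """C-SVC with linear, polynomial or RBF kernel, built to be decomposed.

    Parameters
    ----------
    kernel : {"linear", "polynomial", "rbf"}, default="rbf"
    C : float, default=1.0
        Box constraint of the soft-margin problem.
    gamma : float, default=1.0
        RBF inverse squared kernel width (γ = 1/σ²).
    scale_a, offset_c : float, default=1.0
        Scale and bias of the polynomial kernel ``(a x·z + c)^δ``.
    degree : int, default=3
        Polynomial degree δ.
    standardize : bool, default=True
        Center/scale each feature before training; the record is stored so
        that raw inputs can always be passed to ``predict``/``decision_function``.
    calibrate : bool, default=True
        Fit Platt's sigmoid on pooled out-of-fold latent values.
    calibration_folds : int, default=3
    random_state : int or None
        Seeds the calibration fold assignment.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted original labels; the larger one is the positive class.
    support_vectors_ : ndarray of shape (n_sv, d), in scaled space.
    dual_coef_signed_ : ndarray of shape (n_sv,) — the ``α_i y_i``.
    intercept_ : float
    kernel_spec_ : KernelSpec
    scale_center_, scale_spread_ : ndarray of shape (d,)
    platt_ : PlattCalibration or None
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 1.0,
        gamma: float = 1.0,
        scale_a: float = 1.0,
        offset_c: float = 1.0,
        degree: int = 3,
        standardize: bool = True,
        calibrate: bool = True,
        calibration_folds: int = 3,
        random_state: Optional[int] = None,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.scale_a = scale_a
        self.offset_c = offset_c
        self.degree = degree
        self.standardize = standardize
        self.calibrate = calibrate
        self.calibration_folds = calibration_folds
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _kernel_spec(self) -> KernelSpec:
        return KernelSpec(
            family=self.kernel,
            gamma=self.gamma,
            scale_a=self.scale_a,
            offset_c=self.offset_c,
            degree_delta=self.degree,
        )

    def _make_svc(self) -> SVC:
        spec = self._kernel_spec()
        if spec.family == "linear":
            return SVC(kernel="linear", C=self.C)
        if spec.family == "polynomial":
            # sklearn's poly kernel is (gamma x·z + coef0)^degree
            return SVC(
                kernel="poly",
                C=self.C,
                gamma=spec.scale_a,
                coef0=spec.offset_c,
                degree=spec.degree_delta,
            )
        return SVC(kernel="rbf", C=self.C, gamma=spec.gamma)

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input")
        return X

    def transform_features(self, X) -> np.ndarray:
        """Apply the stored scaling record (identity if standardize=False)."""
        X = self._validate_X(X)
        if X.shape[1] != self.scale_center_.size:
            raise ValueError(
                f"dimension mismatch: model has d={self.scale_center_.size}, got {X.shape[1]}"
            )
        return (X - self.scale_center_) / self.scale_spread_

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        classes = np.sort(np.unique(y))
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {len(classes)}")
        self.classes_ = classes
        y_signed = np.where(y == classes[1], 1, -1)

        if self.standardize:
            center = X.mean(axis=0)
            spread = X.std(axis=0)
            spread[spread == 0] = 1.0
        else:
            center = np.zeros(X.shape[1])
            spread = np.ones(X.shape[1])
        self.scale_center_, self.scale_spread_ = center, spread
        Xs = (X - center) / spread

        svc = self._make_svc().fit(Xs, y_signed)
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_signed_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.kernel_spec_ = self._kernel_spec()
        self.n_features_in_ = X.shape[1]

        self.platt_ = None
        if self.calibrate:
            self.platt_ = fit_platt(
                self, X, y, folds=self.calibration_folds, random_state=self.random_state
            )
        return self

    def _kernel_matrix(self, Xs: np.ndarray) -> np.ndarray:
        """K(x_j, sv_i) for scaled query rows, shape (m, n_sv)."""
        spec, SV = self.kernel_spec_, self.support_vectors_
        if spec.family == "linear":
            return Xs @ SV.T
        if spec.family == "polynomial":
            return (spec.scale_a * (Xs @ SV.T) + spec.offset_c) ** spec.degree_delta
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            + np.sum(SV**2, axis=1)[None, :]
            - 2.0 * Xs @ SV.T
        )
        return np.exp(-spec.gamma * np.maximum(d2, 0.0))

    def decision_function(self, X) -> np.ndarray:
        """The latent variable ``ℓ(x) = Σ_i α_i y_i K(x_i, x) + b``."""
        check_is_fitted(self, "support_vectors_")
        Xs = self.transform_features(X)
        return self._kernel_matrix(Xs) @ self.dual_coef_signed_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        latent = self.decision_function(X)
        pos = latent >= 0  # sign(0) = +1 tie-break
        return np.where(pos, self.classes_[1], self.classes_[0])

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "support_vectors_")
        if self.platt_ is None:
            raise RuntimeError("model was fitted with calibrate=False; no Platt sigmoid")
        risk = self.platt_.risk(self.decision_function(X))
        return np.column_stack([1.0 - risk, risk])


# ---------------------------------------------------------------------------
# functional surface over the estimator
# ---------------------------------------------------------------------------


def fit_svm(
    data: Dataset,
    kernel: KernelSpec,
    cost_C: float,
    standardize: bool = True,
    calibrate: bool = False,
    random_state: Optional[int] = None,
) -> ExplainableSVC:
    """Train a C-SVC on a :class:`Dataset` under the given kernel spec."""
    if not cost_C > 0:
        raise ValueError("cost_C must be positive")
    model = ExplainableSVC(
        kernel=kernel.family,
        C=cost_C,
        gamma=kernel.gamma,
        scale_a=kernel.scale_a,
        offset_c=kernel.offset_c,
        degree=kernel.degree_delta,
        standardize=standardize,
        calibrate=calibrate,
        random_state=random_state,
    )
    model.fit(data.features, data.labels)
    model.feature_names_ = list(data.feature_names)
    return model


def latent_variable(model: ExplainableSVC, X) -> np.ndarray:
    return model.decision_function(X)


def fit_platt(
    model: ExplainableSVC, X, y, folds: int = 3, random_state: Optional[int] = None
) -> PlattCalibration:
    """Platt calibration on pooled out-of-fold latent values.

    Refits a clone of the model on each training fold, collects latent values
    of the held-out folds, and fits a single sigmoid to the pooled values with
    Platt's smoothed targets.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.sort(np.unique(y))
    y_signed = np.where(y == classes[-1], 1, -1)
    if len(classes) < 2 or min(np.bincount((y_signed + 1) // 2)) < folds:
        raise ValueError("each class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    pooled_latent = np.empty(len(y), dtype=float)
    base = clone(model) if isinstance(model, ExplainableSVC) else model
    base.set_params(calibrate=False)
    for tr, te in skf.split(X, y_signed):
        m = clone(base).fit(X[tr], y[tr])
        pooled_latent[te] = m.decision_function(X[te])
    return _platt_sigmoid_fit(pooled_latent, y_signed)


def predict(model: ExplainableSVC, calib: PlattCalibration, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels (±1, sign(0)=+1) and calibrated risks for query rows."""
    latent = model.decision_function(X)
    labels = np.where(latent >= 0, 1, -1)
    return labels, calib.risk(latent)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_json(model: ExplainableSVC) -> str:
    check_is_fitted(model, "support_vectors_")
    doc = {
        "params": model.get_params(),
        "classes": model.classes_.tolist(),
        "support_vectors": model.support_vectors_.tolist(),
        "dual_coef_signed": model.dual_coef_signed_.tolist(),
        "intercept": model.intercept_,
        "kernel_spec": model.kernel_spec_.to_dict(),
        "scale_center": model.scale_center_.tolist(),
        "scale_spread": model.scale_spread_.tolist(),
        "n_features_in": model.n_features_in_,
        "platt": model.platt_.to_dict() if model.platt_ is not None else None,
    }
    return json.dumps(doc)


def model_from_json(s: str) -> ExplainableSVC:
    doc = json.loads(s)
    model = ExplainableSVC(**doc["params"])
    model.classes_ = np.array(doc["classes"])
    model.support_vectors_ = np.array(doc["support_vectors"], dtype=float)
    model.dual_coef_signed_ = np.array(doc["dual_coef_signed"], dtype=float)
    model.intercept_ = float(doc["intercept"])
    model.kernel_spec_ = KernelSpec.from_dict(doc["kernel_spec"])
    model.scale_center_ = np.array(doc["scale_center"], dtype=float)
    model.scale_spread_ = np.array(doc["scale_spread"], dtype=float)
    model.n_features_in_ = int(doc["n_features_in"])
    model.platt_ = PlattCalibration.from_dict(doc["platt"]) if doc["platt"] else None
    return model
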