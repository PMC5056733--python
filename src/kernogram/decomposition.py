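"""Additive decomposition of the SVM latent variable.

Aggregating the kernel-level split over support vectors turns the latent
variable into

``ℓ(x) = b'' + Σ_p f^(p)(x^(p)) + Σ_{p<q} f^(p,q)(x^(p), x^(q)) + Δℓ(x)``

where ``f^(p) = Σ_i α_i y_i g^(p)``, ``f^(p,q) = Σ_i α_i y_i g^(p,q)``, all
input-independent kernel constants are folded into the intercept
``b'' = b + Σ_i α_i y_i · const``, and the rest term ``Δℓ`` is the residual
aggregating interactions of order three and above.  Dropping ``Δℓ`` gives the
visualizable additive approximation; its validity is what the diagnostics
module measures.

Contributions are defined on the model's *scaled* feature space but all public
entry points accept raw inputs and apply the stored scaling record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import pair_index, pair_names
from .svm import ExplainableSVC, PlattCalibration

__all__ = [
    "Decomposition",
    "ShiftedDecomposition",
    "decompose_model",
    "approximate_latent",
    "shift_contributions",
    "from_additive_model",
    "main_effect_values",
    "pair_effect_values",
]

SHIFT_MODES = ("zero", "mean", "median", "minimum")


@dataclass
class Decomposition:
    """Per-observation contributions of every term of the additive expansion."""

    main_contribs: np.ndarray  # (N, d)
    pair_contribs: np.ndarray  # (N, d(d-1)/2)
    intercept_bpp: float  # b'' — intercept plus aggregated kernel constants
    rest: np.ndarray  # (N,)
    latent_full: np.ndarray  # (N,)
    feature_names: list[str]

    @property
    def n(self) -> int:
        return self.main_contribs.shape[0]

    @property
    def d(self) -> int:
        return self.main_contribs.shape[1]

    @property
    def term_names(self) -> list[str]:
        return list(self.feature_names) + pair_names(self.feature_names)

    def contributions(self) -> np.ndarray:
        """All non-constant terms stacked, shape (N, d + d(d-1)/2)."""
        return np.hstack([self.main_contribs, self.pair_contribs])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.contributions(), columns=self.term_names)
        df["rest"] = self.rest
        df["latent"] = self.latent_full
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def meta(self) -> dict:
        return {"intercept_bpp": self.intercept_bpp, "feature_names": self.feature_names}


def _term_matrices(model: ExplainableSVC, Xs: np.ndarray) -> list[np.ndarray]:
    """Per-feature (N, n_sv) matrices of the kernel-level single-input terms."""
    spec, SV = model.kernel_spec_, model.support_vectors_
    d = SV.shape[1]
    if spec.family == "rbf":
        return [
            np.expm1(-spec.gamma * (Xs[:, p][:, None] - SV[None, :, p]) ** 2)
            for p in range(d)
        ]
    # polynomial / linear use u_p = a * sv_p * x_p (a=1 for linear)
    a = spec.scale_a if spec.family == "polynomial" else 1.0
    return [a * Xs[:, p][:, None] * SV[None, :, p] for p in range(d)]


def decompose_model(model: ExplainableSVC, X) -> Decomposition:
    """Decompose the latent variable of `model` at every row of raw inputs X."""
    Xs = model.transform_features(X)
    coef = model.dual_coef_signed_
    spec = model.kernel_spec_
    d = Xs.shape[1]
    pidx = pair_index(d)
    U = _term_matrices(model, Xs)

    if spec.family == "linear":
        main = np.column_stack([U[p] @ coef for p in range(d)])
        pairs = np.zeros((Xs.shape[0], len(pidx)))
        bpp = model.intercept_
    elif spec.family == "polynomial":
        c, delta = spec.offset_c, spec.degree_delta
        const = float(c) ** delta
        main = np.column_stack([((U[p] + c) ** delta - const) @ coef for p in range(d)])
        pairs = np.column_stack(
            [
                (
                    (U[p] + U[q] + c) ** delta
                    - (U[p] + c) ** delta
                    - (U[q] + c) ** delta
                    + const
                )
                @ coef
                for p, q in pidx
            ]
        ) if pidx else np.zeros((Xs.shape[0], 0))
        bpp = model.intercept_ + const * coef.sum()
    else:  # rbf: const = 1, g^(p) = u_p, g^(p,q) = u_p u_q
        main = np.column_stack([U[p] @ coef for p in range(d)])
        pairs = (
            np.column_stack([(U[p] * U[q]) @ coef for p, q in pidx])
            if pidx
            else np.zeros((Xs.shape[0], 0))
        )
        bpp = model.intercept_ + coef.sum()

    latent = model.decision_function(X)
    rest = latent - (bpp + main.sum(axis=1) + pairs.sum(axis=1))
    if spec.family == "linear" or d <= 2 or (spec.family == "polynomial" and spec.degree_delta <= 2):
        rest = np.zeros_like(rest)  # analytically exact
    names = getattr(model, "feature_names_", None) or [f"x{p+1}" for p in range(d)]
    return Decomposition(
        main_contribs=main,
        pair_contribs=pairs,
        intercept_bpp=float(bpp),
        rest=rest,
        latent_full=latent,
        feature_names=list(names),
    )


def approximate_latent(dec: Decomposition) -> np.ndarray:
    """The rest-term-free latent ``ℓ̃ = b'' + Σ main + Σ pairs = ℓ - Δℓ``."""
    return dec.latent_full - dec.rest


def from_additive_model(coefficients, intercept: float, X, feature_names=None) -> Decomposition:
    """Adapter: render any linear additive model (e.g. logistic regression)
    through the same decomposition machinery — main effects ``w^(p) x^(p)``,
    no pairs, no rest."""
    w = np.asarray(coefficients, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != w.size:
        raise ValueError("coefficient / feature dimension mismatch")
    main = X * w
    d = w.size
    latent = main.sum(axis=1) + intercept
    names = list(feature_names) if feature_names is not None else [f"x{p+1}" for p in range(d)]
    return Decomposition(
        main_contribs=main,
        pair_contribs=np.zeros((X.shape[0], d * (d - 1) // 2)),
        intercept_bpp=float(intercept),
        rest=np.zeros(X.shape[0]),
        latent_full=latent,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# display shifting ("points")
# ---------------------------------------------------------------------------


@dataclass
class ShiftedDecomposition:
    """Contributions shifted per term for display; risks are unchanged.

    ``points = contribution - offset`` per term; the sum of offsets plus the
    intercept is folded into the score→risk mapping, so
    ``risk(score) = h(score + score_offset)`` with
    ``score + score_offset = ℓ̃`` exactly.
    """

    main_points: np.ndarray
    pair_points: np.ndarray
    shift_mode: str
    main_offsets: np.ndarray
    pair_offsets: np.ndarray
    intercept_bpp: float
    feature_names: list[str]

    @property
    def score_offset(self) -> float:
        """Constant mapping score back to the approximate latent."""
        return float(self.intercept_bpp + self.main_offsets.sum() + self.pair_offsets.sum())

    @property
    def score(self) -> np.ndarray:
        return self.main_points.sum(axis=1) + self.pair_points.sum(axis=1)

    @property
    def term_names(self) -> list[str]:
        return list(self.feature_names) + pair_names(self.feature_names)

    def points(self) -> np.ndarray:
        return np.hstack([self.main_points, self.pair_points])

    def risk(self, calib: PlattCalibration, score: Optional[np.ndarray] = None) -> np.ndarray:
        s = self.score if score is None else np.asarray(score, dtype=float)
        return calib.risk(s + self.score_offset)


def _offset(values: np.ndarray, mode: str) -> float:
    if mode == "zero":
        return 0.0
    if mode == "mean":
        return float(values.mean())
    if mode == "median":
        return float(np.median(values))
    if mode == "minimum":
        return float(values.min())
    raise ValueError(f"unknown shift mode {mode!r}; expected one of {SHIFT_MODES}")


def shift_contributions(dec: Decomposition, mode: str = "median") -> ShiftedDecomposition:
    """Shift each term's contributions by its zero / mean / median / minimum.

    Offsets are computed on the decomposition passed in (conventionally the
    training set) and should be reused for new observations via
    ``apply_shift``.
    """
    main_off = np.array([_offset(dec.main_contribs[:, j], mode) for j in range(dec.d)])
    pair_off = np.array(
        [_offset(dec.pair_contribs[:, j], mode) for j in range(dec.pair_contribs.shape[1])]
    )
    return ShiftedDecomposition(
        main_points=dec.main_contribs - main_off,
        pair_points=dec.pair_contribs - pair_off,
        shift_mode=mode,
        main_offsets=main_off,
        pair_offsets=pair_off,
        intercept_bpp=dec.intercept_bpp,
        feature_names=dec.feature_names,
    )


def apply_shift(dec: Decomposition, shifted: ShiftedDecomposition) -> ShiftedDecomposition:
    """Shift a new decomposition with offsets frozen from a training one."""
    return ShiftedDecomposition(
        main_points=dec.main_contribs - shifted.main_offsets,
        pair_points=dec.pair_contribs - shifted.pair_offsets,
        shift_mode=shifted.shift_mode,
        main_offsets=shifted.main_offsets,
        pair_offsets=shifted.pair_offsets,
        intercept_bpp=dec.intercept_bpp,
        feature_names=dec.feature_names,
    )


# ---------------------------------------------------------------------------
# effect profiles on arbitrary grids (the nomogram's raw material)
# ---------------------------------------------------------------------------


def _scaled_column(model: ExplainableSVC, p: int, raw_values: np.ndarray) -> np.ndarray:
    return (np.asarray(raw_values, dtype=float) - model.scale_center_[p]) / model.scale_spread_[p]


def _single_terms(model: ExplainableSVC, p: int, scaled: np.ndarray) -> np.ndarray:
    """(m, n_sv) matrix of g^(p)(sv_i^(p), v) for scaled values v."""
    spec, SV = model.kernel_spec_, model.support_vectors_
    if spec.family == "rbf":
        return np.expm1(-spec.gamma * (scaled[:, None] - SV[None, :, p]) ** 2)
    a = spec.scale_a if spec.family == "polynomial" else 1.0
    u = a * scaled[:, None] * SV[None, :, p]
    if spec.family == "linear":
        return u
    c, delta = spec.offset_c, spec.degree_delta
    return (u + c) ** delta - float(c) ** delta


def main_effect_values(model: ExplainableSVC, p: int, raw_values) -> np.ndarray:
    """``f^(p)`` evaluated at raw feature values (other inputs irrelevant)."""
    scaled = _scaled_column(model, p, np.asarray(raw_values, dtype=float).ravel())
    return _single_terms(model, p, scaled) @ model.dual_coef_signed_


def pair_effect_values(model: ExplainableSVC, p: int, q: int, raw_p, raw_q) -> np.ndarray:
    """``f^(p,q)`` on the grid ``raw_p × raw_q``; returns (len(raw_q), len(raw_p))."""
    spec, SV = model.kernel_spec_, model.support_vectors_
    coef = model.dual_coef_signed_
    vp = _scaled_column(model, p, np.asarray(raw_p, dtype=float).ravel())
    vq = _scaled_column(model, q, np.asarray(raw_q, dtype=float).ravel())
    if spec.family == "linear":
        return np.zeros((vq.size, vp.size))
    if spec.family == "rbf":
        up = np.expm1(-spec.gamma * (vp[:, None] - SV[None, :, p]) ** 2)  # (mp, nsv)
        uq = np.expm1(-spec.gamma * (vq[:, None] - SV[None, :, q]) ** 2)  # (mq, nsv)
        return np.einsum("js,is,s->ij", up, uq, coef)
    a, c, delta = spec.scale_a, spec.offset_c, spec.degree_delta
    const = float(c) ** delta
    up = a * vp[:, None] * SV[None, :, p]
    uq = a * vq[:, None] * SV[None, :, q]
    out = np.empty((vq.size, vp.size))
    # full (mq, mp, nsv) broadcast may be large; loop over mq rows to bound memory
    for i in range(vq.size):
        both = (up + uq[i][None, :] + c) ** delta
        only_p = (up + c) ** delta
        only_q = (uq[i][None, :] + c) ** delta
        out[i] = (both - only_p - only_q + const) @ coef
    return out
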