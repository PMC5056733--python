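"""Tabular datasets and the four artificial 3-input benchmark problems.

Each generator produces a 3-feature binary problem in which only ``x1`` and
``x2`` carry class information; ``x3`` is standard-normal noise independent of
the label.  1000 observations by default, balanced classes, split into equal
stratified train/test halves.  The four geometries:

* ``two_circles``    — classes on two concentric circles (radii 1 and 2);
  separable by radius alone.
* ``swiss_roll``     — two interleaved Archimedean spirals ``r = 0.5 + 0.4 θ``,
  ``θ ∈ [0, 3π]``, the second class rotated by π, with small isotropic jitter.
* ``checkerboard``   — ``(x1, x2)`` uniform on ``[0, 3)²``, label by parity of
  ``⌊x1⌋ + ⌊x2⌋`` (a 3×3 board).
* ``two_gaussians``  — two unit-covariance isotropic Gaussians whose means are
  1.5 apart in the ``(x1, x2)`` plane; strongly overlapping, Bayes accuracy
  ``Φ(0.75) ≈ 0.773``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["Dataset", "SynthConfig", "generate", "bayes_reference", "GENERATORS"]

GENERATORS = ("two_circles", "swiss_roll", "checkerboard", "two_gaussians")


@dataclass
class Dataset:
    """Feature matrix with ±1 labels and per-feature metadata."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    categorical_mask: Optional[np.ndarray] = None
    scaling_record: Optional[tuple[np.ndarray, np.ndarray]] = None  # (center, spread)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if len(self.labels) != n:
            raise ValueError("labels length does not match features")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1/+1")
        if self.categorical_mask is None:
            self.categorical_mask = np.zeros(d, dtype=bool)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "label") -> "Dataset":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        y_raw = df[label_column]
        X = df.drop(columns=[label_column])
        classes = np.sort(np.unique(y_raw))
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, found {len(classes)}")
        # positive class = lexicographically/numerically larger original label
        y = np.where(y_raw.to_numpy() == classes[1], 1, -1)
        cat = np.array([not np.issubdtype(t, np.floating) for t in X.dtypes])
        return cls(X.to_numpy(dtype=float), y, list(X.columns), categorical_mask=cat)

    @classmethod
    def from_csv(cls, path, label_column: str = "label", sep: str = ",") -> "Dataset":
        return cls.from_frame(pd.read_csv(path, sep=sep), label_column)


@dataclass
class SynthConfig:
    """Configuration for the artificial-problem generators."""

    name: str
    n_total: int = 1000
    seed: int = 0
    circle_radii: tuple[float, float] = (1.0, 2.0)
    circle_noise: float = 0.0
    spiral_a: float = 0.5
    spiral_b: float = 0.4
    spiral_turns: float = 3.0 * np.pi
    spiral_noise: float = 0.05
    board_size: int = 3
    gauss_distance: float = 1.5

    def __post_init__(self) -> None:
        if self.name not in GENERATORS:
            raise ValueError(f"unknown generator {self.name!r}; expected one of {GENERATORS}")
        if self.n_total % 2:
            raise ValueError("n_total must be even (balanced classes)")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["circle_radii"] = list(self.circle_radii)
        return json.dumps(d)


def _xy_two_circles(cfg: SynthConfig, rng: np.random.Generator, n_per_class: int):
    r1, r2 = cfg.circle_radii
    pts = []
    for r in (r1, r2):
        theta = rng.uniform(0.0, 2 * np.pi, n_per_class)
        rad = r + (rng.normal(0.0, cfg.circle_noise, n_per_class) if cfg.circle_noise else 0.0)
        pts.append(np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]))
    return pts[0], pts[1]


def _xy_swiss_roll(cfg: SynthConfig, rng: np.random.Generator, n_per_class: int):
    out = []
    for rot in (0.0, np.pi):
        theta = rng.uniform(0.0, cfg.spiral_turns, n_per_class)
        r = cfg.spiral_a + cfg.spiral_b * theta
        xy = np.column_stack([r * np.cos(theta + rot), r * np.sin(theta + rot)])
        xy += rng.normal(0.0, cfg.spiral_noise, xy.shape)
        out.append(xy)
    return out[0], out[1]


def _xy_checkerboard(cfg: SynthConfig, rng: np.random.Generator, n_per_class: int):
    # rejection-sample each parity class to an exact 50/50 balance
    buckets = {1: [], -1: []}
    while min(len(b) for b in buckets.values()) < n_per_class:
        xy = rng.uniform(0.0, cfg.board_size, size=(4 * n_per_class, 2))
        parity = (np.floor(xy[:, 0]) + np.floor(xy[:, 1])).astype(int) % 2
        for row, p in zip(xy, parity):
            buckets[1 if p == 0 else -1].append(row)
    return (np.array(buckets[1][:n_per_class]), np.array(buckets[-1][:n_per_class]))


def _xy_two_gaussians(cfg: SynthConfig, rng: np.random.Generator, n_per_class: int):
    offset = cfg.gauss_distance / np.sqrt(2.0)
    m1 = np.zeros(2)
    m2 = np.array([offset, offset])
    return (
        m1 + rng.normal(size=(n_per_class, 2)),
        m2 + rng.normal(size=(n_per_class, 2)),
    )


def generate(cfg: SynthConfig) -> tuple[Dataset, Dataset]:
    """Generate one artificial problem; returns stratified (train, test) halves.

    In all four problems the positive class is the first geometry listed in the
    module docstring (inner circle, un-rotated spiral, even-parity blocks, the
    Gaussian at the origin).
    """
    rng = np.random.default_rng(cfg.seed)
    n_per_class = cfg.n_total // 2
    maker = {
        "two_circles": _xy_two_circles,
        "swiss_roll": _xy_swiss_roll,
        "checkerboard": _xy_checkerboard,
        "two_gaussians": _xy_two_gaussians,
    }[cfg.name]
    xy_pos, xy_neg = maker(cfg, rng, n_per_class)
    X = np.vstack([xy_pos, xy_neg])
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)]).astype(int)
    x3 = rng.normal(size=cfg.n_total)  # irrelevant input, independent of label
    X = np.column_stack([X, x3])

    # stratified half/half split: even positions train, odd test, within class
    perm = rng.permutation(cfg.n_total)
    X, y = X[perm], y[perm]
    train_idx, test_idx = [], []
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        train_idx.append(idx[: len(idx) // 2])
        test_idx.append(idx[len(idx) // 2 :])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    names = ["x1", "x2", "x3"]
    return (
        Dataset(X[train_idx], y[train_idx], names),
        Dataset(X[test_idx], y[test_idx], names),
    )


def bayes_reference(cfg: SynthConfig) -> float:
    """Bayes-optimal accuracy of the generating distribution.

    The first three problems have disjoint class supports (1.0); for the
    overlapping Gaussians with mean distance Δ and unit isotropic covariance
    the optimal rule is the midplane, giving accuracy ``Φ(Δ/2)``.
    """
    if cfg.name == "two_gaussians":
        return float(norm.cdf(cfg.gauss_distance / 2.0))
    if cfg.name == "two_circles" and cfg.circle_noise > 0:
        # overlapping only for very large noise; treat as separable for defaults
        r1, r2 = sorted(cfg.circle_radii)
        if cfg.circle_noise * 6 > (r2 - r1):
            raise ValueError("no closed form for heavily noised circles")
    return 1.0
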