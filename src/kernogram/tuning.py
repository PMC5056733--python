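"""Hyperparameter grid search with k-fold cross-validation and two selection rules.

The default grids are exponential: ``C ∈ {10^-7, …, 10^2}`` (ten values),
``γ ∈ {2^-7, …, 2^2}`` (ten values), polynomial degree ``δ ∈ {1, 2, 3, 4}``
with scale and bias fixed at 1.  The fold partition is drawn once per search
and reused for every grid point, so rows are paired comparisons.

Two selection rules:

* :func:`select_best` — maximal mean CV accuracy (ties: smaller γ/δ, then
  smaller C).
* :func:`select_relaxed` — among grid points within a fraction (default 95%)
  of the best mean accuracy, the widest kernel (smallest γ, or smallest δ);
  ties broken toward larger C.  Wide kernels suppress high-order interaction
  terms, so the relaxed pick trades a little CV accuracy for explainability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datasets import Dataset
from .kernels import KernelSpec
from .svm import ExplainableSVC

__all__ = [
    "GridSpec",
    "CVResult",
    "make_default_grid",
    "cross_validate_grid",
    "select_best",
    "select_relaxed",
]


@dataclass
class GridSpec:
    kernel_family: str
    cost_values: list[float]
    gamma_values: list[float] = field(default_factory=list)
    degree_values: list[int] = field(default_factory=list)
    scale_a: float = 1.0
    offset_c: float = 1.0

    def points(self) -> list[dict]:
        """All grid points as parameter dicts."""
        out = []
        if self.kernel_family == "rbf":
            for g in self.gamma_values:
                for C in self.cost_values:
                    out.append({"gamma": g, "C": C})
        elif self.kernel_family == "polynomial":
            for deg in self.degree_values:
                for C in self.cost_values:
                    out.append({"degree": deg, "C": C})
        else:  # linear
            for C in self.cost_values:
                out.append({"C": C})
        return out


@dataclass
class CVResult:
    kernel_family: str
    table: pd.DataFrame  # one row per grid point; fold_* columns + mean_accuracy
    n_folds: int

    @property
    def width_column(self) -> str:
        """Column that orders kernels narrow→wide (γ for RBF, δ for polynomial)."""
        return {"rbf": "gamma", "polynomial": "degree"}.get(self.kernel_family, "C")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def make_default_grid(family: str) -> GridSpec:
    """The fixed tuning grids: ten C decades, ten γ octaves, degrees 1–4."""
    cost = [10.0**e for e in range(-7, 3)]
    if family == "rbf":
        return GridSpec(kernel_family="rbf", cost_values=cost, gamma_values=[2.0**e for e in range(-7, 3)])
    if family == "polynomial":
        return GridSpec(kernel_family="polynomial", cost_values=cost, degree_values=[1, 2, 3, 4])
    if family == "linear":
        return GridSpec(kernel_family="linear", cost_values=cost)
    raise ValueError(f"unknown kernel family {family!r}")


def cross_validate_grid(
    data: Dataset,
    grid: GridSpec,
    k: int = 10,
    seed: Optional[int] = None,
    standardize: bool = True,
) -> CVResult:
    """Stratified k-fold CV accuracy for every grid point, on a single shared
    fold partition (fixed across grid points for paired comparisons)."""
    y = data.labels
    class_min = min(np.sum(y == 1), np.sum(y == -1))
    if k > class_min:
        raise ValueError(f"k={k} exceeds minority class count {class_min}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(data.features, y))

    rows = []
    for point in grid.points():
        params = dict(
            kernel=grid.kernel_family,
            C=point["C"],
            standardize=standardize,
            calibrate=False,
        )
        if grid.kernel_family == "rbf":
            params["gamma"] = point["gamma"]
        elif grid.kernel_family == "polynomial":
            params.update(degree=point["degree"], scale_a=grid.scale_a, offset_c=grid.offset_c)
        accs = []
        for tr, te in folds:
            m = ExplainableSVC(**params).fit(data.features[tr], y[tr])
            accs.append(float(np.mean(m.predict(data.features[te]) == y[te])))
        row = dict(point)
        for j, a in enumerate(accs):
            row[f"fold_{j}"] = a
        row["mean_accuracy"] = float(np.mean(accs))
        rows.append(row)
    return CVResult(kernel_family=grid.kernel_family, table=pd.DataFrame(rows), n_folds=k)


def select_best(res: CVResult) -> dict:
    """Grid point with maximal mean CV accuracy.

    Ties broken toward the smaller kernel-width parameter (γ or δ), then the
    smaller C.
    """
    df = res.table
    if df.empty:
        raise ValueError("empty CV result")
    wcol = res.width_column
    keys = [df["mean_accuracy"], -df[wcol] if wcol in df else -df["C"], -df["C"]]
    order = np.lexsort([k.to_numpy() for k in reversed(keys)])
    best = df.iloc[order[-1]]
    return {c: best[c] for c in df.columns if not c.startswith("fold_") and c != "mean_accuracy"} | {
        "mean_accuracy": float(best["mean_accuracy"])
    }


def select_relaxed(res: CVResult, fraction: float = 0.95) -> dict:
    """Widest-kernel grid point within `fraction` of the best mean accuracy.

    Among rows with ``mean_accuracy >= fraction * max``, returns the one with
    the smallest γ (RBF) or smallest δ (polynomial); ties go to the larger C.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = res.table
    if df.empty:
        raise ValueError("empty CV result")
    cutoff = fraction * df["mean_accuracy"].max()
    ok = df[df["mean_accuracy"] >= cutoff]
    wcol = res.width_column
    if wcol in ok.columns:
        ok = ok.sort_values([wcol, "C"], ascending=[True, False], kind="mergesort")
    else:
        ok = ok.sort_values("C", ascending=False, kind="mergesort")
    pick = ok.iloc[0]
    return {c: pick[c] for c in df.columns if not c.startswith("fold_") and c != "mean_accuracy"} | {
        "mean_accuracy": float(pick["mean_accuracy"])
    }


def spec_from_selection(res: CVResult, selection: dict, scale_a: float = 1.0, offset_c: float = 1.0) -> tuple[KernelSpec, float]:
    """Turn a selected grid point into (KernelSpec, C)."""
    fam = res.kernel_family
    if fam == "rbf":
        spec = KernelSpec("rbf", gamma=float(selection["gamma"]))
    elif fam == "polynomial":
        spec = KernelSpec("polynomial", scale_a=scale_a, offset_c=offset_c, degree_delta=int(selection["degree"]))
    else:
        spec = KernelSpec("linear")
    return spec, float(selection["C"])
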