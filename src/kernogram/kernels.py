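"""Kernel evaluation and exact additive expansion of single kernel evaluations.

A kernel evaluation ``K(x_i, x)`` is split into a constant, ``d`` main-effect
terms ``g^(p)`` (each depending on one input coordinate), ``d(d-1)/2``
pair-effect terms ``g^(p,q)`` (unordered pairs ``p < q``) and a rest term that
aggregates every monomial involving three or more inputs.  The split is exact:
the four parts always sum back to the kernel value.

Closed forms (derived from the multinomial/Taylor expansions, verified against
the brute-force :func:`expansion_oracle`):

* linear:      ``K = sum_p x_i^(p) x^(p)`` — purely main effects.
* polynomial:  with ``u_p = a x_i^(p) x^(p)``,
  ``const = c^δ``, ``g^(p) = (u_p+c)^δ - c^δ``,
  ``g^(p,q) = (u_p+u_q+c)^δ - (u_p+c)^δ - (u_q+c)^δ + c^δ`` (inclusion–exclusion).
* rbf:         with ``u_p = exp(-γ (x_i^(p)-x^(p))^2) - 1``,
  ``const = 1``, ``g^(p) = u_p``, ``g^(p,q) = u_p u_q`` and
  ``K = prod_p (1+u_p)``, so the rest collects all subset products of size ≥ 3.

The rest term is *defined* as the residual ``K - (const + Σ main + Σ pairs)``,
making the conservation identity exact by construction; the independent
correctness check is term-wise agreement with the enumeration oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "TermSet",
    "kernel_eval",
    "expand_terms",
    "expansion_oracle",
    "pair_index",
    "pair_names",
]

_FAMILIES = ("linear", "polynomial", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus parameters; the single source of truth for expansions.

    Parameters
    ----------
    family : {"linear", "polynomial", "rbf"}
    gamma : float
        RBF inverse squared width, ``γ = 1/σ²``.  Ignored by the other families.
    scale_a : float
        Polynomial scale ``a`` in ``(a x·z + c)^δ``.
    offset_c : float
        Polynomial bias ``c``.
    degree_delta : int
        Polynomial degree ``δ ≥ 1``.
    """

    family: str
    gamma: float = 1.0
    scale_a: float = 1.0
    offset_c: float = 1.0
    degree_delta: int = 3

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "rbf" and not self.gamma > 0:
            raise ValueError("rbf kernel requires gamma > 0")
        if self.family == "polynomial":
            if int(self.degree_delta) != self.degree_delta or self.degree_delta < 1:
                raise ValueError("polynomial kernel requires integer degree_delta >= 1")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "KernelSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class TermSet:
    """Additive split of a single kernel evaluation.

    ``const + main.sum() + pairs.sum() + rest`` equals the kernel value.
    ``pairs`` is indexed by unordered pairs ``(p, q)``, ``p < q``, in
    :func:`pair_index` order.
    """

    const: float
    main: np.ndarray
    pairs: np.ndarray
    rest: float

    @property
    def total(self) -> float:
        return float(self.const + self.main.sum() + self.pairs.sum() + self.rest)


def pair_index(d: int) -> list[tuple[int, int]]:
    """Unordered pairs ``(p, q)`` with ``p < q`` in lexicographic order."""
    return list(combinations(range(d), 2))


def pair_names(feature_names: Sequence[str]) -> list[str]:
    return [f"{feature_names[p]}*{feature_names[q]}" for p, q in pair_index(len(feature_names))]


def _check_inputs(x: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if x.size < 1:
        raise ValueError("inputs must have dimension >= 1")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite input")
    return x, z


def kernel_eval(spec: KernelSpec, x, z) -> float:
    """Evaluate ``K(x, z)`` for the given kernel specification."""
    x, z = _check_inputs(x, z)
    if spec.family == "linear":
        return float(x @ z)
    if spec.family == "polynomial":
        return float((spec.scale_a * (x @ z) + spec.offset_c) ** spec.degree_delta)
    # rbf
    return float(np.exp(-spec.gamma * np.sum((x - z) ** 2)))


def expand_terms(spec: KernelSpec, x_i, x) -> TermSet:
    """Closed-form additive split of one kernel evaluation ``K(x_i, x)``.

    Returns a :class:`TermSet` whose parts sum exactly to the kernel value;
    the rest term is zero for linear kernels, polynomial kernels of degree
    ≤ 2, and problems with ``d ≤ 2`` inputs.
    """
    x_i, x = _check_inputs(x_i, x)
    d = x.size
    K = kernel_eval(spec, x_i, x)

    if spec.family == "linear":
        main = x_i * x
        pairs = np.zeros(d * (d - 1) // 2)
        return TermSet(const=0.0, main=main, pairs=pairs, rest=0.0)

    if spec.family == "polynomial":
        a, c, delta = spec.scale_a, spec.offset_c, spec.degree_delta
        u = a * x_i * x
        const = float(c) ** delta  # 0**0 == 1.0 by Python convention
        main = (u + c) ** delta - const
        pairs = np.array(
            [
                (u[p] + u[q] + c) ** delta
                - (u[p] + c) ** delta
                - (u[q] + c) ** delta
                + const
                for p, q in pair_index(d)
            ]
        )
    else:  # rbf
        # expm1 avoids cancellation for large gamma*distance where u -> -1
        u = np.expm1(-spec.gamma * (x_i - x) ** 2)
        const = 1.0
        main = u
        pairs = np.array([u[p] * u[q] for p, q in pair_index(d)])

    rest = K - (const + main.sum() + pairs.sum())
    if d <= 2 or (spec.family == "polynomial" and spec.degree_delta <= 2):
        rest = 0.0  # analytically exact; suppress rounding residue
    return TermSet(const=const, main=main, pairs=pairs, rest=float(rest))


# ---------------------------------------------------------------------------
# brute-force enumeration oracle (reference implementation, used in tests)
# ---------------------------------------------------------------------------

_MAX_ORACLE_DIM = 12


def _compositions(total: int, parts: int):
    """All tuples of `parts` nonnegative integers summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for tail in _compositions(total - first, parts - 1):
            yield (first,) + tail


def expansion_oracle(spec: KernelSpec, x_i, x, max_order: int | None = None) -> TermSet:
    """Brute-force additive split by explicit monomial enumeration.

    For the RBF kernel the split enumerates all ``2^d`` subset products of
    ``u_p = exp(-γ δ_p²) - 1`` (exact); if ``max_order`` is given, the grouped
    quantities are instead computed from the Taylor/multinomial series of the
    exponential truncated at order ``max_order`` (useful to demonstrate
    convergence).  For the polynomial kernel, all multinomial exponent tuples
    ``(k_1..k_d, k_c)`` with ``Σ = δ`` are enumerated and grouped by the number
    of inputs with nonzero exponent.  Guarded to ``d ≤ 12``.
    """
    x_i, x = _check_inputs(x_i, x)
    d = x.size
    if d > _MAX_ORACLE_DIM:
        raise ValueError(f"oracle limited to d <= {_MAX_ORACLE_DIM}, got {d}")
    pidx = pair_index(d)
    pair_pos = {pq: k for k, pq in enumerate(pidx)}
    main = np.zeros(d)
    pairs = np.zeros(len(pidx))
    const = 0.0
    rest = 0.0

    if spec.family == "linear":
        return TermSet(const=0.0, main=x_i * x, pairs=pairs, rest=0.0)

    if spec.family == "polynomial":
        a, c, delta = spec.scale_a, spec.offset_c, spec.degree_delta
        u = a * x_i * x
        for ks in _compositions(delta, d + 1):  # last slot is the constant's exponent
            k_in, k_c = ks[:-1], ks[-1]
            coef = math.factorial(delta)
            for k in ks:
                coef //= math.factorial(k)
            term = float(coef) * (float(c) ** k_c if k_c else 1.0)
            for p, k in enumerate(k_in):
                if k:
                    term *= u[p] ** k
            support = tuple(p for p, k in enumerate(k_in) if k)
            if len(support) == 0:
                const += term
            elif len(support) == 1:
                main[support[0]] += term
            elif len(support) == 2:
                pairs[pair_pos[support]] += term
            else:
                rest += term
        return TermSet(const=const, main=main, pairs=pairs, rest=rest)

    # rbf
    sq = (x_i - x) ** 2
    if max_order is None:
        u = np.expm1(-spec.gamma * sq)
        const = 1.0
        for size in range(1, d + 1):
            for subset in combinations(range(d), size):
                term = float(np.prod(u[list(subset)]))
                if size == 1:
                    main[subset[0]] += term
                elif size == 2:
                    pairs[pair_pos[subset]] += term
                else:
                    rest += term
        return TermSet(const=const, main=main, pairs=pairs, rest=rest)

    # truncated Taylor series of exp(-gamma * sum sq) grouped by support size
    for n in range(max_order + 1):
        outer = (-spec.gamma) ** n / math.factorial(n)
        for ks in _compositions(n, d):
            coef = math.factorial(n)
            for k in ks:
                coef //= math.factorial(k)
            term = outer * coef * float(np.prod([sq[p] ** k for p, k in enumerate(ks) if k] or [1.0]))
            support = tuple(p for p, k in enumerate(ks) if k)
            if len(support) == 0:
                const += term
            elif len(support) == 1:
                main[support[0]] += term
            elif len(support) == 2:
                pairs[pair_pos[support]] += term
            else:
                rest += term
    return TermSet(const=const, main=main, pairs=pairs, rest=rest)
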