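"""Validity diagnostics for the truncated additive approximation.

Dropping the rest term is only legitimate when it is small: these diagnostics
quantify (i) how often the full SVM and the rest-term-free approximation agree
on the class label, (ii) the range of every contribution relative to the
latent variable (the boxplot view), and (iii) the Pearson correlation
structure between the rest term and the retained terms — a large |r| means the
rest term duplicates (or cancels) a visualized effect and the picture is
misleading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .decomposition import Decomposition, approximate_latent

__all__ = [
    "RangeSummary",
    "DiagnosticsReport",
    "label_agreement",
    "contribution_ranges",
    "correlation_analysis",
    "build_report",
]

# default verdict rule: rest range small relative to the latent's range AND
# the approximation reproduces nearly all training labels
DEFAULT_REST_RATIO = 0.10
DEFAULT_AGREEMENT = 0.95


@dataclass
class RangeSummary:
    """Five-number summaries per term, plus ``rest`` and ``lpmodel`` rows
    (``lpmodel`` = the full SVM latent variable, the reference range)."""

    table: pd.DataFrame  # index: term names; columns: min, q1, median, q3, max

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_dict(self) -> dict:
        return self.table.to_dict(orient="index")


@dataclass
class DiagnosticsReport:
    agreement_train: float
    agreement_test: Optional[float]
    range_summary: RangeSummary
    rest_correlations: dict  # term -> r or None (zero-variance flagged undefined)
    term_correlation_matrix: pd.DataFrame
    verdict: str  # "explainable" | "not_explainable"
    rest_ratio: float
    rest_ratio_threshold: float
    agreement_threshold: float

    def to_dict(self) -> dict:
        return {
            "agreement_train": self.agreement_train,
            "agreement_test": self.agreement_test,
            "range_summary": self.range_summary.to_dict(),
            "rest_correlations": self.rest_correlations,
            "term_correlation_matrix": self.term_correlation_matrix.to_dict(),
            "verdict": self.verdict,
            "rest_ratio": self.rest_ratio,
            "rest_ratio_threshold": self.rest_ratio_threshold,
            "agreement_threshold": self.agreement_threshold,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DiagnosticsReport":
        d = json.loads(s)
        return cls(
            agreement_train=d["agreement_train"],
            agreement_test=d["agreement_test"],
            range_summary=RangeSummary(pd.DataFrame.from_dict(d["range_summary"], orient="index")),
            rest_correlations=d["rest_correlations"],
            term_correlation_matrix=pd.DataFrame.from_dict(d["term_correlation_matrix"]),
            verdict=d["verdict"],
            rest_ratio=d["rest_ratio"],
            rest_ratio_threshold=d["rest_ratio_threshold"],
            agreement_threshold=d["agreement_threshold"],
        )

    def summary_text(self) -> str:
        lines = [
            f"verdict: {self.verdict}",
            f"label agreement (train): {self.agreement_train:.3f}",
        ]
        if self.agreement_test is not None:
            lines.append(f"label agreement (test):  {self.agreement_test:.3f}")
        lines.append(
            f"rest/latent range ratio: {self.rest_ratio:.3f}"
            f" (threshold {self.rest_ratio_threshold})"
        )
        defined = {k: v for k, v in self.rest_correlations.items() if v is not None}
        if defined:
            worst = max(defined, key=lambda k: abs(defined[k]))
            lines.append(f"strongest rest correlation: r(rest, {worst}) = {defined[worst]:.3f}")
        return "\n".join(lines)


def _sign(v: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(v) >= 0, 1, -1)  # sign(0) = +1


def label_agreement(latent_full, latent_approx) -> float:
    """Fraction of observations whose label is unchanged by dropping the rest term."""
    a = np.asarray(latent_full, dtype=float)
    b = np.asarray(latent_approx, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.mean(_sign(a) == _sign(b)))


def contribution_ranges(dec: Decomposition) -> RangeSummary:
    """Five-number summary of every contribution, the rest term, and the full
    latent variable (row ``lpmodel``)."""
    cols = {name: dec.contributions()[:, j] for j, name in enumerate(dec.term_names)}
    cols["rest"] = dec.rest
    cols["lpmodel"] = dec.latent_full
    rows = {
        name: {
            "min": float(np.min(v)),
            "q1": float(np.percentile(v, 25)),
            "median": float(np.median(v)),
            "q3": float(np.percentile(v, 75)),
            "max": float(np.max(v)),
        }
        for name, v in cols.items()
    }
    return RangeSummary(pd.DataFrame.from_dict(rows, orient="index"))


def _pearson(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    if np.std(a) == 0 or np.std(b) == 0:
        return None  # flagged undefined rather than NaN-propagated
    return float(np.corrcoef(a, b)[0, 1])


def correlation_analysis(dec: Decomposition) -> tuple[dict, pd.DataFrame]:
    """Pearson correlations of the rest term with each contribution, and the
    full contribution-by-contribution correlation matrix."""
    if dec.n < 3:
        raise ValueError("need at least 3 observations for correlations")
    C = dec.contributions()
    names = dec.term_names
    rest_corr = {name: _pearson(dec.rest, C[:, j]) for j, name in enumerate(names)}
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i in range(len(names)):
        for j in range(i, len(names)):
            r = _pearson(C[:, i], C[:, j])
            mat.iat[i, j] = mat.iat[j, i] = np.nan if r is None else r
    return rest_corr, mat


def build_report(
    dec_train: Decomposition,
    dec_test: Optional[Decomposition] = None,
    rest_ratio_threshold: float = DEFAULT_REST_RATIO,
    agreement_threshold: float = DEFAULT_AGREEMENT,
) -> DiagnosticsReport:
    """Assemble the full diagnostics report and the explainability verdict.

    Verdict rule (configurable): *explainable* iff the training-set rest-term
    range is at most ``rest_ratio_threshold`` times the latent variable's range
    and the training label agreement is at least ``agreement_threshold``.
    """
    agree_train = label_agreement(dec_train.latent_full, approximate_latent(dec_train))
    agree_test = (
        label_agreement(dec_test.latent_full, approximate_latent(dec_test))
        if dec_test is not None
        else None
    )
    ranges = contribution_ranges(dec_train)
    rest_corr, mat = correlation_analysis(dec_train)
    latent_range = float(np.ptp(dec_train.latent_full))
    rest_range = float(np.ptp(dec_train.rest))
    rest_ratio = rest_range / latent_range if latent_range > 0 else (0.0 if rest_range == 0 else np.inf)
    verdict = (
        "explainable"
        if (rest_ratio <= rest_ratio_threshold and agree_train >= agreement_threshold)
        else "not_explainable"
    )
    return DiagnosticsReport(
        agreement_train=agree_train,
        agreement_test=agree_test,
        range_summary=ranges,
        rest_correlations=rest_corr,
        term_correlation_matrix=mat,
        verdict=verdict,
        rest_ratio=float(rest_ratio),
        rest_ratio_threshold=rest_ratio_threshold,
        agreement_threshold=agreement_threshold,
    )
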