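"""Color-based nomogram and validity plots.

A classical nomogram assigns each input a number of points read off an axis;
here the points are encoded as *color*: one horizontal color bar per main
effect, one 2-D color panel per two-way interaction, all sharing a single
color legend, plus a score→risk bar showing the calibrated sigmoid.  Reading
an observation is: look up the color at each of its input values, convert each
color to points via the legend, add the points, and convert the total score to
a risk with the bottom bar.

The layout object keeps the numeric lattices behind every panel, so a
rendered nomogram can be *read back* programmatically (nearest lattice cell),
which is how the round-trip tests verify that the picture equals the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless, deterministic

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, TwoSlopeNorm

from .decomposition import (
    Decomposition,
    ShiftedDecomposition,
    main_effect_values,
    pair_effect_values,
)
from .diagnostics import contribution_ranges
from .kernels import pair_index
from .svm import ExplainableSVC, PlattCalibration

__all__ = [
    "ColorMapSpec",
    "NomogramLayout",
    "build_color_scale",
    "build_nomogram_layout",
    "render_nomogram",
    "render_validity_plots",
    "render_cumulative_chart",
]

_PALETTES = {
    "diverging": "RdBu_r",  # blue = negative, white = anchor, red = positive
    "sequential": "Blues",
    "rainbow": "rainbow",
    "grayscale": "gray",
    "viridis": "viridis",
}
_LUT_SIZE = 512


@dataclass
class ColorMapSpec:
    """Invertible value→color mapping shared by all nomogram panels."""

    palette: str
    value_range: tuple[float, float]
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.palette not in _PALETTES:
            raise ValueError(f"unknown palette {self.palette!r}; expected one of {tuple(_PALETTES)}")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError("degenerate value range")
        self._cmap = colormaps[_PALETTES[self.palette]]
        if self.palette == "diverging":
            # symmetric about the anchor so the anchor maps to the map's center (white)
            half = max(hi - self.anchor, self.anchor - lo)
            self._norm = Normalize(vmin=self.anchor - half, vmax=self.anchor + half)
        else:
            self._norm = Normalize(vmin=lo, vmax=hi)
        lut_vals = np.linspace(lo, hi, _LUT_SIZE)
        self._lut_values = lut_vals
        self._lut_colors = self._cmap(self._norm(lut_vals))[:, :3]

    def encode(self, values) -> np.ndarray:
        """Values → RGBA array."""
        return self._cmap(self._norm(np.asarray(values, dtype=float)))

    def decode(self, colors) -> np.ndarray:
        """RGB(A) colors → nearest representable values (inverse of encode)."""
        rgb = np.atleast_2d(np.asarray(colors, dtype=float))[:, :3]
        d2 = ((rgb[:, None, :] - self._lut_colors[None, :, :]) ** 2).sum(axis=2)
        return self._lut_values[np.argmin(d2, axis=1)]

    def mpl(self):
        return self._cmap, self._norm


def build_color_scale(shifted: ShiftedDecomposition, palette: str = "diverging") -> ColorMapSpec:
    """Shared color scale spanning every displayed point value (training set)."""
    pts = shifted.points()
    if pts.size == 0:
        raise ValueError("empty contributions")
    lo, hi = float(pts.min()), float(pts.max())
    if hi - lo < 1e-12:  # degenerate all-equal contributions: fall back to unit range
        lo, hi = lo - 0.5, hi + 0.5
    return ColorMapSpec(palette=palette, value_range=(lo, hi), anchor=0.0)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


@dataclass
class MainPanel:
    feature: str
    index: int
    grid: np.ndarray  # raw feature values, length R
    points: np.ndarray  # shifted contribution at each grid value
    categorical: bool = False
    percentile_ticks: Optional[tuple[float, float]] = None


@dataclass
class PairPanel:
    features: tuple[str, str]
    indices: tuple[int, int]
    grid_p: np.ndarray
    grid_q: np.ndarray
    points: np.ndarray  # (len(grid_q), len(grid_p))


@dataclass
class NomogramLayout:
    mains: list[MainPanel]
    pairs: list[PairPanel]
    colormap: ColorMapSpec
    score_grid: np.ndarray
    risk_grid: np.ndarray
    score_offset: float  # score + offset = approximate latent
    calib: PlattCalibration
    verdict: Optional[str] = None
    observation: Optional[np.ndarray] = None

    def read_observation(self, x_raw) -> tuple[float, float]:
        """Read (score, risk) for one raw observation off the rendered lattices,
        using nearest-cell lookup — the programmatic analogue of reading the
        chart by eye."""
        x = np.asarray(x_raw, dtype=float).ravel()
        score = 0.0
        for panel in self.mains:
            j = int(np.argmin(np.abs(panel.grid - x[panel.index])))
            score += float(panel.points[j])
        for panel in self.pairs:
            jp = int(np.argmin(np.abs(panel.grid_p - x[panel.indices[0]])))
            jq = int(np.argmin(np.abs(panel.grid_q - x[panel.indices[1]])))
            score += float(panel.points[jq, jp])
        risk = float(self.calib.risk(np.array([score + self.score_offset]))[0])
        return score, risk


def build_nomogram_layout(
    model: ExplainableSVC,
    shifted: ShiftedDecomposition,
    calib: PlattCalibration,
    X_train: np.ndarray,
    palette: str = "diverging",
    grid_resolution: int = 101,
    clip_quantiles: Optional[tuple[float, float]] = None,
    percentiles: bool = False,
    observation: Optional[Sequence[float]] = None,
    verdict: Optional[str] = None,
) -> NomogramLayout:
    """Evaluate every effect on display lattices and assemble the layout.

    Continuous inputs get `grid_resolution` evenly spaced cells over their
    (optionally quantile-clipped) training range; integer-coded categorical
    inputs get one cell per category.
    """
    X_train = np.asarray(X_train, dtype=float)
    d = X_train.shape[1]
    names = shifted.feature_names
    cat_mask = getattr(model, "categorical_mask_", None)
    cat_mask = np.zeros(d, dtype=bool) if cat_mask is None else np.asarray(cat_mask)

    grids = []
    for p in range(d):
        col = X_train[:, p]
        if cat_mask[p]:
            grids.append(np.unique(col))
        else:
            if clip_quantiles is not None:
                lo, hi = np.quantile(col, clip_quantiles)
            else:
                lo, hi = col.min(), col.max()
            grids.append(np.linspace(lo, hi, grid_resolution))

    mains = []
    for p in range(d):
        pts = main_effect_values(model, p, grids[p]) - shifted.main_offsets[p]
        ticks = None
        if percentiles and not cat_mask[p]:
            ticks = tuple(np.percentile(X_train[:, p], [5, 95]))
        mains.append(
            MainPanel(
                feature=names[p],
                index=p,
                grid=grids[p],
                points=pts,
                categorical=bool(cat_mask[p]),
                percentile_ticks=ticks,
            )
        )

    pairs = []
    for k, (p, q) in enumerate(pair_index(d)):
        pts = pair_effect_values(model, p, q, grids[p], grids[q]) - shifted.pair_offsets[k]
        pairs.append(
            PairPanel(
                features=(names[p], names[q]),
                indices=(p, q),
                grid_p=grids[p],
                grid_q=grids[q],
                points=pts,
            )
        )

    cmap = build_color_scale(shifted, palette)
    scores = shifted.score
    smin, smax = float(scores.min()), float(scores.max())
    if smax - smin < 1e-12:
        smin, smax = smin - 0.5, smax + 0.5
    score_grid = np.linspace(smin, smax, 256)
    risk_grid = calib.risk(score_grid + shifted.score_offset)
    return NomogramLayout(
        mains=mains,
        pairs=pairs,
        colormap=cmap,
        score_grid=score_grid,
        risk_grid=risk_grid,
        score_offset=shifted.score_offset,
        calib=calib,
        verdict=verdict,
        observation=None if observation is None else np.asarray(observation, dtype=float),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _edges(grid: np.ndarray) -> np.ndarray:
    """Cell edges for pcolormesh from cell-center coordinates."""
    g = np.asarray(grid, dtype=float)
    if g.size == 1:
        return np.array([g[0] - 0.5, g[0] + 0.5])
    mids = (g[:-1] + g[1:]) / 2
    return np.concatenate([[2 * g[0] - mids[0]], mids, [2 * g[-1] - mids[-1]]])


def render_nomogram(layout: NomogramLayout, path=None) -> plt.Figure:
    """Draw the color nomogram; returns the figure (optionally saved to path)."""
    n_main, n_pair = len(layout.mains), len(layout.pairs)
    n_rows = n_main + n_pair + 1
    cmap, norm = layout.colormap.mpl()
    heights = [0.6] * n_main + [2.4] * n_pair + [0.6]
    fig, axes = plt.subplots(
        n_rows,
        1,
        figsize=(7.5, 1.0 * n_main + 2.6 * n_pair + 1.4),
        gridspec_kw={"height_ratios": heights},
        constrained_layout=True,
    )
    axes = np.atleast_1d(axes)
    if layout.verdict:
        fig.suptitle(f"approximation verdict: {layout.verdict}", fontsize=9)

    for ax, panel in zip(axes[:n_main], layout.mains):
        if panel.categorical:
            edges = np.arange(len(panel.grid) + 1) - 0.5
            ax.pcolormesh(edges, [0, 1], panel.points[None, :], cmap=cmap, norm=norm)
            ax.set_xticks(np.arange(len(panel.grid)))
            ax.set_xticklabels([f"{g:g}" for g in panel.grid], fontsize=7)
        else:
            ax.pcolormesh(_edges(panel.grid), [0, 1], panel.points[None, :], cmap=cmap, norm=norm)
        if panel.percentile_ticks is not None:
            for t in panel.percentile_ticks:
                ax.axvline(t, color="k", lw=0.8, ls=":")
        if layout.observation is not None:
            ax.axvline(layout.observation[panel.index], color="k", lw=1.4)
        ax.set_yticks([])
        ax.set_ylabel(panel.feature, rotation=0, ha="right", va="center", fontsize=9)

    for ax, panel in zip(axes[n_main : n_main + n_pair], layout.pairs):
        ax.pcolormesh(_edges(panel.grid_p), _edges(panel.grid_q), panel.points, cmap=cmap, norm=norm)
        if layout.observation is not None:
            ax.plot(
                layout.observation[panel.indices[0]],
                layout.observation[panel.indices[1]],
                "ko",
                ms=5,
            )
        ax.set_ylabel(
            f"{panel.features[0]} × {panel.features[1]}",
            rotation=0,
            ha="right",
            va="center",
            fontsize=9,
        )
        ax.tick_params(labelsize=7)

    # score -> risk bar
    ax = axes[-1]
    ax.pcolormesh(
        _edges(layout.score_grid),
        [0, 1],
        layout.risk_grid[None, :],
        cmap="RdBu_r",
        norm=Normalize(0.0, 1.0),
    )
    ax.set_yticks([])
    ax.set_ylabel("score → risk", rotation=0, ha="right", va="center", fontsize=9)
    ax.tick_params(labelsize=7)

    fig.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap=cmap),
        ax=axes[: n_main + n_pair].tolist(),
        label="points",
        fraction=0.05,
    )
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def render_validity_plots(dec: Decomposition, path_scatter=None, path_ranges=None):
    """The two diagnostic plots: (ℓ, ℓ̃) scatter with the identity line, and
    the contribution-range boxplots with the full latent (`lpmodel`) on top."""
    if dec.n < 2:
        raise ValueError("need at least 2 observations")
    approx = dec.latent_full - dec.rest

    fig1, ax = plt.subplots(figsize=(4.5, 4.5), constrained_layout=True)
    lims = [
        min(dec.latent_full.min(), approx.min()),
        max(dec.latent_full.max(), approx.max()),
    ]
    ax.plot(lims, lims, "k-", lw=1)
    ax.plot(dec.latent_full, approx, "o", ms=3, alpha=0.6)
    ax.set_xlabel("latent variable (SVM)")
    ax.set_ylabel("approximated latent variable")
    if path_scatter is not None:
        fig1.savefig(path_scatter, dpi=150)

    summary = contribution_ranges(dec)
    order = [n for n in summary.table.index if n != "lpmodel"] + ["lpmodel"]
    data = []
    C = dec.contributions()
    name_to_col = {n: C[:, j] for j, n in enumerate(dec.term_names)}
    name_to_col["rest"] = dec.rest
    name_to_col["lpmodel"] = dec.latent_full
    for n in order:
        data.append(name_to_col[n])
    fig2, ax = plt.subplots(figsize=(5.5, 0.4 * len(order) + 1.2), constrained_layout=True)
    ax.boxplot(data, orientation="horizontal", tick_labels=order, whis=(0, 100))
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("contribution to the latent variable")
    if path_ranges is not None:
        fig2.savefig(path_ranges, dpi=150)
    return fig1, fig2


def render_cumulative_chart(
    shifted: ShiftedDecomposition,
    row_index: int,
    calib: PlattCalibration,
    path=None,
) -> plt.Figure:
    """Per-observation cumulative contribution chart: one bar per term plus a
    running-total line, annotated with the final score and calibrated risk."""
    pts = shifted.points()
    if not 0 <= row_index < pts.shape[0]:
        raise IndexError(f"row {row_index} out of range")
    row = pts[row_index]
    names = shifted.term_names
    cum = np.cumsum(row)
    score = float(row.sum())
    risk = float(shifted.risk(calib, np.array([score]))[0])

    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * len(row), 3.5), constrained_layout=True)
    xs = np.arange(len(row))
    ax.bar(xs, row, color=np.where(row >= 0, "firebrick", "steelblue"))
    ax.plot(xs, cum, "ko-", ms=4, lw=1)
    ax.axhline(0, color="k", lw=0.6)
    ax.set_xticks(xs)
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("points")
    ax.set_title(f"score = {score:.2f}, risk = {risk:.3f}", fontsize=9)
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
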