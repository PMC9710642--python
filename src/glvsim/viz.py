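"""Stacked-bar timecourse plots and PCA trajectory projections.

Stacked bars are the standard view of compositional timecourses: one bar per
recorded time point, segments proportional to relative abundance within the
chosen node.  For many individuals at once, trajectories are projected onto
the top two principal components of the pooled samples, which makes
convergence to (and divergence between) attractors visible at a glance.
All plotting is headless-safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .dynamics import to_relative
from .exceptions import ConfigurationError, DomainError
from .types import Timecourse

__all__ = ["ProjectedTrajectories", "project_trajectories", "plot_stacked_bars", "plot_pca_trajectories"]


@dataclass
class ProjectedTrajectories:
    """Per-individual 2-D trajectories in a common principal-component plane."""

    coords: list[np.ndarray]  # each |T| x 2
    explained_variance: np.ndarray  # length 2, ratios of total variance
    labels: list[str]


def project_trajectories(
    timecourses: list[Timecourse],
    source: str = "X",
    node: str | None = None,
) -> ProjectedTrajectories:
    """Project all trajectories onto the top two pooled principal components.

    Rows from every individual are pooled, centered, and decomposed once, so
    all trajectories live in the same plane.  ``source`` selects relative
    ("X", the observable scale, default) or absolute ("Z") abundances;
    ``node`` restricts to one node's columns.  The axis sign is fixed by
    making each component's largest-magnitude loading positive, so the
    projection is fully deterministic.
    """
    if source not in ("X", "Z"):
        raise ConfigurationError("source must be 'X' or 'Z'")
    if not timecourses:
        raise DomainError("need at least one timecourse")
    cols = timecourses[0].node_slice(node) if node is not None else slice(None)
    mats = [getattr(tc, source)[:, cols] for tc in timecourses]
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise DomainError("all timecourses must share D and the number of time points")
    if mats[0].shape[1] < 2:
        raise DomainError("need at least 2 dimensions to project onto 2 components")

    pooled = np.vstack(mats)
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(pooled)
    components = pca.components_.copy()
    for i in range(2):
        if components[i, np.argmax(np.abs(components[i]))] < 0:
            components[i] = -components[i]
    center = pooled.mean(axis=0)
    coords = [(m - center) @ components.T for m in mats]
    return ProjectedTrajectories(
        coords=coords,
        explained_variance=pca.explained_variance_ratio_.copy(),
        labels=[tc.label for tc in timecourses],
    )


def _get_axes(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt, plt.subplots(figsize=figsize)


def plot_stacked_bars(timecourse: Timecourse, node: str, output_path) -> Path:
    """Render one node's relative abundances as stacked bars, one per time point.

    Abundances are renormalized within the node, so single-node views of a
    multi-node simulation still stack to height 1.  Writes PNG or SVG by
    file extension; returns the output path.
    """
    sl = timecourse.node_slice(node)
    Xn = to_relative(timecourse.X[:, sl])
    T, d = Xn.shape
    plt, (fig, ax) = _get_axes((max(6, T * 0.25), 4))
    positions = np.arange(T)
    bottom = np.zeros(T)
    cmap = plt.get_cmap("tab20")
    for j in range(d):
        ax.bar(positions, Xn[:, j], bottom=bottom, width=0.9,
               color=cmap(j % 20), label=f"{node}_{j}")
        bottom += Xn[:, j]
    ax.set_xlabel("time point")
    ax.set_ylabel("relative abundance")
    ax.set_title(f"node {node}")
    ax.set_ylim(0, 1)
    if d <= 20:
        ax.legend(fontsize=6, ncol=2, loc="center left", bbox_to_anchor=(1.0, 0.5))
    output_path = Path(output_path)
    fig.savefig(output_path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return output_path


def plot_pca_trajectories(projected: ProjectedTrajectories, output_path) -> Path:
    """Draw each projected trajectory as a polyline, colored by arm label."""
    if not projected.coords:
        raise DomainError("nothing to plot: empty projection")
    plt, (fig, ax) = _get_axes((6, 5))
    palette = plt.get_cmap("tab10")
    label_colors: dict[str, int] = {}
    seen: set[str] = set()
    for coords, label in zip(projected.coords, projected.labels):
        idx = label_colors.setdefault(label, len(label_colors))
        ax.plot(
            coords[:, 0], coords[:, 1], "-", lw=1, alpha=0.8,
            color=palette(idx % 10),
            label=label if label and label not in seen else None,
        )
        ax.plot(coords[-1, 0], coords[-1, 1], "o", ms=3, color=palette(idx % 10))
        seen.add(label)
    ev = projected.explained_variance
    ax.set_xlabel(f"PC1 ({ev[0]:.1%})")
    ax.set_ylabel(f"PC2 ({ev[1]:.1%})")
    if seen - {""}:
        ax.legend()
    output_path = Path(output_path)
    fig.savefig(output_path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return output_path
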