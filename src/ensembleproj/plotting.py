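"""Two-panel scatter figure (PCA vs random projection) with confidence ellipses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .projection import ProjectionResult
from .validation import ClusterReport, confidence_ellipse

__all__ = ["plot_projections"]

_LEVEL_GRAYS = {0.95: "0.35", 0.99: "0.7"}


def _panel(ax, scores, labels, title, ellipse_levels):
    labels = np.asarray(labels)
    clusters = sorted(set(labels) - {-1})
    cmap = plt.get_cmap("tab10")
    for cluster in clusters:
        pts = scores[labels == cluster]
        color = cmap(cluster % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=28, color=color, edgecolor="k",
                   linewidth=0.4, label=f"cluster {cluster}")
        if len(pts) >= 3:
            for level in ellipse_levels:
                try:
                    spec = confidence_ellipse(pts, level)
                except ValueError:
                    continue
                ax.add_patch(
                    Ellipse(
                        spec.center,
                        2 * spec.semi_axes[0],
                        2 * spec.semi_axes[1],
                        angle=np.degrees(spec.angle),
                        fill=False,
                        color=_LEVEL_GRAYS.get(level, color),
                        linewidth=1.0,
                    )
                )
    outliers = scores[labels == -1]
    if len(outliers):
        ax.scatter(outliers[:, 0], outliers[:, 1], s=28, color="0.6",
                   edgecolor="k", linewidth=0.4, label="outlier")
    ax.set_title(title)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    if clusters or len(outliers):
        ax.legend(frameon=False, fontsize=8)


def plot_projections(
    pca: ProjectionResult,
    random_proj: ProjectionResult,
    report: ClusterReport,
    path,
    ellipse_levels=(0.95, 0.99),
) -> None:
    """Save the side-by-side embedding figure (PNG or SVG by extension)."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    _panel(axes[0], pca.scores, report.assignment_pca.labels,
           "PCA (truncated SVD)", ellipse_levels)
    _panel(axes[1], random_proj.scores, report.assignment_random.labels,
           f"random projection (seed {random_proj.seed})", ellipse_levels)
    fig.suptitle(f"verdict: {report.verdict} (agreement {report.agreement:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
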