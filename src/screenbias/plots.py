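"""Minimal heat-map renderings of the correction surfaces."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .leadtime import LeadTimeGridResult
from .lengthbias import LengthBiasSurface


def plot_leadtime_grid(result: LeadTimeGridResult, quantity: str = "p_gt_05_screen",
                       path=None, title: str | None = None):
    """Heat map of one per-cell quantity over the (mean, SD) lambda grid."""
    z = getattr(result, quantity)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(result.lambda_sds, result.lambda_means, z,
                       shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label=quantity)
    ax.set_xlabel("SD of lambda (per year)")
    ax.set_ylabel("mean lambda (per year)")
    ax.set_title(title or quantity)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_lengthbias_surface(surface: LengthBiasSurface, path=None,
                            title: str = "length-bias-corrected relative hazard"):
    """Heat map of the corrected hazard over (q, theta); blank = no solution."""
    z = np.ma.masked_invalid(surface.psi)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(surface.theta_grid, surface.q_grid, z,
                       shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="psi")
    ax.set_xlabel("theta (subtype detection/fatality factor)")
    ax.set_ylabel("q (aggressive-subtype proportion)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
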