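"""Optional plot artifacts: response curves and broken-line tipping points.

Plots are outputs only; no computation ever reads them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .models import ResponseFit, response_curve
from .segmented import SegmentedResult


def plot_response_curve(fit: ResponseFit, y, x, path) -> None:
    grid = np.linspace(np.min(x), np.max(x), 200)
    mean, _ = response_curve(fit, grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, color="tab:blue", alpha=0.6)
    ax.plot(grid, mean, color="tab:red")
    ax.set_xlabel(fit.predictor)
    ax.set_ylabel(fit.response)
    ax.set_title(f"{fit.family}, {fit.form}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_segmented(result: SegmentedResult, y, x, path) -> None:
    """Data, the two fitted segments, and a vertical marker at psi."""
    order = np.argsort(x)
    xs = np.asarray(x, dtype=float)[order]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, color="tab:blue", alpha=0.6)
    ax.plot(xs, result.predict(xs), color="tab:red")
    ax.axvline(result.psi, color="black", linestyle="--",
               label=f"psi = {result.psi:.3g} (p = {result.p_value:.3g})")
    ax.set_xlabel(result.predictor)
    ax.set_ylabel(result.response)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
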