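"""Figure helpers for campaign reports (matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import PCAResult, UnfoldingResult
from .potentials import PotentialParams, lj, softcore_lj

__all__ = [
    "plot_softcore",
    "plot_distance_distributions",
    "plot_unfolding_curve",
    "plot_pca_projection",
]


def plot_softcore(params: PotentialParams, path: str | Path) -> None:
    """Softcore vs plain LJ sulfur-sulfur curve with the crossover marked."""
    r = np.linspace(0.0, params.lj_cutoff, 500)
    r_lj = r[r > 0.05]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(r, softcore_lj(r, params), label="softcore S-S")
    ax.plot(r_lj, lj(r_lj, params.sigma_ss, params.epsilon_ss, params.lj_cutoff),
            "--", label="plain LJ")
    ax.axvline(params.crossover, color="gray", lw=0.8, label="crossover")
    ax.set_ylim(-1.5, 25)
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("V (kJ/mol)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distance_distributions(hists: dict, path: str | Path) -> None:
    """Grid of per-pair d_S-S densities with sub-cutoff close-ups inset."""
    pairs = sorted(hists)
    fig, axes = plt.subplots(
        len({p[0] for p in pairs}), 2, figsize=(8, 7), sharex=True
    )
    axes = np.atleast_2d(axes)
    thiols = sorted({p[0] for p in pairs})
    sulfurs = sorted({p[1] for p in pairs})
    for i, t in enumerate(thiols):
        for j, s in enumerate(sulfurs):
            h = hists[(t, s)]
            ax = axes[i, j]
            centers = 0.5 * (h["edges"][1:] + h["edges"][:-1])
            ax.fill_between(centers, h["density"], alpha=0.6)
            ax.set_title(f"{t}Cys-{s}Cys", fontsize=9)
            if h["n_close"]:
                ins = ax.inset_axes([0.55, 0.45, 0.4, 0.45])
                cc = 0.5 * (h["close_edges"][1:] + h["close_edges"][:-1])
                ins.plot(cc, h["close_density"], lw=1)
                ins.tick_params(labelsize=6)
    for ax in axes[-1]:
        ax.set_xlabel("d_S-S (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_unfolding_curve(unfold: UnfoldingResult, path: str | Path) -> None:
    """Cumulative frequency of unfolding times."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    t, frac = unfold.cumulative_curve()
    if len(t):
        ax.step(t, frac, where="post")
    ax.set_xlabel("time (ps)")
    ax.set_ylabel("cumulative fraction unfolded")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_projection(
    pca: PCAResult,
    path: str | Path,
    color: np.ndarray | None = None,
    color_label: str = "d_S-S (nm)",
) -> None:
    """Scatter of frames on the first two loop modes, optionally colored
    by an external per-frame scalar (e.g. a thiol-disulfide distance)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xy = pca.projections[:, :2]
    if color is not None:
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=color, s=4, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=color_label)
    else:
        ax.scatter(xy[:, 0], xy[:, 1], s=4)
    ax.set_xlabel("mode 1 (nm)")
    ax.set_ylabel("mode 2 (nm)")
    ax.set_title(
        f"modes 1-2: {100 * pca.variance_fraction_12:.0f}% of positional variance",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
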