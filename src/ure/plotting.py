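"""Plot helpers: the theta-scan curve and dihedral-grid weight maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .selection import ThetaScan

__all__ = ["plot_theta_scan", "plot_weight_map"]


def plot_theta_scan(scan: ThetaScan, path: str | Path | None = None):
    """Validation-score and preservation curves vs theta (log x-axis).

    Thin red lines are individual folds, the thick line the fold mean with
    a one-standard-deviation band; gray is the training score; blue (right
    axis) the mean ensemble preservation.  Returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = scan.theta_grid
    for j in range(scan.val_score.shape[1]):
        ax.plot(t, scan.val_score[:, j], color="red", lw=0.6, alpha=0.4)
    mean, sd = scan.mean_val_score, scan.sd_val_score
    ax.plot(t, mean, color="red", lw=2, label="validation score")
    ax.fill_between(t, mean - sd, mean + sd, color="red", alpha=0.15)
    ax.plot(t, scan.mean_train_score, color="gray", lw=1.5, label="training score")
    ax.axhline(0.5, color="black", lw=0.8, ls=":")
    if scan.theta_recommended is not None:
        ax.axvline(scan.theta_recommended, color="green", lw=1, ls="--",
                   label=f"recommended θ = {scan.theta_recommended:.3g}")
    ax.set_xscale("log")
    ax.set_xlabel("θ")
    ax.set_ylabel("sigmoid(log(χ²/χ²_init))")
    ax2 = ax.twinx()
    ax2.plot(t, scan.ep_curve, color="tab:blue", lw=1.5)
    ax2.set_ylabel("ensemble preservation (%)", color="tab:blue")
    ax2.set_ylim(0, 105)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_weight_map(
    phi: np.ndarray,
    psi: np.ndarray,
    weights: np.ndarray,
    path: str | Path | None = None,
    title: str = "",
):
    """Heat map of conformer weights on the (phi, psi) grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phis, psis = np.unique(phi), np.unique(psi)
    grid = np.full((phis.size, psis.size), np.nan)
    ip = np.searchsorted(phis, phi)
    js = np.searchsorted(psis, psi)
    grid[ip, js] = weights
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        grid.T, origin="lower", aspect="auto",
        extent=(phis.min(), phis.max(), psis.min(), psis.max()),
    )
    fig.colorbar(im, ax=ax, label="weight")
    ax.set_xlabel("φ (deg)")
    ax.set_ylabel("ψ (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
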