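"""Figures for activation profiles and 2D landscapes.

Every figure has a machine-readable companion table written by the pipeline;
these helpers only render what the tables already contain.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .landscape import Landscape1D, Landscape2D, Pathway

__all__ = ["plot_profile", "plot_grid", "plot_report"]


def plot_profile(profiles, ax=None, title: str | None = None):
    """Overlay one or more 1D activation profiles with error bars.

    ``profiles`` is a mapping name -> Landscape1D."""
    if isinstance(profiles, Landscape1D):
        profiles = {"profile": profiles}
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, prof in profiles.items():
        ax.errorbar(prof.coordinates, prof.energies, yerr=prof.errors,
                    marker="o", ms=3, capsize=2, lw=1.2, label=name)
    ax.set_xlabel("activation coordinate")
    ax.set_ylabel(r"$\Delta G$ (kcal/mol)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_grid(grid: Landscape2D, pathway: Pathway | None = None, ax=None,
              title: str | None = None, vmax: float | None = None):
    """Heat map of a 2D landscape with the least-energy path overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.5))
    e = grid.energies - grid.energies.min()
    if vmax is None:
        vmax = float(np.percentile(e, 95))
    im = ax.imshow(e.T, origin="lower", aspect="auto", cmap="viridis",
                   vmax=vmax)
    plt.colorbar(im, ax=ax, label=r"$\Delta G$ (kcal/mol)")
    if pathway is not None:
        ii = [n[0] for n in pathway.nodes]
        jj = [n[1] for n in pathway.nodes]
        ax.plot(ii, jj, "w.-", lw=1.5, ms=4)
    ax.set_xlabel("coordinate 1 (conformation)")
    ax.set_ylabel("coordinate 2")
    if title:
        ax.set_title(title)
    return ax


def plot_report(report, outdir):
    """Write the standard figures for a scenario report."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if report.profiles:
        ax = plot_profile(report.profiles,
                          title=f"scenario {report.scenario} profiles")
        ax.figure.savefig(out / "profiles.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
        written.append("profiles.png")
    for name, grid in report.grids.items():
        path = report.pathways.get(name) or report.pathways.get("coupled")
        ax = plot_grid(grid, path, title=f"{report.scenario}: {name}")
        ax.figure.savefig(out / f"grid_{name}.png", dpi=150,
                          bbox_inches="tight")
        plt.close(ax.figure)
        written.append(f"grid_{name}.png")
    return written
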