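"""Figure panels for fit results (heatmaps and slice curves)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def surface_panels(est, path) -> None:
    """Four-row panel: fitted surface, Hand null, effect, residuals."""
    grid = est.grid_
    res = est.result_
    extent = None
    fig, axes = plt.subplots(4, 1, figsize=(5, 14))
    panels = [
        (est.surface_.mean, "GP fitted response"),
        (est.null_.values, "Hand null reference"),
        (res.effect, "effect (null - fit)"),
    ]
    u1 = np.log1p(grid.axis1 / est.theta_.l1)
    u2 = np.log1p(grid.axis2 / est.theta_.l2)
    extent = [u2[0], u2[-1], u1[0], u1[-1]]
    for ax, (values, title) in zip(axes[:3], panels):
        cmap = "RdYlGn" if "effect" in title else "viridis"
        im = ax.imshow(values, origin="lower", aspect="auto", extent=extent, cmap=cmap)
        ax.set_title(title)
        ax.set_xlabel("log(1 + x2/l2)")
        ax.set_ylabel("log(1 + x1/l1)")
        fig.colorbar(im, ax=ax)
    ax = axes[3]
    r = res.residuals
    sc = ax.scatter(
        np.log1p(r["dose2"] / est.theta_.l2),
        np.log1p(r["dose1"] / est.theta_.l1),
        c=r["residual"],
        cmap="RdBu",
        s=60,
    )
    ax.set_title("residuals (data - fit)")
    fig.colorbar(sc, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def monotherapy_panels(est, path) -> None:
    """Monotherapy slices with 95% bands and the observed points."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, which, axis_no in zip(axes, ("drug1-mono", "drug2-mono"), (1, 2)):
        sl = est.slice(which)
        l = est.theta_.l1 if axis_no == 1 else est.theta_.l2
        u = np.log1p(sl.position / l)
        ax.plot(u, sl.mean, color="C0", label="GP mean")
        ax.fill_between(u, sl.lower, sl.upper, alpha=0.3, color="C0", label="95% CI")
        d, y = est.data_.monotherapy(axis_no)
        ax.scatter(np.log1p(d / l), y, color="k", zorder=3, label="data")
        ax.set_xlabel(f"log(1 + dose/l{axis_no})")
        ax.set_ylabel("response")
        ax.set_title(which)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def screen_scatter(table, path) -> None:
    """Hand-GP vs MuSyC volume-difference scatter for a screen."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table["volume_difference_handgp"], table["volume_difference_musyc"])
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Hand-GP volume difference")
    ax.set_ylabel("MuSyC volume difference")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
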