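"""Polar-map rendering in the azimuthal equidistant projection.

Maps follow the canonical right-eye convention: superior up, nasal right,
with eccentricity rings and meridian spokes as the graticule and the optic
disc marked on the nasal side (polar angle 88 degrees by default).
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")  # headless rendering; import order matters
import matplotlib.pyplot as plt
import numpy as np

from . import geometry
from .geometry import CapWindow

__all__ = ["render_polar_map"]


def _graticule(ax, window: CapWindow, mirrored: bool) -> None:
    for ring in np.arange(15, window.radius + 1, 15):
        circ = plt.Circle((0, 0), ring, fill=False, color="0.8", lw=0.6, zorder=1)
        ax.add_patch(circ)
        ax.annotate(f"{ring:g}\N{DEGREE SIGN}", (0, ring), fontsize=6, color="0.5",
                    ha="left", va="bottom")
    for ang in range(0, 360, 45):
        x, y = geometry.project([0, window.radius], [ang, ang])
        ax.plot(x, y, color="0.85", lw=0.5, zorder=1)
    disc_ang = window.optic_disc_angle
    dx, dy = geometry.project(15.0, 360.0 - disc_ang if mirrored else disc_ang)
    ax.plot([dx], [dy], marker="o", ms=9, mfc="none", mec="0.3", zorder=5)
    ax.annotate("OD", (dx, dy), fontsize=6, ha="center", va="center", color="0.3")
    lab_n = "T" if mirrored else "N"
    lab_t = "N" if mirrored else "T"
    pad = window.radius * 1.06
    ax.text(pad, 0, lab_n, ha="center", va="center", fontsize=8)
    ax.text(-pad, 0, lab_t, ha="center", va="center", fontsize=8)
    ax.text(0, pad, "S", ha="center", va="center", fontsize=8)
    ax.text(0, -pad, "I", ha="center", va="center", fontsize=8)


def render_polar_map(
    path,
    burden=None,
    centroids=None,
    boundaries=None,
    window: CapWindow | None = None,
    mirrored: bool = False,
    title: str | None = None,
    cmap: str = "magma",
    dpi: int = 150,
):
    """Render map layers to an image file; returns the path.

    Layers: ``burden`` (a BurdenMap), ``centroids`` (a PointPattern or
    (x, y) arrays), ``boundaries`` (iterable of TumorPerimeter).
    ``mirrored=True`` renders in original left-eye orientation.  Output is
    deterministic for fixed inputs (fixed figure geometry, no timestamps).
    """
    window = window or CapWindow()
    if burden is None and centroids is None and boundaries is None:
        warnings.warn("no layers supplied; rendering a blank graticule", stacklevel=2)
    fig, ax = plt.subplots(figsize=(4.2, 4.2), dpi=dpi)
    R = window.radius

    if burden is not None:
        vals = burden.as_masked()
        if mirrored:
            vals = vals[:, ::-1]
        im = ax.imshow(
            vals,
            extent=(-R, R, -R, R),
            origin="upper",
            cmap=cmap,
            interpolation="nearest",
            zorder=0,
        )
        fig.colorbar(im, ax=ax, shrink=0.75, label=burden.mode.replace("_", " "))

    if boundaries is not None:
        for perim in boundaries:
            x, y = perim.projected()
            if mirrored:
                x = -x
            ax.plot(np.append(x, x[0]), np.append(y, y[0]), lw=0.7, color="tab:blue", zorder=3)

    if centroids is not None:
        if hasattr(centroids, "x"):
            cx, cy = np.asarray(centroids.x), np.asarray(centroids.y)
        else:
            cx, cy = (np.asarray(c) for c in centroids)
        if mirrored:
            cx = -cx
        ax.plot(cx, cy, "k.", ms=4, zorder=4)

    _graticule(ax, window, mirrored)
    ax.set_xlim(-R * 1.12, R * 1.12)
    ax.set_ylim(-R * 1.12, R * 1.12)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=dpi, metadata=_strip_metadata(path))
    plt.close(fig)
    return path


def _strip_metadata(path) -> dict:
    # keep output byte-identical across runs
    s = str(path).lower()
    if s.endswith(".png"):
        return {"Software": None}
    if s.endswith(".svg"):
        return {"Date": None}
    return {}
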