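"""Overlay and limit-curve figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .finder import CrystalCandidate
from .geometry import ReciprocalCell, Reflection, limit_curve, reflection_curve
from .planner import ShotPlan
from .router import Route


def plot_overlay(
    image: np.ndarray,
    candidates: Sequence[CrystalCandidate],
    plan: ShotPlan | None = None,
    route: Route | None = None,
    path: str | Path = "overlay.png",
) -> None:
    """Annotate the montage with candidate hulls, shots and the route.

    Accepted candidates are drawn green, flagged ones orange; primary
    shots pink, subsequent shots yellow, and the visiting route as a thin
    line.
    """
    fig, ax = plt.subplots(figsize=(10, 10))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1)
    for c in candidates:
        xs, ys = c.polygon.exterior.xy
        color = "orange" if c.flags else "lime"
        ax.plot(xs, ys, color=color, lw=1.0)
    if plan is not None:
        scale = 1.0
        prim = [s.center for s in plan.shots if s.kind == "primary"]
        subs = [s.center for s in plan.shots if s.kind == "subsequent"]
        if prim:
            p = np.array(prim) / scale
            ax.plot(p[:, 0], p[:, 1], "o", color="deeppink", ms=4)
        if subs:
            p = np.array(subs) / scale
            ax.plot(p[:, 0], p[:, 1], "o", color="yellow", ms=3)
        if route is not None:
            pos = {s.id: s.center for s in plan.shots}
            pts = np.array([pos[i] for i in route.order]) / scale
            ax.plot(pts[:, 0], pts[:, 1], "-", color="cyan", lw=0.5)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_limit_curves(
    cell: ReciprocalCell,
    wavelengths: np.ndarray,
    reflections: Sequence[Reflection],
    resolution_cutoff: float = 1.55,
    path: str | Path = "limits.png",
) -> None:
    """Oscillation limit vs wavelength: envelope plus per-reflection curves."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for refl in reflections:
        curve = reflection_curve(refl, cell, wavelengths)
        ax.plot(
            curve["wavelength_A"],
            curve["omega_deg"],
            "--",
            lw=1,
            label=f"({refl.h}{refl.k}{refl.l})",
        )
    env = limit_curve(cell, wavelengths, resolution_cutoff=resolution_cutoff)
    ax.plot(env["wavelength_A"], env["omega_deg"], "k-", lw=2, label="chip limit")
    ax.set_xlabel("wavelength (Å)")
    ax.set_ylabel("oscillation limit ±ω (°)")
    ax.set_ylim(0, 30)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
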