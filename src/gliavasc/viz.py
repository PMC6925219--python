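"""Inspection plots: mask overlays and dual-channel line profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .contact import Profile


def save_mask_overlay(image: np.ndarray, mask: np.ndarray,
                      path: str | Path, title: str = "") -> None:
    """Grayscale image with the mask outline in red."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image, cmap="gray")
    ax.contour(mask.astype(float), levels=[0.5], colors="r", linewidths=0.8)
    ax.set_title(title)
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_profile_plot(profile: Profile, path: str | Path,
                      title: str = "") -> None:
    """Green/red intensity along the cell-to-vessel line, in um."""
    x = np.arange(profile.green.size) * profile.pixel_size_um
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(x, profile.green, color="g", label="microglia")
    ax.plot(x, profile.red, color="r", label="vessel")
    ax.set_xlabel("distance from cell center (µm)")
    ax.set_ylabel("intensity")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
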