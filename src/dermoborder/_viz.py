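"""Diagnostic renderings (matplotlib is imported lazily; optional extra)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_signal(result, path: str | Path) -> None:
    """Borderline function with junction lines and irregularity arrows."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = result.signal
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(sig.values, lw=1.0, color="k", label="borderline (smoothed)")
    ax.plot(result.raw_signal.values, lw=0.5, color="0.6", label="raw")
    for j in sig.junctions:
        ax.axvline(j, color="tab:blue", lw=0.6, ls="--")
    for call in result.calls:
        ax.annotate(
            "",
            xy=(call.index, sig.values[call.index]),
            xytext=(call.index, sig.values[call.index] + 8),
            arrowprops=dict(arrowstyle="->", color="red"),
        )
    ax.set_xlabel("arc position (samples)")
    ax.set_ylabel("height (px)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def overlay(image: np.ndarray, result, path: str | Path) -> None:
    """Input image with detected irregularities marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image)
    for call in result.calls:
        r, c = call.coord
        ax.annotate(
            "",
            xy=(c, r),
            xytext=(c + 14, r - 14),
            arrowprops=dict(arrowstyle="->", color="red", lw=1.2),
        )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
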