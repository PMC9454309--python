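"""Preview rendering: CT | CBCT | sCT triptychs with difference maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def save_triptych(ct: np.ndarray, cbct: np.ndarray, sct: np.ndarray,
                  path, window: tuple[float, float] = (-200.0, 300.0),
                  diff_range: float = 100.0) -> Path:
    """Write a PNG with the three slices and their CT-differences.

    ``window`` is the HU display window for the images; difference maps are
    shown symmetric around 0 at ``±diff_range`` HU.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("CT", ct, None), ("CBCT", cbct, cbct - ct),
              ("sCT", sct, sct - ct)]
    fig, axes = plt.subplots(2, 3, figsize=(9, 6.2))
    for col, (title, img, diff) in enumerate(panels):
        ax = axes[0, col]
        ax.imshow(img, cmap="gray", vmin=window[0], vmax=window[1])
        ax.set_title(title)
        ax.axis("off")
        ax = axes[1, col]
        if diff is None:
            ax.axis("off")
            continue
        im = ax.imshow(diff, cmap="coolwarm", vmin=-diff_range,
                       vmax=diff_range)
        ax.set_title(f"{title} − CT")
        ax.axis("off")
    fig.colorbar(im, ax=axes[1, :], shrink=0.7, label="HU difference")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
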