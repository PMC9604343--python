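"""Paired correlation heatmaps (control vs cancer) per pathway.

One figure with two side-by-side panels sharing a diverging colormap fixed to
[−1, +1] (blue = positive, red = negative, masked cells light gray), gene
labels on both axes, written as both SVG and PNG.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .diffcorr import CorrelationMatrixPair

# RdBu maps low -> red, high -> blue: positive correlations render blue.
_CMAP_NAME = "RdBu"
_MASK_COLOR = "0.85"


def plot_correlation_pair(
    pair: CorrelationMatrixPair, out_path: str | Path, formats: tuple[str, ...] = ("svg", "png")
) -> list[Path]:
    """Render the control/cancer correlation matrices side by side.

    ``out_path`` is the output basename; one file per requested format is
    written next to it (e.g. ``out.svg`` and ``out.png``). The color scale is
    fixed to [−1, +1] so the two panels are directly comparable. Returns the
    written paths.
    """
    base = Path(out_path)
    base.parent.mkdir(parents=True, exist_ok=True)

    cmap = matplotlib.colormaps[_CMAP_NAME].copy()
    cmap.set_bad(_MASK_COLOR)
    n = len(pair.genes)

    with matplotlib.rc_context({"svg.fonttype": "none"}):
        fig, axes = plt.subplots(
            1, 2, figsize=(max(6.0, 0.5 * n + 3.0) * 2, max(4.0, 0.5 * n + 2.0)),
            constrained_layout=True,
        )
        for ax, mat, title in (
            (axes[0], pair.cc_control, "control"),
            (axes[1], pair.cc_cancer, "cancer"),
        ):
            im = ax.imshow(np.ma.masked_invalid(mat), cmap=cmap, vmin=-1.0, vmax=1.0)
            ax.set_title(f"{pair.pathway} ({title})")
            ax.set_xticks(range(n), pair.genes, rotation=90, fontsize=8)
            ax.set_yticks(range(n), pair.genes, fontsize=8)
        fig.colorbar(im, ax=axes, shrink=0.8, label="Pearson CC")

        written = []
        try:
            for fmt in formats:
                target = base.with_suffix(f".{fmt}")
                fig.savefig(target, format=fmt)
                written.append(target)
        finally:
            plt.close(fig)
    return written
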