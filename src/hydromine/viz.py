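"""Plotting of cysteine-anchored hydropathy profiles."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np


def plot_aligned_profiles(
    matrix: np.ndarray,
    cys_columns: Sequence[int],
    labels: Optional[Sequence[str]] = None,
    out: Optional[Union[str, Path]] = None,
):
    """Plot rows of an aligned hydropathy matrix, one trace per protein.

    Conserved cysteine columns are marked with vertical lines; NaN gap
    markers render as breaks in the traces.  Gap placement is the package's
    deterministic right-edge padding, an approximation of the hand-placed
    gaps used in the original figure style.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = matrix.shape[0]
    fig, axes = plt.subplots(
        n_rows, 1, sharex=True, figsize=(10, 1.6 * n_rows), squeeze=False
    )
    x = np.arange(matrix.shape[1])
    for r in range(n_rows):
        ax = axes[r, 0]
        ax.plot(x, matrix[r], lw=1.0)
        ax.axhline(0.0, color="grey", lw=0.5)
        for c in cys_columns:
            ax.axvline(c, color="black", lw=0.5, alpha=0.5)
        ax.set_ylim(-4.6, 4.6)
        if labels is not None:
            ax.set_ylabel(labels[r], rotation=0, ha="right", va="center", fontsize=8)
    axes[-1, 0].set_xlabel("aligned position (cysteines anchored)")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
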