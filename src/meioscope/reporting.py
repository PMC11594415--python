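"""Figures and human-readable reports.

The IOD histogram mimics the layout of classical DNA-content cytometry
figures: IOD on the x-axis, cell count on the y-axis, one annotation per
delimited ploidy population giving its mean ± SD IOD (the SD is suppressed
for populations of fewer than six cells).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ploidy import CytometryTable

__all__ = ["plot_iod_histogram"]


def plot_iod_histogram(
    table: CytometryTable, iods: Sequence[float], path: str | Path, bins: int = 60
) -> Path:
    iods = np.asarray(list(iods), dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(iods, bins=bins, color="0.55", edgecolor="0.25")
    c = table.scale.c_unit
    top = ax.get_ylim()[1]
    for k in table.multipliers:
        n = int(table.counts[k].sum())
        if n == 0:
            continue
        mean = table.mean_iod[k]
        sd = table.sd_iod[k]
        label = f"{k}C\nn={n}\n{mean:.1f}" + (f"±{sd:.1f}" if np.isfinite(sd) else "")
        ax.axvline(k * c, color="tab:red", lw=0.6, ls=":")
        ax.text(k * c, top * 0.97, label, ha="center", va="top", fontsize=7)
    ax.set_xlabel("IOD (arbitrary units)")
    ax.set_ylabel("Number of cells")
    ax.set_title(f"DNA content distribution (1C = {c:.2f} IOD)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
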