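"""Simple diagnostic plots: measured vs predicted TSH, and capacity by stratum."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .cohort import STRATUM_ORDER  # noqa: E402
from .population import DEFAULT_CURVE, PopulationCurve, predict_tsh_array  # noqa: E402

__all__ = ["plot_tsh_vs_ft4", "plot_gt_by_stratum"]


def plot_tsh_vs_ft4(
    table: pd.DataFrame, path: str | Path, curve: PopulationCurve = DEFAULT_CURVE
) -> Path:
    """Scatter of measured TSH against FT4 with the population-predicted curve."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, mask, color in (
        ("euthyroid", table["classification"] == "euthyroid", "tab:blue"),
        ("SH", table["classification"] != "euthyroid", "tab:red"),
    ):
        sub = table[mask]
        ax.scatter(sub["ft4_pmol_l"], sub["tsh_miu_l"], s=8, alpha=0.5,
                   color=color, label=name)
    ft4_lo = max(0.5, float(table["ft4_pmol_l"].min()) - 1)
    grid = np.linspace(ft4_lo, float(table["ft4_pmol_l"].max()) + 1, 400)
    ax.plot(grid, predict_tsh_array(grid, curve), "k-", lw=1.5, label="predicted TSH")
    ax.set_xlabel("FT4 (pmol/L)")
    ax.set_ylabel("TSH (mIU/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_gt_by_stratum(table: pd.DataFrame, path: str | Path) -> Path:
    """Strip plot of actual and predicted secretory capacity per stratum."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, label in enumerate(STRATUM_ORDER):
        sub = table[table["stratum"] == label]
        if len(sub) == 0:
            continue
        x = i + rng.uniform(-0.18, 0.18, len(sub))
        ax.scatter(x, sub["gt_actual_pmol_s"], s=8, alpha=0.5, color="tab:blue")
        ax.scatter(x + 0.35, sub["gt_predicted_pmol_s"], s=8, alpha=0.5, color="tab:orange")
    ax.set_xticks(np.arange(len(STRATUM_ORDER)) + 0.18)
    ax.set_xticklabels(STRATUM_ORDER)
    ax.set_ylabel("SPINA-GT (pmol/s)")
    ax.scatter([], [], color="tab:blue", label="actual")
    ax.scatter([], [], color="tab:orange", label="predicted")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
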