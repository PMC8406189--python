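"""Figure-style plots: ddG violin comparison and lag-time ECDFs."""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np


def violin_ddg(groups: Dict[str, Sequence[float]], path: Optional[str] = None):
    """Violin plot of ddG distributions per variant class, with median and
    quartile lines and a dashed line at ddG = 0."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [k for k, v in groups.items() if len(v)]
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.8 * len(labels) + 1.5, 4))
    parts = ax.violinplot(data, showmedians=True, showextrema=False)
    for pc in parts["bodies"]:
        pc.set_alpha(0.6)
    parts["cmedians"].set_color("red")
    for i, v in enumerate(data, start=1):
        q1, q3 = np.percentile(v, [25, 75])
        ax.hlines([q1, q3], i - 0.2, i + 0.2, linestyles="dashed", lw=0.8)
    ax.axhline(0.0, ls="--", color="grey", lw=0.8)
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=20)
    ax.set_ylabel(r"$\Delta\Delta G$ (kcal/mol)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def lag_ecdf(lag_times: Dict[str, Sequence[float]], path: Optional[str] = None):
    """Cumulative resuscitation-time distributions per bin (survivors only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, lag in lag_times.items():
        x = np.sort(np.asarray(lag, dtype=float))
        if x.size == 0:
            continue
        y = np.arange(1, x.size + 1) / x.size
        ax.step(x, y, where="post", label=f"{label} (n={x.size})")
    ax.set_xlabel("resuscitation time (h)")
    ax.set_ylabel("cumulative fraction of survivors")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
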