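"""Summary figure: estimated effect differences with empirical-SE bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_summary(summary, truth: float = 2.0):
    """One panel per (scenario, missingness) cell: mean estimate +/- empirical
    SD versus sample size for each method, with the true difference as a
    horizontal reference line.  Returns the matplotlib Figure.
    """
    cells = summary[["scenario", "missing"]].drop_duplicates().itertuples(index=False)
    cells = sorted((c.scenario, c.missing) for c in cells)
    scenarios = sorted({s for s, _ in cells})
    flags = sorted({m for _, m in cells})
    fig, axes = plt.subplots(
        len(scenarios), len(flags),
        figsize=(4.5 * len(flags), 2.6 * len(scenarios)),
        squeeze=False, sharex=True)
    methods = sorted(summary["method"].unique())
    for i, sc in enumerate(scenarios):
        for j, miss in enumerate(flags):
            ax = axes[i][j]
            sub = summary[(summary["scenario"] == sc) & (summary["missing"] == miss)]
            for k, m in enumerate(methods):
                mm = sub[sub["method"] == m].sort_values("n_patients")
                if mm.empty:
                    continue
                x = mm["n_patients"].to_numpy(dtype=float) * (1.0 + 0.012 * k)
                ax.errorbar(x, mm["mean_estimate"], yerr=mm["sd_estimate"],
                            marker="o", markersize=3, capsize=2, label=m,
                            linestyle="-", linewidth=0.8)
            ax.axhline(truth, color="red", linestyle="--", linewidth=0.8)
            ax.set_xscale("log")
            ax.set_title(f"scenario {sc}" + (", missing data" if miss else ""),
                         fontsize=9)
            if i == len(scenarios) - 1:
                ax.set_xlabel("sample size (patients)")
            if j == 0:
                ax.set_ylabel("effect difference")
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper center", ncol=min(len(labels), 7),
                   fontsize=8, frameon=False)
    fig.tight_layout(rect=(0, 0, 1, 0.95))
    return fig
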