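"""Optional plotting: stacked per-source emission bars (requires matplotlib)."""

from __future__ import annotations

from .footprint import SOURCE_KEYS, FootprintReport


def plot_report(report: FootprintReport, path: str | None = None):
    """Stacked bar of per-season CO2e by source; negative SOC bars hang below zero.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.name for s in report.seasons]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(names), 4))
    bottom_pos = [0.0] * len(names)
    bottom_neg = [0.0] * len(names)
    for source in SOURCE_KEYS:
        vals = [s.sources[source] for s in report.seasons]
        if not any(vals):
            continue
        bottoms = [bn if v < 0 else bp for v, bp, bn in zip(vals, bottom_pos, bottom_neg)]
        ax.bar(names, vals, bottom=bottoms, label=source.replace("_", " "))
        bottom_pos = [bp + max(0.0, v) for bp, v in zip(bottom_pos, vals)]
        bottom_neg = [bn + min(0.0, v) for bn, v in zip(bottom_neg, vals)]
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_ylabel("Mg CO2e ha$^{-1}$")
    ax.set_title(f"{report.label}: {report.total:.1f} Mg CO2e ha$^{{-1}}$ yr$^{{-1}}$")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
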