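"""Static figures: BM-vs-PB VAF scatter and Bland-Altman agreement plot."""

from __future__ import annotations

from pathlib import Path

from .agreement import BlandAltmanResult, VafPair, regression_line


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=(5.5, 5.0))


def vaf_scatter(vaf_pairs: list[VafPair], path: str | Path, title: str = "") -> Path:
    """Scatter of BM vs PB VAF with the bisecting line and the OLS fit."""
    fig, ax = _axes()
    x = [p.bm_vaf for p in vaf_pairs]
    y = [p.pb_vaf for p in vaf_pairs]
    ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    ax.plot([0, 100], [0, 100], color="black", lw=1, label="bisecting line")
    if len(x) >= 2:
        slope, intercept = regression_line(x, y)
        ax.plot([0, 100], [intercept, intercept + 100 * slope],
                color="red", ls="--", lw=1, label="regression line")
    ax.set_xlabel("BM VAF (%)")
    ax.set_ylabel("PB VAF (%)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path


def bland_altman_plot(
    result: BlandAltmanResult, vaf_pairs: list[VafPair], path: str | Path
) -> Path:
    """Difference-vs-mean plot with the mean line and the 2-SD limits."""
    fig, ax = _axes()
    means = [(p.bm_vaf + p.pb_vaf) / 2 for p in vaf_pairs]
    diffs = [p.bm_vaf - p.pb_vaf for p in vaf_pairs]
    ax.scatter(means, diffs, s=12, alpha=0.6, edgecolors="none")
    for y, label in ((result.mean_diff, "mean difference"),
                     (result.lower_limit, "limits of agreement"),
                     (result.upper_limit, None)):
        ax.axhline(y, color="red", ls="--", lw=1, label=label)
    ax.set_xlabel("Mean of BM and PB VAF (%)")
    ax.set_ylabel("BM VAF - PB VAF (%)")
    ax.legend(frameon=False, fontsize=8)
    path = Path(path)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path
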