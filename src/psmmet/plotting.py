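"""Figure helpers: profile scatter + fit, and binned AR box plots.

Thin matplotlib wrappers over the analysis tables; everything they show
is computed by the other modules.
"""

from __future__ import annotations

import numpy as np


def plot_profile(ax, table, fits, *, response="aspect_ratio",
                 position="position_percent"):
    """Scatter of per-cell responses with the per-domain sigmoid fits.

    ``fits`` is the DataFrame from
    :func:`psmmet.profile_fitting.fit_domain_profiles`; landmark markers
    follow the usual convention (diamond = inflection, square = 10% of
    vertical height).
    """
    from .profile_fitting import logistic4

    for domain, grp in table.groupby("domain", sort=False):
        pts = ax.scatter(grp[position], grp[response], s=4, alpha=0.3,
                         label=str(domain))
        color = pts.get_facecolor()[0]
        row = fits.loc[fits.domain == domain]
        if not len(row):
            continue
        row = row.iloc[0]
        if row.get("no_sigmoid", False):
            ax.axhline(row.a, color=color, lw=1, ls="--")
            continue
        xs = np.linspace(table[position].min(), table[position].max(), 200)
        ax.plot(xs, logistic4(xs, row.a, row.b, row.x0, row.k), color=color)
        if np.isfinite(row.x_inflection):
            ax.plot(row.x_inflection,
                    logistic4(row.x_inflection, row.a, row.b, row.x0, row.k),
                    "D", color=color, ms=7, mec="k")
            ax.plot(row.x_height10, row.a + 0.1 * (row.b - row.a),
                    "s", color=color, ms=7, mec="k")
    ax.set_xlabel("PSM distance [%]")
    ax.set_ylabel(response)
    ax.legend(fontsize=8)
    return ax


def plot_binned_boxes(ax, summary):
    """Box plot of a :func:`binned_boxplot_summary` table per domain."""
    domains = summary["domain"].unique()
    width = 0.8 * (
        np.min(np.diff(np.sort(summary["bin_center"].unique())))
        if summary["bin_center"].nunique() > 1 else 10.0
    ) / max(len(domains), 1)
    for j, domain in enumerate(domains):
        grp = summary[summary.domain == domain]
        offset = (j - (len(domains) - 1) / 2) * width
        boxes = [
            {"med": r.median, "q1": r.q1, "q3": r.q3,
             "whislo": r.whisker_low, "whishi": r.whisker_high, "fliers": []}
            for r in grp.itertuples()
        ]
        ax.bxp(boxes, positions=grp["bin_center"] + offset,
               widths=width * 0.9, showfliers=False)
    ax.set_xlabel("PSM distance [%]")
    ax.set_ylabel("aspect ratio")
    return ax
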