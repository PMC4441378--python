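"""Plot helpers for niche-occupancy-history diagrams.

Renders, per PC axis, node age against reconstructed tolerance: internal
node means joined to their descendants by solid lines, and a dashed
vertical bar spanning each extant clade's 80% central tolerance interval
at age 0.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .ancestral import AncestralProfile
from .trees import UltrametricTree


def plot_niche_history(
    tree: UltrametricTree,
    profile: AncestralProfile,
    pc: int,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    table = profile.table
    means = {
        row["node"]: row["mean"] for _, row in table[table["pc"] == pc].iterrows()
    }
    intervals = {
        row["node"]: (row["lo80"], row["hi80"])
        for _, row in table[(table["pc"] == pc) & (table["kind"] == "tip")].iterrows()
    }
    for node in tree.preorder():
        for child in node.children:
            ax.plot(
                [means[node.label], means[child.label]],
                [node.age, child.age],
                "-",
                color="0.3",
                lw=1.2,
            )
    for tip in tree.tips:
        lo, hi = intervals[tip.label]
        ax.plot([lo, hi], [0, 0], "--", lw=2)
        ax.annotate(tip.label, (means[tip.label], 0), textcoords="offset points",
                    xytext=(0, -12), ha="center", fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel(f"PC{pc} tolerance")
    ax.set_ylabel("age (Ma)")
    return ax
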