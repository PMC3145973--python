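"""Optional plotting conveniences for benchmark reports."""

from __future__ import annotations

import numpy as np

from .scoring import PartitionCurve, curve_value


def plot_rmsd_vs_length(records, curve: PartitionCurve | None = None, ax=None):
    """Scatter of matched length against RMSD, same-fold pairs highlighted.

    Same-fold comparisons are drawn in green, different-fold in red; the
    fitted partition curve, when given, is overlaid in blue.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    same = [(r.n, r.r) for r in records if r.same_fold]
    diff = [(r.n, r.r) for r in records if not r.same_fold]
    if diff:
        ax.scatter(*zip(*diff), s=8, c="firebrick", alpha=0.5, label="different fold")
    if same:
        ax.scatter(*zip(*same), s=8, c="seagreen", alpha=0.7, label="same fold")
    if curve is not None:
        n = np.linspace(1, curve.N, 300)
        ax.plot(n, curve_value(n, curve), c="royalblue", lw=1.5, label="partition curve")
    ax.set_xlabel("matched residues n")
    ax.set_ylabel("RMSD r (Å)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_discrimination(curves: dict, ax=None):
    """TP-growth against FP-growth for each ranking key.

    *curves* maps a ranking-key name to the DataFrame produced by
    :func:`foldbench.scoring.discrimination_curve`; better rankings approach
    the top-left corner.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for key, df in curves.items():
        ax.plot(df.FP, df.TP, lw=1.3, label=key)
    ax.set_xlabel("false matches (different fold)")
    ax.set_ylabel("true matches (same fold)")
    ax.legend(frameon=False, fontsize=8)
    return ax
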