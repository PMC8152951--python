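"""Quick-look plots for patterns and pair correlation estimates."""

from __future__ import annotations

__all__ = ["plot_pattern", "plot_pcf"]

_TYPE_COLORS = {"PV": "tab:green", "SST": "m"}


def plot_pattern(pattern, annotation=None, ax=None, **scatter_kw):
    """Scatter a typed point pattern, optionally over its layer annotation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if annotation is not None:
        x, y = annotation.roi.exterior.xy
        ax.plot(x, y, color="0.6", lw=1)
        for name, line in annotation.boundaries.items():
            ax.plot(line[:, 0], line[:, 1], color="gold", lw=0.8)
    for label in pattern.type_labels:
        pts = pattern.coords_of(label)
        ax.scatter(
            pts[:, 0], pts[:, 1], s=8, label=label,
            color=_TYPE_COLORS.get(label), **scatter_kw,
        )
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("depth y (μm)")
    ax.invert_yaxis()  # pia at the top
    ax.set_aspect("equal")
    if pattern.type_labels:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_pcf(estimate, ax=None, label=None, color=None):
    """ĝ(r) with its CSR reference line and envelope band if present."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    ax.axhline(1.0, color="0.7", lw=1, ls="--")
    if estimate.envelope_lo is not None:
        ax.fill_between(
            estimate.r, estimate.envelope_lo, estimate.envelope_hi,
            alpha=0.2, color=color or "0.4", lw=0,
        )
    ax.plot(estimate.r, estimate.g, color=color, lw=1.5,
            label=label or f"{estimate.type_a}–{estimate.type_b}")
    ax.set_xlabel("r (μm)")
    ax.set_ylabel("g(r)")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False, fontsize=8)
    return ax
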