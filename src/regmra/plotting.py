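"""Optional figure helpers (activity heatmap, Kaplan–Meier curves).

matplotlib is imported lazily; install the ``plot`` extra to use these.
Figures are presentation artifacts only — nothing downstream consumes them.
"""

from __future__ import annotations

import numpy as np

from .survival import km_estimate


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting; install regmra[plot]"
        ) from err
    return plt


def plot_activity_heatmap(activity, path, k: int = 2):
    """Regulon x sample dES heatmap with rows ordered by the k-cut clusters."""
    from .activity import cluster_activity

    plt = _plt()
    des = getattr(activity, "des", activity)
    tree = cluster_activity(des, k=min(k, len(des.index)))
    order = tree.labels.sort_values(kind="stable").index
    data = des.loc[order]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(order) + 1.5))
    vmax = np.nanmax(np.abs(data.to_numpy())) or 1.0
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel("samples")
    fig.colorbar(im, ax=ax, label="dES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km(groups: dict, path, title: str = ""):
    """Step survival curves, one per named record group."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, records in groups.items():
        curve = km_estimate(records)
        t = np.concatenate([[0.0], np.repeat(curve.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
        ax.plot(t, s, drawstyle="steps-post", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
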