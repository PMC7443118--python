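"""Diagnostic figures: radial collicular maps, shift-map heat maps,
accuracy bar charts, and the per-trial panel sequence."""

from __future__ import annotations

import numpy as np

from .colliculus import CollicularMap
from .what import ShiftAccuracyMap


def plot_collicular_map(coll_map: CollicularMap, ax=None, title=None):
    """Radial (polar pcolormesh) view of a 240-cell accuracy map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    grid = coll_map.grid
    ecc = np.asarray(grid.eccentricities)
    edges_r = np.concatenate([[ecc[0] * 0.7], np.sqrt(ecc[:-1] * ecc[1:]),
                              [ecc[-1] * 1.2]])
    step = 2 * np.pi / grid.n_azimuth
    edges_phi = (np.arange(grid.n_azimuth + 1) - 0.5) * step
    m = ax.pcolormesh(edges_phi, edges_r, coll_map.as_grid(),
                      cmap="viridis", vmin=0, vmax=1)
    ax.set_yticklabels([])
    if title:
        ax.set_title(title)
    return ax, m


def plot_shift_map(shift_map: ShiftAccuracyMap, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = shift_map.max_shift
    im = ax.imshow(shift_map.values, extent=(-s, s, s, -s),
                   cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("horizontal shift (px)")
    ax.set_ylabel("vertical shift (px)")
    plt.colorbar(im, ax=ax, label="accuracy")
    return ax


def plot_accuracy_bars(table, ax=None):
    """Pre- vs. postsaccadic accuracy per eccentricity (one contrast)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, color, alpha in ((0, "tab:orange", 0.5), (1, "tab:blue", 0.8)):
        sub = table[table.n_saccades == k]
        if len(sub):
            ax.bar(sub.eccentricity, sub.accuracy, width=2.5, color=color,
                   alpha=alpha, label=f"{k} saccade{'s' if k != 1 else ''}",
                   yerr=[sub.accuracy - sub.ci_low, sub.ci_high - sub.accuracy])
    ax.axhline(0.1, ls="--", c="k", lw=0.8, label="chance")
    ax.set_xlabel("target eccentricity (px)")
    ax.set_ylabel("accuracy")
    ax.legend()
    return ax


def render_trial(record, system, path=None):
    """Display / reconstruction / true map / predicted map / fovea panel
    for each fixation of one trial."""
    import matplotlib.pyplot as plt

    from .colliculus import ground_truth_map
    from .retina import crop_fovea
    from .where import predict_map

    n_fix = len(record.trajectory)
    fig = plt.figure(figsize=(3 * 5, 3 * n_fix))
    disp = record.display
    for i, gaze in enumerate(record.trajectory):
        axs = [fig.add_subplot(n_fix, 5, 5 * i + j + 1,
                               projection="polar" if j in (2, 3) else None)
               for j in range(5)]
        axs[0].imshow(disp.pixels, cmap="gray")
        axs[0].plot(gaze[1], gaze[0], "b+")
        axs[0].set_title(f"fixation {i}")
        feats = system.encoder.encode(disp, gaze)
        axs[1].imshow(system.encoder.reconstruct(feats), cmap="gray")
        axs[1].set_title("reconstruction")
        offset = (disp.center[0] + disp.target.position[0] - gaze[0],
                  disp.center[1] + disp.target.position[1] - gaze[1])
        true_map = ground_truth_map(offset, system.shift_map,
                                    system.projection, system.grid)
        plot_collicular_map(true_map, ax=axs[2], title="true")
        plot_collicular_map(predict_map(system.where_model, feats),
                            ax=axs[3], title="predicted")
        axs[4].imshow(crop_fovea(disp, gaze), cmap="gray", vmin=0, vmax=1)
        axs[4].set_title(f"fovea (ans={record.answer}, ok={record.success})"
                         if i == n_fix - 1 else "fovea")
        for ax in (axs[0], axs[1], axs[4]):
            ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
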