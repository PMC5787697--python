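"""Line-chart output for metaprofiles and splicing maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .splicemap import REGION_NAMES  # noqa: E402


def plot_boundary_profile(profile, background_shuffle, background_random, path):
    """Observed coverage vs both randomized backgrounds at one boundary type."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile.offsets, profile.counts, color="crimson", label="observed")
    ax.plot(
        background_shuffle.offsets, background_shuffle.counts,
        color="steelblue", label="shuffled exons",
    )
    ax.plot(
        background_random.offsets, background_random.counts,
        color="seagreen", label="random regions",
    )
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("offset from boundary (bp; intron side positive)")
    ax.set_ylabel("reads covering base")
    ax.set_title(f"{profile.boundary_type} boundary metaprofile")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_splicing_map(maps: dict, path):
    """Per-class density (solid) and significance (dotted) across regions."""
    colors = {"enhanced": "crimson", "silenced": "steelblue"}
    fig, axes = plt.subplots(1, len(REGION_NAMES), figsize=(16, 3.5), sharey=True)
    for ax, region in zip(axes, REGION_NAMES):
        pax = ax.twinx()
        for cls, pm in maps.items():
            c = colors.get(cls, "black")
            ax.plot(pm.density[region], color=c, label=cls)
            if pm.p_values.get(region) is not None:
                pax.plot(pm.p_values[region], color=c, ls=":", alpha=0.6)
        pax.set_ylim(1.05, -0.05)
        ax.set_title(region)
        ax.set_xlabel("position (bp)")
    axes[0].set_ylabel("fraction of events with a peak")
    axes[0].legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
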