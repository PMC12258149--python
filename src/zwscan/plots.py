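"""Plot helpers for scan tracks and expression-ratio densities."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_window_track(df, value_col, out_path, chrom=None, ylabel=None,
                      hlines=()):
    """One scan track (FST, log2 F:M ...) per window along a chromosome."""
    sub = df if chrom is None else df[df["chrom"] == chrom]
    fig, ax = plt.subplots(figsize=(9, 2.5))
    mid = (sub["start"] + sub["end"]) / 2e6
    ax.plot(mid, sub[value_col], lw=0.8)
    for y in hlines:
        ax.axhline(y, color="grey", ls="--", lw=0.6)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(ylabel or value_col)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_ratio_density(ratios, out_path, by_category=True):
    """Frequency density of Zfemale/ZZmale ratios, optionally per W:Z category."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    groups = ratios.groupby("category") if by_category else [("all", ratios)]
    for cat, sub in groups:
        if len(sub) < 2:
            continue
        ax.hist(sub["zf_zzm"], bins=30, density=True, histtype="step",
                label=f"category {cat}")
    ax.axvline(0.5, color="grey", ls="--", lw=0.8)
    ax.axvline(1.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("Z female / ZZ male expression ratio")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
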