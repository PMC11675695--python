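"""Optional matplotlib output for the curve tables (behind the --plot flag)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _plot_long(df, ax, highlight=()):
    for label, sub in df.groupby("item_id"):
        hot = label in highlight
        ax.plot(sub["theta"], sub["value"], lw=2.0 if hot else 0.8,
                alpha=1.0 if hot else 0.6, label=label if hot else None)
    if highlight:
        ax.legend(fontsize=8)
    ax.set_xlabel(r"$\theta$")


def plot_curve_table(frame, outdir, highlight=()) -> list[Path]:
    """One PNG per curve_type from a tidy curve table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for ctype, sub in frame.groupby("curve_type"):
        fig, ax = plt.subplots(figsize=(6, 4))
        _plot_long(sub, ax, highlight)
        ax.set_ylabel(ctype)
        path = outdir / f"curves_{ctype}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def plot_ifti(ifti_curves, path, highlight=()) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in ifti_curves:
        hot = c.label in highlight
        ax.plot(c.grid.values, c.values, lw=2.0 if hot else 0.8,
                alpha=1.0 if hot else 0.6, label=c.label if hot else None)
    if highlight:
        ax.legend(fontsize=8)
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("IFTI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
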