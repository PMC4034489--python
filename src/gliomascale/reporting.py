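"""Plots and delimited summaries of a sensitivity sweep."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import ENDPOINTS, records_to_frame, summarize_max, summary_to_frame

_MARKERS = {0.3: "x", 1.125: "o", 2.25: "D", 4.5: "+"}


def report(records, out_dir) -> list:
    """Write the standard sweep report into ``out_dir``.

    Per parameter: the sensitivity coefficients against the factor,
    restricted to factors in ]0, 2[ (an equal count of down- and up-scalings;
    extreme factors compress S by construction).  Per sweep: the
    dM_time-vs-dM_total correlation scatter and the max-|S| summary table.
    Returns the list of files written.
    """
    if not records:
        raise ValueError("cannot report on an empty record set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    df = df[df["error"].isna()] if df["error"].notna().any() else df
    written = []

    for param, sub in df.groupby("param"):
        sub = sub[(sub.factor > 0) & (sub.factor < 2)]
        fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
        for ax, e in zip(axes.ravel(), ENDPOINTS):
            for g, mark in _MARKERS.items():
                pts = sub[sub.glucose0 == g]
                if len(pts):
                    ax.plot(pts.factor, pts[f"S_{e}"], mark, linestyle="none",
                            label=f"{g} g/L")
            ax.axhline(0.0, color="0.8", lw=0.8)
            ax.set_ylabel(f"S_{e}")
        axes[1, 0].set_xlabel("factor b")
        axes[1, 1].set_xlabel("factor b")
        axes[0, 0].legend(fontsize=7)
        fig.suptitle(f"Sensitivity coefficients, parameter {param}")
        path = out_dir / f"coefficients_{param}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(6, 5))
    for g, mark in _MARKERS.items():
        pts = df[df.glucose0 == g]
        if len(pts):
            ax.plot(pts.dM_total, pts.dM_time, mark, linestyle="none", label=f"{g} g/L")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("relative change of final cell count (dM_total)")
    ax.set_ylabel("relative change of steps to boundary (dM_time)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "delta_correlation.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    summary = summary_to_frame(summarize_max(records))
    path = out_dir / "max_sensitivity_summary.tsv"
    summary.to_csv(path, sep="\t", index=False)
    written.append(path)
    return written
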