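"""Optional matplotlib figures for an evaluation report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import EvaluationReport


def plot_report(report: EvaluationReport, out_dir: str | Path) -> list[Path]:
    """Write top-n, confidence-bin and fraction-called figures as PNG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    curve = report.topn_curve
    K = len(curve["model"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ns = range(1, K + 1)
    ax.plot(ns, curve["model"], "o-", label="classifier")
    ax.plot(ns, curve["by_frequency"], "s--", label="ranked by frequency")
    ax.plot(ns, curve["random"], ":", color="gray", label="random")
    ax.set_xlabel("top n sites considered")
    ax.set_ylabel("cumulative accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    path = out_dir / "topn_curve.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax2 = ax.twinx()
    for b in report.confidence_bins:
        mid = (b["lo"] + b["hi"]) / 2
        ax2.bar(mid, b["n"], width=(b["hi"] - b["lo"]) * 0.9, color="0.85")
        if b["n"] > 0:
            lo, hi = b["ci"]
            ax.errorbar(
                mid, b["accuracy"], yerr=[[b["accuracy"] - lo], [hi - b["accuracy"]]],
                fmt="o", color="C0",
            )
    ax.set_xlabel("confidence score bin")
    ax.set_ylabel("accuracy")
    ax2.set_ylabel("samples")
    ax.set_ylim(0, 1.05)
    ax.set_zorder(ax2.get_zorder() + 1)
    ax.patch.set_visible(False)
    path = out_dir / "confidence_bins.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    cf = report.called_fraction
    fr = [p["fraction"] for p in cf["curve"]]
    acc = [p["accuracy"] for p in cf["curve"]]
    lo = [p["ci"][0] for p in cf["curve"]]
    hi = [p["ci"][1] for p in cf["curve"]]
    ax.fill_between(fr, lo, hi, color="0.9")
    ax.plot(fr, acc, "-", color="C0")
    ax.axhline(cf["target_accuracy"], color="red", lw=0.8, ls="--")
    ax.plot([cf["fraction_at_target"]], [cf["target_accuracy"]], "ro")
    ax.set_xlabel("fraction of samples called")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.05)
    path = out_dir / "fraction_called.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
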