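"""Kaplan-Meier plot rendering for high/low expression arms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .scan import KMCurve

__all__ = ["render_km"]


def _step_coordinates(curve: KMCurve):
    """Right-continuous step coordinates starting at (0, 1)."""
    times = np.concatenate([[0.0], curve.event_times])
    surv = np.concatenate([[1.0], curve.survival_probability])
    return times, surv


def render_km(
    curve_high: KMCurve,
    curve_low: KMCurve,
    annotations: dict,
    out_base,
) -> list:
    """Render a two-arm KM step plot and write it as SVG and PNG.

    ``annotations`` may carry gene, cutoff, hr, ci (pair), p and per-arm n;
    present keys are printed in the annotation box. ``out_base`` is the path
    without extension; returns the list of files written.
    """
    for name, curve in (("high", curve_high), ("low", curve_low)):
        if curve is None:
            raise ValueError(f"missing KM curve for the {name} arm")
        if len(curve.event_times) != len(curve.survival_probability):
            raise ValueError(f"inconsistent KM curve for the {name} arm")
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve, label, color in (
        (curve_high, "high expression", "#c0392b"),
        (curve_low, "low expression", "#2c3e50"),
    ):
        t, s = _step_coordinates(curve)
        ax.step(t, s, where="post", label=label, color=color)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("relapse-free survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", frameon=False)

    lines = []
    if "gene" in annotations:
        ax.set_title(str(annotations["gene"]))
    if "cutoff" in annotations:
        lines.append(f"cutoff = {annotations['cutoff']:.0f}")
    if "hr" in annotations:
        hr_line = f"HR = {annotations['hr']:.2f}"
        if "ci" in annotations:
            lo, hi = annotations["ci"]
            hr_line += f" ({lo:.2f}-{hi:.2f})"
        lines.append(hr_line)
    if "p" in annotations:
        lines.append(f"p = {annotations['p']:.2g}")
    if "n_high" in annotations and "n_low" in annotations:
        lines.append(f"n = {annotations['n_high']} high / {annotations['n_low']} low")
    if lines:
        ax.text(
            0.98, 0.98, "\n".join(lines), transform=ax.transAxes,
            ha="right", va="top", fontsize=9,
            bbox=dict(boxstyle="round", fc="white", ec="0.7"),
        )

    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for ext in ("svg", "png"):
        path = out_base.with_suffix(f".{ext}")
        fig.savefig(path, dpi=150)
        written.append(path)
    plt.close(fig)
    return written
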