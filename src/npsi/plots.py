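"""Diagnostic figures: ternary scatter, TSI plane, seasonal minima, exceedances.

Rendering failures are logged and swallowed — figures are a convenience
on top of the tabular pipeline, never a reason for a run to fail.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stoichiometry import ternary_xy
from .trophic import TSI_CLASS_EDGES
from .units import CONSTANTS

log = logging.getLogger(__name__)

_TSI_COLORS = {
    "ultra_oligotrophic": "#b5e48c",
    "oligotrophic": "#2d6a4f",
    "mesotrophic": "#ffd60a",
    "eutrophic": "#f77f00",
    "hypereutrophic": "#d62828",
}
_SEASON_COLORS = {"spring": "#ffd60a", "summer": "#1d6fb8",
                  "autumn": "#f77f00", "winter": "#7b2cbf"}


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ternary_figure(summary, path):
    """Redfield ternary scatter coloured by TSI class (N left, P right, Si top)."""
    fig, ax = plt.subplots(figsize=(6, 5.5))
    h = math.sqrt(3) / 2
    ax.plot([0, 1, 0.5, 0], [0, 0, h, 0], color="k", lw=1)
    for frac in (0.2,):  # depletion guides at 20% of each component
        # N < 20%: line parallel to the P-Si edge, etc.
        ax.plot([1 - frac, 0.5 + frac / 2], [0, h * (1 - frac)], ls="--", c="grey", lw=0.8)
        ax.plot([frac, 0.5 - frac / 2], [0, h * (1 - frac)], ls="--", c="grey", lw=0.8)
        ax.plot([frac / 2, 1 - frac / 2], [h * frac, h * frac], ls="--", c="grey", lw=0.8)
    x, y = ternary_xy(summary["n_pct"], summary["p_pct"], summary["si_pct"])
    colors = [_TSI_COLORS.get(c, "grey") for c in summary["tsi_class"]]
    ax.scatter(x, y, c=colors, s=35, edgecolor="k", lw=0.4, zorder=3)
    ax.text(-0.03, -0.04, "N", ha="center")
    ax.text(1.03, -0.04, "P", ha="center")
    ax.text(0.5, h + 0.03, "Si", ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("Redfield N:P:Si composition (16:1:%g), coloured by TSI class"
                 % CONSTANTS.redfield_si)
    _save(fig, path)


def tsi_plane_figure(summary, path):
    """DIN vs TotP scatter with TSI class boundaries and the Redfield N:P line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    totp = summary["totp_umol"] * CONSTANTS.mass_p
    din = summary["din_umol"] * CONSTANTS.mass_n
    ax.scatter(totp, din, c="tab:blue", s=30, edgecolor="k", lw=0.4, zorder=3)
    for edge, color in zip(TSI_CLASS_EDGES, ("#2d6a4f", "#b5e48c", "#ffd60a", "#d62828")):
        # invert the TSI equations at each class edge
        ax.axvline(math.exp((edge - 4.15) / 14.42), color=color, lw=1)
        ax.axhline(1000.0 * math.exp((edge - 54.45) / 14.43), color=color, lw=1)
    lims = np.array([totp.min() * 0.5, totp.max() * 2.0])
    ax.plot(lims, lims * CONSTANTS.redfield_n * CONSTANTS.mass_n / CONSTANTS.mass_p,
            "k:", label="molar N:P = 16")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("TotP (µg l$^{-1}$)")
    ax.set_ylabel("DIN (µg l$^{-1}$)")
    ax.legend(frameon=False)
    ax.set_title("Average DIN vs TotP with TSI boundaries")
    _save(fig, path)


def min_si_figure(summary, path):
    """Overall vs minimum monthly Redfield Si percentage, coloured by season."""
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = [_SEASON_COLORS[s] for s in summary["min_si_season"]]
    ax.scatter(summary["si_pct"], summary["min_si_pct"], c=colors,
               s=30, edgecolor="k", lw=0.4)
    ax.axhline(20, ls="--", c="grey", lw=0.8)
    ax.plot([0, 100], [0, 100], c="lightgrey", lw=0.8)
    ax.set_xlabel("Overall Redfield Si %")
    ax.set_ylabel("Minimum monthly Redfield Si %")
    handles = [plt.Line2D([], [], marker="o", ls="", color=c, label=s)
               for s, c in _SEASON_COLORS.items()]
    ax.legend(handles=handles, frameon=False)
    ax.set_title("Seasonal Si depletion (minimum month by season)")
    _save(fig, path)


def exceedance_figure(summary, path):
    """Exceedance ratios vs measured concentrations with monthly ranges."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=False)
    panels = [("DIN", "din_umol", CONSTANTS.mass_n, "d_din",
               "d_din_monthly_min", "d_din_monthly_max"),
              ("TotP", "totp_umol", CONSTANTS.mass_p, "d_totp",
               "d_totp_monthly_min", "d_totp_monthly_max")]
    for ax, (name, conc_col, mass, d_col, lo_col, hi_col) in zip(axes, panels):
        conc = summary[conc_col] * mass
        d = summary[d_col]
        colors = np.where(d > 1, "#d62828", "#2d6a4f")
        ax.vlines(conc, summary[lo_col], summary[hi_col], color="grey",
                  lw=0.6, ls="--", zorder=1)
        ax.scatter(conc, d, c=colors, s=25, edgecolor="k", lw=0.3, zorder=3)
        ax.axhline(1.0, c="k", lw=0.8)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(f"{name} (µg l$^{{-1}}$)")
        ax.set_ylabel(f"Exceedance ratio D_{name}")
        ax.set_title(name)
    _save(fig, path)


def render_figures(summary, monthly, out_dir) -> list[Path]:
    """Render all figures; skip (with a log record) any that fail."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    jobs = [
        (ternary_figure, "ternary_tsi.png"),
        (tsi_plane_figure, "din_totp_tsi.png"),
        (min_si_figure, "min_si_season.png"),
        (exceedance_figure, "exceedance.png"),
    ]
    for func, name in jobs:
        path = out_dir / name
        try:
            func(summary, path)
            written.append(path)
        except Exception:  # noqa: BLE001 — plotting must never abort the pipeline
            log.exception("figure %s failed", name)
    return written
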