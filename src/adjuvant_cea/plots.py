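"""Plots generated from the pipeline's CSV outputs.

Kept separate from the numeric stages so results never depend on
plotting: each function reads a report CSV written by ``run_pipeline``
and writes a PNG next to it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["tornado_plot", "ceac_plot", "nmb_plot", "ce_plane_plot", "render_report"]


def tornado_plot(tornado_csv: str | Path, out_png: str | Path, base_outcome: float | None = None) -> Path:
    df = pd.read_csv(tornado_csv).iloc[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(df) + 1.5))
    left = df[["low_outcome", "high_outcome"]].min(axis=1)
    width = (df["high_outcome"] - df["low_outcome"]).abs()
    ax.barh(df["param"], width, left=left, color="#4878d0")
    if base_outcome is not None:
        ax.axvline(base_outcome, color="k", lw=1)
    ax.set_xlabel("incremental net monetary benefit (USD)")
    ax.set_title("One-way sensitivity analysis")
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def ceac_plot(ceac_csv: str | Path, out_png: str | Path) -> Path:
    df = pd.read_csv(ceac_csv)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(df["wtp"], df["prob_cost_effective"], color="#d65f5f")
    ax.set_xlabel("willingness-to-pay (USD/QALY)")
    ax.set_ylabel("probability intervention is cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def nmb_plot(ceac_csv: str | Path, out_png: str | Path) -> Path:
    df = pd.read_csv(ceac_csv)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(df["wtp"], df["mean_inc_nmb"], color="#6acc64")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("willingness-to-pay (USD/QALY)")
    ax.set_ylabel("mean incremental net monetary benefit (USD)")
    ax.set_title("Net-monetary-benefit acceptability")
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def ce_plane_plot(draws_csv: str | Path, out_png: str | Path, wtp: float | None = None) -> Path:
    df = pd.read_csv(draws_csv)
    inc_cost = df["cost_int"] - df["cost_comp"]
    inc_qaly = df["qaly_int"] - df["qaly_comp"]
    fig, ax = plt.subplots(figsize=(6.5, 6))
    ax.scatter(inc_qaly, inc_cost, s=8, alpha=0.4, color="#4878d0")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    if wtp is not None:
        xs = pd.Series([inc_qaly.min(), inc_qaly.max()])
        ax.plot(xs, wtp * xs, "k--", lw=0.8, label=f"WTP {wtp:,.0f}/QALY")
        ax.legend()
    ax.set_xlabel("incremental QALY")
    ax.set_ylabel("incremental cost (USD)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def render_report(run_dir: str | Path, wtp: float | None = None) -> list[Path]:
    """Render every plot whose source CSV exists in ``run_dir``."""
    run_dir = Path(run_dir)
    made = []
    if (run_dir / "tornado.csv").exists():
        made.append(tornado_plot(run_dir / "tornado.csv", run_dir / "tornado.png"))
    if (run_dir / "ceac.csv").exists():
        made.append(ceac_plot(run_dir / "ceac.csv", run_dir / "ceac.png"))
        made.append(nmb_plot(run_dir / "ceac.csv", run_dir / "nmb_acceptability.png"))
    if (run_dir / "psa_draws.csv").exists():
        made.append(ce_plane_plot(run_dir / "psa_draws.csv", run_dir / "ce_plane.png", wtp=wtp))
    return made
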