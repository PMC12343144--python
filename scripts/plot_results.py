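#!/usr/bin/env python
"""Thin plotting helpers over the CSV/JSON experiment outputs.

Usage::

    python scripts/plot_results.py <results_dir> [--out figures_dir]

Renders whichever outputs are present: per-cycle sweep metrics, the
(beta_1, omega) attachment heatmap with the analytic partition overlay,
and the hysteresis loop.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_sweep(indir: Path, outdir: Path) -> None:
    df = pd.read_csv(indir / "per_cycle.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for r, grp in df.groupby("rho_0"):
        axes[0].plot(grp["k"], grp["mean_M1_frac"], marker="o", label=f"rho0={r}")
        axes[1].plot(grp["k"], grp["mean_KA"], marker="o")
        axes[2].semilogy(grp["k"], grp["peak_EA"].clip(lower=1e-12), marker="o")
    axes[0].set_ylabel("mean M1 fraction")
    axes[1].set_ylabel("mean KA (cells/ml)")
    axes[2].set_ylabel("peak EA (cells/ml)")
    for ax in axes:
        ax.set_xlabel("cycle")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "sweep.png", dpi=150)


def plot_heatmap(indir: Path, outdir: Path) -> None:
    hm = pd.read_csv(indir / "heatmap.csv")
    bd = pd.read_csv(indir / "partition_boundary.csv")
    for r, grp in hm.groupby("rho_0"):
        piv = grp.pivot_table(index="omega", columns="beta_1", values="end_EA")
        fig, ax = plt.subplots(figsize=(5, 4))
        pcm = ax.pcolormesh(piv.columns, piv.index,
                            np.log10(piv.values + 1e-6), cmap="Purples")
        if len(bd):
            ax.plot(bd["beta_1"], bd["omega"], "k--", lw=1.2,
                    label="stability partition")
            ax.legend(fontsize=8)
        ax.set_xscale("log"); ax.set_yscale("log")
        ax.set_xlabel("beta_1 (cells$^{-1}$ ml/day)")
        ax.set_ylabel("omega (cells$^{-1}$ ml/day)")
        fig.colorbar(pcm, label="log10 end-of-cycle EA")
        fig.tight_layout()
        fig.savefig(outdir / f"heatmap_rho0_{r}.png", dpi=150)


def plot_hysteresis(indir: Path, outdir: Path) -> None:
    df = pd.read_csv(indir / "hysteresis.csv")
    vary = [c for c in df.columns if c in ("omega", "beta_1")][0]
    fig, ax = plt.subplots(figsize=(5, 4))
    for d, grp in df.groupby("direction"):
        ax.semilogx(grp[vary], np.log10(grp["end_EA"] + 1e-9),
                    marker="o", ms=3, label=d)
    ax.set_xlabel(vary)
    ax.set_ylabel("log10 end EA (cells/ml)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "hysteresis.png", dpi=150)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("results_dir", type=Path)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()
    indir = args.results_dir
    outdir = args.out or indir
    outdir.mkdir(parents=True, exist_ok=True)
    if (indir / "per_cycle.csv").exists() and (indir / "summary.csv").exists():
        plot_sweep(indir, outdir)
    if (indir / "heatmap.csv").exists():
        plot_heatmap(indir, outdir)
    if (indir / "hysteresis.csv").exists():
        plot_hysteresis(indir, outdir)
    print(f"figures written to {outdir}")


if __name__ == "__main__":
    main()
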