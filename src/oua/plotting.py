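"""Optional overview plots for a result bundle (never required by tests)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_summary"]


def plot_summary(out_dir: str | Path) -> list[Path]:
    """Render mu/theta traces and reward curves from ``trajectories.csv``.

    Returns the list of written PNG paths.
    """
    out = Path(out_dir)
    csv = out / "trajectories.csv"
    if not csv.exists():
        raise FileNotFoundError(f"no trajectories.csv in {out}")
    df = pd.read_csv(csv)
    mu_cols = sorted(c for c in df.columns if c.startswith("mu_")
                     and c != "mu_sigma")
    written = []

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for trial, g in df.groupby("trial"):
        for c in mu_cols:
            axes[0].plot(g["time"], g[c], lw=0.6, alpha=0.5)
        axes[1].plot(g["time"], g["r"], lw=0.4, alpha=0.4)
    axes[0].set_ylabel("mu")
    axes[1].set_ylabel("reward r")
    axes[1].set_xlabel("time")
    fig.tight_layout()
    path = out / "overview.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if "sigma" in df.columns:
        fig, ax = plt.subplots(figsize=(8, 3))
        for trial, g in df.groupby("trial"):
            ax.plot(g["time"], g["sigma"], lw=0.6, alpha=0.5)
        ax.set_xlabel("time")
        ax.set_ylabel("sigma")
        fig.tight_layout()
        path = out / "sigma.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
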