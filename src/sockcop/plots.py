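"""Optional diagnostic plots: time series, scatter, Bland-Altman."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .agreement import bland_altman, lin_ccc
from .preprocess import AlignedPair

__all__ = ["plot_pair_timeseries", "plot_scatter", "plot_bland_altman"]


def _title(pair: AlignedPair) -> str:
    ann = pair.annotations or {}
    bits = [str(ann.get(k)) for k in ("participant", "exercise", "foot") if ann.get(k)]
    return " ".join(bits + [f"CoP {pair.axis.upper()}"])


def plot_pair_timeseries(pair: AlignedPair, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(pair.t, pair.sock, label="sock", lw=1)
    ax.plot(pair.t, pair.platform, label="platform", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"CoP {pair.axis.upper()} (mm, centered)")
    ax.set_title(_title(pair))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_scatter(pair: AlignedPair, path: str | Path) -> Path:
    ccc = lin_ccc(pair)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pair.platform, pair.sock, ".", ms=2, alpha=0.5)
    lim = max(abs(pair.platform).max(), abs(pair.sock).max()) * 1.05
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=1, label="identity")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("platform CoP (mm)")
    ax.set_ylabel("sock CoP (mm)")
    ax.set_title(f"{_title(pair)}  CCC = {ccc.ccc:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bland_altman(pair: AlignedPair, path: str | Path) -> Path:
    ba = bland_altman(pair)
    mean = (pair.sock + pair.platform) / 2
    diff = pair.sock - pair.platform
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(mean, diff, ".", ms=2, alpha=0.5)
    for yv, style in ((ba.bias_mm, "-"), (ba.loa_low_mm, "--"), (ba.loa_high_mm, "--")):
        ax.axhline(yv, color="r", ls=style, lw=1)
    ax.set_xlabel("mean of methods (mm)")
    ax.set_ylabel("sock - platform (mm)")
    ax.set_title(
        f"{_title(pair)}  bias {ba.bias_mm:.1f} mm, "
        f"LoA [{ba.loa_low_mm:.1f}, {ba.loa_high_mm:.1f}]"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
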