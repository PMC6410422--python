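"""QQ and forest plots for scan and epidemiologic results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scan import qq_table

__all__ = ["qq_plot", "forest_plot"]


def qq_plot(pvalues, path, title: str = "QQ plot", lam: float | None = None) -> None:
    qq = qq_table(pvalues)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(qq["expected"], qq["observed"], ".", ms=3, color="steelblue")
    lim = max(qq["expected"].max(), qq["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "-", lw=1, color="grey")
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    label = title if lam is None else f"{title} ($\\lambda$ = {lam:.2f})"
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest_plot(effects: pd.DataFrame, path, title: str = "", log_scale: bool = True) -> None:
    """Per-category estimates with 95% CIs (one row per AAM category)."""
    df = effects.dropna(subset=["or_or_beta"]).reset_index(drop=True)
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.6 * len(df) + 1.2))
    ax.errorbar(
        df["or_or_beta"], y,
        xerr=np.abs(df[["ci_low", "ci_high"]].to_numpy().T - df["or_or_beta"].to_numpy()),
        fmt="s", color="black", capsize=3,
    )
    ref = 1.0 if log_scale else 0.0
    ax.axvline(ref, color="grey", lw=1, ls="--")
    if log_scale:
        ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(df["category"])
    ax.set_xlabel("OR (95% CI)" if log_scale else "beta (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
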