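"""Standard figures: score/trajectory plots, the s-line, and box plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_STRATUM_COLORS = {"Grey": "0.55", "Red": "tab:red", "Green": "tab:green"}


def trajectory_plot(trajectories: pd.DataFrame, path: str | Path) -> None:
    """Score plot with pre -> post arrows, coloured by stratum."""
    fig, ax = plt.subplots(figsize=(7, 4))
    rng = np.random.default_rng(0)  # jitter for the y axis only (display)
    for _, row in trajectories.iterrows():
        y = rng.uniform(-1, 1)
        color = _STRATUM_COLORS.get(row["stratum"], "k")
        ax.annotate("", xy=(row["t_post"], y), xytext=(row["t_pre"], y),
                    arrowprops=dict(arrowstyle="->", color=color, lw=1.2))
        ax.plot(row["t_pre"], y, marker="^", mfc="none", color=color, ms=6)
        ax.plot(row["t_post"], y, marker="^", color=color, ms=6)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("t[1] (predictive score)")
    ax.set_yticks([])
    ax.set_title("pre → post score trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sline_plot(centers_ppm: np.ndarray, covariance: np.ndarray,
               p_corr: np.ndarray, path: str | Path) -> None:
    """S-line: bucket ppm vs covariance with t[1], coloured by |p(corr)|."""
    fig, ax = plt.subplots(figsize=(8, 4))
    sc = ax.scatter(centers_ppm, covariance, c=np.abs(p_corr), cmap="viridis",
                    s=4, vmin=0, vmax=1)
    ax.invert_xaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("cov(X, t[1])")
    fig.colorbar(sc, ax=ax, label="|p(corr)|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def metabolite_boxplots(metabolites: pd.DataFrame, columns: list[str],
                        path: str | Path, by: pd.Series | None = None) -> None:
    """Pre/post box plots per metabolite, optionally split by a patient map."""
    ncols = min(len(columns), 4)
    nrows = int(np.ceil(len(columns) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows),
                             squeeze=False)
    for ax, met in zip(axes.ravel(), columns):
        data, labels = [], []
        if by is None:
            for tp in ("pre", "post"):
                data.append(metabolites.loc[metabolites["timepoint"] == tp, met]
                            .dropna().to_numpy())
                labels.append(tp)
        else:
            for grp in pd.Series(by).dropna().unique():
                members = pd.Series(by)[pd.Series(by) == grp].index
                sel = metabolites["patient_id"].isin(members)
                for tp in ("pre", "post"):
                    data.append(metabolites.loc[sel & (metabolites["timepoint"] == tp),
                                                met].dropna().to_numpy())
                    labels.append(f"{grp}\n{tp}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(met, fontsize=9)
    for ax in axes.ravel()[len(columns):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
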