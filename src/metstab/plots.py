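"""Standard MET diagnostic plots: yield-by-IPCA1, WAASB quadrants, GGE biplot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ammi import AMMIFit, predict_ammi
from .gge import GGEFit, ideal_genotype_ranking
from .stability import StabilityResult

__all__ = ["plot_yield_by_ipca1", "plot_waasb_quadrants", "plot_gge_ranking"]


def plot_yield_by_ipca1(fit: AMMIFit, path=None):
    """Nominal AMMI1 yields of every genotype across the environment
    IPCA1 axis; crossing lines are crossover interactions."""
    env_scores = fit.environment_vectors.iloc[:, 0] * fit.singular_values[0] \
        if fit.p else pd.Series(0.0, index=fit.environments)
    pred1 = predict_ammi(fit, min(1, fit.p))
    order = env_scores.sort_values().index
    fig, ax = plt.subplots(figsize=(7, 5))
    x = env_scores.loc[order]
    for gen in fit.genotypes:
        # nominal yield: drop the environment main effect so lines compare
        nominal = (pred1.loc[gen, order]
                   - fit.environment_effects.loc[order])
        ax.plot(x, nominal, marker="o", ms=3, lw=1, label=gen)
    ax.set_xlabel("environment IPCA1 score")
    ax.set_ylabel("nominal yield (t/ha)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_waasb_quadrants(result: StabilityResult, path=None):
    """WAASB (y) by mean yield (x) with mean cut-off crosshairs."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for frame, marker, color in ((result.genotypes, "o", "tab:blue"),
                                 (result.environments, "s", "tab:red")):
        ax.scatter(frame["yield"], frame["WAASB"], marker=marker, s=25,
                   color=color)
        for name, row in frame.iterrows():
            ax.annotate(name, (row["yield"], row["WAASB"]), fontsize=6)
    allv = result.table()
    ax.axvline(result.genotypes["yield"].mean(), ls="--", lw=0.8, c="gray")
    ax.axhline(result.genotypes["WAASB"].mean(), ls="--", lw=0.8, c="gray")
    ax.set_xlabel("mean yield (t/ha)")
    ax.set_ylabel("WAASB")
    ax.set_title(f"{len(allv)} entities; quadrant IV genotypes are "
                 "productive and stable")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gge_ranking(fit: GGEFit, path=None):
    """Genotype-ranking biplot with concentric circles around the ideal."""
    rank = ideal_genotype_ranking(fit)
    env = fit.environment_coords
    aec = env.to_numpy().mean(axis=0)
    aec = aec / np.linalg.norm(aec)
    ideal = aec * rank["aec_projection"].max()
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(rank["axis1"], rank["axis2"], s=25, color="tab:blue")
    for name, row in rank.iterrows():
        ax.annotate(name, (row["axis1"], row["axis2"]), fontsize=7)
    ax.scatter(env["axis1"], env["axis2"], s=15, color="tab:red", marker="s")
    span = float(np.abs(rank[["axis1", "axis2"]].to_numpy()).max())
    ax.axline((0, 0), ideal, ls="--", lw=0.8, c="gray")
    for rad in np.linspace(0.25, 1.0, 4) * span:
        ax.add_patch(plt.Circle(ideal, rad, fill=False, ls=":", lw=0.7,
                                color="gray"))
    ax.annotate("ideal", ideal, fontsize=8, color="black", weight="bold")
    ax.set_xlabel(f"axis 1 ({100 * fit.explained[0]:.1f}%)")
    ax.set_ylabel(f"axis 2 ({100 * fit.explained[1]:.1f}%)")
    ax.set_aspect("equal")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
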