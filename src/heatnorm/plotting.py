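"""Figures: heritability curves, reaction norms, correlation heatmap, Miami plot."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_heritability(h2: pd.DataFrame, ax=None, trait: str = ""):
    """Posterior mean heritability across the gradient with credible band.

    Expects the frame from ``ReactionNormResults.heritability`` (columns
    ``x, mean, lo, hi``); residual-class changes show as breaks in the
    curve.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(h2["x"], h2["lo"], h2["hi"], alpha=0.25, color="tab:blue")
    ax.plot(h2["x"], h2["mean"], color="tab:blue")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("standardized environmental covariate")
    ax.set_ylabel("heritability")
    if trait:
        ax.set_title(f"Environment-specific heritability - {trait}")
    return ax.figure


def plot_reaction_norms(
    norms: pd.DataFrame,
    tolerant=(),
    susceptible=(),
    ax=None,
    trait: str = "",
):
    """Population norm (black) with tolerant (blue) / susceptible (red) sires."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in norms.columns:
        if col in ("x", "population"):
            continue
        color = (
            "tab:blue" if col in {str(i) for i in tolerant}
            else "tab:red" if col in {str(i) for i in susceptible}
            else "lightgrey"
        )
        ax.plot(norms["x"], norms[col], color=color, lw=1.0)
    ax.plot(norms["x"], norms["population"], color="black", lw=2.5)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("standardized environmental covariate")
    ax.set_ylabel("predicted performance")
    if trait:
        ax.set_title(f"Reaction norms - {trait}")
    return ax.figure


def plot_correlation_heatmap(gamma, ax=None, trait: str = ""):
    """Heatmap of across-environment genetic correlations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    corr = gamma.correlations()
    im = ax.imshow(
        corr, origin="lower", vmin=-1, vmax=1, cmap="RdBu_r",
        extent=[gamma.grid[0], gamma.grid[-1], gamma.grid[0], gamma.grid[-1]],
    )
    ax.figure.colorbar(im, ax=ax, label="genetic correlation")
    ax.set_xlabel("covariate value")
    ax.set_ylabel("covariate value")
    if trait:
        ax.set_title(f"Genetic correlations - {trait}")
    return ax.figure


def plot_miami(windows: pd.DataFrame, ax=None, trait: str = ""):
    """Miami plot: intercept-term window shares above, slope-term below.

    Red line marks each term's selection threshold (smallest selected
    share); red dots mark windows passing the bootstrap test.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    # cumulative genome coordinate
    offsets = {}
    cursor = 0
    for c in pd.unique(windows["chrom"]):
        offsets[c] = cursor
        cursor += int(windows.loc[windows["chrom"] == c, "end"].max()) + 1
    gx = windows["start"].to_numpy() + np.array(
        [offsets[c] for c in windows["chrom"]]
    )
    chrom_codes = pd.factorize(windows["chrom"])[0]
    colors = np.where(chrom_codes % 2 == 0, "steelblue", "darkorange")
    ax.scatter(gx, windows["pct_intercept"], s=4, c=colors)
    ax.scatter(gx, -windows["pct_slope"], s=4, c=colors)
    for term, sign in (("intercept", 1), ("slope", -1)):
        sel_col = f"selected_{term}"
        if sel_col in windows and windows[sel_col].any():
            thr = windows.loc[windows[sel_col], f"pct_{term}"].min()
            ax.axhline(sign * thr, color="red", lw=0.8, ls="--")
        sig_col = f"significant_{term}"
        if sig_col in windows and windows[sig_col].any():
            sig = windows.loc[windows[sig_col]]
            sgx = sig["start"].to_numpy() + np.array(
                [offsets[c] for c in sig["chrom"]]
            )
            ax.scatter(sgx, sign * sig[f"pct_{term}"], s=12, c="red")
    ax.axhline(0.0, color="black", lw=1.0)
    ax.set_xlabel("genome position")
    ax.set_ylabel("% genomic variance (intercept above / slope below)")
    if trait:
        ax.set_title(f"Window-based ssGWAS - {trait}")
    return ax.figure
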