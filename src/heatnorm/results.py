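"""Posterior results and derived genetic parameters.

From the fitted (co)variance matrix G of the random intercept and slope,
the across-environment additive-genetic covariance surface is

    Gamma[k, k'] = phi(x_k)' G phi(x_k')

over a grid of standardized covariate values, with phi the normalized
order-1 Legendre basis.  Derived quantities: across-environment genetic
correlations (their minimum and median summarize the strength of GxE),
environment-specific heritabilities h2(x) = Gamma_kk / (Gamma_kk +
sigma2_pe + sigma2_e[class(x)]), population and individual reaction
norms, and the ranking of sires by their reaction-norm slope to identify
heat-tolerant and heat-susceptible genetic material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heatnorm.basis import phi_matrix
from heatnorm.components import VarianceComponents
from heatnorm.env import assign_residual_class

DEFAULT_GRID = 201


def _as_grid(grid) -> np.ndarray:
    if grid is None:
        return np.linspace(-1.0, 1.0, DEFAULT_GRID)
    if np.isscalar(grid):
        return np.linspace(-1.0, 1.0, int(grid))
    return np.asarray(grid, dtype=float)


@dataclass
class GammaMatrix:
    """Additive-genetic covariance among environmental gradient values."""

    grid: np.ndarray
    Phi: np.ndarray
    Gamma: np.ndarray

    def correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.Gamma))
        if np.any(d == 0):
            raise ValueError("zero diagonal in Gamma; correlations undefined")
        return self.Gamma / np.outer(d, d)


def gamma_matrix(G, grid=None) -> GammaMatrix:
    """``Gamma = Phi G Phi'`` over a grid of standardized covariate values.

    ``G`` is the 2x2 intercept/slope covariance; the default grid has 201
    equally spaced points on [-1, 1].
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (2, 2) or not np.allclose(G, G.T):
        raise ValueError("G must be a symmetric 2x2 matrix")
    x = _as_grid(grid)
    if np.any(np.abs(x) > 1.0 + 1e-9):
        raise ValueError("grid must lie within [-1, 1]")
    Phi = phi_matrix(x)
    return GammaMatrix(grid=x, Phi=Phi, Gamma=Phi @ G @ Phi.T)


def correlation_summary(gamma: GammaMatrix) -> dict:
    """Minimum and median of the off-diagonal genetic correlations.

    The minimum is grid-insensitive for first-order norms (it sits at the
    grid extremes); the median depends on the grid and is reported for
    the grid in ``gamma``.
    """
    if len(gamma.grid) < 2:
        raise ValueError("grid must have at least 2 points")
    corr = gamma.correlations()
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return {
        "min": float(off.min()),
        "median": float(np.median(off)),
        "correlations": corr,
    }


def _gamma_diag(G_flat: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Diagonal of Gamma for (draws, 3) flattened G entries; (draws, grid)."""
    f0 = Phi[:, 0]
    f1 = Phi[:, 1]
    return (
        np.outer(G_flat[:, 0], f0 * f0)
        + 2.0 * np.outer(G_flat[:, 1], f0 * f1)
        + np.outer(G_flat[:, 2], f1 * f1)
    )


def heritability_curve(
    gamma: GammaMatrix,
    sigma2_pe: float,
    sigma2_e,
    class_map,
) -> np.ndarray:
    """Pointwise heritability across the environmental gradient.

    ``class_map`` assigns each grid point to a residual class 1..5, so
    the curve is piecewise ("broken-line") at the class boundaries when
    the residual variances differ.
    """
    sigma2_e = np.asarray(sigma2_e, dtype=float)
    class_map = np.asarray(class_map, dtype=int)
    if len(class_map) != len(gamma.grid):
        raise ValueError("class_map must cover every grid point")
    diag = np.diag(gamma.Gamma)
    denom = diag + sigma2_pe + sigma2_e[class_map - 1]
    if np.any(denom == 0):
        raise ValueError("zero total variance in the heritability denominator")
    return diag / denom


def heritability_bands(
    chain: pd.DataFrame,
    class_boundaries,
    grid=None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior mean and credible band of h2(x), draw by draw.

    Each stored draw of (G, sigma2_pe, sigma2_e) is pushed through the
    heritability formula, matching the posterior-mean-with-95%-interval
    presentation of environment-specific heritabilities.
    """
    x = _as_grid(grid)
    Phi = phi_matrix(x)
    classes = assign_residual_class(x, class_boundaries)
    Gflat = chain[["sigma2_a0", "sigma_a01", "sigma2_a1"]].to_numpy()
    diag = _gamma_diag(Gflat, Phi)  # (draws, grid)
    pe = chain["sigma2_pe"].to_numpy()[:, None]
    e_cols = chain[[f"sigma2_e{t}" for t in range(1, 6)]].to_numpy()
    e = e_cols[:, classes - 1]
    h2 = diag / (diag + pe + e)
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(h2, [alpha, 1.0 - alpha], axis=0)
    return pd.DataFrame(
        {"x": x, "class": classes, "mean": h2.mean(axis=0), "lo": lo, "hi": hi}
    )


def reaction_norms(
    intercept: float,
    slope: float,
    grid=None,
    individuals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Linear reaction norms on the trait scale over the gradient.

    The population norm is ``r(x) = alpha*phi0 + beta*phi1(x)``; an
    individual adds its genetic deviations, ``r_l(x) = (alpha + a0_l)
    phi0 + (beta + a1_l) phi1(x)``.  ``individuals`` needs columns
    ``animal, a0, a1``.
    """
    x = _as_grid(grid)
    Phi = phi_matrix(x)
    out = pd.DataFrame({"x": x})
    out["population"] = intercept * Phi[:, 0] + slope * Phi[:, 1]
    if individuals is not None:
        for row in individuals.itertuples(index=False):
            out[str(row.animal)] = (intercept + row.a0) * Phi[:, 0] + (
                slope + row.a1
            ) * Phi[:, 1]
    return out


def select_extreme_sires(
    gebv: pd.DataFrame,
    pedigree: pd.DataFrame,
    record_env: pd.DataFrame,
    min_daughters: int = 50,
    k: int = 4,
    range_frac: float = 0.6,
    min_classes: int = 4,
    slope_offset: float = 0.0,
) -> dict:
    """Rank eligible sires by reaction-norm slope; return the extremes.

    A sire is eligible when (a) at least ``min_daughters`` recorded
    daughters and (b) the daughters' records span the environmental
    gradient — covering at least ``range_frac`` of the observed covariate
    range with records in at least ``min_classes`` of the 5 residual
    classes — so a flat-looking norm cannot be an artifact of records
    concentrated under comfortable conditions.  The top-``k`` slopes are
    the most heat-tolerant sires, the bottom-``k`` the most susceptible.

    Parameters
    ----------
    gebv : DataFrame
        ``animal, a0, a1`` posterior means.
    record_env : DataFrame
        One row per record: ``sow, x, class``.
    slope_offset : float
        The fixed regression coefficient beta, added so reported slopes
        are total (beta + a1).
    """
    sire_of = dict(zip(pedigree["animal"], pedigree["sire"]))
    env = record_env.copy()
    env["sire"] = env["sow"].map(sire_of)
    env = env.loc[env["sire"].notna() & (env["sire"] != 0)]
    x_lo, x_hi = record_env["x"].min(), record_env["x"].max()
    full_range = x_hi - x_lo

    rows = []
    for sire, grp in env.groupby("sire"):
        n_daughters = grp["sow"].nunique()
        span = grp["x"].max() - grp["x"].min()
        n_classes = grp["class"].nunique()
        rows.append(
            {
                "animal": sire,
                "daughters": n_daughters,
                "env_span_frac": span / full_range if full_range > 0 else 0.0,
                "n_classes": n_classes,
                "eligible": (
                    n_daughters >= min_daughters
                    and span >= range_frac * full_range
                    and n_classes >= min_classes
                ),
            }
        )
    sires = pd.DataFrame(rows)
    sires = sires.merge(gebv, on="animal", how="left")
    sires["slope"] = slope_offset + sires["a1"]
    eligible = sires.loc[sires["eligible"]].sort_values("slope", ascending=False)
    if len(eligible) < 2 * k:
        warnings.warn(
            f"only {len(eligible)} eligible sires for k={k}; returning what exists"
        )
    return {
        "eligible": eligible.reset_index(drop=True),
        "tolerant": eligible.head(k).reset_index(drop=True),
        "susceptible": eligible.tail(k).sort_values("slope").reset_index(drop=True),
    }


# ---------------------------------------------------------------------------


@dataclass
class ReactionNormResults:
    """Posterior output of :meth:`heatnorm.model.ReactionNormModel.fit`."""

    model: object
    chain: pd.DataFrame
    beta_mean: np.ndarray
    fixed_names: list
    a_mean: np.ndarray
    pe_mean: np.ndarray
    animal_ids: np.ndarray
    sow_ids: np.ndarray
    class_boundaries: np.ndarray
    env_stats: dict
    metadata: dict
    a_draws: np.ndarray | None = None
    beta_draws: np.ndarray | None = None
    _gebv_cache: pd.DataFrame | None = field(default=None, repr=False)

    # -- variance components ------------------------------------------------

    def varcomp_mean(self) -> VarianceComponents:
        return VarianceComponents.from_array(self.chain.mean().to_numpy())

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        alpha = 0.5 * (1.0 - level)
        qs = self.chain.quantile([alpha, 1.0 - alpha]).T
        qs.columns = ["lo", "hi"]
        return qs

    def geweke(self) -> pd.Series:
        from heatnorm.model import geweke_diagnostic

        return geweke_diagnostic(self.chain)

    # -- derived genetic parameters ------------------------------------------

    def gamma(self, grid=None) -> GammaMatrix:
        return gamma_matrix(self.varcomp_mean().G, grid=grid)

    def correlation_summary(self, grid=None) -> dict:
        return correlation_summary(self.gamma(grid=grid))

    def heritability(self, grid=None, level: float = 0.95) -> pd.DataFrame:
        return heritability_bands(
            self.chain, self.class_boundaries, grid=grid, level=level
        )

    def gebv(self) -> pd.DataFrame:
        if self._gebv_cache is None:
            self._gebv_cache = pd.DataFrame(
                {
                    "animal": self.animal_ids,
                    "a0": self.a_mean[:, 0],
                    "a1": self.a_mean[:, 1],
                }
            )
        return self._gebv_cache

    def reaction_norms(self, ids=None, grid=None) -> pd.DataFrame:
        """Population norm plus norms for the requested animal ids."""
        individuals = None
        if ids is not None:
            gebv = self.gebv().set_index("animal")
            missing = [i for i in ids if i not in gebv.index]
            if missing:
                raise ValueError(f"unknown animal ids: {missing[:5]}")
            individuals = gebv.loc[list(ids)].reset_index()
        return reaction_norms(
            intercept=float(self.beta_mean[0]),
            slope=float(self.beta_mean[1]),
            grid=grid,
            individuals=individuals,
        )

    def select_extreme_sires(self, min_daughters: int = 50, k: int = 4, **kwargs) -> dict:
        ds = self.model.design
        record_env = pd.DataFrame(
            {
                "sow": ds.sow_ids[ds.rec_pe],
                "x": ds.x,
                "class": ds.rec_class + 1,
            }
        )
        return select_extreme_sires(
            self.gebv(),
            self.model.pedigree,
            record_env,
            min_daughters=min_daughters,
            k=k,
            slope_offset=float(self.beta_mean[1]),
            **kwargs,
        )

    # -- presentation --------------------------------------------------------

    def summary(self, level: float = 0.95) -> str:
        """Plain-text summary of the fit and posterior variance components."""
        md = self.metadata
        ci = self.credible_interval(level)
        table = pd.DataFrame(
            {
                "mean": self.chain.mean(),
                "sd": self.chain.std(ddof=1),
                "lo": ci["lo"],
                "hi": ci["hi"],
            }
        )
        corr = self.correlation_summary()
        lines = [
            "Reaction-norm random-regression model (single-step GBLUP)",
            "=" * 60,
            f"trait: {md['trait']}    covariate: {md['covariate']}",
            f"records: {md['n_records']}    animals: {md['n_animals']}"
            f"    genotyped: {md['n_genotyped']}",
            f"chain: {md['iterations']} iterations, burn-in {md['burn_in']},"
            f" thin {md['thin']} ({len(self.chain)} stored draws)",
            "",
            f"Posterior variance components ({int(level * 100)}% credible interval)",
            table.to_string(float_format=lambda v: f"{v:10.4f}"),
            "",
            "Across-environment genetic correlations:"
            f" min {corr['min']:.3f}, median {corr['median']:.3f}",
            f"Fixed regression: alpha = {self.beta_mean[0]:.4f} (phi0 scale),"
            f" beta = {self.beta_mean[1]:.4f} (phi1 scale)",
        ]
        return "\n".join(lines)
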