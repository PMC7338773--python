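"""Single-step reaction-norm random-regression model fitted by Gibbs sampling.

The model for one trait regressed on one standardized environmental
covariate x (via the normalized order-1 Legendre basis phi0, phi1) is::

    y = alpha*phi0 + beta*phi1(x) + CG + parity
        + a0*phi0 + a1*phi1(x) + pe + e

with (a0, a1) ~ N(0, H (x) G) over all pedigree animals, pe ~ N(0, I
sigma2_pe) per sow, and residuals heteroskedastic over five covariate
quintile classes, e_t ~ N(0, sigma2_e[t]).  Contemporary group (CG) is
the sow birth year; parity has five classes (1, 2, 3, 4, 5+).

The sampler is a single-site Gibbs scheme with the genetic effects
blocked per animal (each (a0, a1) pair drawn jointly from its bivariate
conditional), scalar draws for fixed and permanent-environment effects,
an inverse-Wishart conditional for G and scaled inverse-chi-square
conditionals for sigma2_pe and each residual class.  Location sweeps run
in a compiled kernel; one sweep costs O(records + q^2) where q is the
number of pedigree animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import invwishart

from heatnorm import env as env_mod
from heatnorm.basis import legendre_basis
from heatnorm.components import N_RESIDUAL_CLASSES, Priors, VarianceComponents
from heatnorm.relationship import (
    GenotypeSet,
    HInverse,
    blend_G,
    build_A,
    build_G_vanraden2,
    build_H_inverse,
)
from heatnorm.results import ReactionNormResults


@dataclass
class ModelSpec:
    """Trait, covariate and effect-coding choices for one fit."""

    trait: str = "tnb"
    covariate: str = "THI_i10"
    cg_col: str = "birth_year"
    parity_col: str = "parity_class"
    env_min: float | None = None  # override observed standardization range
    env_max: float | None = None
    class_boundaries: np.ndarray | None = None


@dataclass
class Design:
    """Dense design structure for the sampler and the MME oracle."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    phi: np.ndarray  # (n, 2) Legendre covariables per record
    rec_animal: np.ndarray  # record -> animal index (H ordering)
    rec_pe: np.ndarray  # record -> sow index
    rec_class: np.ndarray  # record -> residual class 0..4
    animal_ids: np.ndarray
    sow_ids: np.ndarray
    x: np.ndarray
    env_stats: dict
    class_boundaries: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_pe(self) -> int:
        return len(self.sow_ids)


def build_design(
    records: pd.DataFrame,
    env_table,
    spec: ModelSpec,
    animal_ids: np.ndarray,
) -> Design:
    """Assemble the record-level design for one trait/covariate fit.

    ``env_table`` may be an :class:`~heatnorm.env.EnvCovariateTable` or a
    plain DataFrame with ``sow``/``parity`` keys; the covariate column is
    merged onto the records, standardized to [-1, 1] and quintile-classed.
    Fixed effects use reference (drop-first) dummy coding so the overall
    intercept (on the phi0 scale) stays identifiable.
    """
    env_df = env_table.data if hasattr(env_table, "data") else env_table
    if spec.covariate not in env_df.columns:
        raise ValueError(f"covariate {spec.covariate!r} not in the covariate table")
    merged = records.merge(
        env_df[["sow", "parity", spec.covariate]], on=["sow", "parity"], how="left"
    )
    if merged[spec.covariate].isna().any():
        missing = merged.loc[merged[spec.covariate].isna(), ["sow", "parity"]]
        raise ValueError(f"records without covariate values:\n{missing.head()}")

    x, stats = env_mod.standardize_env(
        merged[spec.covariate].to_numpy(), vmin=spec.env_min, vmax=spec.env_max
    )
    x = np.clip(x, -1.0, 1.0)
    boundaries = (
        np.asarray(spec.class_boundaries, dtype=float)
        if spec.class_boundaries is not None
        else env_mod.quintile_boundaries(x)
    )
    classes = env_mod.assign_residual_class(x, boundaries) - 1
    phi0, phi1 = legendre_basis(x)
    phi = np.column_stack([phi0, phi1])

    cols = [phi0, phi1]
    names = ["alpha(phi0)", "beta(phi1)"]
    for eff, col in (("cg", spec.cg_col), ("parity", spec.parity_col)):
        levels = np.sort(merged[col].unique())
        for lev in levels[1:]:
            cols.append((merged[col] == lev).to_numpy(float))
            names.append(f"{eff}[{lev}]")
    X = np.column_stack(cols)

    lookup = {a: i for i, a in enumerate(np.asarray(animal_ids).tolist())}
    sows = merged["sow"].to_numpy()
    unmatched = sorted({s for s in sows.tolist() if s not in lookup})
    if unmatched:
        raise ValueError(f"sow ids absent from the pedigree/H ordering: {unmatched[:5]}")
    rec_animal = np.array([lookup[s] for s in sows], dtype=np.int64)
    uniq, rec_pe = np.unique(sows, return_inverse=True)

    return Design(
        y=np.ascontiguousarray(merged[spec.trait].to_numpy(float)),
        X=np.ascontiguousarray(X),
        fixed_names=names,
        phi=np.ascontiguousarray(phi),
        rec_animal=rec_animal,
        rec_pe=rec_pe.astype(np.int64),
        rec_class=classes.astype(np.int64),
        animal_ids=np.asarray(animal_ids),
        sow_ids=uniq,
        x=x,
        env_stats=stats,
        class_boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# compiled sampler kernel


@njit(cache=True)
def _seed_kernel(seed):  # pragma: no cover
    np.random.seed(seed)


@njit(cache=True)
def _gibbs_sweep(
    y, X, phi, rec_animal, rec_pe, rec_class,
    a_ptr, a_rec, p_ptr, p_rec, pe_of_animal, pe_loose,
    Hinv, beta, a, pe, e,
    g00, g01, g11,  # entries of G^{-1}
    inv_s2e, inv_s2pe,
    out_sse, out_scalars,
):  # pragma: no cover - compiled
    n = y.shape[0]
    p = X.shape[1]
    q = a.shape[0]
    npe = pe.shape[0]

    # full residual recompute guards against incremental drift
    for i in range(n):
        acc = y[i]
        for j in range(p):
            acc -= X[i, j] * beta[j]
        l = rec_animal[i]
        acc -= phi[i, 0] * a[l, 0] + phi[i, 1] * a[l, 1]
        acc -= pe[rec_pe[i]]
        e[i] = acc

    # fixed effects (flat prior)
    for j in range(p):
        c = 0.0
        r = 0.0
        for i in range(n):
            w = inv_s2e[rec_class[i]]
            xi = X[i, j]
            if xi != 0.0:
                c += xi * xi * w
                r += xi * w * (e[i] + xi * beta[j])
        new = r / c + np.random.normal() / np.sqrt(c)
        delta = beta[j] - new
        if delta != 0.0:
            for i in range(n):
                if X[i, j] != 0.0:
                    e[i] += X[i, j] * delta
        beta[j] = new

    # Animal effects, blocked per animal.  A recorded sow's permanent-
    # environment effect is drawn jointly with her (a0, a1) pair (3x3
    # conditional) — the sow-level a0/pe confounding mixes poorly under
    # scalar updates.  Animals without records (or without a pe level)
    # get the plain 2x2 genetic block.
    C = np.zeros((3, 3))
    r3 = np.zeros(3)
    L = np.zeros((3, 3))
    u3 = np.zeros(3)
    mu = np.zeros(3)
    wv = np.zeros(3)
    z3 = np.zeros(3)
    for l in range(q):
        m = pe_of_animal[l]
        d = 3 if m >= 0 else 2
        for ii in range(3):
            r3[ii] = 0.0
            for jj in range(3):
                C[ii, jj] = 0.0
        for k in range(a_ptr[l], a_ptr[l + 1]):
            i = a_rec[k]
            w = inv_s2e[rec_class[i]]
            f0 = phi[i, 0]
            f1 = phi[i, 1]
            et = e[i] + f0 * a[l, 0] + f1 * a[l, 1]
            if d == 3:
                et += pe[m]
            C[0, 0] += f0 * f0 * w
            C[0, 1] += f0 * f1 * w
            C[1, 1] += f1 * f1 * w
            r3[0] += f0 * w * et
            r3[1] += f1 * w * et
            if d == 3:
                C[0, 2] += f0 * w
                C[1, 2] += f1 * w
                C[2, 2] += w
                r3[2] += w * et
        s0 = 0.0
        s1 = 0.0
        for j in range(q):
            s0 += Hinv[l, j] * a[j, 0]
            s1 += Hinv[l, j] * a[j, 1]
        hll = Hinv[l, l]
        s0 -= hll * a[l, 0]
        s1 -= hll * a[l, 1]
        r3[0] -= g00 * s0 + g01 * s1
        r3[1] -= g01 * s0 + g11 * s1
        C[0, 0] += hll * g00
        C[0, 1] += hll * g01
        C[1, 1] += hll * g11
        if d == 3:
            C[2, 2] += inv_s2pe
        C[1, 0] = C[0, 1]
        C[2, 0] = C[0, 2]
        C[2, 1] = C[1, 2]
        # d x d Cholesky; solve for the mean; sample new = mu + L^{-T} z
        for ii in range(d):
            acc = C[ii, ii]
            for kk in range(ii):
                acc -= L[ii, kk] * L[ii, kk]
            L[ii, ii] = np.sqrt(acc)
            for jj in range(ii + 1, d):
                acc = C[jj, ii]
                for kk in range(ii):
                    acc -= L[jj, kk] * L[ii, kk]
                L[jj, ii] = acc / L[ii, ii]
        for ii in range(d):
            acc = r3[ii]
            for kk in range(ii):
                acc -= L[ii, kk] * u3[kk]
            u3[ii] = acc / L[ii, ii]
        for ii in range(d - 1, -1, -1):
            acc = u3[ii]
            for kk in range(ii + 1, d):
                acc -= L[kk, ii] * mu[kk]
            mu[ii] = acc / L[ii, ii]
        for ii in range(d):
            z3[ii] = np.random.normal()
        for ii in range(d - 1, -1, -1):
            acc = z3[ii]
            for kk in range(ii + 1, d):
                acc -= L[kk, ii] * wv[kk]
            wv[ii] = acc / L[ii, ii]
        new0 = mu[0] + wv[0]
        new1 = mu[1] + wv[1]
        d0 = a[l, 0] - new0
        d1 = a[l, 1] - new1
        dpe = 0.0
        if d == 3:
            newpe = mu[2] + wv[2]
            dpe = pe[m] - newpe
            pe[m] = newpe
        for k in range(a_ptr[l], a_ptr[l + 1]):
            i = a_rec[k]
            e[i] += phi[i, 0] * d0 + phi[i, 1] * d1 + dpe
        a[l, 0] = new0
        a[l, 1] = new1

    # permanent-environment levels not tied to an animal block (rare)
    for mk in range(pe_loose.shape[0]):
        m = pe_loose[mk]
        c = inv_s2pe
        r = 0.0
        for k in range(p_ptr[m], p_ptr[m + 1]):
            i = p_rec[k]
            w = inv_s2e[rec_class[i]]
            c += w
            r += w * (e[i] + pe[m])
        new = r / c + np.random.normal() / np.sqrt(c)
        delta = pe[m] - new
        for k in range(p_ptr[m], p_ptr[m + 1]):
            e[p_rec[k]] += delta
        pe[m] = new

    # sufficient statistics for the variance conditionals
    for t in range(out_sse.shape[0]):
        out_sse[t] = 0.0
    for i in range(n):
        out_sse[rec_class[i]] += e[i] * e[i]
    pp = 0.0
    for m in range(npe):
        pp += pe[m] * pe[m]
    s00 = 0.0
    s01 = 0.0
    s11 = 0.0
    for l in range(q):
        u0 = 0.0
        u1 = 0.0
        for j in range(q):
            u0 += Hinv[l, j] * a[j, 0]
            u1 += Hinv[l, j] * a[j, 1]
        s00 += a[l, 0] * u0
        s01 += a[l, 0] * u1
        s11 += a[l, 1] * u1
    out_scalars[0] = pp
    out_scalars[1] = s00
    out_scalars[2] = s01
    out_scalars[3] = s11


def _records_csr(index: np.ndarray, n_levels: int):
    order = np.argsort(index, kind="stable")
    counts = np.bincount(index, minlength=n_levels)
    ptr = np.concatenate([[0], np.cumsum(counts)])
    return ptr.astype(np.int64), order.astype(np.int64)


class ReactionNormModel:
    """Reaction-norm random-regression model for one trait and covariate.

    Parameters
    ----------
    records : DataFrame
        Edited phenotype records (``sow, parity, parity_class, birth_year``
        plus trait columns).
    env_table : EnvCovariateTable or DataFrame
        Environmental covariates keyed by (sow, parity).
    pedigree : DataFrame
        ``animal, sire, dam`` (0 = unknown parent).
    genotypes : GenotypeSet, optional
        QC'd genotypes.  When given, the relationship structure is the
        single-step ``H^{-1}`` with a VanRaden-2 genomic matrix blended
        into the pedigree block; otherwise plain ``A^{-1}`` is used.
    spec : ModelSpec
    omega : float
        Blending weight for ``G* = omega G + (1-omega) A22``.
    h_inverse : HInverse, optional
        Precomputed inverse relationship matrix (reused across the
        covariate screen); overrides ``genotypes``.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        env_table,
        pedigree: pd.DataFrame,
        genotypes: GenotypeSet | None = None,
        spec: ModelSpec | None = None,
        omega: float = 0.95,
        max_generations: int = 10,
        h_inverse: HInverse | None = None,
    ):
        self.spec = spec if spec is not None else ModelSpec()
        self.pedigree = pedigree
        if h_inverse is None:
            if genotypes is not None and genotypes.n_animals > 0:
                amat = build_A(pedigree, max_generations=max_generations)
                G = build_G_vanraden2(genotypes)
                G_star = blend_G(G, amat.block(G.ids), omega=omega)
                h_inverse = build_H_inverse(
                    pedigree, G_star, max_generations=max_generations
                )
            else:
                h_inverse = build_H_inverse(
                    pedigree, None, max_generations=max_generations
                )
        self.h_inverse = h_inverse
        self.design = build_design(records, env_table, self.spec, h_inverse.ids)
        self._Hinv_dense = None

    @classmethod
    def from_simulation(cls, sim, spec: ModelSpec | None = None, **kwargs):
        """Convenience constructor from a :class:`~heatnorm.simulate.SimData`."""
        from heatnorm.env import build_interval_covariates
        from heatnorm.relationship import qc_genotypes

        env_table = build_interval_covariates(sim.weather, sim.records)
        if spec is None:
            spec = ModelSpec(trait=sim.config.trait, covariate=sim.truth["env_column"])
        genotypes, _ = qc_genotypes(sim.genotypes)
        return cls(
            sim.records, env_table, sim.pedigree, genotypes=genotypes,
            spec=spec, **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def _hinv(self) -> np.ndarray:
        if self._Hinv_dense is None:
            self._Hinv_dense = np.ascontiguousarray(self.h_inverse.to_dense())
        return self._Hinv_dense

    def _start_varcomp(self) -> VarianceComponents:
        vy = float(np.var(self.design.y))
        return VarianceComponents(
            G=np.diag([0.2 * vy, 0.1 * vy]),
            sigma2_pe=0.1 * vy,
            sigma2_e=np.full(N_RESIDUAL_CLASSES, 0.5 * vy),
        )

    def fit(
        self,
        iterations: int = 20_000,
        burn_in: int = 4_000,
        thin: int = 20,
        seed: int = 0,
        priors: Priors | None = None,
        start: VarianceComponents | None = None,
        update_variances: bool = True,
        store_solutions: bool = False,
    ) -> ReactionNormResults:
        """Run the Gibbs sampler and return posterior results.

        Draw storage follows the (iterations - burn_in) / thin rule; the
        chain is bit-reproducible for a fixed seed.  With
        ``update_variances=False`` the variance components stay at
        ``start`` and only location effects are sampled (used to check
        the sampler against direct mixed-model-equation solutions).
        """
        if burn_in >= iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if priors is None:
            priors = Priors.scaled(float(np.var(self.design.y)))
        vc = start if start is not None else self._start_varcomp()
        ds = self.design
        Hinv = self._hinv()
        q = ds.n_animals

        a_ptr, a_rec = _records_csr(ds.rec_animal, q)
        p_ptr, p_rec = _records_csr(ds.rec_pe, ds.n_pe)
        # each pe level (sow) is blocked with her own animal effect
        pe_of_animal = np.full(q, -1, dtype=np.int64)
        for m in range(ds.n_pe):
            pe_of_animal[ds.rec_animal[p_rec[p_ptr[m]]]] = m
        pe_loose = np.setdiff1d(
            np.arange(ds.n_pe, dtype=np.int64), pe_of_animal[pe_of_animal >= 0]
        )
        class_counts = np.bincount(ds.rec_class, minlength=N_RESIDUAL_CLASSES)
        if np.any(class_counts == 0):
            warnings.warn("empty residual class; its variance stays at the prior")

        beta = np.zeros(ds.X.shape[1])
        beta[0] = float(np.mean(ds.y)) / ds.phi[0, 0]
        a = np.zeros((q, 2))
        pe = np.zeros(ds.n_pe)
        e = np.zeros(ds.n_records)
        out_sse = np.zeros(N_RESIDUAL_CLASSES)
        out_scalars = np.zeros(4)

        G = vc.G.copy()
        sigma2_pe = float(vc.sigma2_pe)
        sigma2_e = vc.sigma2_e.copy()

        _seed_kernel(seed % (2**31 - 1))
        rng = np.random.default_rng([seed, 7])

        n_store = (iterations - burn_in + thin - 1) // thin
        vdraws = np.zeros((n_store, 9))
        beta_mean = np.zeros_like(beta)
        a_mean = np.zeros_like(a)
        pe_mean = np.zeros_like(pe)
        a_draws = np.zeros((n_store, q, 2)) if store_solutions else None
        beta_draws = np.zeros((n_store, len(beta))) if store_solutions else None
        stored = 0

        for it in range(iterations):
            Ginv = np.linalg.inv(G)
            _gibbs_sweep(
                ds.y, ds.X, ds.phi, ds.rec_animal, ds.rec_pe, ds.rec_class,
                a_ptr, a_rec, p_ptr, p_rec, pe_of_animal, pe_loose,
                Hinv, beta, a, pe, e,
                Ginv[0, 0], Ginv[0, 1], Ginv[1, 1],
                1.0 / sigma2_e, 1.0 / sigma2_pe,
                out_sse, out_scalars,
            )
            if update_variances:
                S_a = np.array(
                    [
                        [out_scalars[1], out_scalars[2]],
                        [out_scalars[2], out_scalars[3]],
                    ]
                )
                G = np.asarray(
                    invwishart.rvs(
                        df=priors.nu_g + q, scale=priors.S_g + S_a, random_state=rng
                    )
                ).reshape(2, 2)
                sigma2_pe = (priors.nu_s * priors.s2_pe + out_scalars[0]) / rng.chisquare(
                    priors.nu_s + ds.n_pe
                )
                for t in range(N_RESIDUAL_CLASSES):
                    sigma2_e[t] = (priors.nu_s * priors.s2_e + out_sse[t]) / rng.chisquare(
                        priors.nu_s + class_counts[t]
                    )
            if it >= burn_in and (it - burn_in) % thin == 0:
                vdraws[stored] = VarianceComponents(
                    G=G.copy(), sigma2_pe=sigma2_pe, sigma2_e=sigma2_e.copy()
                ).as_array()
                beta_mean += beta
                a_mean += a
                pe_mean += pe
                if store_solutions:
                    a_draws[stored] = a
                    beta_draws[stored] = beta
                stored += 1

        beta_mean /= stored
        a_mean /= stored
        pe_mean /= stored
        from heatnorm.components import VARCOMP_COLUMNS

        chain = pd.DataFrame(vdraws[:stored], columns=list(VARCOMP_COLUMNS))
        return ReactionNormResults(
            model=self,
            chain=chain,
            beta_mean=beta_mean,
            fixed_names=ds.fixed_names,
            a_mean=a_mean,
            pe_mean=pe_mean,
            animal_ids=ds.animal_ids,
            sow_ids=ds.sow_ids,
            class_boundaries=ds.class_boundaries,
            env_stats=ds.env_stats,
            metadata={
                "iterations": iterations,
                "burn_in": burn_in,
                "thin": thin,
                "seed": seed,
                "n_records": ds.n_records,
                "n_animals": ds.n_animals,
                "n_genotyped": self.h_inverse.n_genotyped,
                "trait": self.spec.trait,
                "covariate": self.spec.covariate,
            },
            a_draws=a_draws,
            beta_draws=beta_draws,
        )

    # -- direct solver oracle ----------------------------------------------

    def mme_solutions(self, varcomp: VarianceComponents):
        """Solve the mixed-model equations at fixed variance components.

        Returns the joint generalized least-squares solutions
        ``(beta, a, pe)`` with ``a`` as a (q, 2) array in H ordering.
        Dense; intended for modest problem sizes and cross-checks.
        """
        ds = self.design
        q = ds.n_animals
        n = ds.n_records
        Za = np.zeros((n, 2 * q))
        Za[np.arange(n), ds.rec_animal] = ds.phi[:, 0]
        Za[np.arange(n), q + ds.rec_animal] = ds.phi[:, 1]
        Zp = np.zeros((n, ds.n_pe))
        Zp[np.arange(n), ds.rec_pe] = 1.0
        W = np.hstack([ds.X, Za, Zp])
        w = 1.0 / varcomp.sigma2_e[ds.rec_class]
        C = (W * w[:, None]).T @ W
        rhs = (W * w[:, None]).T @ ds.y
        npar = W.shape[1]
        prior = np.zeros((npar, npar))
        p0 = ds.X.shape[1]
        Ginv = np.linalg.inv(varcomp.G)
        Hinv = self._hinv()
        prior[p0 : p0 + 2 * q, p0 : p0 + 2 * q] = np.kron(Ginv, Hinv)
        prior[p0 + 2 * q :, p0 + 2 * q :] = np.eye(ds.n_pe) / varcomp.sigma2_pe
        sol = np.linalg.solve(C + prior, rhs)
        beta = sol[:p0]
        a = np.column_stack([sol[p0 : p0 + q], sol[p0 + q : p0 + 2 * q]])
        pe = sol[p0 + 2 * q :]
        return beta, a, pe


# ---------------------------------------------------------------------------
# diagnostics and screening


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain segment at frequency zero.

    Bartlett-windowed autocovariance sum with lag cutoff ``sqrt(n)``; the
    standard plug-in for Geweke-style MCMC standard errors.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    max_lag = max(1, int(np.sqrt(n)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for k in range(1, max_lag + 1):
        gk = float(xc[k:] @ xc[:-k]) / n
        s += 2.0 * (1.0 - k / (max_lag + 1.0)) * gk
    return s


def geweke_diagnostic(chain, first: float = 0.1, last: float = 0.5) -> pd.Series:
    """Geweke convergence z-scores comparing early and late chain segments.

    For each component, the means of the first ``first`` fraction and the
    last ``last`` fraction of stored draws are compared with a z statistic
    whose variance uses spectral-density estimates (so autocorrelation is
    accounted for).  Values beyond ~|2| flag non-stationarity.
    """
    if isinstance(chain, pd.DataFrame):
        df = chain
    else:
        arr = np.atleast_2d(np.asarray(chain, dtype=float))
        if arr.shape[0] == 1:
            arr = arr.T
        df = pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
    n = len(df)
    if n < 100:
        raise ValueError(f"chain too short for the Geweke test ({n} < 100 draws)")
    na = int(first * n)
    nb = int(last * n)
    z = {}
    for col in df.columns:
        xa = df[col].to_numpy()[:na]
        xb = df[col].to_numpy()[-nb:]
        va = _spectral_density_zero(xa) / na
        vb = _spectral_density_zero(xb) / nb
        denom = np.sqrt(va + vb)
        if denom == 0.0:
            raise ValueError(f"component {col!r} has zero variance; z undefined")
        z[col] = (xa.mean() - xb.mean()) / denom
    return pd.Series(z)


def screen_env(
    records: pd.DataFrame,
    env_table,
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet | None = None,
    covariates: list | None = None,
    trait: str = "tnb",
    iterations: int = 30_000,
    burn_in: int = 10_000,
    thin: int = 10,
    seed: int = 0,
    sires_only: bool = True,
    omega: float = 0.95,
) -> pd.DataFrame:
    """Rank candidate covariates by the posterior mean slope variance.

    One reduced fit per covariate; by default only sire genotypes enter
    the relationship matrix, which makes each fit markedly cheaper while
    still detecting the presence of GxE.  Returns a table with one row
    per covariate, sorted by ``sigma2_a1`` descending — the top row is
    the covariate selected for the full fit.  Degenerate (constant)
    covariates are skipped with a warning.
    """
    env_df = env_table.data if hasattr(env_table, "data") else env_table
    if covariates is None:
        covariates = [c for c in env_df.columns if c not in ("sow", "parity")]

    geno = genotypes
    if geno is not None and sires_only:
        sire_ids = set(pedigree.loc[pedigree["sire"] != 0, "sire"].tolist())
        keep = [g for g in geno.ids.tolist() if g in sire_ids]
        geno = geno.subset_animals(keep) if keep else None
    if geno is not None and geno.n_animals > 0:
        amat = build_A(pedigree)
        G = build_G_vanraden2(geno)
        G_star = blend_G(G, amat.block(G.ids), omega=omega)
        h_inverse = build_H_inverse(pedigree, G_star)
    else:
        h_inverse = build_H_inverse(pedigree, None)

    rows = []
    for k, cov in enumerate(covariates):
        try:
            model = ReactionNormModel(
                records, env_df, pedigree,
                spec=ModelSpec(trait=trait, covariate=cov),
                h_inverse=h_inverse,
            )
        except ValueError as err:
            warnings.warn(f"skipping covariate {cov!r}: {err}")
            continue
        res = model.fit(
            iterations=iterations, burn_in=burn_in, thin=thin, seed=seed + k
        )
        post = res.chain.mean()
        rows.append(
            {
                "covariate": cov,
                "sigma2_a0": post["sigma2_a0"],
                "sigma_a01": post["sigma_a01"],
                "sigma2_a1": post["sigma2_a1"],
                "sigma2_a1_sd": res.chain["sigma2_a1"].std(ddof=1),
            }
        )
    out = pd.DataFrame(rows).sort_values("sigma2_a1", ascending=False)
    return out.reset_index(drop=True)
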