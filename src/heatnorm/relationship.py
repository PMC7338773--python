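"""Pedigree, genomic and single-step relationship matrices.

The single-step mixed model needs the inverse of the combined relationship
matrix

.. math::

    H^{-1} = A^{-1} + \\begin{bmatrix} 0 & 0 \\\\
        0 & G^{*-1} - A_{22}^{-1} \\end{bmatrix}

in the (non-genotyped, genotyped) animal ordering, where **A** is the
pedigree numerator relationship matrix (tabular method with inbreeding),
``A22`` its genotyped block, and ``G*`` a genomic relationship matrix
(VanRaden method 2) blended with ``A22`` to guarantee invertibility.
Published expressions of this quantity sometimes print ``A11^{-1}`` as the
leading term; the corrected, standard form with the full ``A^{-1}`` is
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.stats import chi2


# ---------------------------------------------------------------------------
# genotype containers and QC


@dataclass
class GenotypeSet:
    """SNP dosages {0,1,2} (-1 = missing) for a set of animals.

    ``dosages`` is animals x SNPs; ``chrom``/``pos`` are per-SNP and
    positions must be strictly increasing within chromosome.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match ids/snp_ids")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {c}")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, missing excluded."""
        d = self.dosages
        obs = d >= 0
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))

    def subset_snps(self, keep: np.ndarray) -> "GenotypeSet":
        return GenotypeSet(
            self.ids, self.snp_ids[keep], self.chrom[keep], self.pos[keep],
            self.dosages[:, keep],
        )

    def subset_animals(self, ids) -> "GenotypeSet":
        lookup = {a: i for i, a in enumerate(self.ids.tolist())}
        idx = np.array([lookup[a] for a in ids], dtype=int)
        return GenotypeSet(
            self.ids[idx], self.snp_ids, self.chrom, self.pos, self.dosages[idx]
        )


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg per SNP."""
    d = dosages
    obs = d >= 0
    n = obs.sum(axis=0).astype(float)
    n2 = ((d == 2) & obs).sum(axis=0).astype(float)
    n1 = ((d == 1) & obs).sum(axis=0).astype(float)
    n0 = n - n1 - n2
    p = np.where(n > 0, (2 * n2 + n1) / (2 * np.maximum(n, 1)), 0.0)
    q = 1.0 - p
    exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
    obs_counts = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(exp > 0, (obs_counts - exp) ** 2 / exp, 0.0).sum(axis=0)
    pval = chi2.sf(stat, df=1)
    # monomorphic SNPs carry no HWE information
    pval[(p == 0) | (p == 1)] = 1.0
    return pval


def qc_genotypes(
    genotypes: GenotypeSet,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
):
    """Remove SNPs failing MAF, call-rate or Hardy-Weinberg filters.

    Returns
    -------
    (filtered, report)
        ``report`` counts SNPs failing each filter (a SNP can fail
        several) and the numbers kept/removed.
    """
    d = genotypes.dosages
    obs = d >= 0
    call_rate = obs.mean(axis=0)
    freq = genotypes.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = hwe_pvalues(d)

    fail_maf = maf < maf_min
    fail_cr = call_rate < call_rate_min
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(fail_maf | fail_cr | fail_hwe)
    report = {
        "n_input": genotypes.n_snps,
        "fail_maf": int(fail_maf.sum()),
        "fail_call_rate": int(fail_cr.sum()),
        "fail_hwe": int(fail_hwe.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise ValueError(f"all SNPs removed by quality control: {report}")
    return genotypes.subset_snps(keep), report


# ---------------------------------------------------------------------------
# pedigree relationship matrix


@dataclass
class AMatrix:
    """Numerator relationship matrix with inbreeding coefficients."""

    ids: np.ndarray
    matrix: np.ndarray
    inbreeding: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.inbreeding = np.diag(self.matrix) - 1.0

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids.tolist())}
        return np.array([lookup[a] for a in ids], dtype=int)

    def block(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.matrix[np.ix_(idx, idx)]


@njit(cache=True)
def _tabular(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:  # pragma: no cover
    q = sire.shape[0]
    A = np.zeros((q, q))
    for i in range(q):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
    return A


def _topological_order(ped: pd.DataFrame) -> pd.DataFrame:
    """Order animals so parents precede offspring; error on cycles."""
    ids = ped["animal"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate animal ids in pedigree")
    known = set()
    remaining = ped
    ordered = []
    while len(remaining):
        sire_ok = remaining["sire"].isin(known) | (remaining["sire"] == 0)
        dam_ok = remaining["dam"].isin(known) | (remaining["dam"] == 0)
        ready = sire_ok & dam_ok
        if not ready.any():
            cycle_ids = remaining["animal"].tolist()[:10]
            raise ValueError(f"pedigree cycle or missing parents involving {cycle_ids}")
        batch = remaining.loc[ready]
        ordered.append(batch)
        known.update(batch["animal"].tolist())
        remaining = remaining.loc[~ready]
    return pd.concat(ordered, ignore_index=True)


def _prune_generations(ped: pd.DataFrame, max_generations: int) -> pd.DataFrame:
    """Sever parent links deeper than ``max_generations`` ancestor levels.

    Depth is counted from the youngest animals downwards: animals whose
    descendants-to-leaf chain exceeds the cap become founders.
    """
    ped = ped.copy()
    depth = {a: 1 for a in ped["animal"]}
    # children processed after parents -> walk reversed topological order
    for row in ped.iloc[::-1].itertuples(index=False):
        d = depth[row.animal]
        for parent in (row.sire, row.dam):
            if parent != 0 and parent in depth:
                depth[parent] = max(depth[parent], d + 1)
    too_deep = ped["animal"].map(depth) > max_generations
    ped.loc[too_deep, ["sire", "dam"]] = 0
    return ped


def build_A(pedigree: pd.DataFrame, max_generations: int = 10) -> AMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    Parameters
    ----------
    pedigree : DataFrame
        Columns ``animal, sire, dam`` with 0 marking an unknown parent.
        Any order is accepted; a topological sort is applied and cycles
        raise a ``ValueError`` naming the animals involved.
    max_generations : int
        Ancestors deeper than this many generations (traced from the
        youngest animals) are treated as unknown founders.
    """
    ped = _topological_order(pedigree[["animal", "sire", "dam"]])
    ped = _prune_generations(ped, max_generations)
    ids = ped["animal"].to_numpy()
    lookup = {a: i for i, a in enumerate(ids.tolist())}
    sire = np.array([lookup.get(s, -1) for s in ped["sire"]], dtype=np.int64)
    dam = np.array([lookup.get(d, -1) for d in ped["dam"]], dtype=np.int64)
    return AMatrix(ids=ids, matrix=_tabular(sire, dam))


def a_inverse(pedigree: pd.DataFrame, max_generations: int = 10):
    """Sparse ``A^{-1}`` by Henderson's rules with inbreeding.

    Mendelian-sampling variances use the parents' inbreeding coefficients
    from the tabular method, so the result matches the dense inverse of
    :func:`build_A` to numerical precision.

    Returns
    -------
    (ids, A_inv)
        Animal ordering and the CSR sparse inverse.
    """
    amat = build_A(pedigree, max_generations=max_generations)
    ped = _prune_generations(
        _topological_order(pedigree[["animal", "sire", "dam"]]), max_generations
    )
    ids = amat.ids
    lookup = {a: i for i, a in enumerate(ids.tolist())}
    F = amat.inbreeding
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for row in ped.itertuples(index=False):
        i = lookup[row.animal]
        s = lookup.get(row.sire, -1) if row.sire != 0 else -1
        d = lookup.get(row.dam, -1) if row.dam != 0 else -1
        if s >= 0 and d >= 0:
            mvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            mvar = 0.75 - 0.25 * F[s]
        elif d >= 0:
            mvar = 0.75 - 0.25 * F[d]
        else:
            mvar = 1.0
        alpha = 1.0 / mvar
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p1 in (s, d):
            for p2 in (s, d):
                if p1 >= 0 and p2 >= 0:
                    add(p1, p2, 0.25 * alpha)
    n = len(ids)
    return ids, sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# genomic relationship matrix


@dataclass
class GMatrix:
    """Genomic relationship matrix ``Z D Z'`` (VanRaden method 2)."""

    ids: np.ndarray
    matrix: np.ndarray
    d_weights: np.ndarray
    freqs: np.ndarray
    omega: float = 1.0


def build_G_vanraden2(genotypes: GenotypeSet, freqs: np.ndarray | None = None) -> GMatrix:
    """``G = Z D Z'`` with ``Z = M - 2p`` and ``D_ii = 1/[m 2 p_i (1-p_i)]``.

    Allele frequencies default to the genotyped sample; missing dosages
    are mean-imputed (``2 p_i``, i.e. a zero in ``Z``) before the product.
    """
    if freqs is None:
        freqs = genotypes.allele_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("fixed SNPs present; run qc_genotypes first")
    m = genotypes.n_snps
    d = genotypes.dosages.astype(float)
    d[genotypes.dosages < 0] = np.nan
    Z = d - 2.0 * freqs
    Z[np.isnan(Z)] = 0.0
    D = 1.0 / (m * 2.0 * freqs * (1.0 - freqs))
    G = (Z * D) @ Z.T
    return GMatrix(ids=genotypes.ids.copy(), matrix=G, d_weights=D, freqs=freqs)


def blend_G(G: GMatrix, A22: np.ndarray, omega: float = 0.95) -> GMatrix:
    """``G* = omega G + (1 - omega) A22`` to guarantee invertibility."""
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G.matrix.shape:
        raise ValueError("A22 block not conformable with G")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    return GMatrix(
        ids=G.ids,
        matrix=omega * G.matrix + (1.0 - omega) * A22,
        d_weights=G.d_weights,
        freqs=G.freqs,
        omega=omega,
    )


# ---------------------------------------------------------------------------
# single-step H inverse


@dataclass
class HInverse:
    """Inverse single-step relationship matrix.

    ``ids`` lists non-genotyped animals first, then genotyped animals
    (``n_genotyped`` of them at the tail).  ``matrix`` is CSR sparse.
    """

    ids: np.ndarray
    matrix: sp.csr_matrix
    n_genotyped: int

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()


def build_H_inverse(
    pedigree: pd.DataFrame,
    G_star: GMatrix | None = None,
    max_generations: int = 10,
) -> HInverse:
    """Assemble ``H^{-1}`` from the pedigree and a blended genomic matrix.

    With no genotyped animals (``G_star=None``) the result is exactly the
    sparse ``A^{-1}``; when the genomic block equals ``A22`` the
    correction vanishes and ``H^{-1} = A^{-1}`` up to round-off.
    """
    ids, Ainv = a_inverse(pedigree, max_generations=max_generations)
    if G_star is None or len(G_star.ids) == 0:
        return HInverse(ids=ids, matrix=Ainv.tocsr(), n_genotyped=0)

    gen_ids = list(G_star.ids)
    id_set = set(ids.tolist())
    unknown = [g for g in gen_ids if g not in id_set]
    if unknown:
        raise ValueError(f"genotyped animals not in pedigree: {unknown[:5]}")
    gen_set = set(gen_ids)
    order = [a for a in ids.tolist() if a not in gen_set] + gen_ids
    perm = {a: i for i, a in enumerate(order)}
    old_to_new = np.array([perm[a] for a in ids.tolist()], dtype=int)
    P = sp.coo_matrix(
        (np.ones(len(ids)), (old_to_new, np.arange(len(ids)))),
        shape=(len(ids), len(ids)),
    ).tocsr()
    Ainv_p = P @ Ainv @ P.T

    amat = build_A(pedigree, max_generations=max_generations)
    A22 = amat.block(gen_ids)
    try:
        Gstar_inv = np.linalg.inv(G_star.matrix)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "G* is singular; blend with A22 (blend_G) before inverting"
        ) from err
    A22_inv = np.linalg.inv(A22)

    ng = len(order) - len(gen_ids)
    corr = sp.lil_matrix((len(order), len(order)))
    corr[ng:, ng:] = Gstar_inv - A22_inv
    H_inv = (Ainv_p + corr.tocsr()).tocsr()
    return HInverse(ids=np.asarray(order), matrix=H_inv, n_genotyped=len(gen_ids))
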