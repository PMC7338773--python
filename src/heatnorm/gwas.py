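"""Window-based single-step GWAS on back-solved SNP effects.

Genomic breeding values (one intercept and one slope value per genotyped
animal) are back-solved to per-SNP effects through the VanRaden-2
machinery,

    u_hat = D Z' (Z D Z' + eps I)^{-1} a_hat,

per term.  Direct genomic values of 10-SNP sliding windows (stride 1,
never crossing chromosomes) are computed across genotyped animals, each
window's DGV variance is expressed as a percentage of the whole-genome
DGV variance, the top 1% of windows per term is selected, and selected
windows are tested against a circular-permutation null of the maximum
window share.  Significant windows are finally overlapped with gene
annotation intervals (half-open coordinates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from heatnorm.relationship import GenotypeSet, build_G_vanraden2

TERMS = ("intercept", "slope")


@dataclass
class SNPEffects:
    """Back-solved marker effects per reaction-norm term."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effects: np.ndarray  # (n_snps, 2): intercept, slope
    Z: np.ndarray  # centered dosages used in the back-solve
    d_weights: np.ndarray


def backsolve_snp_effects(
    gebv: pd.DataFrame,
    genotypes: GenotypeSet,
    ridge: float = 0.0,
) -> SNPEffects:
    """Back-solve genomic breeding values into per-SNP effects.

    Parameters
    ----------
    gebv : DataFrame
        ``animal, a0, a1`` for (at least) every genotyped animal.
    genotypes : GenotypeSet
        QC'd genotypes of the same animals.
    ridge : float
        Tiny diagonal added to ``Z D Z'`` if it is singular; zero when a
        blended genomic matrix was used consistently upstream.
    """
    gm = build_G_vanraden2(genotypes)
    lookup = gebv.set_index("animal")
    missing = [a for a in genotypes.ids.tolist() if a not in lookup.index]
    if missing:
        raise ValueError(f"gEBV missing for genotyped animals: {missing[:5]}")
    a_hat = lookup.loc[genotypes.ids.tolist(), ["a0", "a1"]].to_numpy(float)

    freqs = gm.freqs
    d = genotypes.dosages.astype(float)
    d[genotypes.dosages < 0] = np.nan
    Z = d - 2.0 * freqs
    Z[np.isnan(Z)] = 0.0

    # ZDZ' with observed allele frequencies is always rank-deficient (the
    # centered Z annihilates the all-ones vector), so the inverse is the
    # Moore-Penrose pseudoinverse: exact whenever a_hat lies in the range
    # of ZDZ', a least-squares projection otherwise.
    K = gm.matrix + ridge * np.eye(gm.matrix.shape[0])
    sol = np.linalg.pinv(K, hermitian=True) @ a_hat
    u = (gm.d_weights[:, None]) * (Z.T @ sol)
    return SNPEffects(
        snp_ids=genotypes.snp_ids.copy(),
        chrom=genotypes.chrom.copy(),
        pos=genotypes.pos.copy(),
        effects=u,
        Z=Z,
        d_weights=gm.d_weights.copy(),
    )


def _window_shares(Z: np.ndarray, u: np.ndarray, chrom: np.ndarray, window: int):
    """Window DGV-variance shares (%) for one term; windows never span chroms.

    Returns (first-SNP index per window, share array).  Uses a cumulative
    sum over per-SNP DGV contributions so the scan is O(animals x SNPs).
    """
    contrib = Z * u  # (n_animals, m)
    total_var = np.var(contrib.sum(axis=1))
    if total_var == 0:
        raise ValueError("whole-genome DGV variance is zero")
    csum = np.concatenate(
        [np.zeros((Z.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1
    )
    starts_all = []
    shares_all = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if np.any(np.diff(idx) != 1):
            raise ValueError("SNPs of one chromosome must be contiguous and ordered")
        n_c = len(idx)
        w = min(window, n_c)
        starts = idx[: n_c - w + 1]
        dgv = csum[:, starts + w] - csum[:, starts]  # (n_animals, n_windows)
        shares = dgv.var(axis=0) / total_var * 100.0
        starts_all.append(starts)
        shares_all.append(shares)
    return np.concatenate(starts_all), np.concatenate(shares_all)


def window_variance(
    effects: SNPEffects,
    genotypes: GenotypeSet | None = None,
    window: int = 10,
    slide: int = 1,
) -> pd.DataFrame:
    """Percent of whole-genome DGV variance per sliding SNP window.

    One row per window and per-term columns ``pct_intercept`` and
    ``pct_slope``; window count per chromosome is ``SNPs - window + 1``
    (chromosomes shorter than the window yield a single full-chromosome
    window).  Variances are population variances across genotyped
    animals.
    """
    if slide != 1:
        raise NotImplementedError("only stride-1 sliding windows are supported")
    Z = effects.Z
    out = None
    for t, term in enumerate(TERMS):
        starts, shares = _window_shares(Z, effects.effects[:, t], effects.chrom, window)
        if out is None:
            n_snps_in = []
            ends = []
            for s in starts:
                c = effects.chrom[s]
                idx = np.flatnonzero(effects.chrom == c)
                w = min(window, len(idx))
                n_snps_in.append(w)
                ends.append(effects.pos[s + w - 1])
            out = pd.DataFrame(
                {
                    "chrom": effects.chrom[starts],
                    "start": effects.pos[starts],
                    "end": np.array(ends) + 1,  # half-open
                    "first_snp": starts,
                    "n_snps": n_snps_in,
                }
            )
        out[f"pct_{term}"] = shares
    return out


def select_top_windows(windows: pd.DataFrame, quantile: float = 0.01) -> pd.DataFrame:
    """Flag the top share windows per term, independently.

    ``ceil(quantile * W)`` windows with the largest variance share are
    selected for the intercept and the slope term separately; the union
    is flagged in ``selected``.  Ties break deterministically by
    (share desc, chrom, position).
    """
    if windows.empty:
        raise ValueError("no windows to select from")
    out = windows.copy()
    n_top = math.ceil(quantile * len(out))
    union = np.zeros(len(out), dtype=bool)
    for term in TERMS:
        order = out.sort_values(
            [f"pct_{term}", "chrom", "start"], ascending=[False, True, True]
        ).index[:n_top]
        sel = np.zeros(len(out), dtype=bool)
        sel[out.index.get_indexer(order)] = True
        out[f"selected_{term}"] = sel
        union |= sel
    out["selected"] = union
    return out


def bootstrap_test(
    windows: pd.DataFrame,
    effects: SNPEffects,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    window: int = 10,
) -> pd.DataFrame:
    """Bootstrap test of the selected windows, per term.

    The null distribution of the *maximum* window share is built by B
    random permutations of the SNP-effect vector along the genome: the
    multiset of effect sizes is preserved exactly while any genomic
    clustering is broken.  A selected window is significant when its
    observed share exceeds the (1 - alpha) quantile of that null; under
    a global null of unclustered effects the permutation group makes the
    observed maximum exchangeable with the null draws, so the chance of
    any false flag is about alpha (family-wise).
    """
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; null quantile noisy")
    rng = np.random.default_rng(seed)
    m = len(effects.snp_ids)
    out = windows.copy()
    for t, term in enumerate(TERMS):
        u = effects.effects[:, t]
        null_max = np.empty(B)
        for b in range(B):
            u_b = u[rng.permutation(m)]
            _, shares = _window_shares(effects.Z, u_b, effects.chrom, window)
            null_max[b] = shares.max()
        threshold = float(np.quantile(null_max, 1.0 - alpha))
        out[f"null_q_{term}"] = threshold
        sel = out[f"selected_{term}"] if f"selected_{term}" in out else out["selected"]
        out[f"significant_{term}"] = sel & (out[f"pct_{term}"] > threshold)
    out["significant"] = out["significant_intercept"] | out["significant_slope"]
    return out


def annotate_windows(windows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Overlap windows with gene intervals (half-open coordinates).

    ``genes`` needs columns ``chrom, start, end, gene`` with half-open
    ``[start, end)`` intervals on the same assembly (see
    :func:`heatnorm.io.read_gff3` / ``read_bed``).  Returns one row per
    (window, gene) overlap with the overlap length in bp.
    """
    import pyranges as pr

    if windows.empty:
        return pd.DataFrame(
            columns=["window_idx", "chrom", "start", "end", "gene", "overlap_bp"]
        )
    win_chroms = set(map(str, pd.unique(windows["chrom"])))
    gene_chroms = set(map(str, pd.unique(genes["chrom"])))
    if not win_chroms & gene_chroms:
        raise ValueError(
            f"no shared chromosome names: windows {sorted(win_chroms)[:5]}"
            f" vs annotation {sorted(gene_chroms)[:5]}"
        )
    wdf = pd.DataFrame(
        {
            "Chromosome": windows["chrom"].astype(str),
            "Start": windows["start"].astype(int),
            "End": windows["end"].astype(int),
            "window_idx": windows.index,
        }
    )
    gdf = pd.DataFrame(
        {
            "Chromosome": genes["chrom"].astype(str),
            "Start": genes["start"].astype(int),
            "End": genes["end"].astype(int),
            "gene": genes["gene"],
        }
    )
    joined = pr.PyRanges(wdf).join(pr.PyRanges(gdf)).df
    if joined.empty:
        return pd.DataFrame(
            columns=["window_idx", "chrom", "start", "end", "gene", "overlap_bp"]
        )
    overlap = np.minimum(joined["End"], joined["End_b"]) - np.maximum(
        joined["Start"], joined["Start_b"]
    )
    return (
        pd.DataFrame(
            {
                "window_idx": joined["window_idx"],
                "chrom": joined["Chromosome"],
                "start": joined["Start"],
                "end": joined["End"],
                "gene": joined["gene"],
                "overlap_bp": overlap,
            }
        )
        .sort_values(["chrom", "start", "gene"])
        .reset_index(drop=True)
    )
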