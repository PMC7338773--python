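"""Back-solved SNP effects, window variance scan, bootstrap, annotation."""

import numpy as np
import pandas as pd
import pytest

from heatnorm.gwas import (
    annotate_windows,
    backsolve_snp_effects,
    bootstrap_test,
    select_top_windows,
    window_variance,
)
from heatnorm.relationship import GenotypeSet


def _geno(dosages, chrom=None, ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    chrom = np.asarray(chrom)
    pos = np.concatenate(
        [np.arange(1, (chrom == c).sum() + 1) * 1000 for c in pd.unique(chrom)]
    )
    return GenotypeSet(
        ids=np.arange(1, n + 1) if ids is None else np.asarray(ids),
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        chrom=chrom,
        pos=pos,
        dosages=dosages,
    )


def _gebv(geno, a):
    a = np.asarray(a, dtype=float)
    return pd.DataFrame({"animal": geno.ids, "a0": a[:, 0], "a1": a[:, 1]})


def _sim_geno(rng, n, m, chrom=None):
    p = rng.uniform(0.2, 0.5, m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    poly = (d.sum(0) > 0) & (d.sum(0) < 2 * n)
    d = d[:, poly]
    return _geno(d, chrom=None if chrom is None else np.asarray(chrom)[poly])


class TestBacksolve:
    def test_single_snp_exact(self):
        geno = _geno([[0], [2]])
        # Z = (-1, +1); gEBV constructed as Z @ u_true
        u_true = 0.7
        gebv = _gebv(geno, np.column_stack([[-u_true, u_true], [0.0, 0.0]]))
        eff = backsolve_snp_effects(gebv, geno)
        assert eff.effects[0, 0] == pytest.approx(u_true, abs=1e-10)

    def test_zero_gebv_zero_effects(self, rng):
        geno = _sim_geno(rng, 12, 40)
        eff = backsolve_snp_effects(_gebv(geno, np.zeros((12, 2))), geno)
        assert np.allclose(eff.effects, 0.0)

    def test_reprojection_recovers_gebv(self, rng):
        """Z u_hat reconstructs gEBV in range(ZDZ') with < 1e-8 rel error."""
        geno = _sim_geno(rng, 20, 50)
        u_true = rng.normal(0, 0.2, size=(geno.n_snps, 2))
        freqs = geno.allele_frequencies()
        Z = geno.dosages - 2 * freqs
        a_hat = Z @ u_true
        eff = backsolve_snp_effects(_gebv(geno, a_hat), geno)
        recon = Z @ eff.effects
        rel = np.linalg.norm(recon - a_hat) / np.linalg.norm(a_hat)
        assert rel < 1e-8
        assert np.corrcoef((Z @ eff.effects[:, 0]), a_hat[:, 0])[0, 1] > 0.99

    def test_missing_gebv_raises(self, rng):
        geno = _sim_geno(rng, 10, 30)
        gebv = _gebv(geno, rng.normal(size=(10, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="gEBV missing"):
            backsolve_snp_effects(gebv, geno)


class TestWindowVariance:
    def test_single_window_carries_everything(self, rng):
        geno = _sim_geno(rng, 30, 14)
        geno = geno.subset_snps(np.arange(min(10, geno.n_snps)))
        u = rng.normal(size=(geno.n_snps, 2))
        eff = backsolve_snp_effects(_gebv(geno, np.zeros((30, 2))), geno)
        eff.effects[:] = u
        win = window_variance(eff, window=geno.n_snps)
        assert len(win) == 1
        assert win["pct_intercept"].iloc[0] == pytest.approx(100.0)
        assert win["pct_slope"].iloc[0] == pytest.approx(100.0)

    def test_window_count_per_chromosome(self, rng):
        chrom = np.repeat([1, 2], [30, 25])
        geno = _sim_geno(rng, 40, 55, chrom=chrom)
        eff = backsolve_snp_effects(
            _gebv(geno, rng.normal(size=(40, 2))), geno
        )
        win = window_variance(eff, window=10)
        counts = win.groupby("chrom").size()
        for c in counts.index:
            n_c = int((eff.chrom == c).sum())
            assert counts[c] == n_c - 9

    def test_localized_effects_localize_variance(self, rng):
        geno = _sim_geno(rng, 300, 80)
        m = geno.n_snps
        u = np.zeros((m, 2))
        u[30:40, 0] = rng.normal(0, 1, 10)  # hot window on the intercept term
        eff = backsolve_snp_effects(_gebv(geno, np.zeros((300, 2))), geno)
        eff.effects[:, 0] = u[:, 0]
        eff.effects[:, 1] = rng.normal(0, 1e-12, m)
        win = window_variance(eff, window=10)
        hot = win.loc[win["first_snp"] == 30, "pct_intercept"].iloc[0]
        disjoint = win.loc[
            (win["first_snp"] + 9 < 30) | (win["first_snp"] > 39), "pct_intercept"
        ]
        assert hot > 90.0
        assert disjoint.max() < 10.0

    def test_disjoint_window_variances_near_total(self, rng):
        """Non-overlapping windows on ~independent SNPs nearly tile the total."""
        geno = _sim_geno(rng, 400, 60)
        m = geno.n_snps
        u = rng.normal(0, 1, size=(m, 2))
        eff = backsolve_snp_effects(_gebv(geno, np.zeros((400, 2))), geno)
        eff.effects[:] = u
        win = window_variance(eff, window=10)
        disjoint = win.loc[win["first_snp"] % 10 == 0]
        total = disjoint["pct_intercept"].sum()
        # independent SNPs: cross-window covariance is small, sum ~ 100
        assert total == pytest.approx(100.0, abs=20.0)


class TestSelection:
    def test_one_percent_of_hundred_is_one(self, rng):
        # 109 SNPs -> exactly 100 sliding windows
        d = rng.integers(0, 3, size=(30, 109)).astype(np.int8)
        geno = _geno(d)
        eff = backsolve_snp_effects(_gebv(geno, rng.normal(size=(30, 2))), geno)
        win = window_variance(eff)
        assert len(win) == 100
        sel = select_top_windows(win, quantile=0.01)
        assert sel["selected_intercept"].sum() == 1
        assert sel["selected_slope"].sum() == 1

    def test_tie_break_deterministic(self):
        win = pd.DataFrame(
            {
                "chrom": [1, 1, 1, 2],
                "start": [100, 200, 300, 100],
                "end": [150, 250, 350, 150],
                "pct_intercept": [1.0, 1.0, 1.0, 1.0],
                "pct_slope": [1.0, 1.0, 1.0, 1.0],
            }
        )
        a = select_top_windows(win, quantile=0.25)
        b = select_top_windows(win.copy(), quantile=0.25)
        assert a["selected"].tolist() == b["selected"].tolist()
        assert a.loc[a["selected_intercept"]].iloc[0]["start"] == 100


class TestBootstrap:
    def test_seed_reproducibility(self, rng):
        geno = _sim_geno(rng, 50, 120)
        eff = backsolve_snp_effects(_gebv(geno, rng.normal(size=(50, 2))), geno)
        win = select_top_windows(window_variance(eff))
        a = bootstrap_test(win, eff, B=150, seed=11)
        b = bootstrap_test(win, eff, B=150, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_power_against_a_dominant_window(self):
        """A window carrying ~half the genomic variance is always flagged."""
        flagged = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            geno = _sim_geno(rng, 120, 520)
            m = geno.n_snps
            u = rng.normal(0, 0.05, size=m)
            u[100:110] = rng.choice([-1.0, 1.0], 10) * 1.0
            eff = backsolve_snp_effects(_gebv(geno, np.zeros((120, 2))), geno)
            eff.effects[:, 0] = u
            eff.effects[:, 1] = u[::-1]
            win = select_top_windows(window_variance(eff))
            out = bootstrap_test(win, eff, B=300, seed=seed)
            hot = out.loc[out["first_snp"] == 100]
            if not hot.empty and bool(hot["significant_intercept"].iloc[0]):
                flagged += 1
        assert flagged >= int(0.95 * n_seeds)

    def test_small_B_warns(self, rng):
        geno = _sim_geno(rng, 20, 60)
        eff = backsolve_snp_effects(_gebv(geno, rng.normal(size=(20, 2))), geno)
        win = select_top_windows(window_variance(eff))
        with pytest.warns(UserWarning, match="bootstrap"):
            bootstrap_test(win, eff, B=50, seed=0)


class TestAnnotation:
    def _windows(self):
        return pd.DataFrame(
            {"chrom": ["1", "1"], "start": [1000, 5000], "end": [2000, 6000]}
        )

    def test_hand_enumerated_overlap(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start": [1100, 1900, 5500],
                "end": [1300, 2500, 5600],
                "gene": ["inside", "spanning", "second"],
            }
        )
        out = annotate_windows(self._windows(), genes)
        got = set(zip(out["gene"], out["start"]))
        assert got == {("inside", 1000), ("spanning", 1000), ("second", 5000)}
        inside = out.loc[out["gene"] == "inside", "overlap_bp"].iloc[0]
        assert inside == 200
        spanning = out.loc[out["gene"] == "spanning", "overlap_bp"].iloc[0]
        assert spanning == 100  # clipped at the window end

    def test_half_open_boundary(self):
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [500], "end": [1000], "gene": ["touches"]}
        )
        out = annotate_windows(self._windows(), genes)
        assert out.empty

    def test_chromosome_name_mismatch(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "gene": ["g"]}
        )
        with pytest.raises(ValueError, match="chromosome"):
            annotate_windows(self._windows(), genes)
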