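from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from divgwas.bayesb import PosteriorSamples
from divgwas.windows import (
    WindowError,
    build_windows,
    call_regions,
    window_genetic_correlation,
    window_variance,
)

from conftest import make_genotypes


def snp_map(positions, chrom=None):
    k = len(positions)
    return pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(k)],
        "chrom": chrom if chrom is not None else ["1"] * k,
        "pos_bp": positions,
    })


def orthonormal_genotypes(n, positions, chrom=None):
    """Duck-typed genotype object with exactly orthogonal, zero-mean columns
    (unchanged by the column-centering inside window_variance)."""
    k = len(positions)
    rng = np.random.default_rng(42)
    M = np.hstack([np.ones((n, 1)), rng.standard_normal((n, k))])
    Q, _ = np.linalg.qr(M)
    Z = Q[:, 1:]  # orthonormal and orthogonal to the constant -> zero mean
    return SimpleNamespace(dosages=Z, snp_map=snp_map(positions, chrom))


def make_samples(alpha, delta=None):
    alpha = np.asarray(alpha, dtype=float)
    S, k, t = alpha.shape
    if delta is None:
        delta = (alpha != 0).astype(np.uint8)
    zeros = lambda *shape: np.zeros(shape)
    return PosteriorSamples(
        alpha=alpha, delta=delta, b=zeros(S, 0, t), litter_effects=zeros(S, 0, t),
        u=zeros(S, 0, t), R=zeros(S, t, t), C=zeros(S, t, t), U=zeros(S, t, t),
        G=zeros(S, t, t), resid=zeros(S, 0, t),
    )


class TestBuildWindows:
    def test_membership_intervals(self):
        # SNPs at 0.1, 0.5, 1.5 Mb: windows {1,2}, {2}, {3}
        wmap = build_windows(snp_map([100_000, 500_000, 1_500_000]))
        members = [list(range(a, e)) for a, e in zip(wmap.anchor, wmap.end)]
        assert members == [[0, 1], [1], [2]]

    def test_single_snp_genome(self):
        wmap = build_windows(snp_map([12345]))
        assert len(wmap) == 1 and wmap.end[0] - wmap.anchor[0] == 1

    def test_exact_one_mb_excluded(self):
        # half-open: a SNP exactly 1,000,000 bp after the anchor is excluded
        wmap = build_windows(snp_map([1, 1_000_001]))
        assert wmap.end[0] - wmap.anchor[0] == 1

    def test_windows_never_span_chromosomes(self):
        wmap = build_windows(snp_map([1, 500_000], chrom=["1", "2"]))
        assert [e - a for a, e in zip(wmap.anchor, wmap.end)] == [1, 1]

    def test_unsorted_map_rejected(self):
        with pytest.raises(WindowError, match="sorted"):
            build_windows(snp_map([500_000, 100_000]))

    def test_duplicate_member_sets_flagged(self):
        wmap = build_windows(snp_map([100, 100, 200_000]))
        assert wmap.duplicate.tolist() == [False, True, False]


class TestWindowVariance:
    def test_single_active_snp_full_share(self):
        g = orthonormal_genotypes(30, [100, 2_000_000, 4_000_000])
        alpha = np.zeros((4, 3, 1))
        alpha[:, 1, 0] = [1.0, -2.0, 0.5, 3.0]
        res = window_variance(make_samples(alpha), build_windows(g.snp_map), g)
        assert res.table["pct_var_trait1"].tolist() == pytest.approx([0.0, 100.0, 0.0])
        assert res.table["ppa_trait1"].tolist() == [0.0, 1.0, 0.0]

    def test_two_equal_sources_half_share_each(self):
        g = orthonormal_genotypes(40, [100, 100], chrom=["1", "2"])
        alpha = np.zeros((1, 2, 1))
        alpha[0, :, 0] = [1.0, -1.0]  # orthonormal columns: equal Var(z a)
        res = window_variance(make_samples(alpha), build_windows(g.snp_map), g)
        assert res.table["pct_var_trait1"].tolist() == pytest.approx([50.0, 50.0])

    def test_disjoint_partition_sums_to_hundred(self):
        """Orthogonal columns: disjoint-window shares sum to 100 +- 1e-6."""
        rng = np.random.default_rng(1)
        positions = np.sort(rng.choice(900_000, size=12, replace=False) + 1)
        chrom = ["1"] * 6 + ["2"] * 6  # two windows tile all SNPs
        g = orthonormal_genotypes(50, list(positions[:6]) + list(positions[6:]), chrom)
        alpha = rng.standard_normal((5, 12, 1))
        res = window_variance(make_samples(alpha), build_windows(g.snp_map), g)
        tiling = res.table[res.table["window"].isin([0, 6])]
        assert tiling["pct_var_trait1"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_draws_flagged(self):
        g = orthonormal_genotypes(20, [100, 200])
        res = window_variance(make_samples(np.zeros((3, 2, 1))),
                              build_windows(g.snp_map), g)
        assert res.no_genetic_variance
        assert res.table["pct_var_trait1"].isna().all()

    def test_zero_saved_draws_rejected(self):
        g = orthonormal_genotypes(20, [100])
        with pytest.raises(WindowError, match="draws"):
            window_variance(make_samples(np.zeros((0, 1, 1))),
                            build_windows(g.snp_map), g)

    def test_infinitesimal_mean_share_tracks_member_count(self):
        """With i.i.d. effects at every SNP, the mean window share approaches
        member_count / k x 100 (the infinitesimal-threshold logic)."""
        rng = np.random.default_rng(3)
        n, k = 400, 120
        pos = np.sort(rng.choice(4_000_000, size=k, replace=False) + 1)
        d = rng.binomial(2, rng.uniform(0.2, 0.5, size=k), size=(n, k)).astype(np.int8)
        g = make_genotypes(d, pos=list(pos))
        alpha = rng.standard_normal((40, k, 1)) * 0.1
        res = window_variance(make_samples(alpha), build_windows(g.snp_map), g)
        expected = (res.table["n_snps"] / k * 100).to_numpy()
        observed = res.table["pct_var_trait1"].to_numpy()
        assert np.corrcoef(expected, observed)[0, 1] > 0.9
        assert 0.7 < observed.sum() / expected.sum() < 1.3


class TestRegions:
    def make_result(self, shares, positions=None, chrom=None):
        """WindowResult whose single-draw shares are exactly `shares` (%)."""
        shares = np.asarray(shares, dtype=float)
        k = len(shares)
        positions = positions or [1 + j * 2_000_000 for j in range(k)]
        g = orthonormal_genotypes(4 * k, positions, chrom)
        alpha = np.zeros((1, k, 1))
        alpha[0, :, 0] = np.sqrt(shares)
        return window_variance(make_samples(alpha), build_windows(g.snp_map), g)

    def test_threshold_is_inclusive(self):
        # posterior-mean shares 0.74 / 0.75 / 0.76: 'at least 0.75' keeps two
        from divgwas.windows import WindowResult

        base = self.make_result([25.0, 25.0, 50.0])
        tbl = base.table.copy()
        tbl["pct_var_trait1"] = [0.74, 0.75, 0.76]
        res = WindowResult(table=tbl, wmap=base.wmap, n_traits=1,
                           n_draws=base.n_draws, denominator_mode="markers")
        regions = call_regions(res, threshold_pct=0.75, trait=1)
        flagged = sorted(w for r in regions for w in r.windows)
        assert flagged == [1, 2]

    def test_overlapping_windows_merge(self):
        # windows at 0.1 and 0.5 Mb share SNP 2 -> one region
        res = self.make_result([60.0, 40.0], positions=[100_000, 500_000])
        regions = call_regions(res, threshold_pct=0.75, trait=1)
        assert len(regions) == 1
        r = regions[0]
        assert r.windows == [0, 1]
        assert r.start_bp == 100_000 and r.end_bp == 500_000
        assert r.max_pct_var == pytest.approx(100.0)  # window 1 holds both SNPs

    def test_different_chromosomes_never_merge(self):
        res = self.make_result([50.0, 50.0], positions=[100, 200],
                               chrom=["1", "2"])
        regions = call_regions(res, threshold_pct=0.75, trait=1)
        assert len(regions) == 2

    def test_region_ppa_any_member_inclusion(self):
        g = orthonormal_genotypes(30, [100, 200_000])
        alpha = np.zeros((4, 2, 1))
        alpha[0, 0, 0] = 5.0  # draw 0: SNP 1
        alpha[1, 1, 0] = 5.0  # draw 1: SNP 2
        # draws 2, 3: nothing
        res = window_variance(make_samples(alpha), build_windows(g.snp_map), g)
        regions = call_regions(res, threshold_pct=0.75, trait=1)
        assert len(regions) == 1
        assert regions[0].ppa == pytest.approx(0.5)  # 2 of 4 draws


class TestGeneticCorrelation:
    def test_proportional_effects_give_plus_one(self):
        g = orthonormal_genotypes(25, [100])
        alpha = np.zeros((6, 1, 2))
        alpha[:, 0, 0] = [1.0, 2.0, 0.5, 1.5, 3.0, 0.2]
        alpha[:, 0, 1] = 2.0 * alpha[:, 0, 0]
        out = window_genetic_correlation(make_samples(alpha), [0], g)
        assert out["mean"] == pytest.approx(1.0)
        assert out["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_negated_effects_give_minus_one(self):
        g = orthonormal_genotypes(25, [100])
        alpha = np.zeros((3, 1, 2))
        alpha[:, 0, 0] = [1.0, 2.0, 0.5]
        alpha[:, 0, 1] = -alpha[:, 0, 0]
        out = window_genetic_correlation(make_samples(alpha), [0], g)
        assert out["mean"] == pytest.approx(-1.0)

    def test_never_included_trait_flagged_undefined(self):
        g = orthonormal_genotypes(25, [100])
        alpha = np.zeros((3, 1, 2))
        alpha[:, 0, 0] = 1.0  # trait 2 never included
        out = window_genetic_correlation(make_samples(alpha), [0], g)
        assert out["undefined"] and out["n_draws"] == 0

    def test_window_table_matches_direct_computation(self):
        rng = np.random.default_rng(9)
        g = orthonormal_genotypes(30, [100, 500, 900])
        alpha = rng.standard_normal((8, 3, 2))
        samples = make_samples(alpha)
        res = window_variance(samples, build_windows(g.snp_map), g)
        direct = window_genetic_correlation(samples, [0, 1, 2], g)
        assert res.table.loc[0, "gencor_mean"] == pytest.approx(direct["mean"])
        assert res.table.loc[0, "gencor_sd"] == pytest.approx(direct["sd"], abs=1e-12)
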