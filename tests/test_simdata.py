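import numpy as np
import pandas as pd
import pytest

from divgwas.pedigree import Pedigree
from divgwas.simdata import (
    SimConfig,
    SimConfigError,
    SimDataError,
    apply_divergent_selection,
    gene_drop,
    simulate,
    simulate_founders,
    simulate_phenotypes,
)


def tiny_config(**kw):
    base = dict(
        n_generations=2, n_sires_per_line=4, n_dams_per_line=8, progeny_per_dam=4,
        n_snps=100, n_chromosomes=2, chrom_length_bp=20_000_000, seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_symmetric_band_mean_dosage(self):
        cfg = tiny_config(founder_maf_low=0.5, founder_maf_high=0.5, n_snps=200)
        g, _ = simulate_founders(cfg, n_founders=400)
        # p = 0.5 everywhere: mean dosage 1.0 within 3 binomial SE
        se = np.sqrt(2 * 0.5 * 0.5 / 400)
        dev = np.abs(g.dosages.mean(axis=0) - 1.0)
        assert (dev < 3 * se).mean() > 0.98  # ~99.7% expected per SNP
        assert abs(g.dosages.mean() - 1.0) < 3 * se / np.sqrt(g.n_snps)

    def test_zero_snps_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_founders(tiny_config(n_snps=0))

    def test_invalid_band_rejected(self):
        with pytest.raises(SimConfigError):
            simulate_founders(tiny_config(founder_maf_low=0.3, founder_maf_high=0.2))

    def test_deterministic(self):
        g1, h1 = simulate_founders(tiny_config())
        g2, h2 = simulate_founders(tiny_config())
        assert np.array_equal(g1.dosages, g2.dosages)
        assert np.array_equal(h1, h2)

    def test_map_sorted_within_chromosome(self):
        g, _ = simulate_founders(tiny_config())
        for _, grp in g.snp_map.groupby("chrom"):
            assert np.all(np.diff(grp["pos_bp"].to_numpy()) > 0)


class TestGeneDrop:
    def test_mendelian_endpoints(self):
        cfg = tiny_config()
        founders, haps = simulate_founders(cfg, n_founders=2)
        # force homozygous founders at the first two SNPs
        haps[:, :, 0] = 0
        haps[:, :, 1] = 1
        ped = Pedigree.from_records(
            [("f1", None, None), ("f2", None, None)]
            + [(f"o{i}", "f1", "f2") for i in range(20)]
        )
        g, _ = gene_drop(ped, founders, seed=4, founder_haps=haps)
        off = g.subset(animal_rows=np.flatnonzero(~ped.is_founder))
        assert np.all(off.dosages[:, 0] == 0)  # 0 x 0 -> 0
        assert np.all(off.dosages[:, 1] == 2)  # 2 x 2 -> 2

    def test_zero_distance_cosegregation(self):
        """SNPs at the same bp never recombine across many meioses."""
        cfg = tiny_config(n_snps=2, n_chromosomes=1)
        founders, haps = simulate_founders(cfg, n_founders=2)
        founders.snp_map.loc[1, "pos_bp"] = founders.snp_map.loc[0, "pos_bp"]
        # heterozygous phase-known parents: hap0 = (1,1), hap1 = (0,0)
        haps[:, 0, :] = 1
        haps[:, 1, :] = 0
        ped = Pedigree.from_records(
            [("f1", None, None), ("f2", None, None)]
            + [(f"o{i}", "f1", "f2") for i in range(1000)]
        )
        _, off_haps = gene_drop(ped, founders, seed=8, founder_haps=haps)
        child = off_haps[2:]  # founders occupy the first two rows
        recombinant = child[:, :, 0] != child[:, :, 1]
        assert recombinant.sum() == 0

    def test_missing_parent_rejected(self):
        cfg = tiny_config()
        founders, _ = simulate_founders(cfg, n_founders=1)
        ped = Pedigree.from_records([("f1", None, None), ("o", "f1", None)])
        with pytest.raises(SimDataError):
            gene_drop(ped, founders, seed=1)


class TestPhenotypes:
    def test_degenerate_model_reproduces_residual_cov(self):
        # no QTL, h2 = c2 = 0: phenotypic covariance ~ R
        cfg = tiny_config(h2=(0.0, 0.0), c2=(0.0, 0.0), r_e=0.3, n_snps=50)
        founders, haps = simulate_founders(cfg, n_founders=2000)
        ped = Pedigree.from_records([(a, None, None) for a in founders.animal_ids])
        ph = simulate_phenotypes(founders, ped, cfg, seed=2)
        # remove the fixed month/sex/parity means before comparing with R
        X = pd.get_dummies(ph[["month", "sex", "parity"]].astype(str)).astype(float)
        X.insert(0, "const", 1.0)
        Y = ph[["trait1", "trait2"]].to_numpy()
        resid = Y - X.to_numpy() @ np.linalg.lstsq(X.to_numpy(), Y, rcond=None)[0]
        S = np.cov(resid, rowvar=False)
        assert S[0, 0] == pytest.approx(1.0, abs=0.1)
        assert S[1, 1] == pytest.approx(1.0, abs=0.1)
        assert S[0, 1] == pytest.approx(0.3, abs=0.1)

    def test_shared_qtl_perfect_correlation(self):
        cfg = tiny_config(qtl_spec=[("1", 10_000_000, 0.1, 0.1, 1.0)],
                          h2=(0.2, 0.2), c2=(0.0, 0.0))
        out = simulate(cfg)
        gv = out.genotypes.dosages.astype(float) @ out.true_effects
        r = np.corrcoef(gv[:, 0], gv[:, 1])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_variance_budget_rejected(self):
        with pytest.raises(SimConfigError):
            tiny_config(h2=(0.5, 0.5), c2=(0.3, 0.3),
                        qtl_spec=[("1", 1000, 0.3, 0.3, 0.0)]).validate()

    def test_heritability_recovery_by_midparent_regression(self):
        """Midparent-offspring regression (an independent quantitative-genetic
        estimator, unbiased under selection on the parents) recovers the
        generating h2 within 3 SE.  Fixed month/sex/parity effects are removed
        by OLS first; the regression is within one line so line divergence
        cannot inflate the between-family variance."""
        from scipy.stats import linregress

        cfg = SimConfig(
            n_generations=3, n_sires_per_line=15, n_dams_per_line=60,
            progeny_per_dam=8, n_snps=60, n_chromosomes=2, seed=21,
            h2=(0.3, 0.49), c2=(0.0, 0.0),
        )
        out = simulate(cfg)
        ph = out.phenotypes.copy()
        X = pd.get_dummies(
            ph[["month", "sex", "parity"]].astype(str), drop_first=True
        ).astype(float)
        X.insert(0, "const", 1.0)
        beta = np.linalg.lstsq(X.to_numpy(), ph["trait2"].to_numpy(), rcond=None)[0]
        ph["adj2"] = ph["trait2"].to_numpy() - X.to_numpy() @ beta
        adj = ph.set_index("animal")["adj2"]
        ped = out.pedigree.to_frame().set_index("animal")
        pairs = []
        for (line, gen), sub in ph[ph.generation >= 2].groupby(["line", "generation"]):
            grp = []
            for animal, y in zip(sub["animal"], sub["adj2"]):
                s, d = ped.loc[animal, ["sire", "dam"]]
                if s in adj.index and d in adj.index:
                    grp.append((0.5 * (adj[s] + adj[d]), y))
            g = np.asarray(grp)
            # center within line x generation so selection response and line
            # divergence cannot masquerade as heritable resemblance
            pairs.append(g - g.mean(axis=0))
        pairs = np.vstack(pairs)
        fit = linregress(pairs[:, 0], pairs[:, 1])
        assert abs(fit.slope - 0.49) < 3 * fit.stderr


class TestSelection:
    def test_divergence_after_selection(self):
        """H-line trait-2 mean exceeds L-line mean after selection (5 seeds)."""
        wins = 0
        for seed in range(5):
            cfg = tiny_config(n_generations=3, seed=100 + seed, h2=(0.3, 0.5))
            out = simulate(cfg)
            last = out.phenotypes[out.phenotypes.generation == 3]
            means = last.groupby("line")["trait2"].mean()
            wins += means["H"] > means["L"]
        assert wins == 5

    def test_no_divergence_without_divergent_selection(self):
        """Parallel (both +1) selection leaves only drift between lines, far
        smaller than the gap opened by true divergent selection."""
        for seed in (7, 8, 9):
            gaps = {}
            for name, direction in (("parallel", {"H": +1, "L": +1}),
                                    ("divergent", {"H": +1, "L": -1})):
                cfg = tiny_config(n_generations=3, seed=seed, h2=(0.3, 0.5),
                                  selection_direction=direction)
                out = simulate(cfg)
                last = out.phenotypes[out.phenotypes.generation == 3]
                m = last.groupby("line")["trait2"].mean()
                gaps[name] = m["H"] - m["L"]
            assert abs(gaps["parallel"]) < abs(gaps["divergent"])
            assert gaps["divergent"] > 0

    def test_selection_reproducible_and_ranked(self):
        cfg = tiny_config()
        out = simulate(cfg)
        cand = out.phenotypes[out.phenotypes.generation == 1]
        s1 = apply_divergent_selection(cand[cand.line == "H"], cfg, "H")
        s2 = apply_divergent_selection(cand[cand.line == "H"], cfg, "H")
        assert s1 == s2
        # selected sires are the top-ranked males on trait 2
        males = cand[(cand.line == "H") & (cand.sex == "M")].sort_values(
            ["trait2", "animal"], ascending=[False, True]
        )
        assert s1[0] == males["animal"].head(cfg.n_sires_per_line).tolist()

    def test_too_few_candidates_rejected(self):
        cfg = tiny_config(n_sires_per_line=50)
        cand = pd.DataFrame({
            "animal": ["x1", "x2"], "sex": ["M", "F"], "trait1": [0, 1],
            "trait2": [0, 1],
        })
        with pytest.raises(SimDataError):
            apply_divergent_selection(cand, cfg, "H")


class TestSimOutput:
    def test_outputs_pure_function_of_seed(self, small_sim):
        cfg = SimConfig(
            n_generations=2, n_sires_per_line=6, n_dams_per_line=15, progeny_per_dam=4,
            n_snps=400, n_chromosomes=4, chrom_length_bp=40_000_000,
            qtl_spec=[("1", 5_000_000, 0.08, 0.10, 0.9)], seed=11,
        )
        again = simulate(cfg)
        assert np.array_equal(small_sim.genotypes.dosages, again.genotypes.dosages)
        assert small_sim.phenotypes.equals(again.phenotypes)

    def test_phenotyped_animals_in_pedigree(self, small_sim):
        ped_set = set(small_sim.pedigree.animals)
        assert set(small_sim.phenotypes["animal"]).issubset(ped_set)

    def test_true_effects_zero_off_qtl(self, small_sim):
        qtl_ids = set(small_sim.true_variance_components["qtl"]["snp_id"])
        smap = small_sim.true_snp_map
        nonzero = np.flatnonzero(np.any(small_sim.true_effects != 0, axis=1))
        assert set(smap["snp_id"].iloc[nonzero]) == qtl_ids

    def test_qtl_allele_frequency_divergence_exceeds_neutral(self):
        """|p_H - p_L| is larger at the QTL than at unlinked neutral SNPs."""
        from scipy.stats import mannwhitneyu

        qtl_divs, neutral_divs = [], []
        for seed in range(3):
            cfg = SimConfig(
                n_generations=3, n_sires_per_line=6, n_dams_per_line=15,
                progeny_per_dam=6, n_snps=120, n_chromosomes=3,
                qtl_spec=[("1", 10_000_000, 0.0, 0.25, 1.0)], seed=200 + seed,
                h2=(0.2, 0.2),
            )
            out = simulate(cfg)
            last_gen = out.phenotypes.loc[
                out.phenotypes.generation == 3, "animal"
            ].tolist()
            rows = out.genotypes.subset(
                animal_rows=[out.genotypes.animal_ids.index(a) for a in last_gen]
            )
            lines = np.array([out.line_assignment[a] for a in rows.animal_ids])
            pH = rows.subset(animal_rows=np.flatnonzero(lines == "H")).allele_frequency()
            pL = rows.subset(animal_rows=np.flatnonzero(lines == "L")).allele_frequency()
            div = np.abs(pH - pL)
            qtl = np.flatnonzero(np.any(out.true_effects != 0, axis=1))
            other_chrom = out.genotypes.snp_map["chrom"] != "1"
            qtl_divs.extend(div[qtl])
            neutral_divs.extend(div[other_chrom.to_numpy()])
        stat = mannwhitneyu(qtl_divs, neutral_divs, alternative="greater")
        assert stat.pvalue < 0.01

    def test_hide_qtl_drops_causal_columns(self):
        cfg = tiny_config(qtl_spec=[("1", 5_000_000, 0.1, 0.1, 1.0)], hide_qtl=True)
        out = simulate(cfg)
        qtl_ids = set(out.true_variance_components["qtl"]["snp_id"])
        assert not qtl_ids & set(out.genotypes.snp_map["snp_id"])
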