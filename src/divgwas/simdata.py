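"""Synthetic divergent-selection datasets with the structure the GWAS assumes.

Two lines are founded from a common base population and divergently selected
on trait 2 (the intramuscular-fat-like selection criterion) for a configurable
number of generations.  Genotypes are gene-dropped through the pedigree with
recombination (uniform 1 cM/Mb, Haldane map function); phenotypes follow the
analysis model exactly: fixed month/sex/parity effects, a common-litter
effect shared by full sibs, a pedigree polygenic effect, sparse (possibly
pleiotropic) QTL effects on real marker columns, and a correlated residual.

Variance bookkeeping is on the scale of a unit founder phenotypic variance:
``h2``, ``c2`` and the per-QTL variance fractions are fractions of that
variance, calibrated against the realized founder genotype (co)variances so
the generated fractions are exact in the founder cohort.  A QTL entry whose
target cross-trait correlation cannot be realized by a single marker (both
fractions positive and |rho| < 1) is expanded into a pair of neighbouring
causal markers whose summed contribution has exactly the requested
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import GenotypeData
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate",
    "simulate_founders",
    "gene_drop",
    "simulate_phenotypes",
    "apply_divergent_selection",
]


class SimConfigError(ValueError):
    pass


class SimDataError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the two-line divergent-selection simulator.

    Defaults follow the emulated design: selection on trait 2, fixed effects
    month (5 levels), sex (2) and parity (2), 10 sires and 40 dams per line
    producing ~240 progeny per line and generation.
    """

    n_generations: int = 3
    n_sires_per_line: int = 10
    n_dams_per_line: int = 40
    progeny_per_dam: int = 6
    n_snps: int = 2000
    n_chromosomes: int = 21
    chrom_length_bp: int = 50_000_000
    founder_maf_low: float = 0.1
    founder_maf_high: float = 0.5
    # (chrom, bp, var fraction trait1, var fraction trait2, effect correlation)
    qtl_spec: list = field(default_factory=list)
    h2: tuple = (0.35, 0.50)
    c2: tuple = (0.10, 0.10)
    r_g_polygenic: float = 0.3
    r_e: float = 0.2
    selection_trait: int = 2
    selection_direction: dict = field(default_factory=lambda: {"H": +1, "L": -1})
    hide_qtl: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise SimConfigError("n_snps must be >= 1")
        if not (0 < self.founder_maf_low <= self.founder_maf_high <= 0.5):
            raise SimConfigError("founder MAF band must satisfy 0 < low <= high <= 0.5")
        if self.selection_trait not in (1, 2):
            raise SimConfigError("selection_trait must be 1 or 2")
        qtl_frac = np.zeros(2)
        for chrom, bp, f1, f2, rho in self.qtl_spec:
            if not (0 < bp <= self.chrom_length_bp):
                raise SimConfigError(f"QTL position {bp} outside chromosome bounds")
            if not (-1 <= rho <= 1):
                raise SimConfigError("QTL effect correlation must be in [-1, 1]")
            if f1 < 0 or f2 < 0:
                raise SimConfigError("QTL variance fractions must be >= 0")
            qtl_frac += (f1, f2)
        for t in range(2):
            tot = self.h2[t] + self.c2[t] + qtl_frac[t]
            if not (0 <= self.h2[t] < 1) or not (0 <= self.c2[t] < 1) or tot >= 1:
                raise SimConfigError(
                    f"trait {t + 1}: h2 + c2 + QTL fractions = {tot:.3f} must be < 1 "
                    "with a positive residual fraction"
                )


@dataclass
class SimOutput:
    genotypes: GenotypeData  # every pedigree animal, pedigree order
    phenotypes: pd.DataFrame  # one record per non-founder animal
    pedigree: Pedigree
    true_effects: np.ndarray  # n_snps x 2, zero off-QTL (full map incl. hidden QTL)
    true_variance_components: dict  # C, U, R matrices and per-QTL shares
    line_assignment: pd.Series  # animal -> 'H'/'L'
    true_snp_map: pd.DataFrame  # map before any hide_qtl column drop


# ---------------------------------------------------------------------------
# founders and gene dropping
# ---------------------------------------------------------------------------


def _make_snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    rows = []
    for c in range(config.n_chromosomes):
        if per_chrom[c] == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length_bp + 1),
                                 size=per_chrom[c], replace=False))
        for p in pos:
            rows.append((f"snp{len(rows) + 1}", str(c + 1), int(p)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None,
                      n_founders: int | None = None):
    """Founder cohort: per-SNP allele frequency uniform on the configured band.

    Returns ``(GenotypeData, haplotypes)`` where haplotypes is an
    (n, 2, k) int8 array (dosage = haplotype sum).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_founders is None:
        n_founders = 2 * (config.n_sires_per_line + config.n_dams_per_line)
    smap = _make_snp_map(config, rng)
    k = len(smap)
    freq = rng.uniform(config.founder_maf_low, config.founder_maf_high, size=k)
    haps = (rng.random((n_founders, 2, k)) < freq).astype(np.int8)
    ids = [f"F{i + 1}" for i in range(n_founders)]
    return GenotypeData(haps.sum(axis=1).astype(np.int8), smap, ids), haps


def _recomb_fractions(snp_map: pd.DataFrame, cm_per_mb: float = 1.0) -> np.ndarray:
    """Recombination fraction between each SNP and its predecessor.

    Haldane: r = 0.5 (1 - exp(-2 d)) with d in Morgans from bp distance at
    ``cm_per_mb``; 0.5 at chromosome starts (independent assortment).
    """
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy(dtype=np.float64)
    r = np.full(len(snp_map), 0.5)
    same = np.empty(len(snp_map), dtype=bool)
    same[0] = False
    same[1:] = chrom[1:] == chrom[:-1]
    d_morgan = np.zeros(len(snp_map))
    d_morgan[1:] = (pos[1:] - pos[:-1]) * cm_per_mb * 1e-8
    r[same] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan[same]))
    return r


@njit(cache=True)
def _drop_kernel(sire, dam, founder_haps, rec, seed):
    np.random.seed(seed)
    n = sire.shape[0]
    k = rec.shape[0]
    haps = np.zeros((n, 2, k), dtype=np.int8)
    n_f = 0
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            haps[i, 0] = founder_haps[n_f, 0]
            haps[i, 1] = founder_haps[n_f, 1]
            n_f += 1
        else:
            for m, par in enumerate((sire[i], dam[i])):
                cur = 1 if np.random.random() < 0.5 else 0
                for j in range(k):
                    if np.random.random() < rec[j]:
                        cur = 1 - cur
                    haps[i, m, j] = haps[par, cur, j]
    return haps


def gene_drop(ped: Pedigree, founder_genotypes: GenotypeData, seed: int,
              founder_haps: np.ndarray | None = None, cm_per_mb: float = 1.0):
    """Drop founder haplotypes through the pedigree with recombination.

    Founders (in pedigree order) take the supplied genotypes; dosage-1
    founders are phased at random when explicit haplotypes are not given.
    Returns ``(GenotypeData, haplotypes)`` over all pedigree animals.
    """
    founders = np.flatnonzero(ped.is_founder)
    half = (ped.sire_idx < 0) != (ped.dam_idx < 0)
    if half.any():
        raise SimDataError("non-founders must have both parents in the pedigree")
    if len(founders) != founder_genotypes.n_animals:
        raise SimDataError(
            f"pedigree has {len(founders)} founders but genotypes for "
            f"{founder_genotypes.n_animals} animals were supplied"
        )
    rng = np.random.default_rng(seed)
    if founder_haps is None:
        d = founder_genotypes.dosages
        if (d < 0).any():
            raise SimDataError("founder genotypes must not contain missing calls")
        h0 = (d >= 1).astype(np.int8)
        h1 = (d == 2).astype(np.int8)
        flip = rng.random(d.shape) < 0.5
        founder_haps = np.stack([np.where(flip, h1, h0), np.where(flip, h0, h1)], axis=1)
        founder_haps = founder_haps.astype(np.int8)
    rec = _recomb_fractions(founder_genotypes.snp_map, cm_per_mb)
    haps = _drop_kernel(ped.sire_idx, ped.dam_idx, founder_haps,
                        rec, int(rng.integers(2**31)))
    g = GenotypeData(haps.sum(axis=1).astype(np.int8),
                     founder_genotypes.snp_map.copy(), list(ped.animals))
    return g, haps


# ---------------------------------------------------------------------------
# trait model
# ---------------------------------------------------------------------------


def _cov2(v1: float, v2: float, rho: float) -> np.ndarray:
    s = np.sqrt([v1, v2])
    return np.array([[v1, rho * s[0] * s[1]], [rho * s[0] * s[1], v2]])


def _chol_psd(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _resolve_qtl_effects(config: SimConfig, smap: pd.DataFrame,
                         founder_dosage: np.ndarray) -> tuple[np.ndarray, list]:
    """Per-SNP true substitution effects (k x 2) realizing the QTL spec.

    Fractions are calibrated on the realized founder dosage covariance so the
    founder-cohort genetic (co)variance of each QTL entry equals its target
    exactly.  Entries needing two markers use the nearest same-chromosome
    neighbour within 1 Mb of the anchor.
    """
    k = len(smap)
    alpha = np.zeros((k, 2))
    qtl_rows = []
    chrom = smap["chrom"].to_numpy()
    pos = smap["pos_bp"].to_numpy()
    for chrom_q, bp, f1, f2, rho in config.qtl_spec:
        on_chrom = np.flatnonzero(chrom == str(chrom_q))
        if on_chrom.size == 0:
            raise SimConfigError(f"no SNPs on chromosome {chrom_q}")
        j1 = on_chrom[np.argmin(np.abs(pos[on_chrom] - bp))]
        needs_pair = f1 > 0 and f2 > 0 and abs(rho) < 1
        if not needs_pair:
            z = founder_dosage[:, j1].astype(float)
            v = z.var()
            if v <= 0:
                raise SimDataError(f"QTL SNP {smap['snp_id'][j1]} is monomorphic in founders")
            a1 = np.sqrt(f1 / v)
            a2 = np.sign(rho if rho != 0 else 1.0) * np.sqrt(f2 / v)
            alpha[j1, 0] += a1
            alpha[j1, 1] += a2
            qtl_rows.append((smap["snp_id"][j1], chrom_q, int(pos[j1]), f1, f2, rho))
        else:
            near = on_chrom[(np.abs(pos[on_chrom] - pos[j1]) <= 1_000_000) & (on_chrom != j1)]
            if near.size == 0:
                raise SimConfigError(
                    f"QTL at {chrom_q}:{bp} needs a neighbouring SNP within 1 Mb "
                    "to realize a partial correlation"
                )
            j2 = near[np.argmin(np.abs(pos[near] - pos[j1]))]
            Z = founder_dosage[:, [j1, j2]].astype(float)
            Sz = np.cov(Z, rowvar=False)
            target = _cov2(f1, f2, rho)
            Lz = np.linalg.cholesky(Sz)
            B = np.linalg.solve(Lz.T, _chol_psd(target).T)  # B' Sz B = target
            alpha[[j1, j2], :] += B
            qtl_rows.append((smap["snp_id"][j1], chrom_q, int(pos[j1]), f1, f2, rho))
            qtl_rows.append((smap["snp_id"][j2], chrom_q, int(pos[j2]), f1, f2, rho))
    return alpha, qtl_rows


@dataclass
class _TraitModel:
    """Frozen generative constants shared by every generation of one run."""

    mu: np.ndarray  # (2,)
    month_eff: np.ndarray  # (5, 2)
    sex_eff: np.ndarray  # (2, 2)
    parity_eff: np.ndarray  # (2, 2)
    alpha: np.ndarray  # (k, 2)
    U: np.ndarray
    C: np.ndarray
    R: np.ndarray
    qtl_table: pd.DataFrame

    @classmethod
    def build(cls, config: SimConfig, smap: pd.DataFrame, founder_dosage: np.ndarray,
              rng: np.random.Generator) -> "_TraitModel":
        alpha, qtl_rows = _resolve_qtl_effects(config, smap, founder_dosage)
        qtl_frac = np.zeros(2)
        for _, _, f1, f2, _ in config.qtl_spec:
            qtl_frac += (f1, f2)
        res = 1.0 - np.asarray(config.h2) - np.asarray(config.c2) - qtl_frac
        U = _cov2(config.h2[0], config.h2[1], config.r_g_polygenic)
        C = np.diag(config.c2).astype(float)
        R = _cov2(res[0], res[1], config.r_e)
        return cls(
            mu=np.array([10.0, 1.0]),
            month_eff=rng.normal(0.0, 0.3, size=(5, 2)),
            sex_eff=rng.normal(0.0, 0.2, size=(2, 2)),
            parity_eff=rng.normal(0.0, 0.2, size=(2, 2)),
            alpha=alpha,
            U=U,
            C=C,
            R=R,
            qtl_table=pd.DataFrame(
                qtl_rows, columns=["snp_id", "chrom", "pos_bp", "frac1", "frac2", "rho"]
            ),
        )


def _draw_polygenic(ped: Pedigree, U: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Breeding values through the pedigree: founders N(0, U); offspring =
    parent average + Mendelian sampling N(0, U/2)."""
    Lu = _chol_psd(U)
    n = len(ped)
    u = np.zeros((n, 2))
    ms = rng.standard_normal((n, 2)) @ Lu.T
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            u[i] = ms[i]
        else:
            u[i] = 0.5 * (u[s] + u[d]) + np.sqrt(0.5) * ms[i]
    return u


def simulate_phenotypes(genotypes: GenotypeData, ped: Pedigree, config: SimConfig,
                        seed: int) -> pd.DataFrame:
    """Standalone phenotype generation for every genotyped animal.

    Fixed-effect levels are drawn per animal (month uniform over 5 levels,
    sex and parity Bernoulli); litter = dam x parity, full sibs of the same
    parity share one litter draw; polygenic values follow the pedigree.
    Founder genotype (co)variances calibrate the QTL effects.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ped_ix = ped.index_of(genotypes.animal_ids)
    founder_rows = np.flatnonzero(ped.is_founder[ped_ix])
    calib = genotypes.dosages[founder_rows] if founder_rows.size else genotypes.dosages
    model = _TraitModel.build(config, genotypes.snp_map, calib, rng)
    u_all = _draw_polygenic(ped, model.U, rng)

    n = genotypes.n_animals
    month = rng.integers(0, 5, size=n)
    sex = rng.integers(0, 2, size=n)
    parity = rng.integers(0, 2, size=n)
    dam = np.array([ped.dam_idx[i] for i in ped_ix])
    litter_key = [f"L{d}_{p}" if d >= 0 else f"Lf{i}" for i, (d, p) in enumerate(zip(dam, parity))]
    # full sibs sharing a litter share its parity level too
    litters = {}
    for i, key in enumerate(litter_key):
        litters.setdefault(key, []).append(i)
    Lc = _chol_psd(model.C)
    c_draw = {key: Lc @ rng.standard_normal(2) for key in litters}
    for key, members in litters.items():
        parity[members] = parity[members[0]]

    g = genotypes.dosages.astype(float) @ model.alpha
    e = rng.standard_normal((n, 2)) @ _chol_psd(model.R).T
    y = (
        model.mu
        + model.month_eff[month]
        + model.sex_eff[sex]
        + model.parity_eff[parity]
        + np.array([c_draw[k] for k in litter_key])
        + u_all[ped_ix]
        + g
        + e
    )
    return pd.DataFrame(
        {
            "animal": genotypes.animal_ids,
            "month": month + 1,
            "sex": np.where(sex == 0, "M", "F"),
            "parity": parity + 1,
            "litter": litter_key,
            "trait1": y[:, 0],
            "trait2": y[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# selection driver
# ---------------------------------------------------------------------------


def apply_divergent_selection(candidates: pd.DataFrame, config: SimConfig,
                              line: str) -> tuple[list, list]:
    """Choose next-generation parents within one line.

    Ranks candidates on the selection trait (direction per line), takes the
    required number of sires and dams, ties broken by animal id.  Returns
    (sires, dams) as animal-id lists.
    """
    trait = f"trait{config.selection_trait}"
    direction = config.selection_direction[line]
    ranked = candidates.sort_values(
        by=[trait, "animal"], ascending=[direction < 0, True], kind="mergesort"
    )
    males = ranked[ranked["sex"] == "M"]["animal"].tolist()
    females = ranked[ranked["sex"] == "F"]["animal"].tolist()
    if len(males) < config.n_sires_per_line or len(females) < config.n_dams_per_line:
        raise SimDataError(
            f"line {line}: need {config.n_sires_per_line} sires and "
            f"{config.n_dams_per_line} dams, have {len(males)} males / {len(females)} females"
        )
    return males[: config.n_sires_per_line], females[: config.n_dams_per_line]


def _mate(sires: list, dams: list, full_sib_of: dict) -> list:
    """Round-robin sire assignment avoiding full-sib pairs when possible."""
    matings = []
    for i, dam in enumerate(dams):
        for off in range(len(sires)):
            sire = sires[(i + off) % len(sires)]
            if full_sib_of.get(dam) is None or full_sib_of.get(sire) != full_sib_of.get(dam):
                break
        matings.append((sire, dam))
    return matings


def simulate(config: SimConfig) -> SimOutput:
    """Run the full two-line divergent-selection design.

    Generation 0 founders (unphenotyped) are split evenly between lines;
    each subsequent generation is bred from parents selected on the
    phenotypes of the previous one (high line up, low line down).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    founder_g, founder_haps = simulate_founders(config, rng)
    smap = founder_g.snp_map
    rec = _recomb_fractions(smap)
    model = _TraitModel.build(config, smap, founder_g.dosages, rng)
    Lu, Lc, Lr = _chol_psd(model.U), _chol_psd(model.C), _chol_psd(model.R)

    n_par = config.n_sires_per_line + config.n_dams_per_line
    ids = list(founder_g.animal_ids)
    sire_of: dict = {a: None for a in ids}
    dam_of: dict = {a: None for a in ids}
    line_of = {a: ("H" if i < n_par else "L") for i, a in enumerate(ids)}
    haps = {a: founder_haps[i] for i, a in enumerate(ids)}
    u_of = {a: Lu @ rng.standard_normal(2) for a in ids}
    full_sib_of: dict = {}

    parents = {}
    for line in ("H", "L"):
        members = [a for a in ids if line_of[a] == line]
        parents[line] = (members[: config.n_sires_per_line], members[config.n_sires_per_line :])

    pheno_rows = []
    counter = 0
    for gen in range(1, config.n_generations + 1):
        new_candidates = {"H": [], "L": []}
        for line in ("H", "L"):
            sires, dams = parents[line]
            matings = _mate(sires, dams, full_sib_of)
            for li, (sire, dam) in enumerate(matings):
                parity = int(rng.integers(0, 2))
                month = li % 5
                litter_id = f"{line}G{gen}L{li + 1}"
                c_lit = Lc @ rng.standard_normal(2)
                for _ in range(config.progeny_per_dam):
                    counter += 1
                    aid = f"{line}{gen}_{counter:05d}"
                    ids.append(aid)
                    sire_of[aid], dam_of[aid] = sire, dam
                    line_of[aid] = line
                    full_sib_of[aid] = (sire, dam)
                    gam = np.empty((2, len(smap)), dtype=np.int8)
                    for m, par in enumerate((sire, dam)):
                        seed_m = int(rng.integers(2**31))
                        gam[m] = _meiosis(haps[par], rec, seed_m)
                    haps[aid] = gam
                    u = 0.5 * (u_of[sire] + u_of[dam]) + np.sqrt(0.5) * (
                        Lu @ rng.standard_normal(2)
                    )
                    u_of[aid] = u
                    sex = "M" if rng.random() < 0.5 else "F"
                    dose = gam.sum(axis=0).astype(float)
                    y = (
                        model.mu
                        + model.month_eff[month]
                        + model.sex_eff[0 if sex == "M" else 1]
                        + model.parity_eff[parity]
                        + c_lit
                        + u
                        + dose @ model.alpha
                        + Lr @ rng.standard_normal(2)
                    )
                    rec_row = {
                        "animal": aid,
                        "line": line,
                        "generation": gen,
                        "month": month + 1,
                        "sex": sex,
                        "parity": parity + 1,
                        "litter": litter_id,
                        "trait1": y[0],
                        "trait2": y[1],
                    }
                    pheno_rows.append(rec_row)
                    new_candidates[line].append(rec_row)
        if gen < config.n_generations:
            for line in ("H", "L"):
                cand = pd.DataFrame(new_candidates[line])
                parents[line] = apply_divergent_selection(cand, config, line)

    ped = Pedigree.from_records(
        (a, sire_of.get(a), dam_of.get(a)) for a in ids
    )
    order = ped.animals
    dosages = np.stack([haps[a].sum(axis=0) for a in order]).astype(np.int8)
    genotypes = GenotypeData(dosages, smap.copy(), list(order))
    true_map = smap.copy()
    if config.hide_qtl:
        causal = np.flatnonzero(np.any(model.alpha != 0.0, axis=1))
        keep = np.setdiff1d(np.arange(len(smap)), causal)
        genotypes = genotypes.subset(snp_cols=keep)

    return SimOutput(
        genotypes=genotypes,
        phenotypes=pd.DataFrame(pheno_rows),
        pedigree=ped,
        true_effects=model.alpha,
        true_variance_components={
            "C": model.C,
            "U": model.U,
            "R": model.R,
            "qtl": model.qtl_table,
        },
        line_assignment=pd.Series(line_of, name="line"),
        true_snp_map=true_map,
    )


@njit(cache=True)
def _meiosis(parent_haps, rec, seed):
    np.random.seed(seed)
    k = rec.shape[0]
    gamete = np.empty(k, dtype=np.int8)
    cur = 1 if np.random.random() < 0.5 else 0
    for j in range(k):
        if np.random.random() < rec[j]:
            cur = 1 - cur
        gamete[j] = parent_haps[cur, j]
    return gamete


def write_sim_output(out: SimOutput, outdir) -> dict:
    """Write the full fixture set as plain text; returns path -> sha256."""
    import hashlib
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.genotypes.write_tsv(outdir / "genotypes.tsv", outdir / "snp_map.tsv")
    out.genotypes.write_plink_text(outdir / "genotypes")
    out.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    out.pedigree.to_frame().to_csv(outdir / "pedigree.csv", index=False)
    truth = out.true_snp_map.copy()
    truth[["effect_trait1", "effect_trait2"]] = out.true_effects
    truth.to_csv(outdir / "true_effects.csv", index=False)
    out.true_variance_components["qtl"].to_csv(outdir / "true_qtl.csv", index=False)
    out.line_assignment.rename_axis("animal").reset_index().to_csv(
        outdir / "lines.csv", index=False
    )
    written = [
        "genotypes.tsv", "snp_map.tsv", "genotypes.ped", "genotypes.map",
        "phenotypes.csv", "pedigree.csv", "true_effects.csv", "true_qtl.csv",
        "lines.csv",
    ]
    manifest = {}
    for name in written:
        manifest[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
    with open(outdir / "manifest.txt", "w") as fh:
        for name, digest in manifest.items():
            fh.write(f"{digest}  {name}\n")
    return manifest
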