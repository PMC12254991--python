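"""Genotype and sample quality control.

Filter cascade: SNP filters (call rate >= 0.95, MAF >= 0.05 on observed
calls, known autosomal position), then animal filters (more than 3% missing
genotypes removed; Mendelian-inheritance failures removed offspring-side
only), then naive expected-dosage imputation of the remaining missing calls.

The Mendelian test screens each animal against each genotyped parent for
opposing-homozygote conflicts (animal 0 vs parent 2 or vice versa); an
animal fails when its conflict rate over comparable SNPs exceeds the
threshold (default 1%).  Only the offspring failing the test is removed;
the parent is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeData
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = ["QCError", "QCReport", "filter_snps", "filter_animals", "naive_impute", "run_qc"]


class QCError(ValueError):
    """QC produced an empty dataset or received bad thresholds."""

    def __init__(self, msg, report=None):
        super().__init__(msg)
        self.report = report


@dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    steps: list = field(default_factory=list)  # (name, kind, removed, retained)

    def add(self, name: str, kind: str, removed: int, retained: int) -> None:
        self.steps.append({"filter": name, "kind": kind, "removed": removed,
                           "retained": retained})
        logger.info("qc: %s removed %d %s(s), %d retained", name, removed, kind, retained)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def filter_snps(g: GenotypeData, min_call_rate: float = 0.95, min_maf: float = 0.05,
                autosomes=None, report: QCReport | None = None):
    """SNP filters: call rate >= threshold, MAF >= threshold, autosomal position.

    MAF is computed on non-missing calls of the SNPs that survive the
    call-rate filter.  Thresholds keep ties (printed as '>=').
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise QCError("thresholds must be in [0, 1]")
    if autosomes is None:
        autosomes = {str(c) for c in range(1, 22)}
    else:
        autosomes = {str(c) for c in autosomes}
    report = report if report is not None else QCReport()

    chrom = g.snp_map["chrom"].astype(str).to_numpy()
    auto_ok = np.isin(chrom, list(autosomes))
    g1 = g.subset(snp_cols=np.flatnonzero(auto_ok))
    report.add("autosomal_position", "snp", int((~auto_ok).sum()), g1.n_snps)

    call_rate = (g1.dosages != MISSING).mean(axis=0) if g1.n_animals else np.ones(g1.n_snps)
    cr_ok = call_rate >= min_call_rate
    g2 = g1.subset(snp_cols=np.flatnonzero(cr_ok))
    report.add("call_rate", "snp", int((~cr_ok).sum()), g2.n_snps)

    freq = g2.allele_frequency()
    maf = np.fmin(freq, 1.0 - freq)
    maf_ok = maf >= min_maf
    g3 = g2.subset(snp_cols=np.flatnonzero(maf_ok))
    report.add("maf", "snp", int((~maf_ok).sum()), g3.n_snps)

    if g3.n_snps == 0:
        raise QCError("no SNPs retained after SNP filters", report)
    return g3, report


def mendelian_conflict_rate(g: GenotypeData, ped: Pedigree) -> np.ndarray:
    """Per-animal opposing-homozygote conflict rate against genotyped parents.

    Rate = conflicting SNPs / SNPs comparable with at least one genotyped
    parent (NaN when an animal has no genotyped parent).
    """
    idx = {a: i for i, a in enumerate(g.animal_ids)}
    d = g.dosages
    rates = np.full(g.n_animals, np.nan)
    ped_pos = {a: i for i, a in enumerate(ped.animals)}
    for i, animal in enumerate(g.animal_ids):
        p = ped_pos.get(animal)
        if p is None:
            continue
        conflicts = 0
        comparable = 0
        for par_ix in (ped.sire_idx[p], ped.dam_idx[p]):
            if par_ix < 0:
                continue
            row = idx.get(ped.animals[par_ix])
            if row is None:
                continue
            a, b = d[i], d[row]
            ok = (a != MISSING) & (b != MISSING)
            comparable += int(ok.sum())
            conflicts += int((ok & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))).sum())
        if comparable:
            rates[i] = conflicts / comparable
    return rates


def filter_animals(g: GenotypeData, ped: Pedigree | None = None,
                   max_missing: float = 0.03, max_mendel_rate: float = 0.01,
                   report: QCReport | None = None):
    """Remove animals with more than ``max_missing`` missing genotypes or a
    Mendelian conflict rate above ``max_mendel_rate`` (offspring-only removal)."""
    if not (0 <= max_missing <= 1):
        raise QCError("max_missing must be in [0, 1]")
    report = report if report is not None else QCReport()

    miss = (g.dosages == MISSING).mean(axis=1) if g.n_snps else np.zeros(g.n_animals)
    keep = miss <= max_missing  # "more than 3%" removes strictly above
    g1 = g.subset(animal_rows=np.flatnonzero(keep))
    report.add("missingness", "animal", int((~keep).sum()), g1.n_animals)

    if ped is not None:
        rates = mendelian_conflict_rate(g1, ped)
        fail = np.nan_to_num(rates, nan=0.0) > max_mendel_rate
        g2 = g1.subset(animal_rows=np.flatnonzero(~fail))
        report.add("mendelian", "animal", int(fail.sum()), g2.n_animals)
    else:
        g2 = g1
        report.add("mendelian", "animal", 0, g2.n_animals)

    if g2.n_animals == 0:
        raise QCError("no animals retained after animal filters", report)
    return g2, report


def naive_impute(g: GenotypeData, seed: int = 0, stochastic: bool = False) -> GenotypeData:
    """Fill remaining missing dosages from per-SNP observed allele frequency.

    Deterministic mode rounds the expected dosage 2p to {0, 1, 2}; stochastic
    mode samples the genotype under Hardy-Weinberg proportions.  This is a
    single-marker fill, not haplotype-based imputation.
    """
    d = g.dosages.copy()
    miss = d == MISSING
    if not miss.any():
        return g
    logger.warning(
        "naive_impute: single-marker expected-dosage fill; not haplotype-based imputation"
    )
    freq = g.allele_frequency()
    bad = np.isnan(freq) & miss.any(axis=0)
    if bad.any():
        raise QCError(f"{int(bad.sum())} SNP(s) have no observed calls; cannot impute")
    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(miss.any(axis=0)):
        rows = np.flatnonzero(miss[:, j])
        p = freq[j]
        if stochastic:
            d[rows, j] = rng.choice(
                [2, 1, 0], size=rows.size, p=[p * p, 2 * p * (1 - p), (1 - p) ** 2]
            )
        else:
            d[rows, j] = int(np.clip(round(2 * p), 0, 2))
    return GenotypeData(d, g.snp_map.copy(), list(g.animal_ids))


def run_qc(g: GenotypeData, ped: Pedigree | None = None, min_call_rate: float = 0.95,
           min_maf: float = 0.05, autosomes=None, max_missing: float = 0.03,
           max_mendel_rate: float = 0.01, impute_seed: int = 0,
           stochastic_impute: bool = False):
    """Full cascade: SNP filters -> animal filters -> naive imputation."""
    report = QCReport()
    g1, _ = filter_snps(g, min_call_rate, min_maf, autosomes, report)
    g2, _ = filter_animals(g1, ped, max_missing, max_mendel_rate, report)
    g3 = naive_impute(g2, impute_seed, stochastic_impute)
    return g3, report
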