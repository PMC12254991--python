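"""Genotype container and text I/O (plain TSV and PLINK-style .ped/.map).

Dosages are reference-allele counts in {0, 1, 2}; missing calls are coded
``MISSING`` (-1).  The SNP map is a DataFrame aligned with the matrix
columns: ``snp_id``, ``chrom`` (string label), ``pos_bp`` (1-based), and
optional ``a1``/``a2`` allele columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["MISSING", "GenotypeData", "read_genotype_tsv", "read_plink_text"]


class GenotypeDataError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Animals x SNPs dosage matrix with its SNP map and animal IDs."""

    dosages: np.ndarray  # int8, animals x snps, MISSING = -1
    snp_map: pd.DataFrame  # snp_id, chrom, pos_bp[, a1, a2]
    animal_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise GenotypeDataError("dosage matrix must be 2-D (animals x SNPs)")
        if self.dosages.shape[1] != len(self.snp_map):
            raise GenotypeDataError(
                f"SNP map has {len(self.snp_map)} rows but matrix has "
                f"{self.dosages.shape[1]} columns"
            )
        if self.dosages.shape[0] != len(self.animal_ids):
            raise GenotypeDataError("animal_ids length must match matrix rows")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise GenotypeDataError("dosages must be 0, 1, 2 or missing (-1)")
        pos = self.snp_map["pos_bp"].to_numpy()
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            p = grp["pos_bp"].to_numpy()
            if np.any(np.diff(p) < 0):
                raise GenotypeDataError("positions must be non-decreasing within chromosome")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Reference-allele frequency per SNP over non-missing calls (NaN if none)."""
        d = self.dosages
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / (2.0 * np.where(n_obs > 0, n_obs, np.nan))

    def subset(self, animal_rows=None, snp_cols=None) -> "GenotypeData":
        d = self.dosages
        ids = self.animal_ids
        smap = self.snp_map
        if animal_rows is not None:
            animal_rows = np.asarray(animal_rows)
            d = d[animal_rows]
            ids = [self.animal_ids[i] for i in animal_rows]
        if snp_cols is not None:
            snp_cols = np.asarray(snp_cols)
            d = d[:, snp_cols]
            smap = smap.iloc[snp_cols].reset_index(drop=True)
        return GenotypeData(d.copy(), smap.copy(), list(ids))

    # ---- text I/O -------------------------------------------------------

    def write_tsv(self, genotype_path, map_path) -> None:
        """Animal-rows TSV (first column animal_id) plus a SNP-map TSV."""
        df = pd.DataFrame(self.dosages, columns=self.snp_map["snp_id"])
        df.insert(0, "animal_id", self.animal_ids)
        df.to_csv(genotype_path, sep="\t", index=False)
        self.snp_map.to_csv(map_path, sep="\t", index=False)

    def write_plink_text(self, prefix) -> None:
        """PLINK-style .ped/.map text dialect.

        .map: chrom, snp_id, 0 (cM), pos_bp.  .ped: FID IID 0 0 0 -9 then two
        allele columns per SNP (alleles 'A' = reference, 'B' = alternative,
        '0 0' = missing); heterozygotes written 'A B'.
        """
        smap = self.snp_map
        with open(f"{prefix}.map", "w") as fh:
            for _, r in smap.iterrows():
                fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{int(r['pos_bp'])}\n")
        code = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
        with open(f"{prefix}.ped", "w") as fh:
            for i, aid in enumerate(self.animal_ids):
                cells = [code[int(x)] for x in self.dosages[i]]
                fh.write(f"{aid} {aid} 0 0 0 -9 " + " ".join(cells) + "\n")


def read_genotype_tsv(genotype_path, map_path) -> GenotypeData:
    gdf = pd.read_csv(genotype_path, sep="\t")
    smap = pd.read_csv(map_path, sep="\t")
    smap["chrom"] = smap["chrom"].astype(str)
    ids = gdf["animal_id"].tolist()
    d = gdf.drop(columns=["animal_id"]).to_numpy(dtype=np.int8)
    return GenotypeData(d, smap, ids)


def read_plink_text(prefix) -> GenotypeData:
    """Read the PLINK-style text dialect written by ``write_plink_text``."""
    rows = []
    with open(f"{prefix}.map") as fh:
        for line in fh:
            chrom, snp_id, _cm, pos = line.split()
            rows.append((snp_id, chrom, int(pos)))
    smap = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])
    ids, dosa = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(smap):
                raise GenotypeDataError(".ped allele columns do not match .map")
            row = np.empty(len(smap), dtype=np.int8)
            for j in range(len(smap)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    row[j] = MISSING
                else:
                    row[j] = (a == "A") + (b == "A")
            dosa.append(row)
    return GenotypeData(np.array(dosa, dtype=np.int8), smap, ids)
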