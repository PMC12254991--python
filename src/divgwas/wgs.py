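"""Screen annotated whole-genome-sequencing variants for line-divergent,
impactful alleles inside associated regions.

The screen keeps moderate/high-impact coding variants (missense, frameshift,
start lost, stop gained, conservative inframe indels), computes per-line
alternative-allele frequencies from called genotypes, and retains a variant
when either (1) one allele is fixed in one line and below frequency 0.5 in
the other, or (2) the two lines segregate at opposite frequencies, both
strictly above 0.65.  'Fixed' means frequency exactly 1.0 among called
samples — a variant fixed in one line but at 0.6 in the other fails
criterion 1 (the documented borderline case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "LineFrequencies",
    "read_variant_tsv",
    "read_vcf",
    "impact_filter",
    "line_frequencies",
    "divergence_filter",
    "intersect_regions",
    "screen_variants",
]

IMPACT_CLASSES = {"HIGH", "MODERATE", "LOW", "MODIFIER"}
RETAINED_IMPACTS = {"HIGH", "MODERATE"}
RETAINED_CONSEQUENCES = {
    "missense_variant",
    "frameshift_variant",
    "start_lost",
    "stop_gained",
    "conservative_inframe_deletion",
    "conservative_inframe_insertion",
}
GT_MISSING = -1


class VariantError(ValueError):
    pass


@dataclass
class VariantRecord:
    chrom: str
    pos_bp: int
    ref: str
    alt: str
    consequences: tuple  # sequence-ontology terms
    impact: str  # HIGH / MODERATE / LOW / MODIFIER
    gene: str
    genotypes: dict  # sample -> alt-allele count 0/1/2 or GT_MISSING
    regions: tuple = ()

    def __post_init__(self):
        if self.pos_bp < 1:
            raise VariantError(f"position must be >= 1, got {self.pos_bp}")


@dataclass
class LineFrequencies:
    """Per-variant alt-allele frequency and call count per line."""

    freq: dict = field(default_factory=dict)  # line -> frequency
    n_called: dict = field(default_factory=dict)  # line -> diploid samples called

    def defined(self, lines=("H", "L")) -> bool:
        return all(self.n_called.get(l, 0) > 0 for l in lines)


def read_variant_tsv(path) -> list[VariantRecord]:
    """Flat TSV: chrom, pos, ref, alt, consequence (&-joined), impact, gene,
    then one genotype column per sample ('0/0', '0/1', '1/1', './.')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["chrom", "pos", "ref", "alt", "consequence", "impact", "gene"]
    missing_cols = [c for c in fixed if c not in df.columns]
    if missing_cols:
        raise VariantError(f"variant TSV lacks columns: {missing_cols}")
    samples = [c for c in df.columns if c not in fixed]
    out = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        gts = {}
        for s in samples:
            gt = getattr(row, s)
            alleles = str(gt).replace("|", "/").split("/")
            if "." in alleles or gt is None:
                gts[s] = GT_MISSING
            else:
                try:
                    gts[s] = sum(int(a) > 0 for a in alleles)
                except ValueError as exc:
                    raise VariantError(f"line {ln}: malformed genotype {gt!r}") from exc
        out.append(VariantRecord(
            chrom=str(row.chrom), pos_bp=int(row.pos), ref=row.ref, alt=row.alt,
            consequences=tuple(str(row.consequence).split("&")),
            impact=str(row.impact), gene=str(row.gene), genotypes=gts,
        ))
    return out


def read_vcf(path, ann_field: str = "ANN") -> list[VariantRecord]:
    """Read an annotated VCF; the annotation INFO field carries
    'allele|consequence|impact|gene|...' entries (snpEff ANN layout)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for v in vcf:
        ann = v.INFO.get(ann_field)
        consequences: tuple = ()
        impact = "MODIFIER"
        gene = ""
        if ann:
            first = str(ann).split(",")[0].split("|")
            if len(first) >= 4:
                consequences = tuple(first[1].split("&"))
                impact = first[2]
                gene = first[3]
        gts = {}
        for s_ix, s in enumerate(samples):
            g = v.genotypes[s_ix]
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                gts[s] = GT_MISSING
            else:
                gts[s] = sum(a > 0 for a in alleles)
        alt = v.ALT[0] if v.ALT else "."
        out.append(VariantRecord(
            chrom=str(v.CHROM), pos_bp=int(v.POS), ref=v.REF, alt=alt,
            consequences=consequences, impact=impact, gene=gene, genotypes=gts,
        ))
    return out


def impact_filter(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep variants with MODERATE/HIGH impact and a listed consequence."""
    bad = [v for v in variants if v.impact not in IMPACT_CLASSES]
    if bad:
        names = ", ".join(f"{v.chrom}:{v.pos_bp}={v.impact!r}" for v in bad[:5])
        raise VariantError(f"unknown impact token(s): {names}")
    kept = [
        v for v in variants
        if v.impact in RETAINED_IMPACTS and set(v.consequences) & RETAINED_CONSEQUENCES
    ]
    logger.info("impact_filter: %d of %d variants retained", len(kept), len(variants))
    return kept


def line_frequencies(variant: VariantRecord, line_assignment: dict) -> LineFrequencies:
    """Alt-allele frequency per line: alt count / (2 x called samples)."""
    lf = LineFrequencies()
    counts: dict = {}
    called: dict = {}
    for sample, gt in variant.genotypes.items():
        if sample not in line_assignment:
            continue
        line = line_assignment[sample]
        if gt == GT_MISSING:
            continue
        counts[line] = counts.get(line, 0) + gt
        called[line] = called.get(line, 0) + 1
    for line, n in called.items():
        lf.freq[line] = counts.get(line, 0) / (2.0 * n)
        lf.n_called[line] = n
    return lf


def _passes_divergence(fH: float, fL: float, fixed_other_max: float,
                       opposite_min: float) -> str | None:
    """Return the criterion label satisfied by alt frequencies (fH, fL).

    Criterion 1: some allele at frequency exactly 1.0 in one line while the
    same allele is below ``fixed_other_max`` in the other.  Criterion 2: one
    allele strictly above ``opposite_min`` in one line while the alternative
    allele is strictly above it in the other (i.e. the alt frequency is
    > opposite_min in one line and < 1 - opposite_min in the other).
    Both are symmetric under swapping lines and under ref/alt recoding.
    """
    for p, q in ((fH, fL), (fL, fH)):
        for a, b in ((p, q), (1 - p, 1 - q)):  # alt allele, then ref allele
            if a == 1.0 and b < fixed_other_max:
                return "fixed_vs_segregating"
    for p, q in ((fH, fL), (fL, fH)):
        if p > opposite_min and (1 - q) > opposite_min:
            return "opposite_frequencies"
    return None


def divergence_filter(variants: list[VariantRecord], line_assignment: dict,
                      fixed_other_max: float = 0.5, opposite_min: float = 0.65,
                      lines=("H", "L")) -> pd.DataFrame:
    """Retain line-divergent variants; returns a table with frequencies and
    the satisfied criterion.  Variants with no called samples in a line are
    skipped with a log entry."""
    if not (0.0 < fixed_other_max <= 1.0):
        raise VariantError(f"fixed_other_max must be in (0, 1], got {fixed_other_max}")
    if not (0.5 < opposite_min <= 1.0):
        raise VariantError(f"opposite_min must be in (0.5, 1], got {opposite_min}")
    rows = []
    for v in variants:
        lf = line_frequencies(v, line_assignment)
        if not lf.defined(lines):
            logger.info("divergence_filter: %s:%d skipped (a line has no calls)",
                        v.chrom, v.pos_bp)
            continue
        crit = _passes_divergence(lf.freq[lines[0]], lf.freq[lines[1]],
                                  fixed_other_max, opposite_min)
        if crit is not None:
            rows.append({
                "chrom": v.chrom, "pos_bp": v.pos_bp, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "consequence": "&".join(v.consequences),
                "impact": v.impact,
                f"freq_{lines[0]}": lf.freq[lines[0]],
                f"freq_{lines[1]}": lf.freq[lines[1]],
                "criterion": crit,
                "regions": ";".join(str(r) for r in v.regions),
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "pos_bp", "ref", "alt", "gene", "consequence", "impact",
        f"freq_{lines[0]}", f"freq_{lines[1]}", "criterion", "regions",
    ])


def intersect_regions(variants: list[VariantRecord], regions) -> list[VariantRecord]:
    """Label each variant with the region(s) containing its position
    (1-based inclusive on [start_bp, end_bp])."""
    out = []
    for v in variants:
        hits = tuple(
            f"{r.chrom}:{r.start_bp}-{r.end_bp}"
            for r in regions
            if str(r.chrom) == v.chrom and r.start_bp <= v.pos_bp <= r.end_bp
        )
        out.append(VariantRecord(
            chrom=v.chrom, pos_bp=v.pos_bp, ref=v.ref, alt=v.alt,
            consequences=v.consequences, impact=v.impact, gene=v.gene,
            genotypes=v.genotypes, regions=hits,
        ))
    return out


def screen_variants(variants: list[VariantRecord], line_assignment: dict,
                    regions=None, fixed_other_max: float = 0.5,
                    opposite_min: float = 0.65,
                    require_region: bool | None = None) -> pd.DataFrame:
    """Full screen: impact filter -> divergence filter -> region intersection.

    When ``regions`` is given, variants outside every region are dropped
    (set ``require_region=False`` to keep them, labelled).  Per-stage counts
    are logged.
    """
    missing = set()
    for v in variants:
        missing |= set(line_assignment) - set(v.genotypes)
    if missing:
        raise VariantError(f"samples in line map but absent from variants: {sorted(missing)}")
    n0 = len(variants)
    kept = impact_filter(variants)
    if regions is not None:
        kept = intersect_regions(kept, regions)
        if require_region is None or require_region:
            kept = [v for v in kept if v.regions]
    logger.info("screen: %d input, %d after impact, running divergence filter", n0, len(kept))
    table = divergence_filter(kept, line_assignment, fixed_other_max, opposite_min)
    logger.info("screen: %d variants retained", len(table))
    return table
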