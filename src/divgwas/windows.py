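"""Sliding-window genetic variance, association calling and region merging.

One 1-Mb window is anchored at every SNP (half-open: members are the SNPs
with position in [anchor, anchor + 1 Mb) on the anchor's chromosome), so the
window count equals the SNP count minus end-of-chromosome attrition of
distinct member sets.  Per saved MCMC draw, a window's genetic value per
individual is the sum of its members' centered dosage x sampled effect; its
variance share is the across-individual variance of that value divided by
the variance of the whole-genome marker value of the same draw (x100).
Windows whose posterior-mean share reaches the association threshold
(default 0.75% of genetic variance) are merged into regions when they
overlap.  Bivariately, the window genetic correlation is the per-draw
Pearson correlation across individuals between the two traits' window
values, summarized by posterior mean and SD over the draws where both
variances are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .bayesb import PosteriorSamples
from .genotypes import GenotypeData

__all__ = [
    "WindowMap",
    "WindowResult",
    "Region",
    "build_windows",
    "window_variance",
    "call_regions",
    "window_genetic_correlation",
    "manhattan_plot",
]

WINDOW_BP = 1_000_000
ASSOC_THRESHOLD_PCT = 0.75


class WindowError(ValueError):
    pass


@dataclass
class WindowMap:
    """Per-anchor member ranges: window w covers map indices [anchor[w], end[w])."""

    chrom: np.ndarray  # per window, chromosome label (str array)
    anchor: np.ndarray  # int index into the SNP map
    end: np.ndarray  # exclusive member end index
    start_bp: np.ndarray
    end_bp: np.ndarray  # position of last member SNP
    duplicate: np.ndarray  # True if member set equals the previous anchor's
    window_bp: int = WINDOW_BP

    def __len__(self) -> int:
        return len(self.anchor)


def build_windows(snp_map: pd.DataFrame, window_bp: int = WINDOW_BP) -> WindowMap:
    """SNP-anchored sliding windows over a position-sorted map."""
    chrom = snp_map["chrom"].astype(str).to_numpy()
    pos = snp_map["pos_bp"].to_numpy(dtype=np.int64)
    k = len(snp_map)
    ends = np.empty(k, dtype=np.int64)
    start = 0
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        if np.any(np.diff(p) < 0):
            raise WindowError(f"SNP map not sorted within chromosome {c}")
        # half-open: position exactly anchor + window_bp is excluded
        ends[sel] = sel[0] + np.searchsorted(p, p + window_bp, side="left")
        start += len(sel)
    anchors = np.arange(k, dtype=np.int64)
    dup = np.zeros(k, dtype=bool)
    if k > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        dup[1:] = same_chrom & (ends[1:] == ends[:-1]) & (pos[1:] == pos[:-1])
    return WindowMap(
        chrom=chrom.copy(), anchor=anchors, end=ends,
        start_bp=pos.copy(), end_bp=pos[np.maximum(ends - 1, 0)].copy(),
        duplicate=dup, window_bp=window_bp,
    )


@njit(cache=True)
def _window_kernel(ZT, alpha, delta, anchor, wend, urec, use_poly,
                   share_sum, share_cnt, ppa_cnt, gc_sum, gc_sumsq, gc_cnt,
                   tot_pos):
    S, k, t = alpha.shape
    n = ZT.shape[1]
    nw = anchor.shape[0]
    g = np.zeros((t, n))
    gw = np.zeros((t, n))
    cum = np.zeros((t, k + 1), dtype=np.int64)
    var_tot = np.zeros(t)
    var_w = np.zeros(t)
    for s in range(S):
        for t_ in range(t):
            for i in range(n):
                g[t_, i] = 0.0
            for j in range(k):
                cum[t_, j + 1] = cum[t_, j] + (1 if delta[s, j, t_] != 0 else 0)
                a = alpha[s, j, t_]
                if a != 0.0:
                    for i in range(n):
                        g[t_, i] += ZT[j, i] * a
            if use_poly:
                for i in range(n):
                    g[t_, i] += urec[s, i, t_]
            mean = 0.0
            for i in range(n):
                mean += g[t_, i]
            mean /= n
            v = 0.0
            for i in range(n):
                dv = g[t_, i] - mean
                v += dv * dv
            var_tot[t_] = v / n
            if var_tot[t_] > 0.0:
                tot_pos[t_] += 1
        for w in range(nw):
            a0 = anchor[w]
            e0 = wend[w]
            any_active = False
            for t_ in range(t):
                if cum[t_, e0] > cum[t_, a0]:
                    any_active = True
            if not any_active:
                continue
            for t_ in range(t):
                n_act = cum[t_, e0] - cum[t_, a0]
                if n_act > 0:
                    ppa_cnt[w, t_] += 1
                for i in range(n):
                    gw[t_, i] = 0.0
                if n_act > 0:
                    for j in range(a0, e0):
                        a = alpha[s, j, t_]
                        if a != 0.0:
                            for i in range(n):
                                gw[t_, i] += ZT[j, i] * a
                mean = 0.0
                for i in range(n):
                    mean += gw[t_, i]
                mean /= n
                v = 0.0
                for i in range(n):
                    dv = gw[t_, i] - mean
                    v += dv * dv
                var_w[t_] = v / n
                if var_tot[t_] > 0.0 and n_act > 0:
                    share_sum[w, t_] += var_w[t_] / var_tot[t_] * 100.0
                if var_tot[t_] > 0.0:
                    share_cnt[w, t_] += 1
            if t == 2 and var_w[0] > 0.0 and var_w[1] > 0.0:
                m0 = 0.0
                m1 = 0.0
                for i in range(n):
                    m0 += gw[0, i]
                    m1 += gw[1, i]
                m0 /= n
                m1 /= n
                cov = 0.0
                for i in range(n):
                    cov += (gw[0, i] - m0) * (gw[1, i] - m1)
                r = cov / n / np.sqrt(var_w[0] * var_w[1])
                gc_sum[w] += r
                gc_sumsq[w] += r * r
                gc_cnt[w] += 1


@dataclass
class WindowResult:
    """Posterior window summaries plus the handles needed downstream."""

    table: pd.DataFrame
    wmap: WindowMap
    n_traits: int
    n_draws: int
    denominator_mode: str
    no_genetic_variance: bool = False
    samples: PosteriorSamples | None = field(default=None, repr=False)
    genotypes: GenotypeData | None = field(default=None, repr=False)


def window_variance(samples: PosteriorSamples, wmap: WindowMap,
                    genotypes: GenotypeData,
                    denominator_mode: str = "markers",
                    animal_index: np.ndarray | None = None) -> WindowResult:
    """Posterior-mean percentage of genetic variance per window and trait.

    ``denominator_mode='markers'`` divides by the whole-genome marker
    variance of the same draw; ``'markers+polygenic'`` adds the polygenic
    value (requires ``animal_index`` mapping records to pedigree rows).
    Draws with zero total variance are skipped for the share; per-window PPA
    counts every draw.
    """
    if samples.n_saved < 1:
        raise WindowError("zero saved draws")
    if denominator_mode not in ("markers", "markers+polygenic"):
        raise WindowError("denominator_mode must be 'markers' or 'markers+polygenic'")
    t = samples.n_traits
    Z = genotypes.dosages.astype(np.float64)
    if Z.shape[1] != samples.alpha.shape[1]:
        raise WindowError("genotype columns do not match sampled effects")
    Z = Z - Z.mean(axis=0, keepdims=True)
    ZT = np.ascontiguousarray(Z.T)
    use_poly = denominator_mode == "markers+polygenic"
    if use_poly:
        if animal_index is None or samples.u.shape[1] == 0:
            raise WindowError("markers+polygenic mode needs animal_index and sampled u")
        urec = np.ascontiguousarray(samples.u[:, animal_index, :])
    else:
        urec = np.zeros((1, ZT.shape[1], t))
    nw = len(wmap)
    share_sum = np.zeros((nw, t))
    share_cnt = np.zeros((nw, t), dtype=np.int64)
    ppa_cnt = np.zeros((nw, t), dtype=np.int64)
    gc_sum = np.zeros(nw)
    gc_sumsq = np.zeros(nw)
    gc_cnt = np.zeros(nw, dtype=np.int64)
    tot_pos = np.zeros(t, dtype=np.int64)
    _window_kernel(ZT, samples.alpha, samples.delta, wmap.anchor, wmap.end,
                   urec, use_poly, share_sum, share_cnt, ppa_cnt,
                   gc_sum, gc_sumsq, gc_cnt, tot_pos)
    S = samples.n_saved
    with np.errstate(invalid="ignore", divide="ignore"):
        # a window with no active member in a contributing draw has share 0
        # there, so the posterior mean divides by the contributing-draw count
        share_mean = share_sum / tot_pos[None, :].astype(float)
        gc_mean = np.where(gc_cnt > 0, gc_sum / np.maximum(gc_cnt, 1), np.nan)
        gc_var = np.where(
            gc_cnt > 0,
            np.maximum(gc_sumsq / np.maximum(gc_cnt, 1) - gc_mean**2, 0.0),
            np.nan,
        )
    no_gv = bool((tot_pos == 0).all())
    cols = {
        "window": np.arange(nw),
        "chrom": wmap.chrom,
        "start_bp": wmap.start_bp,
        "end_bp": wmap.end_bp,
        "n_snps": wmap.end - wmap.anchor,
        "duplicate": wmap.duplicate,
    }
    for t_ in range(t):
        cols[f"pct_var_trait{t_ + 1}"] = share_mean[:, t_]
        cols[f"ppa_trait{t_ + 1}"] = ppa_cnt[:, t_] / S
    if t == 2:
        cols["gencor_mean"] = gc_mean
        cols["gencor_sd"] = np.sqrt(gc_var)
        cols["gencor_n_draws"] = gc_cnt
    return WindowResult(
        table=pd.DataFrame(cols), wmap=wmap, n_traits=t, n_draws=S,
        denominator_mode=denominator_mode, no_genetic_variance=no_gv,
        samples=samples, genotypes=genotypes,
    )


@dataclass
class Region:
    chrom: str
    start_bp: int
    end_bp: int
    windows: list
    trait: int  # 1-based trait the call was made on
    max_pct_var: float
    ppa: float
    gencor_highest: float = np.nan
    gencor_highest_sd: float = np.nan
    max_pct_var_other: float = np.nan

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start_bp": self.start_bp, "end_bp": self.end_bp,
            "trait": self.trait, "n_windows": len(self.windows),
            "max_pct_var": self.max_pct_var, "ppa": self.ppa,
            "gencor_highest": self.gencor_highest,
            "gencor_highest_sd": self.gencor_highest_sd,
        }


def call_regions(result: WindowResult, threshold_pct: float = ASSOC_THRESHOLD_PCT,
                 trait: int = 1) -> list[Region]:
    """Merge overlapping associated windows (share >= threshold) into regions.

    Region PPA is the fraction of saved draws in which at least one member
    SNP of the region has a nonzero effect for the trait; the region's
    'highest' genetic correlation is the constituent window posterior-mean
    correlation largest in magnitude (bivariate runs).
    """
    tbl = result.table
    col = f"pct_var_trait{trait}"
    if col not in tbl.columns:
        raise WindowError(f"trait {trait} not present in window result")
    flagged = tbl.index[tbl[col].fillna(-np.inf) >= threshold_pct].to_numpy()
    wmap = result.wmap
    regions: list[Region] = []
    if flagged.size == 0:
        return regions
    runs: list[list[int]] = [[flagged[0]]]
    for w in flagged[1:]:
        prev = runs[-1][-1]
        same = wmap.chrom[w] == wmap.chrom[prev]
        overlapping = same and wmap.anchor[w] < max(wmap.end[x] for x in runs[-1])
        if overlapping:
            runs[-1].append(w)
        else:
            runs.append([w])
    delta = result.samples.delta if result.samples is not None else None
    for run in runs:
        first, last = run[0], run[-1]
        members = np.arange(wmap.anchor[first], max(wmap.end[x] for x in run))
        ppa = np.nan
        if delta is not None:
            ppa = float((delta[:, members, trait - 1].sum(axis=1) > 0).mean())
        gch = gchsd = np.nan
        if "gencor_mean" in tbl.columns:
            sub = tbl.loc[run, ["gencor_mean", "gencor_sd"]].dropna(subset=["gencor_mean"])
            if len(sub):
                ix = sub["gencor_mean"].abs().idxmax()
                gch = float(sub.loc[ix, "gencor_mean"])
                gchsd = float(sub.loc[ix, "gencor_sd"])
        other = np.nan
        other_col = f"pct_var_trait{3 - trait}"
        if other_col in tbl.columns:
            other = float(tbl.loc[run, other_col].max())
        regions.append(Region(
            chrom=str(wmap.chrom[first]),
            start_bp=int(wmap.start_bp[first]),
            end_bp=int(max(wmap.end_bp[x] for x in run)),
            windows=list(run), trait=trait,
            max_pct_var=float(tbl.loc[run, col].max()),
            ppa=ppa, gencor_highest=gch, gencor_highest_sd=gchsd,
            max_pct_var_other=other,
        ))
    return regions


def window_genetic_correlation(samples: PosteriorSamples, member_snps,
                               genotypes: GenotypeData) -> dict:
    """Posterior mean/SD of the genetic correlation of an arbitrary SNP set.

    Per saved draw, the Pearson correlation across individuals between the
    two traits' summed marker values over ``member_snps``; draws where either
    variance is zero are skipped.  Returns mean, sd and the contributing-draw
    count (mean is NaN, flagged 'undefined', when no draw contributes).
    """
    if samples.n_traits != 2:
        raise WindowError("window genetic correlation requires bivariate samples")
    members = np.asarray(member_snps, dtype=np.int64)
    Z = genotypes.dosages[:, members].astype(float)
    Z = Z - Z.mean(axis=0, keepdims=True)
    vals = []
    for s in range(samples.n_saved):
        g1 = Z @ samples.alpha[s, members, 0]
        g2 = Z @ samples.alpha[s, members, 1]
        v1, v2 = g1.var(), g2.var()
        if v1 > 0 and v2 > 0:
            cov = ((g1 - g1.mean()) * (g2 - g2.mean())).mean()
            vals.append(cov / np.sqrt(v1 * v2))
    if not vals:
        return {"mean": np.nan, "sd": np.nan, "n_draws": 0, "undefined": True}
    arr = np.asarray(vals)
    return {"mean": float(arr.mean()), "sd": float(arr.std()),
            "n_draws": len(vals), "undefined": False}


def write_regions_bed(regions: list[Region], path) -> None:
    """BED-like TSV (0-based half-open start for BED compatibility)."""
    rows = []
    for r in regions:
        d = r.to_dict()
        d["start_bp"] = d["start_bp"] - 1
        rows.append(d)
    pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "trait", "n_windows",
                                "max_pct_var", "ppa", "gencor_highest",
                                "gencor_highest_sd"]).to_csv(path, sep="\t", index=False)


def write_region_table(regions: list[Region], path) -> None:
    """Region summary CSV shaped like the per-trait association tables."""
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom,
            "start_mb": r.start_bp / 1e6,
            "end_mb": r.end_bp / 1e6,
            "trait": r.trait,
            "pct_gen_var": round(r.max_pct_var, 2),
            "ppa": round(r.ppa, 4) if np.isfinite(r.ppa) else "",
            "highest_gencor": round(r.gencor_highest, 2) if np.isfinite(r.gencor_highest) else "",
            "gencor_sd": round(r.gencor_highest_sd, 4) if np.isfinite(r.gencor_highest_sd) else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def manhattan_plot(result: WindowResult, trait: int, path,
                   thresholds=(0.75, 1.50)) -> None:
    """Window variance share vs genomic position with threshold tiers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbl = result.table
    col = f"pct_var_trait{trait}"
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for c in pd.unique(tbl["chrom"]):
        sub = tbl[tbl["chrom"] == c]
        x = sub["start_bp"].to_numpy() + offset
        y = sub[col].to_numpy()
        base = ax.scatter(x, y, s=4, alpha=0.6)
        hi = y >= thresholds[0]
        hi2 = y >= thresholds[1]
        ax.scatter(x[hi & ~hi2], y[hi & ~hi2], s=8, color="tab:blue")
        ax.scatter(x[hi2], y[hi2], s=10, color="tab:orange")
        ticks.append(offset + (sub["start_bp"].max() if len(sub) else 0) / 2)
        labels.append(str(c))
        offset += (sub["start_bp"].max() if len(sub) else 0) + 1
    for th, style in zip(thresholds, ("--", ":")):
        ax.axhline(th, linestyle=style, color="grey", linewidth=0.8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% genetic variance (1-Mb window)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
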