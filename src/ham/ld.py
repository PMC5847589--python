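"""Pairwise linkage disequilibrium (D, D', r^2) and LD-decay summaries.

Inbred lines are treated as single haplotype draws: each non-heterozygous,
non-missing call contributes one two-locus haplotype, so haplotype
frequencies are estimated directly without EM phasing.  D = p(AB) -
p(A)p(B); D' = |D| / Dmax with the usual sign-dependent Dmax; r^2 =
D^2 / (p(A) p(a) p(B) p(b)), which equals the squared Pearson correlation
of the 0/1 allele indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeTable


@dataclass
class LDResult:
    snp_a: str
    snp_b: str
    D: float
    Dprime: float
    r2: float
    n: int
    defined: bool = True


def pairwise_ld(col_a: np.ndarray, col_b: np.ndarray,
                snp_a: str = "a", snp_b: str = "b") -> LDResult:
    """LD between two SNP genotype columns from inbred lines.

    Heterozygous and missing entries are pairwise-deleted.  Monomorphic
    columns give undefined LD, flagged via ``defined=False`` (not zero).
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    keep = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    a, b = a[keep] // 2, b[keep] // 2  # alt-allele indicators
    n = len(a)
    if n < 2:
        return LDResult(snp_a, snp_b, np.nan, np.nan, np.nan, n, defined=False)
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDResult(snp_a, snp_b, np.nan, np.nan, np.nan, n, defined=False)
    pAB = (a & b).mean()
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = np.nan
    dprime = abs(D) / dmax if D != 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDResult(snp_a, snp_b, float(D), float(dprime), float(r2), n)


def ld_table(gt: GenotypeTable, window_bp: int = 5_000_000) -> pd.DataFrame:
    """Long-format LD for all SNP pairs within ``window_bp`` per chromosome."""
    if window_bp <= 0:
        raise ValueError("window must be positive")
    rows = []
    for c in pd.unique(gt.chrom):
        idx = np.flatnonzero(gt.chrom == c)
        for j, k in combinations(range(len(idx)), 2):
            d = int(gt.pos_bp[idx[k]] - gt.pos_bp[idx[j]])
            if d > window_bp:
                continue
            res = pairwise_ld(
                gt.calls[:, idx[j]], gt.calls[:, idx[k]],
                gt.snp_ids[idx[j]], gt.snp_ids[idx[k]],
            )
            rows.append((res.snp_a, res.snp_b, c, d, res.D, res.Dprime, res.r2,
                         res.defined))
    return pd.DataFrame(
        rows, columns=["snp_a", "snp_b", "chrom", "dist_bp", "D", "Dprime", "r2",
                       "defined"]
    )


def ld_decay(
    gt: GenotypeTable,
    window_bp: int = 5_000_000,
    n_bins: int = 20,
    subsample_fraction: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 and D' per distance bin over within-window SNP pairs.

    ``subsample_fraction`` randomly thins the SNP set first (reproducible by
    seed), mirroring the usual practice of computing LD heatmaps on a
    random marker subset to bound the O(n^2) pair count.
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    if subsample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        keep = np.zeros(gt.n_snps, dtype=bool)
        k = max(2, int(round(subsample_fraction * gt.n_snps)))
        keep[rng.choice(gt.n_snps, size=k, replace=False)] = True
        gt = gt.subset(snp_mask=keep)
    table = ld_table(gt, window_bp)
    table = table[table["defined"].astype(bool)]
    edges = np.linspace(0, window_bp, n_bins + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = table[(table["dist_bp"] >= lo) & (table["dist_bp"] < hi)]
        if len(sel):
            out.append((lo, hi, len(sel), sel["r2"].mean(), sel["Dprime"].mean()))
    return pd.DataFrame(
        out, columns=["dist_lo_bp", "dist_hi_bp", "n_pairs", "mean_r2", "mean_Dprime"]
    )


def cumulative_positions(gt: GenotypeTable) -> np.ndarray:
    """Genome-cumulative bp coordinate (chr1..chrN concatenated) per SNP,
    the axis convention used for whole-genome LD heatmaps."""
    offset = 0
    out = np.empty(gt.n_snps, dtype=np.int64)
    for c in pd.unique(gt.chrom):
        idx = np.flatnonzero(gt.chrom == c)
        out[idx] = gt.pos_bp[idx] + offset
        offset += int(gt.pos_bp[idx].max())
    return out
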