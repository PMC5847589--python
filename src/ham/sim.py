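"""Simulator for multi-parent (MAGIC) crossing designs.

Emulates the funnel used to build 8-founder rice MAGIC populations: two-way
crosses among inbred founders, four-way and eight-way intercrosses, then
single-seed descent (SSD).  Meiosis follows the Haldane model: crossover
counts per chromosome are Poisson(length_cM / 100) with positions uniform
in cM and no interference.  The simulator returns the true founder mosaic
of every line alongside GBS-like genotypes with configurable genotyping
error and missingness, so haplotype reconstruction and GWAS can be scored
against known truth.

Defaults mirror the population the package targets: 8 founders, 100
eight-way intercross families, 4 lines per family (~400 lines), F5 lines
(four selfing generations, residual heterozygosity ~(1/2)^4 per locus) on
a 12-chromosome rice-like genome at 4 cM/Mb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, FounderPanel, GenotypeTable, PhenotypeTable

# homolog = ordered list of (start_bp, end_bp, founder_index), half-open
# [start, end) in 1-based coordinates; segments tile [1, L+1).
Homolog = list[tuple[int, int, int]]

#: rice chromosome lengths (bp), chr1..chr12
RICE_CHROM_LENGTHS_BP = {
    f"chr{i + 1:02d}": int(mb * 1e6)
    for i, mb in enumerate([43, 36, 36, 35, 30, 31, 30, 28, 23, 23, 29, 27])
}


@dataclass
class GeneticMap:
    """Per-chromosome physical and genetic lengths with a linear bp<->cM map."""

    table: pd.DataFrame  # columns: chrom, length_bp, length_cm

    def __post_init__(self) -> None:
        self._bp = dict(zip(self.table["chrom"], self.table["length_bp"].astype(int)))
        self._cm = dict(zip(self.table["chrom"], self.table["length_cm"].astype(float)))

    @classmethod
    def uniform(cls, lengths_bp: dict[str, int], cm_per_mb: float = 4.0) -> "GeneticMap":
        df = pd.DataFrame(
            {
                "chrom": list(lengths_bp),
                "length_bp": list(lengths_bp.values()),
            }
        )
        df["length_cm"] = df["length_bp"] * (cm_per_mb / 1e6)
        return cls(df)

    @classmethod
    def rice_like(cls, cm_per_mb: float = 4.0) -> "GeneticMap":
        return cls.uniform(RICE_CHROM_LENGTHS_BP, cm_per_mb)

    @property
    def chroms(self) -> list[str]:
        return self.table["chrom"].tolist()

    def length_bp(self, chrom: str) -> int:
        return self._bp[chrom]

    def length_cm(self, chrom: str) -> float:
        return self._cm[chrom]

    def cm_to_bp(self, chrom: str, cm: float) -> int:
        L_bp, L_cm = self.length_bp(chrom), self.length_cm(chrom)
        if L_cm <= 0:
            return 1
        return int(np.clip(round(cm / L_cm * L_bp), 1, L_bp))

    def bp_to_cm(self, chrom: str, bp: np.ndarray | float):
        L_bp, L_cm = self.length_bp(chrom), self.length_cm(chrom)
        return np.asarray(bp, dtype=float) / L_bp * L_cm


@dataclass
class CrossDesign:
    """A balanced 2^k-founder funnel followed by SSD inbreeding."""

    founder_ids: list[str]
    n_families: int = 100
    n_lines_per_family: int = 4
    selfing_generations: int = 4

    def __post_init__(self) -> None:
        n = len(self.founder_ids)
        if n == 0:
            raise ValueError("empty design: zero founders")
        if n & (n - 1) or n < 2:
            raise ValueError("founder count must be a power of two >= 2")
        if len(set(self.founder_ids)) != n:
            raise ValueError("founder ids must be unique")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")


@dataclass
class TrueMosaic:
    """True founder-origin segments for every simulated line.

    ``segments[line_id][chrom]`` holds the two homologs, each an ordered
    list of half-open ``(start_bp, end_bp, founder_index)`` tuples tiling
    the chromosome exactly.
    """

    founder_ids: list[str]
    chrom_lengths: dict[str, int]
    segments: dict[str, dict[str, tuple[Homolog, Homolog]]]

    @property
    def line_ids(self) -> list[str]:
        return list(self.segments)

    def founders_at(self, line_id: str, chrom: str, pos_bp: np.ndarray) -> np.ndarray:
        """Founder index at each position for both homologs; shape (2, n)."""
        pos_bp = np.asarray(pos_bp)
        out = np.empty((2, len(pos_bp)), dtype=np.int64)
        for h, hap in enumerate(self.segments[line_id][chrom]):
            ends = np.array([s[1] for s in hap])
            founders = np.array([s[2] for s in hap])
            out[h] = founders[np.searchsorted(ends, pos_bp, side="right")]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for line, per_chrom in self.segments.items():
            for chrom, haps in per_chrom.items():
                for h, hap in enumerate(haps):
                    for start, end, f in hap:
                        rows.append((chrom, start, end, line, h, self.founder_ids[f]))
        return pd.DataFrame(
            rows, columns=["chrom", "start_bp", "end_bp", "line", "homolog", "founder"]
        )

    def validate(self) -> None:
        for line, per_chrom in self.segments.items():
            for chrom, haps in per_chrom.items():
                L = self.chrom_lengths[chrom]
                for hap in haps:
                    if hap[0][0] != 1 or hap[-1][1] != L + 1:
                        raise ValueError(f"{line}/{chrom}: segments do not span chromosome")
                    for (s0, e0, _), (s1, e1, _) in zip(hap, hap[1:]):
                        if e0 != s1 or s0 >= e0:
                            raise ValueError(f"{line}/{chrom}: gap/overlap in segments")


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeTable | None
    founders: FounderPanel | None
    mosaic: TrueMosaic
    pedigree: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _slice(hap: Homolog, start: int, end: int) -> Homolog:
    out = []
    for s, e, f in hap:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((lo, hi, f))
    return out


def _gamete_chrom(
    haps: tuple[Homolog, Homolog], L_bp: int, L_cm: float, rng: np.random.Generator
) -> Homolog:
    """One recombinant chromatid under the Haldane model (no interference)."""
    n_xo = rng.poisson(L_cm / 100.0) if L_cm > 0 else 0
    cur = int(rng.integers(2))
    if n_xo == 0:
        return list(haps[cur])
    cuts_cm = np.sort(rng.uniform(0.0, L_cm, size=n_xo))
    cuts_bp = sorted({int(np.clip(round(c / L_cm * L_bp), 1, L_bp)) for c in cuts_cm})
    out: Homolog = []
    prev = 1
    for cut in cuts_bp + [L_bp + 1]:
        if cut > prev:
            out.extend(_slice(haps[cur], prev, cut))
        prev = cut
        cur = 1 - cur
    # merge adjacent same-founder segments
    merged: Homolog = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


Individual = dict  # chrom -> (Homolog, Homolog)


def _founder_individual(f: int, gmap: GeneticMap) -> Individual:
    return {
        c: ([(1, gmap.length_bp(c) + 1, f)], [(1, gmap.length_bp(c) + 1, f)])
        for c in gmap.chroms
    }


def _gamete(ind: Individual, gmap: GeneticMap, rng: np.random.Generator) -> dict:
    return {
        c: _gamete_chrom(ind[c], gmap.length_bp(c), gmap.length_cm(c), rng)
        for c in gmap.chroms
    }


def _cross(p1: Individual, p2: Individual, gmap: GeneticMap, rng) -> Individual:
    g1, g2 = _gamete(p1, gmap, rng), _gamete(p2, gmap, rng)
    return {c: (g1[c], g2[c]) for c in gmap.chroms}


# three perfect matchings of four two-way hybrids; rotated round-robin
# across eight-way families so founder pairings vary.
_FOURWAY_MATCHINGS = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]


def _funnel_individual(
    n_founders: int, family_index: int, gmap: GeneticMap, rng
) -> Individual:
    founders = [_founder_individual(f, gmap) for f in range(n_founders)]
    if n_founders == 2:
        return _cross(founders[0], founders[1], gmap, rng)
    twoway = [
        _cross(founders[i], founders[i + 1], gmap, rng)
        for i in range(0, n_founders, 2)
    ]
    if len(twoway) == 4:
        (a, b), (c, d) = _FOURWAY_MATCHINGS[family_index % 3]
        four1 = _cross(twoway[a], twoway[b], gmap, rng)
        four2 = _cross(twoway[c], twoway[d], gmap, rng)
        return _cross(four1, four2, gmap, rng)
    level = twoway
    while len(level) > 1:
        level = [
            _cross(level[i], level[i + 1], gmap, rng) for i in range(0, len(level), 2)
        ]
    return level[0]


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def random_founder_panel(
    founder_ids: list[str],
    gmap: GeneticMap,
    n_snps_per_chrom: int,
    seed: int,
    p_alt: float = 0.5,
) -> FounderPanel:
    """Random homozygous founder genotypes, polymorphic at every SNP.

    Each founder independently carries the alternate allele with probability
    ``p_alt``; monomorphic columns are redrawn so the panel stays usable for
    haplotype inference (two founders share an allele at ~50% of SNPs, i.e.
    founders are pairwise distinguishable at about half the positions).
    """
    rng = np.random.default_rng(seed)
    nf = len(founder_ids)
    chroms, pos, snp_ids = [], [], []
    for c in gmap.chroms:
        L = gmap.length_bp(c)
        n = min(n_snps_per_chrom, L)
        p = np.sort(rng.choice(np.arange(1, L + 1), size=n, replace=False))
        chroms.extend([c] * n)
        pos.extend(p.tolist())
        snp_ids.extend(f"{c}_{x}" for x in p)
    n_snps = len(pos)
    calls = 2 * (rng.random((nf, n_snps)) < p_alt).astype(np.int8)
    mono = (calls == calls[0]).all(axis=0)
    while mono.any():
        calls[:, mono] = 2 * (rng.random((nf, int(mono.sum()))) < p_alt).astype(np.int8)
        mono = (calls == calls[0]).all(axis=0)
    alleles = np.array([("A", "T")] * n_snps, dtype=object)
    gt = GenotypeTable(list(founder_ids), snp_ids, chroms, pos, alleles, calls)
    return FounderPanel(list(founder_ids), gt)


def simulate_population(
    design: CrossDesign,
    gmap: GeneticMap,
    founders: FounderPanel | None = None,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedPopulation:
    """Run the funnel + SSD and project mosaics onto founder SNP alleles.

    Parameters
    ----------
    founders
        Homozygous founder panel used for the mosaic -> genotype projection.
        When ``None`` only the true mosaic is produced.
    error_rate, missing_rate
        Per-call genotyping error and missingness, injected after projection.
    """
    if not 0 <= error_rate <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_f = len(design.founder_ids)
    segments: dict[str, dict] = {}
    ped_rows = []
    for fam in range(design.n_families):
        top = _funnel_individual(n_f, fam, gmap, rng)
        for k in range(design.n_lines_per_family):
            ind = top
            for _ in range(design.selfing_generations):
                ind = _cross(ind, ind, gmap, rng)
            line_id = f"L{fam:03d}_{k}"
            segments[line_id] = {c: ind[c] for c in gmap.chroms}
            ped_rows.append((line_id, fam, design.selfing_generations))
    mosaic = TrueMosaic(
        list(design.founder_ids),
        {c: gmap.length_bp(c) for c in gmap.chroms},
        segments,
    )
    pedigree = pd.DataFrame(ped_rows, columns=["line", "family", "selfing_generations"])

    genotypes = None
    if founders is not None:
        genotypes = _project_genotypes(mosaic, founders, error_rate, missing_rate, rng)
    return SimulatedPopulation(genotypes, founders, mosaic, pedigree, seed)


def _project_genotypes(
    mosaic: TrueMosaic,
    founders: FounderPanel,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> GenotypeTable:
    pgt = founders.genotypes
    codes = founders.allele_codes()  # founders x SNPs, {0,2,MISSING}
    lines = mosaic.line_ids
    calls = np.empty((len(lines), pgt.n_snps), dtype=np.int8)
    for i, line in enumerate(lines):
        for chrom in pd.unique(pgt.chrom):
            snp_idx = np.flatnonzero(pgt.chrom == chrom)
            f01 = mosaic.founders_at(line, chrom, pgt.pos_bp[snp_idx])
            a0 = codes[f01[0], snp_idx]
            a1 = codes[f01[1], snp_idx]
            col = ((a0 + a1) // 2).astype(np.int8)
            col[(a0 == MISSING) | (a1 == MISSING)] = MISSING
            calls[i, snp_idx] = col
    if error_rate > 0:
        err = (rng.random(calls.shape) < error_rate) & (calls != MISSING)
        flip = np.where(calls == 1, 2 * rng.integers(0, 2, calls.shape), 2 - calls)
        calls[err] = flip[err].astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    gt = GenotypeTable(
        list(lines),
        list(pgt.snp_ids),
        pgt.chrom.copy(),
        pgt.pos_bp.copy(),
        pgt.alleles.copy(),
        calls,
        pos_cm=None if pgt.pos_cm is None else pgt.pos_cm.copy(),
    )
    gt.validate()
    return gt


def founder_proportions(mosaic: TrueMosaic) -> tuple[pd.DataFrame, pd.Series]:
    """bp-length-weighted founder genome fractions, per line and population mean.

    Per-line fractions average the two homologs and sum to 1 exactly.
    """
    founders = mosaic.founder_ids
    total_bp = sum(mosaic.chrom_lengths.values())
    rows = {}
    for line, per_chrom in mosaic.segments.items():
        acc = np.zeros(len(founders))
        for haps in per_chrom.values():
            for hap in haps:
                for s, e, f in hap:
                    acc[f] += e - s
        rows[line] = acc / (2.0 * total_bp)
    per_line = pd.DataFrame.from_dict(rows, orient="index", columns=founders)
    return per_line, per_line.mean(axis=0)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class CausalSpec:
    """A single causal locus with founder-level allele classes.

    ``founder_class`` maps every founder id to a class label and
    ``class_effects`` maps labels to numeric effects.  For binary traits the
    effects must be 0/1 and a line scores 1 only when both homologs carry a
    class-1 founder (recessive inheritance, the glutinous-endosperm pattern).
    """

    chrom: str
    pos_bp: int
    founder_class: dict[str, str]
    class_effects: dict[str, float]
    binary: bool = False


def simulate_phenotype(
    pop: SimulatedPopulation,
    causal: CausalSpec,
    h2: float = 0.5,
    h2_poly: float = 0.0,
    n_poly_loci: int = 50,
    noise_sd: float | None = None,
    seed: int = 0,
    trait: str = "trait",
) -> PhenotypeTable:
    """Phenotype = causal-class effect + polygenic term + Gaussian noise.

    In the default mode the three components are standardized so the causal
    locus explains a fraction ``h2`` of the variance and the polygenic term
    ``h2_poly``.  When ``noise_sd`` is given, raw class effects are used and
    noise with that SD is added instead (convenient when class separation in
    residual-SD units must be controlled exactly).
    """
    if not 0 <= h2 <= 1 or h2 + h2_poly > 1:
        raise ValueError("need 0 <= h2, h2 + h2_poly <= 1")
    mosaic = pop.mosaic
    missing = set(mosaic.founder_ids) - set(causal.founder_class)
    if missing:
        raise ValueError(f"class effects missing for founders {sorted(missing)}")
    rng = np.random.default_rng(seed)
    lines = mosaic.line_ids
    fidx = {f: i for i, f in enumerate(mosaic.founder_ids)}
    eff = np.empty(len(mosaic.founder_ids))
    for f, cls in causal.founder_class.items():
        if cls not in causal.class_effects:
            raise ValueError(f"no effect given for class {cls!r}")
        eff[fidx[f]] = causal.class_effects[cls]

    g = np.empty(len(lines))
    both_one = np.empty(len(lines), dtype=bool)
    for i, line in enumerate(lines):
        f01 = mosaic.founders_at(line, causal.chrom, np.array([causal.pos_bp]))
        e0, e1 = eff[f01[0, 0]], eff[f01[1, 0]]
        g[i] = 0.5 * (e0 + e1)
        both_one[i] = (e0 == 1) and (e1 == 1)

    if causal.binary:
        values = both_one.astype(float)
        return PhenotypeTable(pd.DataFrame({trait: values}, index=pd.Index(lines, name="line_id")))

    if noise_sd is not None:
        y = g + noise_sd * rng.standard_normal(len(lines))
    else:
        y = np.zeros(len(lines))
        if h2 > 0:
            sd = g.std()
            if sd == 0:
                raise ValueError("causal classes are constant across lines; h2 > 0 impossible")
            y += math.sqrt(h2) * (g - g.mean()) / sd
        if h2_poly > 0:
            p = _polygenic_term(mosaic, n_poly_loci, rng)
            y += math.sqrt(h2_poly) * p
        resid = 1.0 - h2 - h2_poly
        if resid > 0:
            y += math.sqrt(resid) * rng.standard_normal(len(lines))
    return PhenotypeTable(pd.DataFrame({trait: y}, index=pd.Index(lines, name="line_id")))


def _polygenic_term(mosaic: TrueMosaic, n_loci: int, rng) -> np.ndarray:
    """Sum of random founder effects at random background loci, standardized."""
    chroms = list(mosaic.chrom_lengths)
    lines = mosaic.line_ids
    p = np.zeros(len(lines))
    for _ in range(n_loci):
        c = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, mosaic.chrom_lengths[c] + 1))
        u = rng.standard_normal(len(mosaic.founder_ids))
        for i, line in enumerate(lines):
            f01 = mosaic.founders_at(line, c, np.array([pos]))
            p[i] += 0.5 * (u[f01[0, 0]] + u[f01[1, 0]])
    sd = p.std()
    return (p - p.mean()) / sd if sd > 0 else p


# ---------------------------------------------------------------------------
# synthetic annotation inputs for the mining stage
# ---------------------------------------------------------------------------


def simulate_gene_models(
    gmap: GeneticMap, n_genes_per_chrom: int, seed: int = 0, gene_bp: int = 4000
):
    """Evenly spaced synthetic gene models covering each chromosome."""
    from .io_formats import GeneModelTable

    rows = []
    for c in gmap.chroms:
        L = gmap.length_bp(c)
        starts = np.linspace(1, max(1, L - gene_bp), n_genes_per_chrom).astype(int)
        for k, s in enumerate(starts):
            rows.append((f"{c}g{k:04d}", c, int(s), int(s) + gene_bp - 1, "+"))
    return GeneModelTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start_bp", "end_bp", "strand"])
    )


def simulate_variant_impacts(
    genes,
    founder_ids: list[str],
    causal_gene: str,
    causal_founders: list[str],
    seed: int = 0,
    background_rate: float = 0.3,
):
    """Synthetic per-founder variant-impact records.

    Background genes receive shared MODERATE/LOW/MODIFIER variant signatures;
    the causal gene gets a private HIGH-impact variant in ``causal_founders``
    (the Wx-style in-frame insertion pattern) plus two supporting variants so
    its carriers exceed the reference-like threshold.
    """
    from .io_formats import VariantImpactTable

    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes.records["gene"]:
        for f in founder_ids:
            if gene == causal_gene and f in causal_founders:
                rows += [
                    (gene, f, f"{gene}_ins", "HIGH"),
                    (gene, f, f"{gene}_m1", "MODERATE"),
                    (gene, f, f"{gene}_m2", "LOW"),
                ]
            elif rng.random() < background_rate:
                rows += [
                    (gene, f, f"{gene}_v1", "MODERATE"),
                    (gene, f, f"{gene}_v2", "MODIFIER"),
                ]
    df = pd.DataFrame(rows, columns=["gene", "founder", "variant", "impact"])
    return VariantImpactTable(df)
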