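"""Post-GWAS haplotype-based allele mining.

Given a trait-locus peak, lines are grouped by their most probable founder
haplotype at the peak SNP; founder alleles are sorted into phenotypic
classes by all pairwise Mann-Whitney U tests with family-wise error
control (Holm step-down, alpha = 0.01); founders are typed per gene from
their variant-impact signatures (reference-like alleles with fewer than
two variants are always Cluster 1, at most one cluster per founder);
candidate genes in the locus region are then narrowed to those whose
allele type separates the phenotypic classes and which carry a HIGH-impact
variant in a discriminating class.  Utilities for the segregation
chi-square test and two-trait phenotype-diversity binning round off the
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gwas import LocusRegion
from .hmm import HaplotypeProbabilities
from .io_formats import (
    GeneModelTable,
    PhenotypeTable,
    VariantImpactTable,
)

IMPACT_WEIGHTS = {"HIGH": 4, "MODERATE": 3, "LOW": 2, "MODIFIER": 1}


# ---------------------------------------------------------------------------
# founder groups at the peak
# ---------------------------------------------------------------------------


@dataclass
class FounderGroups:
    snp_id: str
    assignments: dict[str, list[str]]  # founder -> line ids
    unassigned: list[str]
    min_posterior: float

    def sizes(self) -> dict[str, int]:
        return {f: len(v) for f, v in self.assignments.items()}


def group_lines_by_peak_haplotype(
    probs: HaplotypeProbabilities, snp_id: str, min_posterior: float = 0.8
) -> FounderGroups:
    """Assign each line to its maximum-posterior founder at ``snp_id`` when
    that posterior reaches ``min_posterior``; otherwise leave unassigned."""
    try:
        s = probs.snp_ids.index(snp_id)
    except ValueError:
        raise KeyError(f"unknown snp id {snp_id!r}") from None
    P = probs.probs[:, s, :]
    best = P.argmax(axis=1)
    assignments: dict[str, list[str]] = {f: [] for f in probs.founder_ids}
    unassigned = []
    for i, line in enumerate(probs.line_ids):
        if P[i, best[i]] >= min_posterior:
            assignments[probs.founder_ids[best[i]]].append(line)
        else:
            unassigned.append(line)
    return FounderGroups(snp_id, assignments, unassigned, min_posterior)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_u(
    x, y, exact_if: int = 25
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts (x, y) pairs with x > y plus half of the ties.  When the
    pooled sample size is at most ``exact_if`` the two-sided P-value is
    exact: the full null distribution of the rank sum is built by a
    tie-aware subset-sum recursion over the pooled mid-ranks, and the
    symmetric tail probability Pr(|U - mn/2| >= |u - mn/2|) is returned.
    Larger samples use the normal approximation with tie correction (no
    continuity correction, so identical samples give P = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    if nx + ny <= exact_if:
        p = _exact_two_sided(ranks, nx, ny, u)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
        )
    return u, min(1.0, p)


def _exact_two_sided(ranks: np.ndarray, nx: int, ny: int, u: float) -> float:
    """Exact symmetric-tail P by dynamic programming over doubled mid-ranks."""
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dp = np.zeros((nx + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(nx, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[nx]  # index = doubled rank-sum of the x subset
    s = np.arange(total + 1)
    u2 = s - nx * (nx + 1)  # doubled U for each rank-sum
    center = nx * ny  # doubled mn/2
    obs_dev = abs(int(round(2 * u)) - center)
    tail = counts[np.abs(u2 - center) >= obs_dev].sum()
    return float(tail / counts.sum())


# ---------------------------------------------------------------------------
# founder-allele classification at the peak
# ---------------------------------------------------------------------------


@dataclass
class AlleleClassAssignment:
    classes: dict[str, str]  # founder -> class label (A, B, ...)
    unclassified: dict[str, str]  # founder -> reason
    tests: pd.DataFrame  # founder_a, founder_b, U, p_raw, p_adj, significant
    alpha: float

    def partition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for f, c in self.classes.items():
            out.setdefault(c, []).append(f)
        return {c: sorted(fs) for c, fs in out.items()}


def classify_founder_alleles(
    groups: FounderGroups,
    pheno: PhenotypeTable,
    trait: str | None = None,
    alpha: float = 0.01,
    min_n: int = 2,
    fwer_method: str = "holm",
) -> AlleleClassAssignment:
    """Partition founders into phenotypic classes at the peak SNP.

    All pairwise Mann-Whitney tests are run among founders whose haplotype
    group holds at least ``min_n`` lines; raw P-values are adjusted over
    the whole pair family (Holm by default) and founders whose adjusted P
    is >= alpha are joined.  Classes are the connected components of this
    "not significantly different" graph, labelled A, B, C, ... by
    ascending class median phenotype.  Founders with too few lines are
    reported unclassified with the reason.
    """
    trait = trait or pheno.values.columns[0]
    values = {
        f: pheno.values.loc[lines, trait].dropna().to_numpy(dtype=float)
        for f, lines in groups.assignments.items()
    }
    eligible = sorted(f for f, v in values.items() if len(v) >= min_n)
    unclassified = {
        f: f"group size {len(v)} < min_n={min_n}"
        for f, v in values.items()
        if len(v) < min_n
    }
    if len(eligible) < 2:
        raise ValueError("need at least two founders with group size >= min_n")
    pairs = list(combinations(eligible, 2))
    raw = []
    stats_u = []
    for a, b in pairs:
        u, p = mann_whitney_u(values[a], values[b])
        raw.append(p)
        stats_u.append(u)
    reject, p_adj, *_ = multipletests(raw, alpha=alpha, method=fwer_method)
    tests = pd.DataFrame(
        {
            "founder_a": [a for a, _ in pairs],
            "founder_b": [b for _, b in pairs],
            "U": stats_u,
            "p_raw": raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )
    g = nx.Graph()
    g.add_nodes_from(eligible)
    for (a, b), pa in zip(pairs, p_adj):
        if pa >= alpha:
            g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: np.median(np.concatenate([values[f] for f in c])))
    classes = {}
    for k, comp in enumerate(comps):
        label = chr(ord("A") + k)
        for f in comp:
            classes[f] = label
    return AlleleClassAssignment(classes, unclassified, tests, alpha)


# ---------------------------------------------------------------------------
# gene allele typing from variant impacts
# ---------------------------------------------------------------------------


@dataclass
class GeneAlleleTypeTable:
    """gene x founder cluster labels (1 = reference-like) with signatures."""

    labels: pd.DataFrame  # index gene, columns founders, int labels
    signatures: dict  # (gene, founder) -> tuple of variant ids
    severity: dict  # (gene, founder) -> weighted variant score

    def gene_labels(self, gene_id: str) -> pd.Series:
        return self.labels.loc[gene_id]


def type_gene_alleles(
    impacts: VariantImpactTable, founder_ids: list[str]
) -> GeneAlleleTypeTable:
    """Cluster founder alleles per gene by variant-impact signature.

    Founders with fewer than two recorded variants against the reference
    are always Cluster 1 (reference-like).  Remaining founders share a
    cluster iff their variant-id signatures are identical; clusters are
    numbered 2, 3, ... by ascending severity score (weighted variant
    count: HIGH=4, MODERATE=3, LOW=2, MODIFIER=1; ties broken by
    lexicographic signature), so at most one cluster per founder and never
    more clusters than founders.
    """
    rec = impacts.records
    unknown = set(rec["founder"]) - set(founder_ids)
    if unknown:
        raise ValueError(f"impact table references unknown founders {sorted(unknown)}")
    genes = sorted(rec["gene"].unique())
    labels = pd.DataFrame(1, index=pd.Index(genes, name="gene"), columns=founder_ids,
                          dtype=int)
    signatures: dict = {}
    severity: dict = {}
    for gene, sub in rec.groupby("gene"):
        sigs: dict[str, tuple] = {}
        for f in founder_ids:
            fsub = sub[sub["founder"] == f]
            sig = tuple(sorted(fsub["variant"]))
            score = int(fsub["impact"].map(IMPACT_WEIGHTS).sum())
            signatures[(gene, f)] = sig
            severity[(gene, f)] = score
            if len(sig) >= 2:
                sigs[f] = sig
        clusters: dict[tuple, list[str]] = {}
        for f, sig in sigs.items():
            clusters.setdefault(sig, []).append(f)
        # founders sharing a signature share its severity score
        ordered = sorted(
            clusters, key=lambda sig: (severity[(gene, clusters[sig][0])], sig)
        )
        for k, sig in enumerate(ordered, start=2):
            for f in clusters[sig]:
                labels.loc[gene, f] = k
    return GeneAlleleTypeTable(labels, signatures, severity)


def cluster_founders_ward(table: GeneAlleleTypeTable):
    """Ward-linkage hierarchical clustering of founders on their gene-wise
    allele-type labels (Euclidean distance on one-hot encoded labels).

    Returns (linkage matrix, founder order); deterministic for fixed input.
    """
    from scipy.cluster.hierarchy import linkage

    founders = list(table.labels.columns)
    if len(founders) < 2:
        raise ValueError("need at least two founders to cluster")
    cols = []
    for gene in table.labels.index:
        lab = table.labels.loc[gene].to_numpy()
        for v in np.unique(lab):
            cols.append((lab == v).astype(float))
    X = np.array(cols).T  # founders x (gene, label) indicator features
    return linkage(X, method="ward"), founders


# ---------------------------------------------------------------------------
# candidate-gene narrowing
# ---------------------------------------------------------------------------


@dataclass
class CandidateGeneReport:
    region: LocusRegion
    genes: pd.DataFrame  # gene, class_discordant, high_in_discriminating, surviving

    @property
    def n_discordant(self) -> int:
        return int(self.genes["class_discordant"].sum())

    @property
    def surviving(self) -> list[str]:
        return self.genes.loc[self.genes["surviving"], "gene"].tolist()


def narrow_candidates(
    region: LocusRegion,
    classes: AlleleClassAssignment,
    types: GeneAlleleTypeTable,
    genes: GeneModelTable,
    impacts: VariantImpactTable,
) -> CandidateGeneReport:
    """Two-step candidate narrowing inside a locus region.

    Step 1 flags genes whose allele-type label differs between founders of
    different phenotypic classes (class-discordant).  Step 2 keeps, among
    those, genes carrying at least one HIGH-impact variant in a founder
    belonging to a discriminating class.  Surviving candidates satisfy
    both.
    """
    if not classes.classes:
        raise ValueError("empty class assignment")
    in_region = genes.in_interval(region.chrom, region.start_bp, region.end_bp)
    high = impacts.records[impacts.records["impact"] == "HIGH"]
    rows = []
    classified = list(classes.classes)
    for gene in in_region["gene"]:
        if gene in types.labels.index:
            lab = types.labels.loc[gene]
        else:
            lab = pd.Series(1, index=types.labels.columns)
        discordant = False
        disc_classes: set[str] = set()
        for f1, f2 in combinations(classified, 2):
            if classes.classes[f1] != classes.classes[f2] and lab[f1] != lab[f2]:
                discordant = True
                disc_classes.update((classes.classes[f1], classes.classes[f2]))
        high_flag = False
        if discordant:
            carriers = set(high.loc[high["gene"] == gene, "founder"])
            high_flag = any(
                classes.classes.get(f) in disc_classes for f in carriers
            )
        rows.append((gene, discordant, high_flag, discordant and high_flag))
    df = pd.DataFrame(
        rows, columns=["gene", "class_discordant", "high_in_discriminating", "surviving"]
    )
    return CandidateGeneReport(region, df)


# ---------------------------------------------------------------------------
# segregation test and phenotype-diversity bins
# ---------------------------------------------------------------------------


def segregation_chisq(
    observed_positive: int, total: int, expected_fraction: float = 0.125
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of a trait count against the expected
    carrier fraction (1/8 for a trait private to one of eight founders).

    No continuity correction is applied, matching the convention under
    which 57 carriers among 358 lines gives P = 0.0503.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed_positive <= total:
        raise ValueError("observed count outside [0, total]")
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must lie in (0, 1)")
    f_obs = [observed_positive, total - observed_positive]
    f_exp = [total * expected_fraction, total * (1 - expected_fraction)]
    chi2, p = stats.chisquare(f_obs, f_exp)
    return float(chi2), float(p)


def phenotype_diversity_bins(
    pheno_x: np.ndarray, pheno_y: np.ndarray, n_bins: tuple[int, int] = (5, 6)
) -> tuple[np.ndarray, int]:
    """Joint occupancy grid of two traits over equal-width bins.

    Each trait's observed range is split into ``n_bins`` equal-width,
    right-closed-last bins (numpy histogram convention); the grid counts
    lines per combination and the number of occupied cells measures
    phenotypic diversity.  Lines missing either trait are dropped.
    """
    x = np.asarray(pheno_x, dtype=float)
    y = np.asarray(pheno_y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    bx, by = n_bins
    if x.min() == x.max():
        warnings.warn("constant trait: single bin on x")
        bx = 1
    if y.min() == y.max():
        warnings.warn("constant trait: single bin on y")
        by = 1
    grid, _, _ = np.histogram2d(x, y, bins=[bx, by])
    return grid, int((grid >= 1).sum())
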