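import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ham import (
    GeneModelTable,
    PhenotypeTable,
    VariantImpactTable,
    classify_founder_alleles,
    cluster_founders_ward,
    group_lines_by_peak_haplotype,
    mann_whitney_u,
    narrow_candidates,
    phenotype_diversity_bins,
    segregation_chisq,
    type_gene_alleles,
)
from ham.gwas import LocusRegion
from ham.hmm import HaplotypeProbabilities
from ham.mining import FounderGroups

FOUNDERS = [f"F{i}" for i in range(1, 9)]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def brute_force_two_sided(x, y):
    """Independent oracle: enumerate all C(n, nx) group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    n = len(pooled)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    obs = u_stat(tuple(range(nx)))
    center = nx * (n - nx) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        u = u_stat(idx)
        total += 1
        if abs(u - center) >= abs(obs - center) - 1e-9:
            count += 1
    return obs, count / total


def test_mw_textbook_example():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)  # 2/20 rank splits


def test_mw_complementarity():
    rng = np.random.default_rng(0)
    x, y = rng.integers(0, 5, 7), rng.integers(0, 5, 9)
    ux, _ = mann_whitney_u(x, y)
    uy, _ = mann_whitney_u(y, x)
    assert ux + uy == pytest.approx(len(x) * len(y))


def test_mw_identical_samples_p_one():
    _, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
    assert p == 1.0
    # large-sample asymptotic path too
    x = list(range(20)) * 2
    _, p = mann_whitney_u(x, x)
    assert p == 1.0


def test_mw_empty_sample_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1, 2])


@pytest.mark.parametrize("nx,ny", [(1, 3), (2, 4), (3, 3), (4, 4), (5, 6), (6, 6)])
def test_mw_exact_matches_enumeration(nx, ny):
    rng = np.random.default_rng(nx * 10 + ny)
    for _ in range(3):
        x = rng.integers(0, 4, nx).tolist()  # small range forces ties
        y = rng.integers(0, 4, ny).tolist()
        u, p = mann_whitney_u(x, y)
        u_ref, p_ref = brute_force_two_sided(x, y)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)


# ---------------------------------------------------------------------------
# founder groups + classification
# ---------------------------------------------------------------------------


def make_probs(posteriors, founder_ids):
    posteriors = np.asarray(posteriors)[None, :, :].transpose(1, 0, 2)
    n_l = posteriors.shape[0]
    return HaplotypeProbabilities(
        posteriors, [f"L{i}" for i in range(n_l)], ["peak"], founder_ids,
        np.array(["chr01"], dtype=object), np.array([1000]),
    )


def test_grouping_threshold():
    probs = make_probs(
        [[1.0, 0.0], [0.4, 0.6], [0.15, 0.85]], ["A", "B"]
    )
    groups = group_lines_by_peak_haplotype(probs, "peak", min_posterior=0.8)
    assert groups.assignments == {"A": ["L0"], "B": ["L2"]}
    assert groups.unassigned == ["L1"]
    with pytest.raises(KeyError):
        group_lines_by_peak_haplotype(probs, "nope")


def groups_from_sizes(sizes):
    lines = {}
    i = 0
    assignments = {}
    for f, n in sizes.items():
        assignments[f] = [f"L{i + k}" for k in range(n)]
        i += n
    return FounderGroups("peak", assignments, [], 0.8)


def pheno_from(values_per_founder, groups):
    rows = {}
    for f, lines in groups.assignments.items():
        for line, v in zip(lines, values_per_founder[f]):
            rows[line] = v
    return PhenotypeTable(pd.DataFrame({"t": pd.Series(rows)}))


def test_classify_two_separated_founders():
    """(6,6) groups with ranges 1-6 vs 11-16: exact P = 2/924 < 0.01."""
    groups = groups_from_sizes({"RU": 6, "TC": 6})
    pheno = pheno_from({"RU": list(range(1, 7)), "TC": list(range(11, 17))}, groups)
    res = classify_founder_alleles(groups, pheno)
    assert res.tests["p_raw"].iloc[0] == pytest.approx(2 / 924, abs=1e-12)
    assert res.classes["RU"] != res.classes["TC"]
    # labels ordered by ascending median
    assert res.classes["RU"] == "A" and res.classes["TC"] == "B"


def test_classify_identical_groups_single_class():
    groups = groups_from_sizes({"A": 5, "B": 5, "C": 5})
    vals = {f: [1, 2, 3, 4, 5] for f in "ABC"}
    res = classify_founder_alleles(groups, pheno_from(vals, groups))
    assert len(set(res.classes.values())) == 1


def test_single_line_founder_unclassified():
    groups = groups_from_sizes({"RU": 6, "TC": 6, "SU": 1})
    pheno = pheno_from(
        {"RU": list(range(1, 7)), "TC": list(range(11, 17)), "SU": [9]}, groups
    )
    res = classify_founder_alleles(groups, pheno)
    assert "SU" not in res.classes
    assert "group size 1 < min_n=2" in res.unclassified["SU"]


def test_classify_needs_two_eligible():
    groups = groups_from_sizes({"A": 1, "B": 1, "C": 5})
    with pytest.raises(ValueError, match="at least two"):
        classify_founder_alleles(groups, pheno_from({"A": [1], "B": [2], "C": [1] * 5}, groups))


def test_classes_partition_and_within_class_nonsignificant():
    rng = np.random.default_rng(8)
    sizes = {f: 20 for f in FOUNDERS}
    groups = groups_from_sizes(sizes)
    effect = {f: [0, 0, 0, 4, 4, 4, 8, 8][i] for i, f in enumerate(FOUNDERS)}
    vals = {f: (effect[f] + rng.standard_normal(20)).tolist() for f in FOUNDERS}
    res = classify_founder_alleles(groups, pheno_from(vals, groups))
    # partition covers all eligible founders exactly once
    assert sorted(sum(res.partition().values(), [])) == sorted(FOUNDERS)
    # stored test matrix: within-class pairs all non-significant
    for _, row in res.tests.iterrows():
        same = res.classes[row["founder_a"]] == res.classes[row["founder_b"]]
        if same:
            assert row["p_adj"] >= res.alpha


# ---------------------------------------------------------------------------
# gene allele typing + Ward clustering
# ---------------------------------------------------------------------------


def impacts_from(records):
    return VariantImpactTable(
        pd.DataFrame(records, columns=["gene", "founder", "variant", "impact"])
    )


def test_type_gene_alleles_reference_like_and_signatures():
    table = type_gene_alleles(
        impacts_from(
            [
                ("g1", "F1", "v1", "HIGH"),  # single variant -> still Cluster 1
                ("g1", "F2", "v1", "HIGH"),
                ("g1", "F2", "v2", "LOW"),
                ("g1", "F3", "v1", "HIGH"),
                ("g1", "F3", "v2", "LOW"),
                ("g1", "F4", "v3", "MODERATE"),
                ("g1", "F4", "v4", "MODERATE"),
            ]
        ),
        FOUNDERS,
    )
    lab = table.gene_labels("g1")
    assert lab["F1"] == 1  # fewer than two variations
    assert lab["F5"] == 1  # absent founder treated as zero variants
    assert lab["F2"] == lab["F3"]  # identical signatures share a cluster
    assert lab["F2"] != lab["F4"]
    # F2/F3 severity 4+2=6 equals F4 severity 3+3=6: the lexicographically
    # smaller signature (v1,v2) takes the lower cluster number
    assert lab["F2"] == 2 and lab["F4"] == 3


def test_type_gene_alleles_max_clusters():
    records = []
    for i, f in enumerate(FOUNDERS):
        records += [(f"g", f, f"{f}_a", "MODERATE"), (f"g", f, f"{f}_b", "LOW")]
    table = type_gene_alleles(impacts_from(records), FOUNDERS)
    assert table.gene_labels("g").nunique() == 8


def test_ward_clustering_blocks_and_determinism():
    labels = pd.DataFrame(1, index=[f"g{i}" for i in range(6)], columns=FOUNDERS)
    labels.loc[:, ["F5", "F6", "F7", "F8"]] = 2
    from ham.mining import GeneAlleleTypeTable

    table = GeneAlleleTypeTable(labels, {}, {})
    Z1, founders = cluster_founders_ward(table)
    Z2, _ = cluster_founders_ward(table)
    np.testing.assert_array_equal(Z1, Z2)
    from scipy.cluster.hierarchy import fcluster

    cut = fcluster(Z1, 2, criterion="maxclust")
    assert len(set(cut[:4])) == 1 and len(set(cut[4:])) == 1
    assert cut[0] != cut[4]
    # identical label vectors merge at height 0
    assert Z1[0, 2] == 0.0


# ---------------------------------------------------------------------------
# candidate narrowing
# ---------------------------------------------------------------------------


def wx_like_fixture():
    """51 genes in the region; 8 class-discordant, 1 of them with a HIGH
    variant in the discriminating founder (the Wx narrative shape)."""
    genes = GeneModelTable(
        pd.DataFrame(
            {
                "gene": [f"g{i:02d}" for i in range(51)],
                "chrom": "chr06",
                "start_bp": np.arange(51) * 10_000 + 1_000_000,
                "end_bp": np.arange(51) * 10_000 + 1_005_000,
                "strand": "+",
            }
        )
    )
    records = []
    discordant = [f"g{i:02d}" for i in range(8)]
    for g in discordant:
        # RU-like founder F1 carries a >=2-variant signature, others reference
        impact = "HIGH" if g == "g00" else "MODERATE"
        records += [(g, "F1", f"{g}_a", impact), (g, "F1", f"{g}_b", "LOW")]
    impacts = impacts_from(records)
    types = type_gene_alleles(impacts, FOUNDERS)
    region = LocusRegion("chr06", "peak", ["peak"], 1e-6, 1_000_000, 1_600_000)

    from ham.mining import AlleleClassAssignment

    classes = AlleleClassAssignment(
        {f: ("A" if f == "F1" else "B") for f in FOUNDERS}, {}, pd.DataFrame(), 0.01
    )
    return region, classes, types, genes, impacts


def test_narrow_candidates_wx_shape():
    region, classes, types, genes, impacts = wx_like_fixture()
    report = narrow_candidates(region, classes, types, genes, impacts)
    assert len(report.genes) == 51
    assert report.n_discordant == 8
    assert report.surviving == ["g00"]


def test_narrow_candidates_concordant_gene_excluded():
    region, classes, types, genes, impacts = wx_like_fixture()
    report = narrow_candidates(region, classes, types, genes, impacts)
    row = report.genes.set_index("gene").loc["g50"]
    assert not row["class_discordant"] and not row["surviving"]


def test_narrow_candidates_empty_region_valid():
    region, classes, types, genes, impacts = wx_like_fixture()
    empty = LocusRegion("chr01", "peak", ["peak"], 1e-6, 1, 2)
    report = narrow_candidates(empty, classes, types, genes, impacts)
    assert len(report.genes) == 0 and report.surviving == []


def test_narrow_candidates_monotone_in_high_records():
    """Removing a HIGH-impact record never adds a surviving gene."""
    region, classes, types, genes, impacts = wx_like_fixture()
    base = set(narrow_candidates(region, classes, types, genes, impacts).surviving)
    rec = impacts.records
    high_rows = rec.index[rec["impact"] == "HIGH"]
    for idx in high_rows:
        reduced = VariantImpactTable(rec.drop(index=idx).reset_index(drop=True))
        types_r = type_gene_alleles(reduced, FOUNDERS)
        surv = set(narrow_candidates(region, classes, types_r, genes, reduced).surviving)
        assert surv <= base


# ---------------------------------------------------------------------------
# segregation test + diversity bins
# ---------------------------------------------------------------------------


def test_segregation_chisq_values():
    chi2, p = segregation_chisq(57, 358, 0.125)
    assert chi2 == pytest.approx(3.832, abs=5e-4)
    assert p == pytest.approx(0.0503, abs=5e-5)
    chi2, p = segregation_chisq(45, 360, 0.125)  # observed == expected
    assert chi2 == 0 and p == 1
    chi2, p = segregation_chisq(0, 8, 0.5)
    assert chi2 == pytest.approx(8.0)
    assert p == pytest.approx(0.00468, abs=5e-6)


def test_segregation_chisq_validation():
    with pytest.raises(ValueError):
        segregation_chisq(1, 0)
    with pytest.raises(ValueError):
        segregation_chisq(9, 8)
    with pytest.raises(ValueError):
        segregation_chisq(1, 8, 0.0)


def test_diversity_bins():
    x = np.full(30, 5.0)
    grid, occupied = phenotype_diversity_bins(x, x)
    assert occupied == 1

    # lines at all 5x6 bin midpoints -> 30 occupied cells
    xs = np.repeat(np.linspace(0.1, 0.9, 5), 6) * 10
    ys = np.tile(np.linspace(0.1, 0.9, 6), 5) * 12
    grid, occupied = phenotype_diversity_bins(xs, ys, (5, 6))
    assert occupied == 30
    assert grid.sum() == 30


def test_diversity_bins_conservation_with_missing():
    rng = np.random.default_rng(3)
    x = rng.random(50)
    y = rng.random(50)
    x[:5] = np.nan
    grid, _ = phenotype_diversity_bins(x, y)
    assert grid.sum() == 45
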