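import numpy as np
import pytest

from ham import (
    CrossDesign,
    FounderPanel,
    GeneticMap,
    GenotypeTable,
    random_founder_panel,
    simulate_population,
)

FOUNDERS8 = [f"F{i}" for i in range(1, 9)]


@pytest.fixture(scope="session")
def gmap1():
    """Single 25-Mb chromosome at 4 cM/Mb (100 cM)."""
    return GeneticMap.uniform({"chr01": 25_000_000}, 4.0)


@pytest.fixture(scope="session")
def pop8(gmap1):
    """8-founder MAGIC population: 96 F5 lines, 250 SNPs, GBS-like noise."""
    design = CrossDesign(FOUNDERS8, n_families=12, n_lines_per_family=8)
    panel = random_founder_panel(FOUNDERS8, gmap1, 250, seed=11)
    pop = simulate_population(
        design, gmap1, panel, error_rate=0.01, missing_rate=0.03, seed=12
    )
    return pop


def panel_subset(panel: FounderPanel, snp_ids) -> FounderPanel:
    mask = np.isin(panel.genotypes.snp_ids, list(snp_ids))
    return FounderPanel(panel.founder_ids, panel.genotypes.subset(snp_mask=mask))


def two_founder_panel(n_snps=20, chrom="chr01", spacing=1_000_000) -> FounderPanel:
    """Founder A all-reference, founder B all-alternate: distinguishable at
    every SNP."""
    pos = np.arange(1, n_snps + 1) * spacing
    gt = GenotypeTable(
        ["A", "B"],
        [f"s{i}" for i in range(n_snps)],
        [chrom] * n_snps,
        pos,
        np.array([("A", "T")] * n_snps, dtype=object),
        np.vstack([np.zeros(n_snps, np.int8), np.full(n_snps, 2, np.int8)]),
    )
    return FounderPanel(["A", "B"], gt)
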