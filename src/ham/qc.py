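"""SNP filtering and a documented stand-in for external imputation.

The filter mirrors the GBS marker-selection criteria used for 8-founder
MAGIC panels: minor allele frequency strictly greater than 1/16 (so every
retained SNP can in principle be carried by at least one founder lineage),
no third allele, and less than 5% missing calls.  MAF is computed over
non-missing calls with lines counted as single (inbred) allele draws;
heterozygotes contribute half an allele to each side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, FounderPanel, GenotypeTable


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_multiallelic: int
    removed_maf: int
    removed_missing: int
    maf_min: float
    max_missing: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def filter_snps(
    gt: GenotypeTable,
    maf_min: float = 0.0625,
    max_missing: float = 0.05,
    require_biallelic: bool = True,
) -> tuple[GenotypeTable, FilterReport]:
    """Retain SNPs with MAF > ``maf_min``, missing fraction < ``max_missing``
    and (optionally) a biallelic flag.  Inequalities are strict on the MAF
    side and on the missing side, honouring "more than 0.0625" and "less
    than 5%".  Removal counts are reported per criterion (non-exclusive).
    """
    maf = gt.maf()
    miss = gt.missing_fraction()
    ok_bi = gt.biallelic if require_biallelic else np.ones(gt.n_snps, bool)
    with np.errstate(invalid="ignore"):
        ok_maf = np.nan_to_num(maf, nan=0.0) > maf_min
        ok_miss = miss < max_missing
    keep = ok_bi & ok_maf & ok_miss
    report = FilterReport(
        n_input=gt.n_snps,
        n_retained=int(keep.sum()),
        removed_multiallelic=int((~ok_bi).sum()),
        removed_maf=int((~ok_maf).sum()),
        removed_missing=int((~ok_miss).sum()),
        maf_min=maf_min,
        max_missing=max_missing,
    )
    if report.n_retained == 0:
        warnings.warn("all SNPs removed by filtering; returning empty table")
    return gt.subset(snp_mask=keep), report


def impute_missing(
    gt: GenotypeTable,
    method: str = "column_mode",
    panel: FounderPanel | None = None,
    hmm_params=None,
) -> GenotypeTable:
    """Fill MISSING calls; observed entries are never altered.

    ``column_mode`` fills each SNP with its most frequent observed code
    (ties broken toward the reference homozygote).  ``hmm_posterior`` fills
    from the founder-HMM posterior: each missing call becomes the allele of
    the maximum-posterior founder at that position, which exploits flanking
    markers the way a haplotype-aware imputer would.
    """
    calls = gt.calls.copy()
    miss = calls == MISSING
    if not miss.any():
        return gt
    if (miss.all(axis=0)).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(
            f"SNP {gt.snp_ids[j]} has no observed calls; filter before imputing"
        )
    if method == "column_mode":
        for j in np.flatnonzero(miss.any(axis=0)):
            col = calls[:, j]
            obs = col[col != MISSING]
            codes, counts = np.unique(obs, return_counts=True)
            best = counts.max()
            # ties -> smallest code, i.e. reference homozygote first
            fill = codes[counts == best].min()
            col[col == MISSING] = fill
    elif method == "hmm_posterior":
        if panel is None:
            raise ValueError("hmm_posterior imputation needs a FounderPanel")
        from .hmm import HMMParams, infer_founder_probabilities

        params = hmm_params or HMMParams()
        probs = infer_founder_probabilities(gt, panel, params)
        map_f = probs.probs.argmax(axis=2)  # lines x snps
        codes = panel.allele_codes()
        for i, j in zip(*np.nonzero(miss)):
            a = codes[map_f[i, j], j]
            calls[i, j] = a if a != MISSING else 0
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out = gt.subset()  # shallow structural copy
    from dataclasses import replace

    return replace(out, calls=calls)
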