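"""Data model and readers/writers for the formats the HAM pipeline touches.

Genotypes are held as a lines x SNPs matrix of small integer codes:
0 = reference homozygote, 2 = alternate homozygote, 1 = heterozygote and
``MISSING`` (= -1) for no-calls.  Physical coordinates are 1-based; gene
spans are 1-based inclusive.  Genetic positions (cM) are optional and, when
absent, derived from bp at a uniform rate (default 4 cM/Mb, a typical rice
genome-wide average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

DEFAULT_CM_PER_MB = 4.0


class FormatError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Biallelic SNP genotype matrix for a set of (near-)inbred lines.

    Attributes
    ----------
    line_ids : list of str
        Row identifiers.
    snp_ids : list of str
        Column identifiers.
    chrom : ndarray of str
        Per-SNP chromosome label.
    pos_bp : ndarray of int
        Per-SNP 1-based physical position.
    alleles : ndarray of str, shape (n_snps, 2)
        (ref, alt) symbols per SNP.
    calls : ndarray of int8, shape (n_lines, n_snps)
        Genotype codes {0, 1, 2, MISSING}.
    pos_cm : ndarray of float, optional
        Genetic positions (centiMorgan).
    biallelic : ndarray of bool
        False for records flagged multi-allelic on input (their calls are
        set to MISSING, never silently dropped).
    """

    line_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray
    calls: np.ndarray
    pos_cm: np.ndarray | None = None
    biallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.pos_cm is not None:
            self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.snp_ids), dtype=bool)
        else:
            self.biallelic = np.asarray(self.biallelic, dtype=bool)

    # -- basic geometry ----------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if self.calls.shape != (self.n_lines, self.n_snps):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_lines} lines x {self.n_snps} SNPs"
            )
        if self.alleles.shape != (self.n_snps, 2):
            raise ValueError("every SNP needs exactly two allele symbols")
        for c in pd.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,MISSING}")

    def subset(
        self,
        lines: Sequence[str] | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypeTable":
        gt = self
        if lines is not None:
            idx = [gt.line_ids.index(l) for l in lines]
            gt = replace(gt, line_ids=list(lines), calls=gt.calls[idx, :])
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            gt = replace(
                gt,
                snp_ids=[s for s, k in zip(gt.snp_ids, snp_mask) if k],
                chrom=gt.chrom[snp_mask],
                pos_bp=gt.pos_bp[snp_mask],
                alleles=gt.alleles[snp_mask],
                calls=gt.calls[:, snp_mask],
                pos_cm=None if gt.pos_cm is None else gt.pos_cm[snp_mask],
                biallelic=gt.biallelic[snp_mask],
            )
        return gt

    # -- per-SNP summaries ---------------------------------------------------

    def alt_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls.

        Lines are counted as single (inbred) allele draws; heterozygotes
        contribute half an alternate allele.
        """
        obs = self.calls != MISSING
        alt = np.where(obs, self.calls / 2.0, 0.0)
        with np.errstate(invalid="ignore"):
            return alt.sum(axis=0) / obs.sum(axis=0)

    def maf(self) -> np.ndarray:
        p = self.alt_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def ensure_cm(self, cm_per_mb: float = DEFAULT_CM_PER_MB) -> np.ndarray:
        """Return genetic positions, deriving them uniformly from bp if absent."""
        if self.pos_cm is None:
            self.pos_cm = self.pos_bp * (cm_per_mb / 1e6)
        return self.pos_cm


@dataclass
class FounderPanel:
    """A :class:`GenotypeTable` restricted to the founder cultivars."""

    founder_ids: list[str]
    genotypes: GenotypeTable

    def __post_init__(self) -> None:
        if len(set(self.founder_ids)) != len(self.founder_ids):
            raise ValueError("founder_ids must be unique")
        if not 2 <= len(self.founder_ids) <= 16:
            raise ValueError("expected between 2 and 16 founders")
        if self.founder_ids != self.genotypes.line_ids:
            raise ValueError("panel genotype rows must match founder_ids")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def heterozygous_flags(self) -> np.ndarray:
        """Boolean founder x SNP matrix flagging unexpected heterozygous calls."""
        return self.genotypes.calls == 1

    def allele_codes(self) -> np.ndarray:
        """Founder x SNP codes; heterozygous/missing calls mapped to MISSING."""
        codes = self.genotypes.calls.copy()
        codes[codes == 1] = MISSING
        return codes


@dataclass
class VariantImpactTable:
    """Per-founder variant-effect records (SnpEff-style tabular export)."""

    records: pd.DataFrame  # columns: gene, founder, variant, impact

    def __post_init__(self) -> None:
        required = {"gene", "founder", "variant", "impact"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"impact table needs columns {sorted(required)}")
        bad = ~self.records["impact"].isin(IMPACT_LEVELS)
        if bad.any():
            rows = self.records.index[bad].tolist()
            raise ValueError(f"unknown impact labels in rows {rows}")

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.records[self.records["gene"] == gene_id]


@dataclass
class GeneModelTable:
    """Gene spans, 1-based inclusive."""

    records: pd.DataFrame  # columns: gene, chrom, start_bp, end_bp, strand

    def __post_init__(self) -> None:
        if (self.records["end_bp"] < self.records["start_bp"]).any():
            raise ValueError("gene model with end < start")

    def in_interval(self, chrom: str, start_bp: int, end_bp: int) -> pd.DataFrame:
        r = self.records
        hit = (r["chrom"] == chrom) & (r["start_bp"] <= end_bp) & (r["end_bp"] >= start_bp)
        return r[hit]


@dataclass
class PhenotypeTable:
    """One value per line per trait; binary traits coded {0, 1}."""

    values: pd.DataFrame  # index: line_id, one column per trait

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate line ids in phenotype table")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    def trait(self, name: str) -> pd.Series:
        return self.values[name]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotype_table(path: str, format: str = "vcf") -> GenotypeTable:
    """Read a genotype matrix from ``vcf``, ``hapmap`` or ``csv`` dialects.

    Unphased diploid records collapse to the 0/1/2/MISSING code.  Records
    with more than one ALT allele are kept but flagged multi-allelic and
    their calls set to MISSING ("no third allele" handling is left to QC).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "csv":
        return _read_genotype_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    line_ids = list(vcf.samples)
    snp_ids, chrom, pos, alleles, rows, bi = [], [], [], [], [], []
    for i, v in enumerate(vcf):
        multi = len(v.ALT) != 1
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        alleles.append((v.REF, v.ALT[0] if v.ALT else "."))
        bi.append(not multi)
        if multi:
            rows.append(np.full(len(line_ids), MISSING, dtype=np.int8))
            warnings.warn(f"multi-allelic record at {v.CHROM}:{v.POS} flagged")
        else:
            g = np.asarray(v.gt_types, dtype=np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            g[g == 3] = MISSING
            rows.append(g)
    calls = (
        np.vstack(rows).T if rows else np.empty((len(line_ids), 0), dtype=np.int8)
    )
    gt = GenotypeTable(line_ids, snp_ids, chrom, pos, np.array(alleles, dtype=object),
                       calls, biallelic=np.array(bi, dtype=bool))
    gt.validate()
    return gt


_HAPMAP_META_COLS = 11  # rs#..QCcode; samples start at column 12 (index 11)


def _read_hapmap(path: str) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] <= _HAPMAP_META_COLS:
        raise FormatError("HapMap table has no sample columns")
    line_ids = list(df.columns[_HAPMAP_META_COLS:])
    snp_ids = df.iloc[:, 0].tolist()
    chrom = df.iloc[:, 2].to_numpy(dtype=object)
    pos = df.iloc[:, 3].astype(int).to_numpy()
    alleles, rows, bi = [], [], []
    for i, allele_str in enumerate(df.iloc[:, 1]):
        parts = str(allele_str).split("/")
        if len(parts) != 2:
            warnings.warn(f"multi-allelic HapMap record {snp_ids[i]} flagged")
            alleles.append((parts[0], parts[1] if len(parts) > 1 else "."))
            bi.append(False)
            rows.append(np.full(len(line_ids), MISSING, dtype=np.int8))
            continue
        ref, alt = parts
        alleles.append((ref, alt))
        bi.append(True)
        row = np.empty(len(line_ids), dtype=np.int8)
        for j, g in enumerate(df.iloc[i, _HAPMAP_META_COLS:]):
            g = str(g)
            if len(g) != 2 or "N" in g:
                row[j] = MISSING
            else:
                n_alt = (g[0] == alt) + (g[1] == alt)
                n_ref = (g[0] == ref) + (g[1] == ref)
                if n_alt + n_ref != 2:
                    raise FormatError(
                        f"line {i + 2}: genotype {g!r} not drawn from alleles {ref}/{alt}"
                    )
                row[j] = n_alt
        rows.append(row)
    calls = np.vstack(rows).T if rows else np.empty((len(line_ids), 0), dtype=np.int8)
    gt = GenotypeTable(line_ids, snp_ids, chrom, pos, np.array(alleles, dtype=object),
                       calls, biallelic=np.array(bi, dtype=bool))
    gt.validate()
    return gt


def _read_genotype_csv(path: str) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"CHROM": str})
    meta = ["CHROM", "POS", "ID", "REF", "ALT"]
    if df.columns[: len(meta)].tolist() != meta:
        raise FormatError(f"genotype CSV must start with columns {meta}")
    line_ids = list(df.columns[len(meta):])
    calls = df[line_ids].fillna(MISSING).to_numpy(dtype=np.int8).T
    gt = GenotypeTable(
        line_ids,
        df["ID"].astype(str).tolist(),
        df["CHROM"].to_numpy(dtype=object),
        df["POS"].astype(int).to_numpy(),
        df[["REF", "ALT"]].to_numpy(dtype=object),
        calls,
    )
    gt.validate()
    return gt


def read_variant_impacts(path: str) -> VariantImpactTable:
    """Read a (gene, founder, variant, impact) CSV; impact labels are
    normalized case-insensitively to HIGH/MODERATE/LOW/MODIFIER."""
    df = pd.read_csv(path, dtype=str)
    required = ["gene", "founder", "variant", "impact"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"impact table missing columns {missing_cols}")
    df = df[required].copy()
    df["impact"] = df["impact"].str.upper().str.replace("VARIANTS_IMPACT_", "", regex=False)
    bad = ~df["impact"].isin(IMPACT_LEVELS)
    if bad.any():
        raise FormatError(
            "unknown impact labels "
            f"{sorted(df.loc[bad, 'impact'].unique())} in rows {list(df.index[bad])}"
        )
    dups = df.duplicated(subset=["gene", "founder", "variant"])
    if dups.any():
        warnings.warn(f"{int(dups.sum())} duplicate impact rows dropped")
        df = df[~dups]
    return VariantImpactTable(df.reset_index(drop=True))


def read_gene_models(path: str) -> GeneModelTable:
    """Read gene features from GFF3 (1-based inclusive coordinates kept)."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for f in db.features_of_type("gene"):
        gene_id = f.attributes.get("ID", [f.id])[0]
        rows.append((gene_id, f.seqid, f.start, f.end, f.strand or "."))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start_bp", "end_bp", "strand"])
    if df.empty:
        df = pd.DataFrame(columns=["gene", "chrom", "start_bp", "end_bp", "strand"])
    return GeneModelTable(df)


def read_phenotype_table(path: str) -> PhenotypeTable:
    df = pd.read_csv(path)
    if "line_id" not in df.columns:
        raise FormatError("phenotype CSV needs a 'line_id' column")
    return PhenotypeTable(df.set_index("line_id"))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_vcf(gt: GenotypeTable, path: str) -> None:
    """Write a GenotypeTable as a minimal VCF 4.2 text file."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gt.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gt.line_ids) + "\n")
        for j in range(gt.n_snps):
            ref, alt = gt.alleles[j]
            gts = "\t".join(code_to_gt[int(c)] for c in gt.calls[:, j])
            fh.write(
                f"{gt.chrom[j]}\t{gt.pos_bp[j]}\t{gt.snp_ids[j]}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotype_csv(gt: GenotypeTable, path: str) -> None:
    meta = pd.DataFrame(
        {
            "CHROM": gt.chrom,
            "POS": gt.pos_bp,
            "ID": gt.snp_ids,
            "REF": gt.alleles[:, 0],
            "ALT": gt.alleles[:, 1],
        }
    )
    calls = pd.DataFrame(gt.calls.T, columns=gt.line_ids)
    pd.concat([meta, calls], axis=1).to_csv(path, index=False)


def write_phenotype_table(pheno: PhenotypeTable, path: str) -> None:
    pheno.values.rename_axis("line_id").to_csv(path)
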