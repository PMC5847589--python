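"""End-to-end orchestration: simulate/load -> QC -> haplotype -> GWAS -> mine.

A single config (dict or YAML path) drives the run; one master seed feeds
every stochastic stage.  Every artifact is written under the run directory
and hashed into ``manifest.json`` so identical config + seed reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gwas_mod
from . import hmm as hmm_mod
from . import io_formats as io
from . import mining, qc, sim

REQUIRED_KEYS = ("seed", "phenotype")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _check_config(cfg: dict) -> None:
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if "simulation" not in cfg and "inputs" not in cfg:
        missing.append("simulation|inputs")
    if "simulation" in cfg and cfg.get("phenotype") == "simulated":
        missing = [m for m in missing if m != "phenotype"]
    if missing:
        raise KeyError(f"config is missing required keys: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_ham_pipeline(config, out_dir: str | Path) -> dict:
    """Run the full HAM pipeline; returns the manifest dict.

    Config layout (defaults in parentheses)::

        seed: int
        simulation:                 # or `inputs:` with file paths
          n_founders (8), n_families (25), n_lines_per_family (8),
          selfing_generations (4), chrom_lengths_bp ({3 chroms x 25 Mb}),
          n_snps_per_chrom (120), error_rate (0.002), missing_rate (0.02),
          causal: {chrom, pos_bp, carrier_founders, h2 (0.6)}
        phenotype: "simulated"      # or a CSV path
        qc: {maf_min (0.0625), max_missing (0.05), impute ("hmm_posterior")}
        hmm: {error_rate (0.01), junction_density (1.75)}
        gwas: {n_components (2), region_factor (1e3)}
        mine: {alpha (0.01), min_n (2), min_posterior (0.8)}
    """
    cfg = _load_config(config)
    _check_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict[str, str] = {}

    # -- stage 1: inputs ----------------------------------------------------
    genes = impacts = None
    if "simulation" in cfg:
        gt, panel, pheno, truth_info = _simulate_inputs(cfg, seed, out, artifacts)
        genes, impacts = truth_info.get("genes"), truth_info.get("impacts")
    else:
        inp = cfg["inputs"]
        gt = io.read_genotype_table(inp["genotypes"], inp.get("format", "vcf"))
        panel_gt = io.read_genotype_table(inp["founders"], inp.get("format", "vcf"))
        panel = io.FounderPanel(list(panel_gt.line_ids), panel_gt)
        pheno = io.read_phenotype_table(cfg["phenotype"])
        if "gene_models" in inp:
            genes = io.read_gene_models(inp["gene_models"])
        if "variant_impacts" in inp:
            impacts = io.read_variant_impacts(inp["variant_impacts"])

    # -- stage 2: QC + imputation -------------------------------------------
    qc_cfg = cfg.get("qc", {})
    filtered, report = qc.filter_snps(
        gt,
        maf_min=qc_cfg.get("maf_min", 0.0625),
        max_missing=qc_cfg.get("max_missing", 0.05),
    )
    snp_keep = np.isin(gt.snp_ids, filtered.snp_ids)
    panel = io.FounderPanel(panel.founder_ids, panel.genotypes.subset(snp_mask=snp_keep))
    hmm_cfg = cfg.get("hmm", {})
    params = hmm_mod.HMMParams(
        error_rate=hmm_cfg.get("error_rate", 0.01),
        junction_density=hmm_cfg.get("junction_density", 1.75),
    )
    imputed = qc.impute_missing(
        filtered, qc_cfg.get("impute", "hmm_posterior"), panel=panel, hmm_params=params
    )
    _write_json(out / "qc_report.json", report.to_dict(), artifacts)
    io.write_genotype_csv(imputed, out / "genotypes_imputed.csv")
    artifacts["genotypes_imputed.csv"] = _sha256(out / "genotypes_imputed.csv")

    # -- stage 3: founder haplotypes ----------------------------------------
    probs = hmm_mod.infer_founder_probabilities(imputed, panel, params)
    probs.to_long_dataframe().to_csv(out / "haplotype_posteriors.csv", index=False)
    artifacts["haplotype_posteriors.csv"] = _sha256(out / "haplotype_posteriors.csv")

    # -- stage 4: GWAS -------------------------------------------------------
    gwas_cfg = cfg.get("gwas", {})
    K = gwas_mod.compute_kinship(imputed)
    Q = gwas_mod.compute_structure(imputed, gwas_cfg.get("n_components", 2))
    res_snp = gwas_mod.gwas_snp(pheno, imputed, Q, K)
    res_hap = gwas_mod.gwas_haplotype(pheno, probs, Q, K)
    for name, res in (("gwas_snp.csv", res_snp), ("gwas_haplotype.csv", res_hap)):
        res.table.to_csv(out / name, index=False)
        artifacts[name] = _sha256(out / name)
    region = gwas_mod.define_locus_region(res_hap, gwas_cfg.get("region_factor", 1e3))
    _write_json(
        out / "locus_region.json",
        {
            "chrom": region.chrom,
            "peak_snp": region.peak_snp,
            "n_members": len(region.member_snps),
            "start_bp": region.start_bp,
            "end_bp": region.end_bp,
            "threshold": region.threshold,
        },
        artifacts,
    )
    qq = gwas_mod.bonferroni_qq(res_hap)
    qq.to_csv(out / "qq_haplotype.csv", index=False)
    artifacts["qq_haplotype.csv"] = _sha256(out / "qq_haplotype.csv")

    # -- stage 5: allele mining ----------------------------------------------
    mine_cfg = cfg.get("mine", {})
    groups = mining.group_lines_by_peak_haplotype(
        probs, region.peak_snp, mine_cfg.get("min_posterior", 0.8)
    )
    classes = mining.classify_founder_alleles(
        groups, pheno,
        alpha=mine_cfg.get("alpha", 0.01), min_n=mine_cfg.get("min_n", 2),
    )
    _write_json(
        out / "founder_classes.json",
        {"classes": classes.classes, "unclassified": classes.unclassified},
        artifacts,
    )
    if genes is not None and impacts is not None:
        types = mining.type_gene_alleles(impacts, panel.founder_ids)
        report_c = mining.narrow_candidates(region, classes, types, genes, impacts)
        report_c.genes.to_csv(out / "candidate_genes.csv", index=False)
        artifacts["candidate_genes.csv"] = _sha256(out / "candidate_genes.csv")

    manifest = {
        "seed": seed,
        "config": _jsonable(cfg),
        "artifacts": dict(sorted(artifacts.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _simulate_inputs(cfg: dict, seed: int, out: Path, artifacts: dict):
    s = cfg["simulation"]
    n_f = s.get("n_founders", 8)
    founder_ids = s.get("founder_ids", [f"F{i + 1}" for i in range(n_f)])
    lengths = s.get(
        "chrom_lengths_bp", {f"chr{i + 1:02d}": 25_000_000 for i in range(3)}
    )
    gmap = sim.GeneticMap.uniform(lengths, s.get("cm_per_mb", 4.0))
    design = sim.CrossDesign(
        founder_ids,
        n_families=s.get("n_families", 25),
        n_lines_per_family=s.get("n_lines_per_family", 8),
        selfing_generations=s.get("selfing_generations", 4),
    )
    panel = sim.random_founder_panel(
        founder_ids, gmap, s.get("n_snps_per_chrom", 120), seed=seed + 1
    )
    pop = sim.simulate_population(
        design, gmap, panel,
        error_rate=s.get("error_rate", 0.002),
        missing_rate=s.get("missing_rate", 0.02),
        seed=seed,
    )
    causal = s.get("causal", {})
    chrom = causal.get("chrom", gmap.chroms[0])
    pos_bp = causal.get("pos_bp", gmap.length_bp(chrom) // 2)
    carriers = causal.get("carrier_founders", founder_ids[:1])
    spec = sim.CausalSpec(
        chrom=chrom,
        pos_bp=pos_bp,
        founder_class={f: ("carrier" if f in carriers else "ref") for f in founder_ids},
        class_effects={"carrier": 1.0, "ref": 0.0},
    )
    pheno = sim.simulate_phenotype(pop, spec, h2=causal.get("h2", 0.6), seed=seed + 2)

    io.write_vcf(pop.genotypes, out / "lines.vcf")
    io.write_vcf(panel.genotypes, out / "founders.vcf")
    pop.mosaic.to_dataframe().to_csv(out / "true_mosaic.tsv", sep="\t", index=False)
    io.write_phenotype_table(pheno, out / "phenotype.csv")
    for name in ("lines.vcf", "founders.vcf", "true_mosaic.tsv", "phenotype.csv"):
        artifacts[name] = _sha256(out / name)

    genes = sim.simulate_gene_models(gmap, s.get("n_genes_per_chrom", 40), seed=seed + 3)
    causal_gene = _gene_covering(genes, chrom, pos_bp)
    impacts = sim.simulate_variant_impacts(
        genes, founder_ids, causal_gene, list(carriers), seed=seed + 4
    )
    genes.records.to_csv(out / "gene_models.csv", index=False)
    impacts.records.to_csv(out / "variant_impacts.csv", index=False)
    artifacts["gene_models.csv"] = _sha256(out / "gene_models.csv")
    artifacts["variant_impacts.csv"] = _sha256(out / "variant_impacts.csv")
    return pop.genotypes, panel, pheno, {"genes": genes, "impacts": impacts}


def _gene_covering(genes, chrom: str, pos_bp: int) -> str:
    hit = genes.in_interval(chrom, pos_bp, pos_bp)
    if len(hit):
        return hit["gene"].iloc[0]
    sub = genes.records[genes.records["chrom"] == chrom]
    i = (sub["start_bp"] - pos_bp).abs().idxmin()
    return sub.loc[i, "gene"]


def _write_json(path: Path, obj: dict, artifacts: dict) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
    artifacts[path.name] = _sha256(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
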