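"""Q+K mixed-model association in SNP and founder-haplotype modes.

The model is y = Q beta + g(s) + u + e with fixed structure covariates Q,
a per-marker genetic term, and a random polygenic effect u ~ N(0, sg^2 K).
Variance components are estimated once by REML on the null model via the
spectral decomposition of K (the "population parameters previously
determined" / EMMAX-style two-stage approximation); each marker is then
tested by GLS in the whitened space.

SNP mode tests the biallelic dosage (1-df Wald statistic referred to
chi-square(1)).  Haplotype mode replaces the dosage with the founder
posterior-probability design (one column dropped for identifiability) and
tests all founder effects jointly with an F statistic on
(df_founders, n - rank(Q) - df_founders) degrees of freedom, returning
per-founder effects relative to the dropped founder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .hmm import HaplotypeProbabilities
from .io_formats import MISSING, GenotypeTable, PhenotypeTable

_EPS = 1e-12


@dataclass
class KinshipMatrix:
    values: np.ndarray
    line_ids: list[str]
    method: str = "realized-relationship"

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")


@dataclass
class StructureCovariates:
    values: np.ndarray  # n_lines x q, first column = intercept
    line_ids: list[str]
    source: str = "pca"

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("structure covariates are rank deficient")


@dataclass
class GWASResult:
    table: pd.DataFrame  # snp, chrom, pos, stat, df, p, neglog10p, effect cols
    mode: str
    model: dict = field(default_factory=dict)


@dataclass
class LocusRegion:
    chrom: str
    peak_snp: str
    member_snps: list[str]
    threshold: float
    start_bp: int
    end_bp: int


def _dosage(gt: GenotypeTable) -> np.ndarray:
    if (gt.calls == MISSING).any():
        raise ValueError("complete (imputed) genotypes required")
    return gt.calls.astype(float)


def compute_kinship(gt: GenotypeTable) -> KinshipMatrix:
    """Realized-relationship matrix from centered allele dosages, scaled so
    the mean diagonal equals 1."""
    X = _dosage(gt)
    X = X - X.mean(axis=0, keepdims=True)
    K = X @ X.T
    tr = np.trace(K)
    if tr <= 0:
        raise ValueError("kinship undefined: all SNPs monomorphic")
    K *= gt.n_lines / tr
    return KinshipMatrix(K, list(gt.line_ids))


def compute_structure(gt: GenotypeTable, n_components: int = 2) -> StructureCovariates:
    """Intercept plus top principal components of the centered dosages."""
    if n_components >= gt.n_lines:
        raise ValueError("n_components must be smaller than the number of lines")
    X = _dosage(gt)
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant genotype matrix: principal components undefined")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :n_components] * S[:n_components]
    Q = np.column_stack([np.ones(gt.n_lines), pcs])
    return StructureCovariates(Q, list(gt.line_ids))


# ---------------------------------------------------------------------------
# two-stage mixed model
# ---------------------------------------------------------------------------


class MixedModel:
    """Spectral-decomposition mixed model shared by both GWAS modes.

    Eigendecomposes K once (shifting by the smallest epsilon*I needed for
    positive semidefiniteness, logged via warnings) and caches the rotation,
    so many phenotypes can be fitted against the same K cheaply.
    """

    def __init__(self, K: KinshipMatrix, Q: StructureCovariates):
        if K.line_ids != Q.line_ids:
            raise ValueError("K and Q line ids differ")
        self.line_ids = K.line_ids
        vals = np.linalg.eigvalsh(K.values)
        shift = 0.0
        if vals[0] < -1e-8:
            shift = -vals[0] + 1e-8
            warnings.warn(f"kinship shifted by {shift:.3e} * I to reach PSD")
        self.s, self.U = np.linalg.eigh(K.values + shift * np.eye(len(K.values)))
        self.s = np.clip(self.s, 0.0, None)
        self.Qt = self.U.T @ Q.values
        self.q = Q.values.shape[1]
        self.shift = shift

    def fit_null(self, y: np.ndarray) -> dict:
        """REML variance components on the null model y = Q beta + u + e."""
        yt = self.U.T @ y
        n, q = len(yt), self.q
        if np.var(y) < _EPS:
            return {"delta": np.inf, "sigma_g2": 0.0, "sigma_e2": 0.0, "constant": True,
                    "yt": yt}

        def neg_reml(log_delta: float) -> float:
            w = self.s + np.exp(log_delta)
            Xw = self.Qt / w[:, None]
            XtWX = self.Qt.T @ Xw
            beta = np.linalg.solve(XtWX, Xw.T @ yt)
            r = yt - self.Qt @ beta
            sg2 = (r * r / w).sum() / (n - q)
            sign, logdet = np.linalg.slogdet(XtWX)
            return 0.5 * ((n - q) * np.log(sg2) + np.log(w).sum() + logdet)

        grid = np.linspace(-8, 8, 17)
        best = grid[int(np.argmin([neg_reml(g) for g in grid]))]
        res = optimize.minimize_scalar(
            neg_reml, bounds=(best - 1.5, best + 1.5), method="bounded"
        )
        delta = float(np.exp(res.x))
        w = self.s + delta
        Xw = self.Qt / w[:, None]
        beta = np.linalg.solve(self.Qt.T @ Xw, Xw.T @ yt)
        r = yt - self.Qt @ beta
        sg2 = float((r * r / w).sum() / (n - q))
        return {"delta": delta, "sigma_g2": sg2, "sigma_e2": sg2 * delta,
                "constant": False, "yt": yt}

    def whiten(self, null: dict):
        """Return (y*, Q*, rotate) where rotate maps raw columns into the
        whitened space used for per-marker GLS."""
        delta = null["delta"] if np.isfinite(null["delta"]) else 1.0
        w = np.sqrt(self.s + delta)
        ys = null["yt"] / w
        Qs = self.Qt / w[:, None]

        def rotate(X: np.ndarray) -> np.ndarray:
            return (self.U.T @ X) / w[:, None]

        return ys, Qs, rotate


def _align_phenotype(pheno: PhenotypeTable, trait: str | None, line_ids: list[str]):
    df = pheno.values
    trait = trait or df.columns[0]
    y = df.loc[line_ids, trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values for tested lines")
    return y, trait


def gwas_snp(
    pheno: PhenotypeTable,
    gt: GenotypeTable,
    Q: StructureCovariates,
    K: KinshipMatrix,
    trait: str | None = None,
) -> GWASResult:
    """Per-SNP 1-df Wald test of the allele dosage under the Q+K model."""
    y, trait = _align_phenotype(pheno, trait, K.line_ids)
    if gt.line_ids != K.line_ids:
        raise ValueError("genotype and kinship line ids differ")
    model = MixedModel(K, Q)
    null = model.fit_null(y)
    ys, Qs, rotate = model.whiten(null)
    X = rotate(_dosage(gt))
    proj = np.linalg.lstsq(Qs, np.column_stack([ys, X]) if X.size else ys[:, None],
                           rcond=None)[0]
    resid = np.column_stack([ys, X]) - Qs @ proj
    y_r, X_r = resid[:, 0], resid[:, 1:]
    xx = (X_r * X_r).sum(axis=0)
    xy = X_r.T @ y_r
    yy = float(y_r @ y_r)
    n, q = len(ys), model.q
    dfres = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xx > _EPS, xy / np.maximum(xx, _EPS), 0.0)
        rss = yy - beta * beta * xx
        sigma2 = np.maximum(rss, 0.0) / dfres
        stat = np.where(
            (xx > _EPS) & (sigma2 > _EPS), beta * beta * xx / np.maximum(sigma2, _EPS), 0.0
        )
    p = stats.chi2.sf(stat, df=1)
    p = np.where(stat <= 0, 1.0, p)
    table = _result_frame(gt, stat, 1, p)
    table["effect"] = beta
    return GWASResult(table, mode="snp", model=_model_info(null, model, trait))


def gwas_haplotype(
    pheno: PhenotypeTable,
    probs: HaplotypeProbabilities,
    Q: StructureCovariates,
    K: KinshipMatrix,
    trait: str | None = None,
    zero_col_tol: float = 1e-8,
) -> GWASResult:
    """Multi-df joint test of founder effects at each SNP.

    The design at a SNP is the line x founder posterior matrix with the
    alphabetically last founder dropped for identifiability (effects are
    relative to it); founder columns with numerically zero mass are dropped
    from the test at that SNP and recorded in the result table.
    """
    y, trait = _align_phenotype(pheno, trait, K.line_ids)
    if probs.line_ids != K.line_ids:
        raise ValueError("posterior and kinship line ids differ")
    model = MixedModel(K, Q)
    null = model.fit_null(y)
    ys, Qs, rotate = model.whiten(null)
    Qpinv = np.linalg.pinv(Qs)
    y_r = ys - Qs @ (Qpinv @ ys)
    yy = float(y_r @ y_r)
    n, q = len(ys), model.q
    founders = probs.founder_ids
    ref = max(founders)  # alphabetically last
    n_snps = probs.probs.shape[1]
    stat = np.zeros(n_snps)
    pvals = np.ones(n_snps)
    dfs = np.zeros(n_snps, dtype=int)
    effects = np.full((n_snps, len(founders)), np.nan)
    dropped: list[str] = []
    for s in range(n_snps):
        D = probs.probs[:, s, :]
        mass = D.sum(axis=0)
        keep = [f for f, m in zip(founders, mass) if m > zero_col_tol]
        dropped.append(";".join(f for f, m in zip(founders, mass) if m <= zero_col_tol))
        test_f = [f for f in keep if f != ref or ref not in keep]
        if ref in keep:
            test_f = [f for f in keep if f != ref]
        cols = [founders.index(f) for f in test_f]
        if not cols or yy < _EPS:
            continue
        Ds = rotate(D[:, cols])
        D_r = Ds - Qs @ (Qpinv @ Ds)
        beta, _, rank, _ = np.linalg.lstsq(D_r, y_r, rcond=None)
        if rank == 0:
            continue
        rss1 = float(y_r @ y_r - (D_r @ beta) @ y_r)
        df1 = int(rank)
        dfres = n - q - df1
        if dfres <= 0:
            continue
        rss1 = max(rss1, 0.0)
        num = (yy - rss1) / df1
        den = rss1 / dfres
        if den < _EPS:
            stat[s] = np.inf if num > 0 else 0.0
            pvals[s] = 0.0 if num > 0 else 1.0
        else:
            stat[s] = num / den
            pvals[s] = float(stats.f.sf(stat[s], df1, dfres))
        dfs[s] = df1
        for f, b in zip(test_f, beta):
            effects[s, founders.index(f)] = b
    table = _result_frame_from_probs(probs, stat, dfs, pvals)
    for j, f in enumerate(founders):
        table[f"effect_{f}"] = effects[:, j]
    table["dropped_founders"] = dropped
    return GWASResult(table, mode="haplotype", model=_model_info(null, model, trait))


def _model_info(null: dict, model: MixedModel, trait: str) -> dict:
    return {
        "trait": trait,
        "delta": null["delta"],
        "sigma_g2": null["sigma_g2"],
        "sigma_e2": null["sigma_e2"],
        "psd_shift": model.shift,
        "q_columns": model.q,
    }


def _result_frame(gt: GenotypeTable, stat, df, p) -> pd.DataFrame:
    return _frame(gt.snp_ids, gt.chrom, gt.pos_bp, stat, df, p)


def _result_frame_from_probs(probs: HaplotypeProbabilities, stat, df, p) -> pd.DataFrame:
    return _frame(probs.snp_ids, probs.chrom, probs.pos_bp, stat, df, p)


def _frame(snp_ids, chrom, pos, stat, df, p) -> pd.DataFrame:
    p = np.clip(np.asarray(p, dtype=float), np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "snp": list(snp_ids),
            "chrom": np.asarray(chrom),
            "pos_bp": np.asarray(pos),
            "stat": np.asarray(stat, dtype=float),
            "df": df,
            "p": p,
            "neglog10p": -np.log10(p),
        }
    )


# ---------------------------------------------------------------------------
# locus regions, multiple testing
# ---------------------------------------------------------------------------


def define_locus_region(result: GWASResult, factor: float = 1e3) -> LocusRegion:
    """Trait-locus region: the maximal contiguous run of SNPs around the
    genome-wide minimum P whose P-values fall below min(P) * factor.

    The peak is the argmin P (ties resolved to the lowest genome
    coordinate); the threshold is capped at 1.
    """
    t = result.table
    if t.empty:
        raise ValueError("empty GWAS result")
    i_peak = int(t["p"].to_numpy().argmin())  # first minimum = lowest coordinate
    threshold = min(1.0, float(t["p"].iloc[i_peak]) * factor)
    chrom = t["chrom"].iloc[i_peak]
    on_chrom = np.flatnonzero((t["chrom"] == chrom).to_numpy())
    k = int(np.where(on_chrom == i_peak)[0][0])
    p_chr = t["p"].to_numpy()[on_chrom]
    lo = k
    while lo > 0 and p_chr[lo - 1] < threshold:
        lo -= 1
    hi = k
    while hi + 1 < len(on_chrom) and p_chr[hi + 1] < threshold:
        hi += 1
    members = on_chrom[lo: hi + 1]
    return LocusRegion(
        chrom=chrom,
        peak_snp=t["snp"].iloc[i_peak],
        member_snps=t["snp"].iloc[members].tolist(),
        threshold=threshold,
        start_bp=int(t["pos_bp"].iloc[members].min()),
        end_bp=int(t["pos_bp"].iloc[members].max()),
    )


def bonferroni_qq(result: GWASResult) -> pd.DataFrame:
    """Bonferroni-adjusted P-values plus Q-Q plot coordinates.

    Adjusted P = min(1, P * m).  Expected quantiles are -log10((i - 0.5)/m)
    against the sorted observed -log10 P.
    """
    t = result.table
    m = len(t)
    if m < 1:
        raise ValueError("need at least one test")
    out = t[["snp", "chrom", "pos_bp", "p"]].copy()
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * m)
    order = np.argsort(out["p"].to_numpy())
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    out["expected_neglog10p"] = -np.log10((ranks - 0.5) / m)
    out["observed_neglog10p"] = -np.log10(out["p"])
    return out
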