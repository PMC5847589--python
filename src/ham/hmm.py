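"""Founder-haplotype reconstruction for MAGIC lines via an explicit HMM.

Each near-inbred line is modelled as a hidden Markov chain along every
chromosome whose hidden state is the founder of origin at each SNP (a
single founder per position, not a founder pair, because F5/F6 lines are
near-homozygous).  Emissions compare the observed call with the founder's
homozygous allele: probability 1 - eps on a match and eps on a mismatch,
where eps is the genotyping error rate; heterozygous or missing
observations are uninformative (uniform emission), as are SNPs where the
founder itself is heterozygous or missing.  Transitions between adjacent
SNPs keep the current founder with probability exp(-d * rho) for map
distance d (Morgan) and expected junction density rho (switches/Morgan),
with the remaining mass split equally among the other founders.  The
stationary prior is uniform.

Posteriors come from the scaled forward-backward recursions; hard paths
from Viterbi with ties broken toward the lower founder index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, FounderPanel, GenotypeTable
from .sim import GeneticMap, TrueMosaic


@dataclass
class HMMParams:
    """Explicit parameters of the founder HMM.

    error_rate : genotyping error eps in [0, 0.5); default 0.01 (GBS-like).
    junction_density : expected founder switches per Morgan.  Default 1.75,
        a modelling choice reflecting an 8-way funnel plus SSD; the
        posterior is insensitive to moderate misspecification because
        emissions dominate when founders are locally distinguishable.
    cm_per_mb : uniform genetic rate used when the genotype table carries
        no genetic positions and no map is given.
    """

    error_rate: float = 0.01
    junction_density: float = 1.75
    cm_per_mb: float = 4.0
    gmap: GeneticMap | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.junction_density <= 0:
            raise ValueError("junction_density must be positive")


@dataclass
class HaplotypeProbabilities:
    """line x SNP x founder posterior array; rows over founders sum to 1."""

    probs: np.ndarray
    line_ids: list[str]
    snp_ids: list[str]
    founder_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray

    def map_labels(self) -> np.ndarray:
        """Maximum-posterior founder index per (line, SNP)."""
        return self.probs.argmax(axis=2)

    def to_long_dataframe(self) -> pd.DataFrame:
        n_l, n_s, n_f = self.probs.shape
        return pd.DataFrame(
            {
                "line": np.repeat(self.line_ids, n_s * n_f),
                "chrom": np.tile(np.repeat(self.chrom, n_f), n_l),
                "pos_bp": np.tile(np.repeat(self.pos_bp, n_f), n_l),
                "snp": np.tile(np.repeat(self.snp_ids, n_f), n_l),
                "founder": np.tile(self.founder_ids, n_l * n_s),
                "prob": self.probs.reshape(-1),
            }
        )


@dataclass
class MosaicPath:
    """Hard founder assignment per (line, SNP) plus derived segments."""

    labels: np.ndarray  # line x SNP founder indices
    line_ids: list[str]
    snp_ids: list[str]
    founder_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray

    def to_segments(self) -> pd.DataFrame:
        """Run-length segments (BED-like, bp bounds from flanking SNPs)."""
        rows = []
        for i, line in enumerate(self.line_ids):
            for c in pd.unique(self.chrom):
                idx = np.flatnonzero(self.chrom == c)
                lab = self.labels[i, idx]
                pos = self.pos_bp[idx]
                start = 0
                for k in range(1, len(idx) + 1):
                    if k == len(idx) or lab[k] != lab[start]:
                        rows.append(
                            (line, c, int(pos[start]), int(pos[k - 1]),
                             self.founder_ids[lab[start]])
                        )
                        start = k
        return pd.DataFrame(rows, columns=["line", "chrom", "start_bp", "end_bp", "founder"])


# ---------------------------------------------------------------------------


def _emissions(gt: GenotypeTable, panel: FounderPanel, eps: float) -> np.ndarray:
    """Emission matrix, shape (n_lines, n_snps, n_founders)."""
    codes = panel.allele_codes()  # founders x snps, {0,2,MISSING}
    calls = gt.calls  # lines x snps
    n_l, n_s = calls.shape
    n_f = panel.n_founders
    E = np.ones((n_l, n_s, n_f))
    informative_obs = (calls == 0) | (calls == 2)  # lines x snps
    for f in range(n_f):
        fa = codes[f]  # snps
        known = fa != MISSING
        match = (calls == fa[None, :]) & known[None, :] & informative_obs
        mismatch = (calls != fa[None, :]) & known[None, :] & informative_obs
        E[:, :, f][match] = 1.0 - eps
        E[:, :, f][mismatch] = eps
        E[:, :, f][informative_obs & ~known[None, :]] = 0.5
    return E


def _check_alignment(gt: GenotypeTable, panel: FounderPanel) -> None:
    if panel.n_founders == 0:
        raise ValueError("zero founders")
    if list(panel.genotypes.snp_ids) != list(gt.snp_ids):
        raise ValueError("line table and founder panel have misaligned SNP indices")


def _stay_probs(gt: GenotypeTable, idx: np.ndarray, params: HMMParams) -> np.ndarray:
    if params.gmap is not None:
        c = gt.chrom[idx[0]]
        cm = np.asarray(params.gmap.bp_to_cm(c, gt.pos_bp[idx]))
    else:
        cm = gt.ensure_cm(params.cm_per_mb)[idx]
    d_morgan = np.diff(cm) / 100.0
    return np.exp(-np.abs(d_morgan) * params.junction_density)


def infer_founder_probabilities(
    gt: GenotypeTable, panel: FounderPanel, params: HMMParams | None = None
) -> HaplotypeProbabilities:
    """Forward-backward posterior founder probabilities for every line.

    Chromosomes are processed independently; the first SNP of each uses the
    uniform stationary prior.  Raises if some observation has probability
    zero under every founder (possible only at ``error_rate`` = 0).
    """
    params = params or HMMParams()
    _check_alignment(gt, panel)
    n_f = panel.n_founders
    E = _emissions(gt, panel, params.error_rate)
    post = np.empty_like(E)
    for c in pd.unique(gt.chrom):
        idx = np.flatnonzero(gt.chrom == c)
        stay = _stay_probs(gt, idx, params)
        post[:, idx, :] = _forward_backward(E[:, idx, :], stay, n_f)
    return HaplotypeProbabilities(
        post, list(gt.line_ids), list(gt.snp_ids), list(panel.founder_ids),
        gt.chrom, gt.pos_bp,
    )


def _transition_apply(mat: np.ndarray, stay: float, n_f: int) -> np.ndarray:
    """Row-stochastic transition applied to each row of ``mat`` (lines x F)."""
    if n_f == 1:
        return mat
    off = (1.0 - stay) / (n_f - 1)
    return (stay - off) * mat + off * mat.sum(axis=1, keepdims=True)


def _forward_backward(E: np.ndarray, stay: np.ndarray, n_f: int) -> np.ndarray:
    n_l, n_s, _ = E.shape
    alpha = np.empty_like(E)
    scale = np.empty((n_l, n_s))
    a = E[:, 0, :] / n_f
    _rescale(a, scale[:, 0], 0)
    alpha[:, 0, :] = a
    for t in range(1, n_s):
        a = _transition_apply(a, stay[t - 1], n_f) * E[:, t, :]
        _rescale(a, scale[:, t], t)
        alpha[:, t, :] = a
    beta = np.ones((n_l, n_f))
    post = np.empty_like(E)
    post[:, n_s - 1, :] = alpha[:, n_s - 1, :]
    for t in range(n_s - 2, -1, -1):
        beta = _transition_apply(beta * E[:, t + 1, :], stay[t], n_f)
        beta /= beta.sum(axis=1, keepdims=True)
        g = alpha[:, t, :] * beta
        g /= g.sum(axis=1, keepdims=True)
        post[:, t, :] = g
    return post


def _rescale(a: np.ndarray, out: np.ndarray, t: int) -> None:
    s = a.sum(axis=1)
    if np.any(s <= 0):
        raise ValueError(
            f"observation at SNP index {t} impossible under every founder "
            "(zero-probability path; increase error_rate)"
        )
    out[:] = s
    a /= s[:, None]


def viterbi_mosaic(
    gt: GenotypeTable, panel: FounderPanel, params: HMMParams | None = None
) -> MosaicPath:
    """Most probable founder path per line under the same HMM.

    Ties are broken toward the lower founder index.
    """
    params = params or HMMParams()
    _check_alignment(gt, panel)
    n_f = panel.n_founders
    with np.errstate(divide="ignore"):
        logE = np.log(_emissions(gt, panel, params.error_rate))
    labels = np.empty((gt.n_lines, gt.n_snps), dtype=np.int64)
    for c in pd.unique(gt.chrom):
        idx = np.flatnonzero(gt.chrom == c)
        stay = _stay_probs(gt, idx, params)
        labels[:, idx] = _viterbi_chrom(logE[:, idx, :], stay, n_f)
    return MosaicPath(
        labels, list(gt.line_ids), list(gt.snp_ids), list(panel.founder_ids),
        gt.chrom, gt.pos_bp,
    )


def _viterbi_chrom(logE: np.ndarray, stay: np.ndarray, n_f: int) -> np.ndarray:
    n_l, n_s, _ = logE.shape
    delta = logE[:, 0, :] - np.log(n_f)
    _check_finite(delta, 0)
    back = np.empty((n_s, n_l, n_f), dtype=np.int8)
    with np.errstate(divide="ignore"):
        for t in range(1, n_s):
            off = (1.0 - stay[t - 1]) / max(n_f - 1, 1)
            L = np.full((n_f, n_f), np.log(off) if off > 0 else -np.inf)
            np.fill_diagonal(L, np.log(stay[t - 1]) if stay[t - 1] > 0 else -np.inf)
            cand = delta[:, :, None] + L[None, :, :]  # lines x from x to
            back[t] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + logE[:, t, :]
            _check_finite(delta, t)
            delta -= delta.max(axis=1, keepdims=True)
    path = np.empty((n_l, n_s), dtype=np.int64)
    path[:, n_s - 1] = delta.argmax(axis=1)
    for t in range(n_s - 1, 0, -1):
        path[:, t - 1] = back[t][np.arange(n_l), path[:, t]]
    return path


def _check_finite(delta: np.ndarray, t: int) -> None:
    if np.any(~np.isfinite(delta).any(axis=1)):
        raise ValueError(
            f"zero-probability path at SNP index {t}: observation impossible "
            "under every founder with error_rate = 0"
        )


def reconstruction_accuracy(
    pred: MosaicPath | HaplotypeProbabilities, truth: TrueMosaic
) -> tuple[pd.Series, float]:
    """Fraction of SNP cells whose MAP founder matches the true mosaic.

    Cells where the line's two true homologs disagree (residual
    heterozygosity) carry no single truth founder and are excluded.
    Returns (per-line fractions, overall fraction).
    """
    labels = pred.labels if isinstance(pred, MosaicPath) else pred.map_labels()
    if labels.shape[1] != len(pred.snp_ids):
        raise ValueError("label/SNP length mismatch")
    fidx = {f: i for i, f in enumerate(truth.founder_ids)}
    name_map = np.array([fidx[f] for f in pred.founder_ids])
    per_line = {}
    n_ok = n_tot = 0
    for i, line in enumerate(pred.line_ids):
        ok = tot = 0
        for c in pd.unique(pred.chrom):
            idx = np.flatnonzero(pred.chrom == c)
            f01 = truth.founders_at(line, c, pred.pos_bp[idx])
            homozygous = f01[0] == f01[1]
            ok += int((name_map[labels[i, idx]][homozygous] == f01[0][homozygous]).sum())
            tot += int(homozygous.sum())
        per_line[line] = ok / tot if tot else np.nan
        n_ok += ok
        n_tot += tot
    return pd.Series(per_line), (n_ok / n_tot if n_tot else np.nan)
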