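import itertools

import numpy as np
import pytest

from ham import (
    FounderPanel,
    GenotypeTable,
    HMMParams,
    infer_founder_probabilities,
    reconstruction_accuracy,
    viterbi_mosaic,
)
from ham.hmm import MosaicPath
from ham.io_formats import MISSING
from ham.sim import TrueMosaic

from conftest import panel_subset, two_founder_panel


def make_line(calls, panel, pos_cm=None):
    pg = panel.genotypes
    return GenotypeTable(
        ["line"],
        list(pg.snp_ids),
        pg.chrom.copy(),
        pg.pos_bp.copy(),
        pg.alleles.copy(),
        np.asarray([calls], dtype=np.int8),
        pos_cm=pos_cm,
    )


def enumerate_posteriors(calls, founder_codes, pos_cm, eps, rho):
    """Brute-force posterior over all founder paths for one line (oracle)."""
    n_f, n_s = founder_codes.shape

    def emit(obs, fa):
        if obs in (1, MISSING):
            return 1.0
        if fa == MISSING:
            return 0.5
        return 1.0 - eps if obs == fa else eps

    stay = np.exp(-np.diff(pos_cm) / 100.0 * rho)
    post = np.zeros((n_s, n_f))
    total = 0.0
    for path in itertools.product(range(n_f), repeat=n_s):
        p = 1.0 / n_f * emit(calls[0], founder_codes[path[0], 0])
        for t in range(1, n_s):
            trans = stay[t - 1] if path[t] == path[t - 1] else (1 - stay[t - 1]) / (n_f - 1)
            p *= trans * emit(calls[t], founder_codes[path[t], t])
        total += p
        for t, f in enumerate(path):
            post[t, f] += p
    return post / total


def test_forward_backward_matches_path_enumeration():
    """3-SNP, 2-founder toy: posteriors equal exhaustive enumeration to 1e-12."""
    panel = two_founder_panel(n_snps=3)
    pos_cm = np.array([0.0, 3.0, 10.0])
    for calls in ([0, 2, 0], [0, MISSING, 2], [1, 2, 2], [2, 2, 2]):
        line = make_line(calls, panel, pos_cm=pos_cm)
        params = HMMParams(error_rate=0.1, junction_density=1.75)
        probs = infer_founder_probabilities(line, panel, params)
        oracle = enumerate_posteriors(
            np.array(calls), panel.allele_codes(), pos_cm, 0.1, 1.75
        )
        np.testing.assert_allclose(probs.probs[0], oracle, atol=1e-12)


def test_pure_founder_line_posterior_is_one():
    panel = two_founder_panel(n_snps=10)
    line = make_line(np.full(10, 2), panel)  # identical to founder B
    probs = infer_founder_probabilities(line, panel, HMMParams(error_rate=0.0))
    np.testing.assert_allclose(probs.probs[0, :, 1], 1.0, atol=1e-12)


def test_posteriors_normalized(pop8):
    from ham import filter_snps

    gtf, _ = filter_snps(pop8.genotypes)
    panel = panel_subset(pop8.founders, gtf.snp_ids)
    probs = infer_founder_probabilities(gtf, panel)
    np.testing.assert_allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)
    assert probs.probs.min() >= 0 and probs.probs.max() <= 1


def test_posterior_invariant_to_snp_order_reversal():
    panel = two_founder_panel(n_snps=8)
    calls = np.array([0, 0, 2, MISSING, 2, 1, 0, 0])
    line = make_line(calls, panel)
    fwd = infer_founder_probabilities(line, panel, HMMParams(error_rate=0.05))

    pg = panel.genotypes
    max_bp = pg.pos_bp.max() + 1
    rev = GenotypeTable(
        ["A", "B"], list(pg.snp_ids)[::-1], pg.chrom, (max_bp - pg.pos_bp)[::-1],
        pg.alleles[::-1], pg.calls[:, ::-1],
    )
    rev_panel = FounderPanel(["A", "B"], rev)
    rev_line = make_line(calls[::-1], rev_panel)
    bwd = infer_founder_probabilities(rev_line, rev_panel, HMMParams(error_rate=0.05))
    np.testing.assert_allclose(bwd.probs[0, ::-1, :], fwd.probs[0], atol=1e-10)


def test_posterior_contrast_shrinks_as_error_rate_grows():
    panel = two_founder_panel(n_snps=6)
    line = make_line([0, 0, 0, 0, 0, 0], panel)
    contrasts = []
    for eps in (0.01, 0.1, 0.3, 0.45):
        probs = infer_founder_probabilities(line, panel, HMMParams(error_rate=eps))
        contrasts.append(np.abs(probs.probs[0, :, 0] - 0.5).mean())
    assert all(a > b for a, b in zip(contrasts, contrasts[1:]))


def test_viterbi_constant_path_for_pure_line():
    panel = two_founder_panel(n_snps=10)
    line = make_line(np.zeros(10), panel)
    path = viterbi_mosaic(line, panel, HMMParams(error_rate=0.01))
    assert (path.labels == 0).all()


def test_viterbi_single_crossover_located_within_one_interval():
    panel = two_founder_panel(n_snps=20)
    calls = np.concatenate([np.zeros(8), np.full(12, 2)])  # junction in interval 7-8
    line = make_line(calls, panel)
    path = viterbi_mosaic(line, panel, HMMParams(error_rate=0.01))
    switches = np.flatnonzero(np.diff(path.labels[0]) != 0)
    assert len(switches) == 1
    assert switches[0] in (6, 7, 8)


def test_impossible_observation_with_zero_error_raises():
    panel = two_founder_panel(n_snps=3)
    codes = panel.genotypes.calls.copy()
    codes[:, 1] = 0  # both founders reference at SNP 1
    panel.genotypes.calls = codes
    line = make_line([0, 2, 0], panel)  # alt call impossible
    with pytest.raises(ValueError, match="impossible"):
        infer_founder_probabilities(line, panel, HMMParams(error_rate=0.0))
    with pytest.raises(ValueError, match="impossible|zero-probability"):
        viterbi_mosaic(line, panel, HMMParams(error_rate=0.0))


def single_founder_mosaic(founder, pos, founder_ids, chrom="chr01", L=100_000_000):
    return TrueMosaic(
        founder_ids,
        {chrom: L},
        {"line": {chrom: ([(1, L + 1, founder)], [(1, L + 1, founder)])}},
    )


def path_with_labels(labels, panel):
    pg = panel.genotypes
    return MosaicPath(
        np.asarray([labels]), ["line"], list(pg.snp_ids), list(panel.founder_ids),
        pg.chrom, pg.pos_bp,
    )


def test_reconstruction_accuracy_extremes_and_random_baseline():
    panel = two_founder_panel(n_snps=50)
    truth = single_founder_mosaic(0, panel.genotypes.pos_bp, ["A", "B"])
    per_line, overall = reconstruction_accuracy(path_with_labels(np.zeros(50, int), panel), truth)
    assert overall == 1.0
    _, wrong = reconstruction_accuracy(path_with_labels(np.ones(50, int), panel), truth)
    assert wrong == 0.0

    # random 8-founder assignment vs a single-founder truth ~ 1/8 correct
    founders = [f"F{i}" for i in range(1, 9)]
    n = 4000
    pos = np.arange(1, n + 1) * 100
    gt = GenotypeTable(
        founders, [f"s{i}" for i in range(n)], ["chr01"] * n, pos,
        np.array([("A", "T")] * n, dtype=object), np.zeros((8, n), np.int8),
    )
    panel8 = FounderPanel(founders, gt)
    truth8 = single_founder_mosaic(0, pos, founders)
    rng = np.random.default_rng(1)
    _, acc = reconstruction_accuracy(
        path_with_labels(rng.integers(0, 8, n), panel8), truth8
    )
    assert abs(acc - 0.125) < 0.02


def test_map_accuracy_on_simulated_population(pop8):
    """MAP founder equals the true mosaic founder at >= 95% of cells."""
    from ham import filter_snps, impute_missing

    gtf, _ = filter_snps(pop8.genotypes)
    panel = panel_subset(pop8.founders, gtf.snp_ids)
    probs = infer_founder_probabilities(gtf, panel, HMMParams(error_rate=0.01))
    _, overall = reconstruction_accuracy(probs, pop8.mosaic)
    assert overall >= 0.95
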