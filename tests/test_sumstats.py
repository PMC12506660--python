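"""Summary-statistic estimators against hand evaluations and dual-path oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ghostpop.coalescent import LocusAlignment, overlay_mutations, simulate_genealogy
from ghostpop.demography import island_model, single_population_model
from ghostpop.sumstats import (
    THREE_POP,
    TWO_POP,
    SamplingStrategy,
    four_gamete_filter,
    hudson_fst,
    nucleotide_diversity,
    segregating_sites,
    summarize_dataset,
    tajimas_d,
    watterson_theta,
    wc_fst,
)
from ghostpop.theory import is_defined

from conftest import random_alignment


def aln_from(rows, pops, length=100):
    alleles = np.array(rows, dtype=np.int8)
    positions = np.arange(alleles.shape[1])
    return LocusAlignment(alleles, positions, tuple(pops), length)


# ---------------------------------------------------------------------------
# S and Watterson's theta
# ---------------------------------------------------------------------------


def test_segregating_sites_counts():
    a = aln_from([[0, 0, 0], [0, 0, 0]], ["pop0", "pop0"])
    assert segregating_sites(a) == 0
    b = aln_from([[0, 1, 0, 1], [1, 1, 1, 1]], ["pop0", "pop0"])
    assert segregating_sites(b) == 2


def test_restriction_excludes_ghost_only_polymorphism():
    # site 0 varies only within the ghost; site 1 varies in the sampled pair
    a = aln_from(
        [[0, 0], [0, 1], [0, 0], [1, 0]],
        ["pop0", "pop0", "ghost", "ghost"],
    )
    assert segregating_sites(a, THREE_POP) == 2
    assert segregating_sites(a, TWO_POP) == 1
    # brute-force recount after physically removing the ghost rows
    stripped = aln_from([[0, 0], [0, 1]], ["pop0", "pop0"])
    assert segregating_sites(a, TWO_POP) == segregating_sites(stripped)


def test_watterson_theta_values():
    assert watterson_theta(0, 10) == 0.0
    a1 = sum(1.0 / i for i in range(1, 10))
    assert watterson_theta(5, 10) == pytest.approx(5 / a1)
    assert watterson_theta(5, 10) == pytest.approx(1.76742, abs=1e-4)
    with pytest.raises(ValueError):
        watterson_theta(3, 1)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def test_pi_monomorphic_zero_everywhere():
    a = aln_from([[0, 0], [0, 0], [0, 0], [0, 0]], ["pop0", "pop0", "pop1", "pop1"])
    for mode in ("pooled", "within_pop", "between_pair"):
        assert nucleotide_diversity(a, mode=mode) == 0.0


def test_pi_two_haplotypes_four_differences():
    a = aln_from([[0, 0, 0, 0], [1, 1, 1, 1]], ["pop0", "pop0"])
    assert nucleotide_diversity(a, estimator="pairwise") == pytest.approx(4.0)
    assert nucleotide_diversity(a, estimator="frequency") == pytest.approx(2.0)


@settings(derandomize=True, max_examples=1000)
@given(st.integers(0, 2**63 - 1))
def test_pairwise_equals_frequency_times_correction(seed):
    """pi_pairwise = pi_frequency * n/(n-1), exactly, for any alignment."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 30))
    a = random_alignment(rng, n_hap=2 * (n // 2) + 2, n_sites=int(rng.integers(1, 20)))
    f = nucleotide_diversity(a, estimator="frequency")
    p = nucleotide_diversity(a, estimator="pairwise")
    assert p == pytest.approx(f * a.n_haplotypes / (a.n_haplotypes - 1), abs=1e-9)


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**63 - 1))
def test_invariance_to_reordering_and_relabeling(seed):
    """S, theta, pi unchanged by row shuffles and ancestral/derived flips."""
    rng = np.random.default_rng(seed)
    a = random_alignment(rng, n_hap=10, n_sites=6)
    perm = rng.permutation(a.n_haplotypes)
    shuffled = LocusAlignment(
        a.alleles[perm],
        a.positions,
        tuple(a.pop_of_sample[i] for i in perm),
        a.locus_length,
    )
    flipped = LocusAlignment(1 - a.alleles, a.positions, a.pop_of_sample, a.locus_length)
    for other in (shuffled, flipped):
        assert segregating_sites(a) == segregating_sites(other)
        assert nucleotide_diversity(a) == pytest.approx(nucleotide_diversity(other))


def test_pooled_pi_exceeds_within_under_structure():
    """The Wahlund pattern: pooling structured demes inflates diversity."""
    m = island_model(5000.0, 1e-6, n_demes=2, mu=5e-8, samples_per_pop=8)
    pooled, within = [], []
    for s in range(500):
        g = simulate_genealogy(m, seed=s)
        aln = overlay_mutations(g, 5e-8, 1000, "infinite_sites", s)
        if aln.n_sites == 0:
            continue
        pooled.append(nucleotide_diversity(aln, mode="pooled"))
        within.append(nucleotide_diversity(aln, mode="within_pop"))
    assert np.mean(pooled) > np.mean(within)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def textbook_tajimas_d(alleles: np.ndarray) -> float:
    """Independent straight-from-the-textbook evaluation (oracle)."""
    n, S_sites = alleles.shape
    counts = alleles.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    # pi as literal average over all haplotype pairs
    diffs = [
        np.sum(alleles[i] != alleles[j]) for i, j in itertools.combinations(range(n), 2)
    ]
    pi = np.mean(diffs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_undefined_without_segregating_sites():
    a = aln_from([[0, 0], [0, 0], [0, 0], [0, 0]], ["pop0"] * 4)
    assert not is_defined(tajimas_d(a))


def test_tajimas_d_matches_textbook_on_toy_and_random():
    toy = aln_from(
        [[0, 0, 1, 0, 1], [0, 1, 0, 0, 1], [1, 0, 0, 0, 0], [0, 0, 0, 1, 1]],
        ["pop0"] * 4,
    )
    assert tajimas_d(toy) == pytest.approx(textbook_tajimas_d(toy.alleles))
    rng = np.random.default_rng(31)
    for _ in range(50):
        a = random_alignment(rng, n_hap=8, n_sites=10)
        expected = textbook_tajimas_d(a.alleles)
        got = tajimas_d(a)
        if is_defined(got):
            assert got == pytest.approx(expected, abs=1e-10)


def test_tajimas_d_sign_convention():
    # all singletons: excess of rare variants, D < 0
    sing = np.zeros((10, 6), dtype=np.int8)
    for j in range(6):
        sing[j % 10, j] = 1
    assert tajimas_d(aln_from(sing, ["pop0"] * 10)) < 0
    # intermediate-frequency variants only: D > 0
    inter = np.zeros((10, 6), dtype=np.int8)
    inter[:5, :] = 1
    assert tajimas_d(aln_from(inter, ["pop0"] * 10)) > 0


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------


def wc_haploid_hand(counts, sizes):
    """Independent spreadsheet-style W&C evaluation for one site."""
    counts = np.asarray(counts, float)
    sizes = np.asarray(sizes, float)
    r = len(sizes)
    p = counts / sizes
    ntot = sizes.sum()
    nc = (ntot - np.sum(sizes**2) / ntot) / (r - 1)
    pbar = counts.sum() / ntot
    msa = np.sum(sizes * (p - pbar) ** 2) / (r - 1)
    msw = np.sum(sizes * p * (1 - p)) / (ntot - r)
    a = (msa - msw) / nc
    return a / (a + msw)


def test_wc_fst_printed_fixture():
    """4/20 vs 16/20 derived counts at one site equals the hand evaluation."""
    col = [1] * 4 + [0] * 16 + [1] * 16 + [0] * 4  # popA 4/20, popB 16/20
    alleles = np.array(col, np.int8).reshape(40, 1)
    a = LocusAlignment(alleles, np.array([0]), tuple(["pop0"] * 20 + ["pop1"] * 20), 100)
    assert wc_fst(a) == pytest.approx(wc_haploid_hand([4, 16], [20, 20]))
    assert wc_fst(a) == pytest.approx(0.504644, abs=1e-5)


def test_wc_fst_fixed_difference_near_one():
    a = aln_from(
        [[0] * 5] * 20 + [[1] * 5] * 20, ["pop0"] * 20 + ["pop1"] * 20
    )
    assert wc_fst(a) > 0.95


def test_wc_fst_no_differentiation_near_zero():
    """Identical haplotype sets: estimate is the small negative -1/(nc-1).

    With exactly equal sample frequencies the among-population mean square
    vanishes and the variance-components ratio lands at -1/(nc-1), here
    -1/19: no differentiation, up to the estimator's small-sample term.
    """
    rng = np.random.default_rng(17)
    vals = []
    for _ in range(100):
        block = rng.integers(0, 2, size=(20, 5)).astype(np.int8)
        doubled = np.vstack([block, block])  # identical haplotype sets
        a = LocusAlignment(
            doubled, np.arange(5), tuple(["pop0"] * 20 + ["pop1"] * 20), 50
        )
        v = wc_fst(a)
        if is_defined(v):
            vals.append(v)
            assert v == pytest.approx(-1.0 / 19.0)
    assert np.mean(np.abs(vals)) < 0.06


def test_wc_fst_monomorphic_undefined():
    a = aln_from([[0], [0], [0], [0]], ["pop0", "pop0", "pop1", "pop1"])
    assert not is_defined(wc_fst(a))


def test_wc_close_to_hudson_on_balanced_fixtures():
    m = island_model(5000.0, 2e-5, n_demes=2, mu=5e-8, samples_per_pop=20)
    for s in range(20):
        g = simulate_genealogy(m, seed=s)
        aln = overlay_mutations(g, 5e-8, 1000, "infinite_sites", s)
        if aln.n_sites < 3:
            continue
        w, h = wc_fst(aln), hudson_fst(aln)
        assert abs(w - h) < 0.05


def test_strategy_restriction_consistency():
    """2-pop statistics equal those on data with ghost rows removed."""
    rng = np.random.default_rng(5)
    a = random_alignment(rng, n_hap=18, n_sites=12, pops=("pop0", "pop1", "ghost"))
    stripped = a.restrict(("pop0", "pop1"))
    assert segregating_sites(a, TWO_POP) == segregating_sites(stripped)
    assert nucleotide_diversity(a, TWO_POP) == pytest.approx(
        nucleotide_diversity(stripped)
    )
    d1, d2 = tajimas_d(a, TWO_POP), tajimas_d(stripped)
    assert (not is_defined(d1) and not is_defined(d2)) or d1 == pytest.approx(d2)
    assert wc_fst(a, TWO_POP) == pytest.approx(wc_fst(stripped))


# ---------------------------------------------------------------------------
# four-gamete filter
# ---------------------------------------------------------------------------


def brute_force_violations(alleles):
    out = set()
    for i, j in itertools.combinations(range(alleles.shape[1]), 2):
        gam = {tuple(row) for row in alleles[:, [i, j]]}
        if len(gam) == 4:
            out.add((i, j))
    return out


def test_four_gamete_infinite_sites_unchanged():
    m = single_population_model(Ne=20000, mu=1e-7, samples_per_pop=8)
    g = simulate_genealogy(m, seed=2)
    aln = overlay_mutations(g, 1e-7, 1000, "infinite_sites", 2)
    filtered, report = four_gamete_filter(aln)
    assert report.violating_pairs == []
    assert filtered.n_sites == aln.n_sites


def test_four_gamete_hand_built_violation():
    a = aln_from([[0, 0], [0, 1], [1, 0], [1, 1]], ["pop0"] * 4)
    filtered, report = four_gamete_filter(a)
    assert report.violating_pairs == [(0, 1)]
    assert filtered.n_sites == 1
    assert report.block == (0, 1)  # leftmost single-site block wins the tie


def test_four_gamete_random_recombinants_block_is_clean():
    rng = np.random.default_rng(77)
    for _ in range(30):
        a = random_alignment(rng, n_hap=10, n_sites=15)
        filtered, report = four_gamete_filter(a)
        assert set(report.violating_pairs) == brute_force_violations(a.alleles)
        assert brute_force_violations(filtered.alleles) == set()
        # maximality: no longer clean window exists (quadratic oracle)
        viol = brute_force_violations(a.alleles)
        best = report.block[1] - report.block[0]
        for start in range(a.n_sites):
            for stop in range(start + best + 1, a.n_sites + 1):
                inside = any(start <= i and j < stop for i, j in viol)
                assert inside, "filter missed a longer clean block"


# ---------------------------------------------------------------------------
# dataset summaries
# ---------------------------------------------------------------------------


def test_summarize_monomorphic_dataset():
    a = aln_from([[0]] * 40 + [[0]] * 20, ["pop0"] * 20 + ["pop1"] * 20 + ["ghost"] * 20)
    rec = summarize_dataset([a, a, a], TWO_POP)
    assert rec.S == 0 and rec.theta_w == 0 and rec.pi == 0
    assert not is_defined(rec.tajimas_d)
    assert rec.n_undefined_d == 3


def test_summarize_single_locus_identity():
    rng = np.random.default_rng(8)
    a = random_alignment(rng, n_hap=12, n_sites=9, pops=("pop0", "pop1", "ghost"))
    rec = summarize_dataset([a], THREE_POP)
    assert rec.S == segregating_sites(a, THREE_POP)
    assert rec.pi == pytest.approx(nucleotide_diversity(a, THREE_POP))
    assert rec.fst == pytest.approx(wc_fst(a, THREE_POP))


def test_empty_strategy_restriction_raises():
    a = aln_from([[0, 1], [1, 0]], ["pop0", "pop0"])
    with pytest.raises(ValueError):
        SamplingStrategy(("ghost",)).apply(a)
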