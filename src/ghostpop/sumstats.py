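"""From-scratch estimators of the standard diversity and differentiation statistics.

Everything operates on phased biallelic haplotype alignments
(:class:`~ghostpop.coalescent.LocusAlignment`) restricted by a
:class:`SamplingStrategy` — either the two sampled populations or all
three including the ghost.  Implemented here rather than wrapped from a
library because contrasting the 2- versus 3-population estimates of the
*same* statistic is the whole point, and the estimators must therefore be
under full control:

* ``segregating_sites`` — S after restriction to the strategy's samples;
* ``watterson_theta`` — S / a1 with a1 the harmonic number of n-1;
* ``nucleotide_diversity`` — pi, in frequency form (sum of 2p(1-p)) and
  bias-corrected pairwise form (factor n/(n-1)), within, pooled or
  between population pairs;
* ``tajimas_d`` — (pi - theta_W) / sqrt(e1 S + e2 S (S-1)), the standard
  normalisation constants;
* ``wc_fst`` — the Weir & Cockerham (1984) variance-components estimator
  in its haploid form, multi-locus as a ratio of summed components;
* ``four_gamete_filter`` — trims a locus to its longest block of sites
  with no four-gamete violation (recombination/recurrent-mutation proxy).

Undefined values (Tajima's D at S=0, FST with no polymorphism) are the
NaN sentinel from :mod:`ghostpop.theory`, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coalescent import LocusAlignment
from .theory import UNDEFINED, is_defined

__all__ = [
    "SamplingStrategy",
    "TWO_POP",
    "THREE_POP",
    "TajimaNormalization",
    "SummaryStatRecord",
    "segregating_sites",
    "watterson_theta",
    "nucleotide_diversity",
    "tajimas_d",
    "wc_fst",
    "hudson_fst",
    "four_gamete_filter",
    "FourGameteReport",
    "summarize_dataset",
]


@dataclass(frozen=True)
class SamplingStrategy:
    """Which populations enter a statistic: a subset of the model's demes."""

    included_pops: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.included_pops:
            raise ValueError("a sampling strategy must include >= 1 population")

    @property
    def name(self) -> str:
        return f"{len(self.included_pops)}-pop"

    def apply(self, aln: LocusAlignment) -> LocusAlignment:
        return aln.restrict(self.included_pops)


TWO_POP = SamplingStrategy(("pop0", "pop1"))
THREE_POP = SamplingStrategy(("pop0", "pop1", "ghost"))


@dataclass(frozen=True)
class TajimaNormalization:
    """Tajima (1989) normalisation constants for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_sample_size(cls, n: int) -> "TajimaNormalization":
        if n < 2:
            raise ValueError("sample size must be >= 2")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def _restricted(aln: LocusAlignment, strategy: SamplingStrategy | None) -> LocusAlignment:
    return aln if strategy is None else strategy.apply(aln)


def segregating_sites(aln: LocusAlignment, strategy: SamplingStrategy | None = None) -> int:
    """Number of sites polymorphic within the strategy-restricted sample.

    Sites that are monomorphic after restriction (e.g. variable only in
    the excluded ghost) are not counted.
    """
    sub = _restricted(aln, strategy)
    if sub.n_haplotypes == 0:
        raise ValueError("empty sample after restriction")
    counts = sub.alleles.sum(axis=0)
    return int(np.count_nonzero((counts > 0) & (counts < sub.n_haplotypes)))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S / a1 for a sample of n haplotypes."""
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / TajimaNormalization.for_sample_size(n).a1


def nucleotide_diversity(
    aln: LocusAlignment,
    strategy: SamplingStrategy | None = None,
    mode: str = "pooled",
    estimator: str = "pairwise",
    per_site: bool = False,
) -> float:
    """Nucleotide diversity pi of one locus.

    ``mode``:
      * ``pooled`` — all haplotypes of the restricted sample together;
      * ``within_pop`` — pi within each included population, averaged;
      * ``between_pair`` — requires exactly two included populations;
        mean differences between one haplotype from each (pi_ij).

    ``estimator``: ``frequency`` is sum over sites of 2p(1-p);
    ``pairwise`` is the mean pairwise difference count, equal to the
    frequency value times n/(n-1).  Values are per locus (summed over
    sites) unless ``per_site``.
    """
    sub = _restricted(aln, strategy)

    def freq_pi(block: np.ndarray) -> float:
        n = block.shape[0]
        if n < 2:
            raise ValueError("need >= 2 haplotypes for diversity")
        p = block.mean(axis=0)
        val = float(np.sum(2.0 * p * (1.0 - p)))
        if estimator == "pairwise":
            val *= n / (n - 1)
        elif estimator != "frequency":
            raise ValueError(f"unknown estimator {estimator!r}")
        return val

    if mode == "pooled":
        val = freq_pi(sub.alleles)
    elif mode == "within_pop":
        pops = sorted(set(sub.pop_of_sample))
        vals = []
        for pop in pops:
            mask = np.array([s == pop for s in sub.pop_of_sample])
            vals.append(freq_pi(sub.alleles[mask]))
        val = float(np.mean(vals))
    elif mode == "between_pair":
        pops = sorted(set(sub.pop_of_sample))
        if len(pops) != 2:
            raise ValueError("between_pair mode needs exactly two populations")
        m0 = np.array([s == pops[0] for s in sub.pop_of_sample])
        p0 = sub.alleles[m0].mean(axis=0)
        p1 = sub.alleles[~m0].mean(axis=0)
        val = float(np.sum(p0 * (1 - p1) + p1 * (1 - p0)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return val / sub.locus_length if per_site else val


def tajimas_d(aln: LocusAlignment, strategy: SamplingStrategy | None = None) -> float:
    """Tajima's D of one locus; NaN sentinel when S = 0.

    Uses the bias-corrected pairwise pi (the form the statistic is defined
    with) and the e1/e2 variance normalisation.
    """
    sub = _restricted(aln, strategy)
    n = sub.n_haplotypes
    if n < 2:
        raise ValueError("need >= 2 haplotypes for Tajima's D")
    S = segregating_sites(sub)
    if S == 0:
        return UNDEFINED
    const = TajimaNormalization.for_sample_size(n)
    pi = nucleotide_diversity(sub, mode="pooled", estimator="pairwise")
    theta = S / const.a1
    var = const.e1 * S + const.e2 * S * (S - 1)
    return float((pi - theta) / np.sqrt(var))


def _wc_components(aln: LocusAlignment) -> tuple[float, float]:
    """Summed Weir-Cockerham haploid variance components (a, a+b) of a locus."""
    pops = sorted(set(aln.pop_of_sample))
    r = len(pops)
    if r < 2:
        raise ValueError("FST needs >= 2 populations")
    masks = [np.array([s == pop for s in aln.pop_of_sample]) for pop in pops]
    n_i = np.array([m.sum() for m in masks], dtype=float)
    if np.any(n_i < 2):
        raise ValueError("FST needs >= 2 haplotypes per population")
    n_tot = n_i.sum()
    n_c = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)
    p_i = np.stack([aln.alleles[m].mean(axis=0) for m in masks])  # (r, sites)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / n_tot
    msa = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / (r - 1)
    msw = (n_i[:, None] * p_i * (1.0 - p_i)).sum(axis=0) / (n_tot - r)
    a = (msa - msw) / n_c
    b = msw
    return float(a.sum()), float((a + b).sum())


def wc_fst(
    alignments: Iterable[LocusAlignment] | LocusAlignment,
    strategy: SamplingStrategy | None = None,
    multilocus: str = "ratio-of-sums",
) -> float:
    """Weir & Cockerham's FST on haploid (phased) data.

    Variance components a (among populations) and b (within) are computed
    per site and combined across sites and loci.  ``ratio-of-sums`` (the
    default, and the stable choice) divides summed numerators by summed
    denominators; ``mean-of-ratios`` averages per-locus ratios.  Returns
    the NaN sentinel when no polymorphic site exists; small negative
    estimates are legitimate and are not clamped.
    """
    if isinstance(alignments, LocusAlignment):
        alignments = [alignments]
    nums, dens = [], []
    for aln in alignments:
        a, ab = _wc_components(_restricted(aln, strategy))
        nums.append(a)
        dens.append(ab)
    if multilocus == "ratio-of-sums":
        den = sum(dens)
        return UNDEFINED if den == 0 else float(sum(nums) / den)
    if multilocus == "mean-of-ratios":
        ratios = [n / d for n, d in zip(nums, dens) if d != 0]
        return UNDEFINED if not ratios else float(np.mean(ratios))
    raise ValueError(f"unknown multilocus rule {multilocus!r}")


def hudson_fst(aln: LocusAlignment, strategy: SamplingStrategy | None = None) -> float:
    """Hudson-style FST, 1 - Hw/Hb, used as a cross-check on ``wc_fst``.

    Hw is the mean within-population pairwise diversity, Hb the mean
    between-population pairwise diversity, both summed over sites.
    Two-population samples only.
    """
    sub = _restricted(aln, strategy)
    pops = sorted(set(sub.pop_of_sample))
    if len(pops) != 2:
        raise ValueError("hudson_fst is defined for exactly two populations")
    hw = nucleotide_diversity(sub, mode="within_pop", estimator="pairwise")
    hb = nucleotide_diversity(sub, mode="between_pair")
    if hb == 0:
        return UNDEFINED
    return 1.0 - hw / hb


@dataclass
class FourGameteReport:
    """Outcome of the four-gamete filter on one locus."""

    violating_pairs: list[tuple[int, int]]  # site indices (i < j)
    block: tuple[int, int]  # kept site-index range [start, stop)
    n_sites_before: int
    n_sites_after: int


def four_gamete_filter(aln: LocusAlignment) -> tuple[LocusAlignment, FourGameteReport]:
    """Trim a locus to its longest four-gamete-compatible block of sites.

    A pair of biallelic sites displaying all four gametes (00, 01, 10, 11)
    implies recombination or recurrent mutation; the returned alignment is
    the longest contiguous run of sites containing no such pair, with ties
    broken toward the leftmost block.
    """
    S = aln.n_sites
    if S == 0:
        return aln, FourGameteReport([], (0, 0), 0, 0)
    g = aln.alleles.astype(bool)
    violating: list[tuple[int, int]] = []
    # leftmost admissible block start for windows ending at each site
    min_start = np.zeros(S, dtype=int)
    for j in range(1, S):
        col_j = g[:, j]
        for i in range(j):
            col_i = g[:, i]
            has = (
                np.any(~col_i & ~col_j)
                and np.any(~col_i & col_j)
                and np.any(col_i & ~col_j)
                and np.any(col_i & col_j)
            )
            if has:
                violating.append((i, j))
                if i + 1 > min_start[j]:
                    min_start[j] = i + 1
    best = (0, 1)
    left = 0
    for j in range(S):
        left = max(left, min_start[j])
        if j + 1 - left > best[1] - best[0]:
            best = (left, j + 1)
    filtered = LocusAlignment(
        aln.alleles[:, best[0] : best[1]],
        aln.positions[best[0] : best[1]],
        aln.pop_of_sample,
        aln.locus_length,
    )
    return filtered, FourGameteReport(violating, best, S, filtered.n_sites)


@dataclass
class SummaryStatRecord:
    """Per-replicate, per-strategy summary statistics of a dataset.

    ``S`` is summed over loci; ``theta_w``, ``pi`` and ``tajimas_d`` are
    per-locus values averaged over loci (pi summed over sites within a
    locus; divide by locus length for a per-site value); ``fst`` is the
    multi-locus Weir-Cockerham estimate.  ``n_undefined_d`` counts loci
    where D was undefined (S = 0) and excluded from the average.
    """

    model_id: str = ""
    divergence: str = ""
    replicate: int = 0
    strategy: str = ""
    S: int = 0
    theta_w: float = 0.0
    pi: float = 0.0
    tajimas_d: float = UNDEFINED
    fst: float = UNDEFINED
    n_loci: int = 0
    n_undefined_d: int = 0


def summarize_dataset(
    dataset: Sequence[LocusAlignment],
    strategy: SamplingStrategy,
    **meta,
) -> SummaryStatRecord:
    """Summary statistics of one replicate dataset under one strategy."""
    S_per_locus = [segregating_sites(a, strategy) for a in dataset]
    n_hap = strategy.apply(dataset[0]).n_haplotypes
    theta = [watterson_theta(s, n_hap) for s in S_per_locus]
    pi = [
        nucleotide_diversity(a, strategy, mode="pooled", estimator="pairwise")
        for a in dataset
    ]
    d_vals = [tajimas_d(a, strategy) for a in dataset]
    d_def = [d for d in d_vals if is_defined(d)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fst = wc_fst(dataset, strategy)
    return SummaryStatRecord(
        strategy=strategy.name,
        S=int(np.sum(S_per_locus)),
        theta_w=float(np.mean(theta)),
        pi=float(np.mean(pi)),
        tajimas_d=float(np.mean(d_def)) if d_def else UNDEFINED,
        fst=fst,
        n_loci=len(dataset),
        n_undefined_d=len(d_vals) - len(d_def),
        **meta,
    )
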