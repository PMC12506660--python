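"""Closed-form bias theory for summary statistics when a ghost population is ignored.

An unsampled ("ghost") population that exchanges genes with the sampled
populations distorts summary statistics computed from the sampled data
alone.  This module quantifies those distortions under the classical
island model.  Bias is always defined as

    bias = statistic(2 sampled populations) - statistic(all 3 populations)

so a negative bias means the two-population estimate *under*-states the
three-population truth.

Three layers are provided:

* exact algebra on allele frequencies (``fst_theoretical``,
  ``fst_bias_no_migration``) and on per-population diversities
  (``pi_bias_no_migration``, ``pi_bias_with_migration``);
* drift-migration equilibrium results, FST = 1/(1+4*Ne*m), where ignoring
  the ghost changes the observable migration rate from m to (2/3)m
  (``equilibrium_fst``, ``equilibrium_fst_bias``);
* stochastic scans over the parameter space backed by a discrete
  Wright-Fisher forward simulator (``wf_island_forward_sim``) or the
  structured coalescent (``theory_bias_simulation``).

All frequencies refer to one allele of a biallelic locus.  Populations
are labelled A and B (sampled) and C (the ghost).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNDEFINED",
    "is_defined",
    "AlleleFreqTriple",
    "IslandMigrationParams",
    "DiversityTriple",
    "PairwiseDiversityMatrix",
    "BiasScanResult",
    "expected_heterozygosity",
    "fst_theoretical",
    "fst_bias_no_migration",
    "fst_bias_scan",
    "equilibrium_fst",
    "equilibrium_fst_bias",
    "wf_island_forward_sim",
    "pi_bias_no_migration",
    "pi_bias_with_migration",
    "theory_bias_simulation",
]

#: Sentinel for statistics that are undefined (e.g. FST when the total
#: heterozygosity is zero).  NaN propagates through arithmetic, which is
#: exactly the behaviour wanted: anything derived from an undefined value
#: is itself undefined.
UNDEFINED: float = float("nan")


def is_defined(x: float) -> bool:
    """True if ``x`` is a defined statistic value (not the NaN sentinel)."""
    return not math.isnan(x)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_freq(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class AlleleFreqTriple:
    """Allele frequencies of one biallelic locus in populations A, B and C.

    A and B are the sampled populations; C is the unsampled ghost.
    """

    pA: float
    pB: float
    pC: float

    def __post_init__(self) -> None:
        _check_freq("pA", self.pA)
        _check_freq("pB", self.pB)
        _check_freq("pC", self.pC)

    @property
    def mean2(self) -> float:
        """Mean frequency over the two sampled populations."""
        return 0.5 * (self.pA + self.pB)

    @property
    def mean3(self) -> float:
        """Mean frequency over all three populations (ghost included)."""
        return (self.pA + self.pB + self.pC) / 3.0


@dataclass(frozen=True)
class IslandMigrationParams:
    """Island-model parameters: per-deme size ``Ne`` and migration rate ``m``."""

    Ne: float
    m: float

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ValueError(f"Ne must be positive, got {self.Ne!r}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must lie in [0, 1], got {self.m!r}")


@dataclass(frozen=True)
class DiversityTriple:
    """Within-population nucleotide diversities of A, B and the ghost C."""

    piA: float
    piB: float
    piC: float

    def __post_init__(self) -> None:
        for name in ("piA", "piB", "piC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class PairwiseDiversityMatrix:
    """Symmetric 3x3 matrix of mean pairwise diversities among A, B, C.

    Entry (i, j) is the mean number of differences between one sequence
    drawn from population i and one from population j; the diagonal holds
    within-population diversities.  Under strong local drift a diagonal
    entry can exceed an off-diagonal one, so no ordering is enforced.
    """

    LABELS = ("A", "B", "C")

    def __init__(self, values: np.ndarray | Sequence[Sequence[float]]):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("pairwise diversities must be >= 0")
        if not np.allclose(arr, arr.T, rtol=1e-9, atol=1e-12):
            raise ValueError("pairwise diversity matrix must be symmetric")
        self.values = arr

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = key
        return float(self.values[self.LABELS.index(i), self.LABELS.index(j)])


@dataclass
class BiasScanResult:
    """Tidy container for a bias scan over a parameter grid.

    ``axes`` maps axis names to their grid values; ``surfaces`` maps
    reduction labels (e.g. ``"max_abs"``) to arrays whose shape matches the
    axis lengths in order.
    """

    axes: dict[str, np.ndarray]
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = tuple(len(v) for v in self.axes.values())
        for name, surf in self.surfaces.items():
            if surf.shape[: len(shape)] != shape:
                raise ValueError(
                    f"surface {name!r} has shape {surf.shape}, "
                    f"expected leading dims {shape}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Return one tidy row per grid point with one column per surface."""
        mesh = np.meshgrid(*self.axes.values(), indexing="ij")
        data = {name: grid.ravel() for name, grid in zip(self.axes, mesh)}
        for name, surf in self.surfaces.items():
            if surf.ndim == len(self.axes):
                data[name] = surf.ravel()
            else:  # replicate axis: emit mean and spread
                data[f"{name}_mean"] = surf.mean(axis=-1).ravel()
                data[f"{name}_sd"] = surf.std(axis=-1, ddof=1).ravel()
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# exact theory, no migration
# ---------------------------------------------------------------------------


def expected_heterozygosity(p: float) -> float:
    """Hardy-Weinberg expected heterozygosity ``H(p) = 2 p (1 - p)``."""
    _check_freq("p", p)
    return 2.0 * p * (1.0 - p)


def _fst_from_freqs(ps: np.ndarray) -> float:
    """FST = (HT - HS) / HT for one deme-frequency vector."""
    hs = float(np.mean(2.0 * ps * (1.0 - ps)))
    pbar = float(np.mean(ps))
    ht = 2.0 * pbar * (1.0 - pbar)
    if ht == 0.0:
        return UNDEFINED
    return (ht - hs) / ht


def fst_theoretical(freqs: AlleleFreqTriple, include_ghost: bool = False) -> float:
    """Heterozygosity-based FST from allele frequencies.

    With ``include_ghost=False`` only the sampled populations A and B enter
    (the two-population estimate FST(2)); with ``include_ghost=True`` the
    ghost C is included (FST(3)).  Returns the ``UNDEFINED`` sentinel when
    the total expected heterozygosity is zero, i.e. every included
    population is fixed for the same allele.
    """
    if include_ghost:
        ps = np.array([freqs.pA, freqs.pB, freqs.pC])
    else:
        ps = np.array([freqs.pA, freqs.pB])
    return _fst_from_freqs(ps)


def fst_bias_no_migration(freqs: AlleleFreqTriple) -> float:
    """Bias FST(2) - FST(3) from omitting the ghost, island model, no migration.

    Undefined (NaN) if either FST is undefined.  The bias vanishes when
    pA = pB = pC and is largest when the sampled frequencies differ and the
    ghost frequency lies between them.
    """
    f2 = fst_theoretical(freqs, include_ghost=False)
    f3 = fst_theoretical(freqs, include_ghost=True)
    return f2 - f3  # NaN propagates


def fst_bias_scan(grid_step: float = 0.01) -> BiasScanResult:
    """Scan FST bias over the full (pA, pB, pC) frequency grid.

    For every sampled-frequency pair (pA, pB) the bias is evaluated across
    all ghost frequencies pC on the same grid and reduced three ways:
    ``max_abs`` (maximum absolute bias), ``mean_abs`` and ``mean_signed``.
    Grid points where FST is undefined for every pC (e.g. pA = pB = 0) are
    NaN in the reductions.
    """
    if not 0.0 < grid_step <= 0.5:
        raise ValueError("grid_step must lie in (0, 0.5]")
    g = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    g = np.clip(g, 0.0, 1.0)
    pA, pB, pC = np.meshgrid(g, g, g, indexing="ij")

    def fst(ps: list[np.ndarray]) -> np.ndarray:
        stack = np.stack(ps)
        hs = np.mean(2.0 * stack * (1.0 - stack), axis=0)
        pbar = np.mean(stack, axis=0)
        ht = 2.0 * pbar * (1.0 - pbar)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
        return out

    bias = fst([pA, pB]) - fst([pA, pB, pC])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        surfaces = {
            "max_abs": np.nanmax(np.abs(bias), axis=2),
            "mean_abs": np.nanmean(np.abs(bias), axis=2),
            "mean_signed": np.nanmean(bias, axis=2),
        }
    return BiasScanResult(axes={"pA": g, "pB": g}, surfaces=surfaces)


# ---------------------------------------------------------------------------
# drift-migration equilibrium
# ---------------------------------------------------------------------------


def equilibrium_fst(params: IslandMigrationParams, n_pops: int = 2) -> float:
    """Equilibrium FST of the island model, 2- or 3-population observation.

    The classical result is FST = 1/(1 + 4 Ne m).  Observing only the two
    sampled demes of a three-deme island leaves the per-generation rate at
    m; observing all three demes averages in- and out-flow over two of
    three possible sources, so the observable rate becomes (2/3) m and

        FST(3) = 1 / (1 + (8/3) Ne m).
    """
    if n_pops == 2:
        return 1.0 / (1.0 + 4.0 * params.Ne * params.m)
    if n_pops == 3:
        return 1.0 / (1.0 + (8.0 / 3.0) * params.Ne * params.m)
    raise ValueError(f"n_pops must be 2 or 3, got {n_pops!r}")


def equilibrium_fst_bias(params: IslandMigrationParams) -> float:
    """Equilibrium bias FST(2) - FST(3) from ignoring ghost migration.

    Non-positive for every m > 0 (the two-population value is always the
    smaller of the two) and tends to 0 at both boundaries m -> 0 and
    m -> infinity.
    """
    return equilibrium_fst(params, 2) - equilibrium_fst(params, 3)


# ---------------------------------------------------------------------------
# Wright-Fisher forward engine for the stochastic scans
# ---------------------------------------------------------------------------


@dataclass
class WrightFisherResult:
    """Trajectories from :func:`wf_island_forward_sim`.

    ``freqs`` has shape (n_generations+1, n_demes, n_sites); ``pi`` is the
    per-generation mean heterozygosity 2p(1-p) per deme, averaged over
    sites, shape (n_generations+1, n_demes).
    """

    freqs: np.ndarray
    pi: np.ndarray


def wf_island_forward_sim(
    pop_sizes: Sequence[float | None],
    migration_spec: np.ndarray | Sequence[Sequence[float]],
    initial_freqs: np.ndarray | Sequence[float],
    n_generations: int,
    mutation_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> WrightFisherResult:
    """Discrete-generation Wright-Fisher simulation of island demes.

    Each generation applies, in order: deterministic migration mixing of
    allele frequencies, symmetric mutation at ``mutation_rate``, and
    binomial drift sampling of 2*Ne gametes per deme.  ``migration_spec``
    is a forward composition matrix: entry (i, j) is the fraction of deme
    i's gene pool replaced by migrants from deme j each generation; rows
    must sum to at most 1.  A ``None`` (or infinite) population size turns
    drift off for that deme, leaving the deterministic dynamics.

    ``initial_freqs`` may be one frequency per deme or a (demes, sites)
    array of independent sites.  Reproducible for a fixed integer seed.
    """
    mig = np.asarray(migration_spec, dtype=float)
    d = mig.shape[0]
    if mig.shape != (d, d):
        raise ValueError("migration_spec must be square")
    if np.any(mig < 0):
        raise ValueError("migration rates must be >= 0")
    rowsum = mig.sum(axis=1) - np.diag(mig)
    if np.any(rowsum > 1.0 + 1e-12):
        raise ValueError("off-diagonal migration row sums must be <= 1")

    p = np.atleast_2d(np.asarray(initial_freqs, dtype=float))
    if p.shape[0] == 1 and d > 1:
        p = np.repeat(p, d, axis=0)
    if p.shape[0] != d:
        raise ValueError("initial_freqs first dimension must match deme count")

    sizes = np.array(
        [np.inf if n is None else float(n) for n in pop_sizes], dtype=float
    )
    if sizes.shape[0] != d:
        raise ValueError("pop_sizes length must match deme count")
    if np.any(sizes <= 0):
        raise ValueError("population sizes must be positive")

    rng = np.random.default_rng(seed)
    # mixing matrix: row i = (1 - sum_j m_ij) on diagonal plus m_ij inflow
    mix = mig.copy()
    np.fill_diagonal(mix, 0.0)
    np.fill_diagonal(mix, 1.0 - mix.sum(axis=1))

    traj = np.empty((n_generations + 1,) + p.shape)
    traj[0] = p
    u = mutation_rate
    finite = np.isfinite(sizes)
    for t in range(1, n_generations + 1):
        p = mix @ p
        if u:
            p = p * (1.0 - u) + (1.0 - p) * u
        if finite.any():
            n2 = (2 * sizes[finite]).astype(np.int64)
            p_f = p[finite]
            p[finite] = rng.binomial(n2[:, None], p_f) / n2[:, None]
        traj[t] = p
    het = 2.0 * traj * (1.0 - traj)
    return WrightFisherResult(freqs=traj, pi=het.mean(axis=2))


# ---------------------------------------------------------------------------
# nucleotide-diversity bias
# ---------------------------------------------------------------------------


def pi_bias_no_migration(div: DiversityTriple) -> float:
    """Bias in nucleotide diversity from omitting the ghost, no migration.

    pi_hat(2) = (piA + piB)/2 and pi_hat(3) = (piA + piB + piC)/3, so the
    bias collapses to ``(piA + piB - 2 piC)/6``: negative exactly when the
    ghost is more diverse than the sampled average.
    """
    return (div.piA + div.piB - 2.0 * div.piC) / 6.0


def pi_bias_with_migration(divmat: PairwiseDiversityMatrix) -> float:
    """Diversity bias with migration, from the full pairwise matrix.

    With migration, pi_hat(3) is the pooled mean pairwise diversity over
    all nine ordered population pairs, (1/9) * sum_ij pi_ij, while
    pi_hat(2) remains (piAA + piBB)/2.  A diverse, divergent ghost makes
    the cross terms large and the bias negative.
    """
    v = divmat.values
    pi2 = 0.5 * (v[0, 0] + v[1, 1])
    pi3 = v.sum() / 9.0  # symmetric: full-matrix sum == sum over ordered pairs
    return pi2 - pi3


# ---------------------------------------------------------------------------
# stochastic bias scans (Fig.-style distributions)
# ---------------------------------------------------------------------------

_PI_SCAN = dict(Ne=5000.0, n_sites=400, n_generations=2000)
_D_SCAN = dict(Ne=5000, t_split=500.0, t_ghost=30000.0, n_loci=20, samples=10)


def _pi_bias_replicate(m: float, rng: np.random.Generator) -> float:
    """One replicate of the pi-bias scan: WF demes A, B + ghost C.

    All demes start from shared standing variation, then drift apart for
    ``n_generations`` while A and B each receive a fraction ``m`` of their
    gene pool from the ghost per generation (asymmetric gene flow from C).
    """
    ne = _PI_SCAN["Ne"]
    s = _PI_SCAN["n_sites"]
    p0 = rng.uniform(0.05, 0.95, size=s)
    mig = np.array([[0.0, 0.0, m], [0.0, 0.0, m], [0.0, 0.0, 0.0]])
    res = wf_island_forward_sim(
        [ne, ne, ne], mig, np.tile(p0, (3, 1)), _PI_SCAN["n_generations"], seed=rng
    )
    p = res.freqs[-1]  # (3, sites)
    # pairwise diversity matrix: pi_ij = mean_s [p_i (1-p_j) + p_j (1-p_i)]
    mat = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            mat[i, j] = np.mean(p[i] * (1 - p[j]) + p[j] * (1 - p[i]))
    return pi_bias_with_migration(PairwiseDiversityMatrix(mat))


def _d_bias_replicate(m: float, seed: int) -> float:
    """One replicate of the Tajima's D bias scan via the structured coalescent.

    Three demes with the ghost as an outgroup; backward migration from the
    sampled demes into the ghost at rate ``m`` represents forward gene flow
    out of the ghost.  Bias is D(2) - D(3) averaged over loci.
    """
    from .coalescent import simulate_dataset
    from .demography import custom_three_population_model
    from .sumstats import SamplingStrategy, tajimas_d

    model = custom_three_population_model(
        Ne=_D_SCAN["Ne"],
        t0=_D_SCAN["t_split"],
        t1=_D_SCAN["t_ghost"],
        migration={("pop0", "ghost"): m, ("pop1", "ghost"): m},
        n_loci=_D_SCAN["n_loci"],
        samples_per_pop=_D_SCAN["samples"],
    )
    (loci,) = simulate_dataset(model, n_replicates=1, seed=seed)
    two = SamplingStrategy(("pop0", "pop1"))
    three = SamplingStrategy(("pop0", "pop1", "ghost"))
    d2 = [tajimas_d(a, two) for a in loci]
    d3 = [tajimas_d(a, three) for a in loci]
    d2 = [x for x in d2 if is_defined(x)]
    d3 = [x for x in d3 if is_defined(x)]
    if not d2 or not d3:
        return UNDEFINED
    return float(np.mean(d2) - np.mean(d3))


def theory_bias_simulation(
    statistic: str,
    m_values: Iterable[float],
    replicates: int = 10,
    seed: int = 0,
) -> BiasScanResult:
    """Simulated bias distributions of pi or Tajima's D across migration rates.

    For each migration rate m the two-population estimate (sampled demes
    only) is contrasted with the three-population estimate (ghost
    included), over independent replicates; the result holds the full
    (m, replicate) bias surface.  ``statistic`` is ``"pi"`` (Wright-Fisher
    forward engine) or ``"tajimas_d"`` (structured coalescent engine).
    Deterministic for a fixed seed.
    """
    m_arr = np.asarray(list(m_values), dtype=float)
    if np.any((m_arr < 0) | (m_arr > 1)):
        raise ValueError("m_values must lie in [0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if statistic not in ("pi", "tajimas_d"):
        raise ValueError(f"unknown statistic {statistic!r}")

    surface = np.empty((m_arr.size, replicates))
    for i, m in enumerate(m_arr):
        for r in range(replicates):
            ss = np.random.SeedSequence([seed, i, r])
            if statistic == "pi":
                rng = np.random.default_rng(ss)
                surface[i, r] = _pi_bias_replicate(float(m), rng)
            else:
                sub = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
                surface[i, r] = _d_bias_replicate(float(m), sub)
    return BiasScanResult(axes={"m": m_arr}, surfaces={"bias": surface})
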