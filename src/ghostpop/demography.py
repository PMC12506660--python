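"""Demographic models: the five isolation-with-migration ghost topologies.

Two populations (``pop0``, ``pop1``) are sampled; a third (``ghost``) is
not.  Backwards in time, ``pop0`` and ``pop1`` merge into ``anc01`` at
``t0`` and ``anc01`` merges with ``ghost`` into ``root`` at ``t1``.
Migration is specified backwards in time: ``rate[i][j]`` is the
probability per generation that a lineage currently in deme ``i`` traces
its ancestry into deme ``j`` — equivalently, forward-time gene flow from
``j`` into ``i``.

The five model topologies differ only in their migration matrices:

========  ==========================================================
model     backward migration (forward gene flow in parentheses)
========  ==========================================================
``a``     pop0<->pop1 at m_low; ghost isolated
``b``     as ``a`` plus pop0,pop1 -> ghost at m_low  (ghost emigrates
          into both sampled populations at the low rate)
``c``     as ``b`` but ghost flow at m_high
``d``     all ordered pairs at m_low (low bidirectional everywhere)
``e``     pop0<->pop1 at m_low; ghost<->sampled at m_high
========  ==========================================================

Two divergence depths are built in, on a human scale (generation time
29 y): ``recent`` puts both splits at 1,850 generations; ``deep`` puts
the sampled-population split at 17,241 and the ghost split at 68,966
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PopulationSpec",
    "SplitEvent",
    "MigrationMatrix",
    "DemographicModel",
    "ModelValidationError",
    "build_model",
    "custom_three_population_model",
    "MODEL_IDS",
    "DIVERGENCES",
    "RECENT_SPLIT",
    "DEEP_SPLIT_T0",
    "DEEP_SPLIT_T1",
]

MODEL_IDS = ("a", "b", "c", "d", "e")
DIVERGENCES = ("recent", "deep")

RECENT_SPLIT = 1850.0  # generations; both splits under the recent scenario
DEEP_SPLIT_T0 = 17241.0  # pop0/pop1 split, deep scenario
DEEP_SPLIT_T1 = 68966.0  # ghost split, deep scenario

SAMPLED = ("pop0", "pop1")
GHOST = "ghost"


class ModelValidationError(ValueError):
    """A demographic model is internally inconsistent."""


@dataclass(frozen=True)
class PopulationSpec:
    """A deme: unique ``name`` and diploid effective size ``Ne``."""

    name: str
    Ne: float

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ModelValidationError(f"Ne must be > 0 for {self.name!r}")


@dataclass(frozen=True)
class SplitEvent:
    """Backward-time merge of ``derived`` demes into ``ancestor`` at ``time``."""

    time: float
    derived: tuple[str, ...]
    ancestor: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ModelValidationError("split time must be > 0")
        if self.ancestor in self.derived:
            raise ModelValidationError("ancestor cannot be among derived demes")
        if len(set(self.derived)) != len(self.derived):
            raise ModelValidationError("derived demes must be distinct")


class MigrationMatrix:
    """Backward-time migration rates among named demes.

    ``rate[i][j]`` is the per-lineage, per-generation probability of a
    lineage moving from deme i to deme j backwards in time.  Entries lie
    in [0, 1], the diagonal is zero and row sums cannot exceed 1.
    """

    def __init__(self, names: Sequence[str], rates: np.ndarray | None = None):
        self.names = tuple(names)
        d = len(self.names)
        self.rates = np.zeros((d, d)) if rates is None else np.asarray(rates, float)
        if self.rates.shape != (d, d):
            raise ModelValidationError("migration matrix shape mismatch")
        self._validate()

    def _validate(self) -> None:
        r = self.rates
        if np.any((r < 0) | (r > 1)):
            raise ModelValidationError("migration rates must lie in [0, 1]")
        if np.any(np.diag(r) != 0):
            raise ModelValidationError("migration matrix diagonal must be zero")
        if np.any(r.sum(axis=1) > 1.0 + 1e-12):
            raise ModelValidationError("migration row sums must be <= 1")

    def set(self, src: str, dst: str, rate: float) -> None:
        i, j = self.names.index(src), self.names.index(dst)
        self.rates[i, j] = rate
        self._validate()

    def get(self, src: str, dst: str) -> float:
        return float(self.rates[self.names.index(src), self.names.index(dst)])


@dataclass
class DemographicModel:
    """Populations, split events, migration and mutation for one simulation.

    ``samples_per_pop`` counts *haplotypes* sampled from each of the three
    leaf-era demes (10 diploid individuals = 20 haplotypes by default).

    ``migration_units`` fixes how the matrix entries are read:
    ``"coalescent_4N"`` (the default for the a-e catalogue) treats entry
    (i, j) as the composite 4*Ne_i*m_ij, so the backward per-generation
    per-lineage rate is ``entry / (4 Ne_i)``; ``"per_generation"`` treats
    entries as raw backward per-generation probabilities.
    """

    populations: list[PopulationSpec]
    events: list[SplitEvent]
    migration: MigrationMatrix
    migration_units: str = "coalescent_4N"
    mu: float = 1e-8
    locus_length: int = 1000
    n_loci: int = 20
    samples_per_pop: int = 20
    years_per_generation: float = 29.0
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def pop_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    @property
    def leaf_populations(self) -> tuple[str, ...]:
        """Demes that exist at sampling time (never an event ancestor)."""
        ancestors = {e.ancestor for e in self.events}
        return tuple(n for n in self.pop_names if n not in ancestors)

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ModelValidationError("population names must be unique")
        if sorted(e.time for e in self.events) != [e.time for e in self.events]:
            raise ModelValidationError("events must be sorted by time")
        if self.migration.names != tuple(self.leaf_populations):
            raise ModelValidationError(
                "migration matrix must be defined over the leaf-era demes"
            )
        # every lineage must be able to reach a common deme in the final
        # epoch: either the splits funnel everything into one ancestor, or
        # the demes left alive are connected by migration
        alive = set(self.leaf_populations)
        for ev in self.events:
            for d in ev.derived:
                if d not in alive:
                    raise ModelValidationError(
                        f"split at t={ev.time} references inactive deme {d!r}"
                    )
                alive.discard(d)
            if ev.ancestor not in names:
                raise ModelValidationError(f"unknown ancestor {ev.ancestor!r}")
            alive.add(ev.ancestor)
        if len(alive) > 1:
            leaf = self.leaf_populations
            if not alive <= set(leaf):
                raise ModelValidationError(
                    "ancestral demes have no migration; lineages would be "
                    f"stranded among {sorted(alive)}"
                )
            idx = [leaf.index(a) for a in sorted(alive)]
            reach = (self.migration.rates[np.ix_(idx, idx)] > 0) | np.eye(
                len(idx), dtype=bool
            )
            for _ in range(len(idx)):  # transitive closure
                reach = reach | (reach @ reach)
            if not np.any(reach.all(axis=0)):
                raise ModelValidationError(
                    "no deme is reachable from all others; lineages would "
                    f"be stranded among {sorted(alive)}"
                )
        if self.mu < 0 or self.locus_length <= 0 or self.n_loci <= 0:
            raise ModelValidationError("mu, locus_length, n_loci must be valid")
        if self.samples_per_pop < 1:
            raise ModelValidationError("samples_per_pop must be >= 1")
        if self.migration_units not in ("coalescent_4N", "per_generation"):
            raise ModelValidationError(
                f"unknown migration_units {self.migration_units!r}"
            )

    def to_dict(self) -> dict:
        """JSON-serialisable description (provenance sidecars)."""
        return {
            "label": self.label,
            "populations": [asdict(p) for p in self.populations],
            "events": [
                {"time": e.time, "derived": list(e.derived), "ancestor": e.ancestor}
                for e in self.events
            ],
            "migration": {
                "names": list(self.migration.names),
                "rates": self.migration.rates.tolist(),
                "units": self.migration_units,
            },
            "mu": self.mu,
            "locus_length": self.locus_length,
            "n_loci": self.n_loci,
            "samples_per_pop": self.samples_per_pop,
            "years_per_generation": self.years_per_generation,
        }


def _migration_for_model(model_id: str, m_low: float, m_high: float) -> MigrationMatrix:
    names = SAMPLED + (GHOST,)
    mig = MigrationMatrix(names)
    # sampled pair always exchanges at the low rate
    mig.set("pop0", "pop1", m_low)
    mig.set("pop1", "pop0", m_low)
    if model_id == "a":
        pass  # ghost isolated
    elif model_id in ("b", "c"):
        # unidirectional forward flow ghost -> sampled, i.e. backward
        # movement of sampled lineages into the ghost
        m = m_low if model_id == "b" else m_high
        mig.set("pop0", GHOST, m)
        mig.set("pop1", GHOST, m)
    elif model_id == "d":
        for src in names:
            for dst in names:
                if src != dst:
                    mig.set(src, dst, m_low)
    elif model_id == "e":
        for p in SAMPLED:
            mig.set(p, GHOST, m_high)
            mig.set(GHOST, p, m_high)
    else:
        raise ModelValidationError(f"unknown model id {model_id!r}")
    return mig


def build_model(
    model_id: str,
    divergence: str,
    m_low: float = 0.05,
    m_high: float = 0.5,
    Ne: float = 5000.0,
    mu: float = 1e-8,
    n_loci: int = 20,
    locus_length: int = 1000,
    samples_per_pop: int = 20,
    t0: float | None = None,
    t1: float | None = None,
) -> DemographicModel:
    """Construct one of the five ghost topologies at a divergence depth.

    Parameters follow the human-scaled defaults: Ne = 5,000 diploids in
    every deme, mu = 1e-8 per site per generation, 20 unlinked loci of
    1,000 bp, 20 haplotypes per population, m_low = 0.05 and m_high = 0.5.
    Migration values are 4*Ne*m composites (``migration_units =
    "coalescent_4N"``): a backward per-generation lineage rate of
    ``m / (4 Ne)``, i.e. genuinely low gene flow on the coalescent
    timescale.  ``t0``/``t1`` override the built-in split times
    (generations); under ``recent`` both default to 1,850, under ``deep``
    to 17,241 and 68,966.
    """
    if model_id not in MODEL_IDS:
        raise ModelValidationError(f"model_id must be one of {MODEL_IDS}")
    if divergence not in DIVERGENCES:
        raise ModelValidationError(f"divergence must be one of {DIVERGENCES}")
    if divergence == "recent":
        t0 = RECENT_SPLIT if t0 is None else t0
        t1 = RECENT_SPLIT if t1 is None else t1
    else:
        t0 = DEEP_SPLIT_T0 if t0 is None else t0
        t1 = DEEP_SPLIT_T1 if t1 is None else t1
    if t1 < t0:
        raise ModelValidationError("ghost split t1 cannot precede sampled split t0")

    pops = [PopulationSpec(n, Ne) for n in SAMPLED + (GHOST, "anc01", "root")]
    events = [
        SplitEvent(t0, SAMPLED, "anc01"),
        SplitEvent(t1, ("anc01", GHOST), "root"),
    ]
    return DemographicModel(
        populations=pops,
        events=events,
        migration=_migration_for_model(model_id, m_low, m_high),
        mu=mu,
        locus_length=locus_length,
        n_loci=n_loci,
        samples_per_pop=samples_per_pop,
        label=f"{model_id}-{divergence}",
    )


def single_population_model(
    Ne: float,
    mu: float = 1e-8,
    locus_length: int = 1000,
    n_loci: int = 1,
    samples_per_pop: int = 10,
) -> DemographicModel:
    """A single panmictic deme: the neutral-coalescent calibration case."""
    return DemographicModel(
        populations=[PopulationSpec("pop0", Ne)],
        events=[],
        migration=MigrationMatrix(("pop0",)),
        migration_units="per_generation",
        mu=mu,
        locus_length=locus_length,
        n_loci=n_loci,
        samples_per_pop=samples_per_pop,
        label="panmictic",
    )


def island_model(
    Ne: float,
    m: float | np.ndarray,
    n_demes: int = 2,
    mu: float = 1e-8,
    locus_length: int = 1000,
    n_loci: int = 1,
    samples_per_pop: int = 10,
) -> DemographicModel:
    """Demes of equal size joined by migration, with no split events.

    ``m`` is either a single symmetric backward per-generation rate or a
    full (n_demes x n_demes) backward rate matrix.
    """
    names = tuple(f"pop{i}" for i in range(n_demes))
    if np.isscalar(m):
        rates = np.full((n_demes, n_demes), float(m))
        np.fill_diagonal(rates, 0.0)
    else:
        rates = np.asarray(m, dtype=float)
    return DemographicModel(
        populations=[PopulationSpec(n, Ne) for n in names],
        events=[],
        migration=MigrationMatrix(names, rates),
        migration_units="per_generation",
        mu=mu,
        locus_length=locus_length,
        n_loci=n_loci,
        samples_per_pop=samples_per_pop,
        label=f"island{n_demes}",
    )


def custom_three_population_model(
    Ne: float,
    t0: float,
    t1: float,
    migration: Mapping[tuple[str, str], float],
    mu: float = 1e-8,
    n_loci: int = 20,
    locus_length: int = 1000,
    samples_per_pop: int = 20,
) -> DemographicModel:
    """Three-deme model with an arbitrary backward migration dictionary.

    ``migration`` maps ``(src, dst)`` deme-name pairs to *raw* backward
    per-generation rates (``migration_units="per_generation"``); demes are
    ``pop0``, ``pop1`` and ``ghost``.  Used by the theory-facing bias
    scans, which need strong-mixing regimes outside the a-e catalogue.
    """
    mig = MigrationMatrix(SAMPLED + (GHOST,))
    for (src, dst), rate in migration.items():
        mig.set(src, dst, rate)
    pops = [PopulationSpec(n, Ne) for n in SAMPLED + (GHOST, "anc01", "root")]
    events = [
        SplitEvent(t0, SAMPLED, "anc01"),
        SplitEvent(t1, ("anc01", GHOST), "root"),
    ]
    return DemographicModel(
        populations=pops,
        events=events,
        migration=mig,
        migration_units="per_generation",
        mu=mu,
        locus_length=locus_length,
        n_loci=n_loci,
        samples_per_pop=samples_per_pop,
        label="custom",
    )
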