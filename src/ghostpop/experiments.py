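"""Simulation grids and the two- versus three-population permutation contrast.

The central experiment: simulate replicate datasets under every ghost
topology (models a-e) and divergence depth, estimate summary statistics
twice — once from the two sampled populations only, once with the ghost
included — and ask whether the two sampling strategies give detectably
different mean FST and mean pi.  Detectability is assessed with a label
permutation test on per-replicate values, pooled over the models with
ghost gene flow (b-e); model a (ghost isolated) is reported separately
as a control.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from configparser import ConfigParser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coalescent import simulate_dataset
from .demography import DIVERGENCES, MODEL_IDS, build_model
from .sumstats import THREE_POP, TWO_POP, summarize_dataset

__all__ = [
    "ExperimentConfig",
    "PermutationResult",
    "run_grid",
    "permutation_test",
    "divergence_contrast",
    "contrast_from_table",
    "write_outputs",
]

GRID_COLUMNS = [
    "model",
    "divergence",
    "replicate",
    "strategy",
    "S",
    "theta_w",
    "pi",
    "tajimas_d",
    "fst",
    "n_loci",
    "n_undefined_d",
    "status",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment grid."""

    model_ids: tuple[str, ...] = MODEL_IDS
    divergences: tuple[str, ...] = DIVERGENCES
    n_replicates: int = 10
    seed: int = 0
    n_loci: int = 20
    locus_length: int = 1000
    samples_per_pop: int = 20
    m_low: float = 0.05
    m_high: float = 0.5
    Ne: float = 5000.0
    mu: float = 1e-8
    n_permutations: int = 10_000
    out_dir: str = "ghostpop_results"

    def __post_init__(self) -> None:
        for m in self.model_ids:
            if m not in MODEL_IDS:
                raise ValueError(f"unknown model id {m!r}")
        for d in self.divergences:
            if d not in DIVERGENCES:
                raise ValueError(f"unknown divergence {d!r}")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for permutation tests")
        if self.n_permutations < 100:
            raise ValueError("need >= 100 permutations")

    @classmethod
    def from_ini(cls, path: str | Path) -> "ExperimentConfig":
        """Load from an INI file with a single ``[experiment]`` section."""
        cp = ConfigParser()
        cp.read(path)
        sec = cp["experiment"]
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in sec:
                continue
            raw = sec[f.name]
            if f.name in ("model_ids", "divergences"):
                kwargs[f.name] = tuple(x.strip() for x in raw.split(","))
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


@dataclass
class PermutationResult:
    """Outcome of one label-permutation test of a difference in means."""

    statistic_name: str
    observed_difference: float
    p_value: float
    n_permutations: int
    seed: int
    n_group1: int
    n_group2: int


def permutation_test(
    group1: Sequence[float],
    group2: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    statistic_name: str = "mean",
) -> PermutationResult:
    """Two-sided permutation test of ``|mean(group1) - mean(group2)|``.

    The null distribution is built by re-randomising group labels
    ``n_perm`` times; the p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)``, so it is bounded below
    by ``1/(n_perm + 1)`` and can never be zero.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 values")
    observed = abs(g1.mean() - g2.mean())
    pooled = np.concatenate([g1, g2])
    if np.all(pooled == pooled[0]):
        warnings.warn("degenerate permutation test: all values identical")
        return PermutationResult(
            statistic_name, 0.0, 1.0, n_perm, seed, g1.size, g2.size
        )
    rng = np.random.default_rng(seed)
    n1, n_tot = g1.size, pooled.size
    # vectorised label shuffles: argsort of uniform draws = random permutation
    order = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    shuffled = pooled[order]
    m1 = shuffled[:, :n1].mean(axis=1)
    m2 = shuffled[:, n1:].mean(axis=1)
    null = np.abs(m1 - m2)
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(
        statistic_name, float(observed), float(p), n_perm, seed, g1.size, g2.size
    )


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate and summarise every (model, divergence, replicate, strategy).

    Returns a tidy table with one row per cell.  Each (model, divergence)
    cell derives its own seed from the root seed, so any cell can be
    regenerated in isolation; a failing cell is recorded with
    ``status='failed'`` and the grid continues.
    """
    rows = []
    for div in config.divergences:
        for model_id in config.model_ids:
            cell_seed = int(
                np.random.SeedSequence(
                    [config.seed, MODEL_IDS.index(model_id), DIVERGENCES.index(div)]
                ).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            try:
                model = build_model(
                    model_id,
                    div,
                    m_low=config.m_low,
                    m_high=config.m_high,
                    Ne=config.Ne,
                    mu=config.mu,
                    n_loci=config.n_loci,
                    locus_length=config.locus_length,
                    samples_per_pop=config.samples_per_pop,
                )
                datasets = simulate_dataset(model, config.n_replicates, cell_seed)
                for rep, dataset in enumerate(datasets):
                    for strat in (TWO_POP, THREE_POP):
                        rec = summarize_dataset(
                            dataset,
                            strat,
                            model_id=model_id,
                            divergence=div,
                            replicate=rep,
                        )
                        rows.append(
                            {
                                "model": rec.model_id,
                                "divergence": rec.divergence,
                                "replicate": rec.replicate,
                                "strategy": rec.strategy,
                                "S": rec.S,
                                "theta_w": rec.theta_w,
                                "pi": rec.pi,
                                "tajimas_d": rec.tajimas_d,
                                "fst": rec.fst,
                                "n_loci": rec.n_loci,
                                "n_undefined_d": rec.n_undefined_d,
                                "status": "ok",
                            }
                        )
            except Exception as exc:  # degrade gracefully, keep the grid going
                warnings.warn(f"cell ({model_id}, {div}) failed: {exc}")
                rows.append(
                    {
                        "model": model_id,
                        "divergence": div,
                        "replicate": -1,
                        "strategy": "",
                        "S": 0,
                        "theta_w": np.nan,
                        "pi": np.nan,
                        "tajimas_d": np.nan,
                        "fst": np.nan,
                        "n_loci": 0,
                        "n_undefined_d": 0,
                        "status": "failed",
                    }
                )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def contrast_from_table(
    table: pd.DataFrame,
    divergence: str,
    models: tuple[str, ...] = ("b", "c", "d", "e"),
    statistics: tuple[str, ...] = ("fst", "pi"),
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Permutation tests of 2-pop vs 3-pop per-replicate means.

    ``group1`` holds the two-population values and ``group2`` the
    three-population values of each statistic, pooled over ``models``
    (default: the topologies with ghost gene flow, b-e).  Raises if any
    requested (model, strategy) cell is missing.
    """
    sub = table[(table.divergence == divergence) & (table.status == "ok")]
    missing = [
        (m, s)
        for m in models
        for s in ("2-pop", "3-pop")
        if sub[(sub.model == m) & (sub.strategy == s)].empty
    ]
    if missing:
        raise ValueError(f"missing grid cells for contrast: {missing}")
    pool = sub[sub.model.isin(models)]
    results = {}
    for i, stat in enumerate(statistics):
        # undefined statistic values (NaN sentinel) carry no information
        # about the strategy contrast and are excluded
        g1 = pool[pool.strategy == "2-pop"][stat].dropna().to_numpy()
        g2 = pool[pool.strategy == "3-pop"][stat].dropna().to_numpy()
        results[stat] = permutation_test(
            g1, g2, n_perm=n_perm, seed=seed + i, statistic_name=f"mean {stat}"
        )
    return results


def divergence_contrast(
    config: ExperimentConfig, table: pd.DataFrame | None = None
) -> dict[str, dict[str, PermutationResult]]:
    """Paired recent/deep permutation contrasts of mean FST and mean pi."""
    if table is None:
        table = run_grid(config)
    out = {}
    for div in config.divergences:
        out[div] = contrast_from_table(
            table, div, n_perm=config.n_permutations, seed=config.seed
        )
    return out


def write_outputs(
    table: pd.DataFrame,
    results: dict[str, dict[str, PermutationResult]],
    out_dir: str | Path,
    config: ExperimentConfig | None = None,
) -> dict[str, Path]:
    """Write the grid table, permutation summary and provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"grid": out / "grid.csv", "permutations": out / "permutation_tests.csv"}
    table.to_csv(paths["grid"], index=False)
    rows = [
        {
            "divergence": div,
            "statistic": res.statistic_name,
            "observed_difference": res.observed_difference,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
            "n_group1": res.n_group1,
            "n_group2": res.n_group2,
        }
        for div, per_stat in results.items()
        for res in per_stat.values()
    ]
    pd.DataFrame(rows).to_csv(paths["permutations"], index=False)
    if config is not None:
        paths["provenance"] = out / "provenance.json"
        paths["provenance"].write_text(
            json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
        )
    return paths
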