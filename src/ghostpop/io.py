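"""Readers and writers for simulated haplotype datasets.

A "replicate" is a list of :class:`~ghostpop.coalescent.LocusAlignment`
objects (unlinked loci).  Supported on-disk forms, all plain text:

* **VCF** — one file per replicate; each locus is a contig, haplotypes
  are haploid samples named ``<pop>_h<i>``, alleles A (ancestral, REF)
  and T (derived, ALT); positions are 1-based on export.
* **FASTA** — per-locus alignment, 0/1 mapped to A/T at variable sites.
* **ms** — classic simulator block format (``//``, ``segsites:``,
  ``positions:`` with positions scaled to (0, 1), then 0/1 haplotype
  strings).
* **IMa3 input** — header comment line, population count and names, locus
  count, then per-locus blocks: name, per-population sequence counts,
  length, mutation-model code (I = infinite sites), inheritance scalar,
  followed by one 10-character-named sequence line per haplotype.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .coalescent import LocusAlignment
from .demography import DemographicModel

__all__ = [
    "write_vcf",
    "write_fasta",
    "write_ms",
    "read_ms",
    "write_ima3",
    "write_provenance",
]

_BASES = {0: "A", 1: "T"}


def _sample_names(aln: LocusAlignment) -> list[str]:
    names, counter = [], {}
    for pop in aln.pop_of_sample:
        counter[pop] = counter.get(pop, 0)
        names.append(f"{pop}_h{counter[pop]}")
        counter[pop] += 1
    return names


def write_vcf(replicate: Sequence[LocusAlignment], path: str | Path) -> Path:
    """Write one replicate as an uncompressed haploid VCF (one contig/locus)."""
    path = Path(path)
    names = _sample_names(replicate[0])
    lines = ["##fileformat=VCFv4.2", "##source=ghostpop"]
    for i, aln in enumerate(replicate):
        lines.append(f"##contig=<ID=locus_{i},length={aln.locus_length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names)
    )
    for i, aln in enumerate(replicate):
        for s in range(aln.n_sites):
            gts = "\t".join(str(int(a)) for a in aln.alleles[:, s])
            lines.append(
                f"locus_{i}\t{int(aln.positions[s]) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fasta(replicate: Sequence[LocusAlignment], path: str | Path) -> Path:
    """Write per-locus alignments as FASTA, variable sites mapped to A/T."""
    path = Path(path)
    records = []
    for i, aln in enumerate(replicate):
        names = _sample_names(aln)
        for h in range(aln.n_haplotypes):
            seq = "".join(_BASES[int(a)] for a in aln.alleles[h])
            records.append(f">locus_{i}|{names[h]}\n{seq or '-'}")
    path.write_text("\n".join(records) + "\n")
    return path


def write_ms(replicate: Sequence[LocusAlignment], path: str | Path) -> Path:
    """Write a replicate in ms-style blocks (positions scaled to (0, 1))."""
    path = Path(path)
    n = replicate[0].n_haplotypes
    out = [f"ghostpop ms-style output: {n} haplotypes, {len(replicate)} loci", "seed"]
    for aln in replicate:
        out.append("")
        out.append("//")
        out.append(f"segsites: {aln.n_sites}")
        if aln.n_sites:
            pos = " ".join(
                f"{(p + 0.5) / aln.locus_length:.6f}" for p in aln.positions
            )
            out.append(f"positions: {pos}")
            for h in range(aln.n_haplotypes):
                out.append("".join(str(int(a)) for a in aln.alleles[h]))
    path.write_text("\n".join(out) + "\n")
    return path


def read_ms(
    path: str | Path,
    pop_of_sample: Sequence[str],
    locus_length: int = 1000,
) -> list[LocusAlignment]:
    """Parse an ms-style file back into alignments.

    ms output does not carry population labels or physical locus lengths,
    so both must be supplied; positions are de-scaled onto
    ``[0, locus_length)`` and deduplicated if rounding collides.
    """
    text = Path(path).read_text().splitlines()
    loci: list[LocusAlignment] = []
    i = 0
    labels = tuple(pop_of_sample)
    while i < len(text):
        if text[i].strip() == "//":
            i += 1
            seg = int(text[i].split(":")[1])
            i += 1
            if seg == 0:
                loci.append(
                    LocusAlignment(
                        np.zeros((len(labels), 0), np.int8),
                        np.array([], int),
                        labels,
                        locus_length,
                    )
                )
                continue
            raw = [float(x) for x in text[i].split(":")[1].split()]
            pos = np.array([int(p * locus_length) for p in raw])
            for j in range(1, len(pos)):  # enforce strict increase
                if pos[j] <= pos[j - 1]:
                    pos[j] = pos[j - 1] + 1
            pos = np.minimum(pos, locus_length - 1)
            for j in range(len(pos) - 2, -1, -1):
                if pos[j] >= pos[j + 1]:
                    pos[j] = pos[j + 1] - 1
            i += 1
            rows = []
            for _ in range(len(labels)):
                rows.append([int(c) for c in text[i].strip()])
                i += 1
            loci.append(LocusAlignment(np.array(rows, np.int8), pos, labels, locus_length))
        else:
            i += 1
    return loci


def write_ima3(
    replicate: Sequence[LocusAlignment],
    path: str | Path,
    pops: Sequence[str] | None = None,
    title: str = "ghostpop simulated dataset",
) -> Path:
    """Write one replicate as an IMa3 input file.

    Monomorphic flanking context is not emitted; each locus is written as
    its variable sites under the infinite-sites (I) mutation-model code
    with inheritance scalar 1, which is the conventional encoding for
    phased autosomal SNP haplotypes.
    """
    path = Path(path)
    first = replicate[0]
    if pops is None:
        seen = dict.fromkeys(first.pop_of_sample)
        pops = list(seen)
    out = [title, f"{len(pops)}", " ".join(pops)]
    # population tree string: ((0,1):2,  third pop outgroup if present
    if len(pops) == 3:
        out.append("((0,1):3,2):4")
    elif len(pops) == 2:
        out.append("(0,1):2")
    out.append(f"{len(replicate)}")
    for i, aln in enumerate(replicate):
        counts = [sum(1 for p in aln.pop_of_sample if p == pop) for pop in pops]
        n_cols = max(aln.n_sites, 1)
        out.append(
            f"locus{i} " + " ".join(str(c) for c in counts) + f" {n_cols} I 1"
        )
        names = _sample_names(aln)
        order = [h for pop in pops for h in range(aln.n_haplotypes)
                 if aln.pop_of_sample[h] == pop]
        for h in order:
            seq = "".join(_BASES[int(a)] for a in aln.alleles[h]) or "A"
            out.append(f"{names[h]:<10.10s}{seq}")
    path.write_text("\n".join(out) + "\n")
    return path


def write_provenance(
    model: DemographicModel, seed: int, path: str | Path, extra: dict | None = None
) -> Path:
    """JSON sidecar with the fully resolved model and root seed."""
    path = Path(path)
    payload = {"model": model.to_dict(), "seed": int(seed)}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
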