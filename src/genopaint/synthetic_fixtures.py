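"""Deterministic synthetic genotype data for testing and demonstration.

Emulates the marker tables of a biparental population: each haplotype of
each sample is a mosaic of alternating parental blocks, with breakpoint
counts drawn Poisson(crossover_rate) per chromosome per gamete and
breakpoint positions uniform along the chromosome.  Marker calls are read
off the two haplotypes at (by default) evenly spaced positions; missing
calls are injected independently per cell.  All randomness flows from a
single seed, so a given parameter set always produces the same table.

``het_fraction`` controls heterozygosity: it is the probability, per
sample x chromosome, that the second haplotype is simulated independently
of the first (otherwise it is a copy, giving a fully homozygous
chromosome).

A minimal VCF v4.2 writer is included so the VCF conversion path can be
exercised end-to-end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .genotype_core import (
    AlleleState,
    Call,
    EncodingDialect,
    GenotypeError,
    GenotypeTable,
    Marker,
    normalize_table,
    serialize_call,
)

PathLike = Union[str, Path]


@dataclass
class SimulationParams:
    """Study conditions for the synthetic biparental population.

    crossover_rate is the expected number of crossovers per chromosome per
    gamete (Poisson mean); het_fraction and missing_rate are probabilities
    in [0, 1]; seed fixes all randomness.
    """

    n_samples: int = 3
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr01": 40_000_000, "chr02": 30_000_000})
    markers_per_chrom: int = 20
    crossover_rate: float = 2.0
    het_fraction: float = 0.5
    missing_rate: float = 0.02
    dialect: EncodingDialect = EncodingDialect.PHASED
    seed: int = 0
    random_marker_positions: bool = False

    def __post_init__(self) -> None:
        if self.markers_per_chrom < 1:
            raise GenotypeError("markers_per_chrom must be >= 1")
        for nm, p in (("het_fraction", self.het_fraction),
                      ("missing_rate", self.missing_rate)):
            if not 0.0 <= p <= 1.0:
                raise GenotypeError(f"{nm} must be in [0, 1], got {p}")
        if self.crossover_rate < 0:
            raise GenotypeError("crossover_rate must be >= 0")


def simulate_haplotype(rng: np.random.Generator, length: int,
                       crossover_rate: float) -> tuple[list[int], int]:
    """One gamete: sorted breakpoint positions plus the starting allele.

    The haplotype carries the starting allele (0 = A, 1 = B) up to the first
    breakpoint and alternates thereafter.
    """
    n_break = rng.poisson(crossover_rate)
    breaks = sorted(int(b) for b in rng.integers(1, length, size=n_break))
    start_allele = int(rng.integers(0, 2))
    return breaks, start_allele


def _allele_at(pos: int, breaks: list[int], start_allele: int) -> int:
    flips = sum(1 for b in breaks if b <= pos)
    return (start_allele + flips) % 2


def _marker_positions(rng: np.random.Generator, length: int, n: int,
                      random_placement: bool) -> list[int]:
    if random_placement:
        pos = sorted(int(p) for p in rng.choice(
            np.arange(1, length + 1), size=n, replace=False))
        return pos
    # evenly spaced grid, strictly inside [1, length]
    return [max(1, round((i + 1) * length / (n + 1))) for i in range(n)]


def simulate_table(params: SimulationParams) -> GenotypeTable:
    """Generate a normalized genotype table under the given conditions."""
    rng = np.random.default_rng(params.seed)
    _A, _B, _N = AlleleState.A, AlleleState.B, AlleleState.MISSING
    state = {0: _A, 1: _B}
    phased = params.dialect is EncodingDialect.PHASED

    samples = [f"S{i + 1}" for i in range(params.n_samples)]
    markers: list[Marker] = []
    positions_by_chrom: dict[str, list[int]] = {}
    for chrom, length in params.chrom_lengths.items():
        pos = _marker_positions(rng, length, params.markers_per_chrom,
                                params.random_marker_positions)
        positions_by_chrom[chrom] = pos
        markers.extend(Marker(chrom=chrom, name=f"{chrom}_{p}", position=p)
                       for p in pos)

    # simulate haplotype mosaics per sample x chromosome
    haplotypes: dict[tuple[str, str], tuple] = {}
    for s in samples:
        for chrom, length in params.chrom_lengths.items():
            h1 = simulate_haplotype(rng, length, params.crossover_rate)
            if rng.random() < params.het_fraction:
                h2 = simulate_haplotype(rng, length, params.crossover_rate)
            else:
                h2 = h1
            haplotypes[(s, chrom)] = (h1, h2)

    calls: list[list[Call]] = []
    for m in markers:
        row: list[Call] = []
        for s in samples:
            (b1, a1), (b2, a2) = haplotypes[(s, m.chrom)]
            if params.missing_rate > 0 and rng.random() < params.missing_rate:
                row.append(Call(_N, _N, phased=False))
                continue
            al1 = state[_allele_at(m.position, b1, a1)]
            al2 = state[_allele_at(m.position, b2, a2)]
            if not phased and al1 is _B and al2 is _A:
                al1, al2 = al2, al1  # canonical unphased het order
            row.append(Call(al1, al2, phased=phased))
        calls.append(row)

    return normalize_table(GenotypeTable(
        markers=markers, samples=samples, calls=calls,
        dialect=params.dialect))


def write_synthetic_vcf(table: GenotypeTable, path: PathLike) -> Path:
    """Write a table as a minimal GT-only VCF v4.2.

    Only the PHASED and UNPHASED dialects have a VCF encoding; SIMPLE
    tables are rejected.  Each marker becomes one biallelic diploid record
    (REF=A, ALT=T) whose GT strings are the table's own tokens, so VCF
    conversion round-trips the table (up to unphased-het canonicalisation).
    """
    if table.dialect is EncodingDialect.SIMPLE:
        raise GenotypeError(
            "the simple A/B/H/N dialect has no VCF genotype encoding; "
            "use a phased or unphased table")
    out = Path(path)
    chroms: dict[str, int] = {}
    for m in table.markers:
        chroms[m.chrom] = max(chroms.get(m.chrom, 0), m.position)
    with open(out, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, ln in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, m in enumerate(table.markers):
            gts = "\t".join(serialize_call(c, table.dialect)
                            for c in table.calls[i])
            fh.write(f"{m.chrom}\t{m.position}\t{m.name}\tA\tT\t.\t.\t.\tGT\t"
                     f"{gts}\n")
    return out


def count_breakpoints(table_params: SimulationParams,
                      n_haplotypes: int) -> float:
    """Mean simulated breakpoints per haplotype over ``n_haplotypes`` draws.

    Uses the same gamete model (and seeding scheme) as
    :func:`simulate_table`; intended for calibration checks of the
    crossover process.
    """
    rng = np.random.default_rng(table_params.seed)
    length = next(iter(table_params.chrom_lengths.values()))
    total = 0
    for _ in range(n_haplotypes):
        breaks, _start = simulate_haplotype(rng, length,
                                            table_params.crossover_rate)
        total += len(breaks)
    return total / n_haplotypes
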