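"""Shared fixtures: small synthetic tables, toy databases, color sets."""

from __future__ import annotations

import pytest

from genopaint import (
    AlleleState,
    Call,
    ChromLengthDB,
    EncodingDialect,
    GenotypeTable,
    Marker,
    RenderConfig,
    SimulationParams,
    load_color_sets,
    normalize_table,
    simulate_table,
)

A, B, N = AlleleState.A, AlleleState.B, AlleleState.MISSING


def make_table(rows, samples, dialect=EncodingDialect.PHASED):
    """Build a normalized table from (chrom, name, pos, [calls]) rows."""
    markers = [Marker(chrom=c, name=n, position=p) for c, n, p, _ in rows]
    calls = [list(r[3]) for r in rows]
    return normalize_table(GenotypeTable(markers=markers, samples=list(samples),
                                         calls=calls, dialect=dialect))


@pytest.fixture
def toy_lengths():
    return {"chrT1": 1_000_000, "chrT2": 700_000}


@pytest.fixture
def toy_db(toy_lengths):
    return ChromLengthDB(entries={"toy": dict(toy_lengths)})


@pytest.fixture
def color_registry():
    return load_color_sets()


@pytest.fixture
def normal_colors(color_registry):
    return color_registry["normal"]


@pytest.fixture
def toy_params(toy_lengths):
    return SimulationParams(n_samples=3, chrom_lengths=dict(toy_lengths),
                            markers_per_chrom=8, crossover_rate=2.0,
                            het_fraction=0.5, missing_rate=0.05,
                            dialect=EncodingDialect.PHASED, seed=11)


@pytest.fixture
def toy_table(toy_params):
    return simulate_table(toy_params)


@pytest.fixture
def base_config():
    return RenderConfig(species="toy", dpi=60)
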