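"""Shared fixtures: the worked Lys toy and session-scoped synthetic genomes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from codonace import (
    CodonFrequencyTable,
    DeltaTable,
    GeneRecord,
    GeneticCode,
    SyntheticSpec,
    build_delta_table,
    build_frequency_table,
    generate,
)
from codonace.synthetic_genomes import default_selected_table


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.from_ncbi_id(11)


def make_table(
    code: GeneticCode, overrides: dict[str, float], role: str
) -> CodonFrequencyTable:
    """Uniform table with selected codon frequencies overridden."""
    freqs = {}
    for aa, codons in code.families.items():
        for c in codons:
            freqs[c] = 1.0 / len(codons)
    freqs.update(overrides)
    return CodonFrequencyTable(freqs=freqs, code=code, role=role)


def random_table(
    rng: np.random.Generator, code: GeneticCode, role: str = "f_n"
) -> CodonFrequencyTable:
    """Dirichlet-random within-family frequencies (all strictly positive)."""
    freqs = {}
    for aa, codons in code.families.items():
        p = rng.dirichlet(np.ones(len(codons)) * 2.0)
        p = np.clip(p, 1e-4, None)
        p /= p.sum()
        freqs.update(zip(codons, p))
    return CodonFrequencyTable(freqs=freqs, code=code, role=role)


@dataclass
class LysToy:
    """The shared worked example: a 4-codon Lys gene, f_n 0.75/0.25 vs f_o 0.5/0.5."""

    f_n: CodonFrequencyTable
    f_o: CodonFrequencyTable
    delta: DeltaTable
    gene: GeneRecord


@pytest.fixture(scope="session")
def lys_toy(code) -> LysToy:
    f_n = make_table(code, {"AAA": 0.75, "AAG": 0.25}, "f_n")
    f_o = make_table(code, {"AAA": 0.5, "AAG": 0.5}, "f_o")
    return LysToy(
        f_n=f_n,
        f_o=f_o,
        delta=build_delta_table(f_o, f_n),
        gene=GeneRecord("G1", {"AAA": 2, "AAG": 2}, {"K": 4}, 4),
    )


@pytest.fixture(scope="session")
def null_genome(code):
    """300 genes sampled iid from the default background table."""
    spec = SyntheticSpec(n_genes=300, seed=7, code=code)
    genes, labels = generate(spec)
    return genes, labels, spec


@pytest.fixture(scope="session")
def alien_genome(code):
    """500 genes with a planted 20% GC-shifted alien class."""
    spec = SyntheticSpec(n_genes=500, alien_fraction=0.2, seed=11, code=code)
    genes, labels = generate(spec)
    return genes, labels, spec


@pytest.fixture(scope="session")
def selection_genome(code):
    """500 genes with a planted 20% translation-optimized class."""
    spec = SyntheticSpec(
        n_genes=500,
        selected_fraction=0.2,
        selected_table=default_selected_table(code),
        seed=21,
        code=code,
    )
    genes, labels = generate(spec)
    f_n = build_frequency_table(genes, code, role="f_n")
    return genes, labels, spec, f_n


@pytest.fixture(scope="session")
def calibration_genome(code):
    """1000 null genes of exactly 300 codons for Z-score calibration."""
    spec = SyntheticSpec(
        n_genes=1000, length_mean=300, length_sigma=0.0, seed=101, code=code
    )
    genes, _ = generate(spec)
    delta = build_delta_table(default_selected_table(code), spec.null_table)
    return genes, delta, spec.null_table
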