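"""Codon-frequency reference tables and per-codon adaptiveness scores.

Two within-family frequency tables drive everything downstream: f_n, the
codon usage expected in the absence of codon selection (the stochastic null),
and f_o, the usage of translation-optimized genes. The adaptiveness of each
codon is the log-ratio delta = ln(f_o / f_n); natural logarithms are used
throughout, so a gene's summed score decomposes codon by codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import GeneRecord, GeneticCode, pool_counts

__all__ = [
    "CodonFrequencyTable",
    "DeltaTable",
    "build_frequency_table",
    "table_from_counts",
    "build_delta_table",
    "display_normalize",
]


@dataclass
class CodonFrequencyTable:
    """Per-amino-acid normalized synonymous codon frequencies.

    Within every amino-acid family the frequencies sum to 1; codons unseen in
    the source gene set receive the pseudocount (default 0.5) before
    normalization so all frequencies are strictly positive.
    """

    freqs: dict[str, float]
    code: GeneticCode
    role: str = "f_n"
    pseudocount: float = 0.5
    source: str = ""

    def __post_init__(self) -> None:
        for aa, codons in self.code.families.items():
            total = sum(self.freqs[c] for c in codons)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"family {aa}: frequencies sum to {total}, expected 1"
                )
            if any(self.freqs[c] <= 0 for c in codons):
                raise ValueError(f"family {aa}: non-positive frequency")

    def as_array(self) -> np.ndarray:
        return np.array([self.freqs[c] for c in self.code.sense_codons])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "codon": list(self.code.sense_codons),
                "amino_acid": [
                    self.code.codon_to_aa[c] for c in self.code.sense_codons
                ],
                "frequency": [
                    f"{self.freqs[c]:.12f}" for c in self.code.sense_codons
                ],
                "role": self.role,
                "source": self.source or "-",
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, code: GeneticCode) -> "CodonFrequencyTable":
        df = pd.read_csv(path, sep="\t")
        freqs = dict(zip(df["codon"], df["frequency"].astype(float)))
        # re-normalize away the 12-decimal rounding so family sums are exact
        for aa, codons in code.families.items():
            tot = sum(freqs[c] for c in codons)
            for c in codons:
                freqs[c] /= tot
        src = str(df["source"].iloc[0])
        return cls(
            freqs=freqs,
            code=code,
            role=str(df["role"].iloc[0]),
            source="" if src == "-" else src,
        )


@dataclass
class DeltaTable:
    """Per-codon scores delta_ij = ln(f_o/f_n); zero for single-codon families."""

    delta: dict[str, float]
    code: GeneticCode
    source: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.delta[c] for c in self.code.sense_codons])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "codon": list(self.code.sense_codons),
                "amino_acid": [
                    self.code.codon_to_aa[c] for c in self.code.sense_codons
                ],
                "delta": [
                    f"{self.delta[c]:.12f}" for c in self.code.sense_codons
                ],
                "role": "delta",
                "source": self.source or "-",
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, code: GeneticCode) -> "DeltaTable":
        df = pd.read_csv(path, sep="\t")
        src = str(df["source"].iloc[0])
        return cls(
            delta=dict(zip(df["codon"], df["delta"].astype(float))),
            code=code,
            source="" if src == "-" else src,
        )


def table_from_counts(
    counts: Mapping[str, float],
    code: GeneticCode,
    role: str = "f_n",
    pseudocount: float = 0.5,
    source: str = "",
) -> CodonFrequencyTable:
    """Normalize raw codon counts into a frequency table, family by family.

    Zero-count codons are assigned the pseudocount before normalization. A
    degenerate family with no observed codons at all is an error: frequencies
    estimated from pseudocounts alone carry no information.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount}")
    freqs: dict[str, float] = {}
    for aa, codons in code.families.items():
        fam = {c: float(counts.get(c, 0)) for c in codons}
        if len(codons) > 1 and sum(fam.values()) == 0:
            raise ValueError(f"amino-acid family {aa} has no observed codons")
        fam = {c: (n if n > 0 else pseudocount) for c, n in fam.items()}
        total = sum(fam.values())
        if total == 0:  # single-codon family with pseudocount 0
            fam = {c: 1.0 for c in codons}
            total = float(len(codons))
        for c in codons:
            freqs[c] = fam[c] / total
    return CodonFrequencyTable(
        freqs=freqs, code=code, role=role, pseudocount=pseudocount, source=source
    )


def build_frequency_table(
    genes: Sequence[GeneRecord],
    code: GeneticCode,
    role: str = "f_n",
    pseudocount: float = 0.5,
    source: str = "",
) -> CodonFrequencyTable:
    """Pool a gene set and normalize to a within-family frequency table."""
    pooled = pool_counts(genes)
    src = source or f"{len(genes)} genes, {pooled.n_codons_total} codons"
    return table_from_counts(
        pooled.codon_counts, code, role=role, pseudocount=pseudocount, source=src
    )


def build_delta_table(
    f_o: CodonFrequencyTable, f_n: CodonFrequencyTable
) -> DeltaTable:
    """delta(cdn) = ln(f_o(cdn) / f_n(cdn)) for every sense codon.

    Codons of single-codon families necessarily score 0; swapping the two
    tables negates every delta.
    """
    if f_o.code.code_id != f_n.code.code_id:
        raise ValueError(
            f"genetic codes differ: {f_o.code.code_id} vs {f_n.code.code_id}"
        )
    delta = {
        c: float(np.log(f_o.freqs[c] / f_n.freqs[c]))
        for c in f_o.code.sense_codons
    }
    return DeltaTable(
        delta=delta,
        code=f_o.code,
        source=f"f_o: {f_o.source or '?'} | f_n: {f_n.source or '?'}",
    )


def display_normalize(
    values: Mapping[str, float], code: GeneticCode
) -> dict[str, float]:
    """Scale each amino-acid family so its maximum value displays as 1.000.

    Presentation only — computation always uses raw frequencies. Delta
    columns should be passed through exp() first (monotone and sign-free)
    so the normalization is well defined.
    """
    out: dict[str, float] = {}
    for aa, codons in code.families.items():
        mx = max(values[c] for c in codons)
        if mx <= 0:
            raise ValueError(f"family {aa}: maximum value {mx} is not positive")
        for c in codons:
            out[c] = values[c] / mx
    return out
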