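"""Synthetic CDS generator with controlled codon-usage structure.

Genes are sampled under the same stochastic model the ACE null assumes:
amino acids drawn iid from a fixed composition, codons drawn iid within each
family from a class-specific frequency table. Three gene classes are
supported — null (background/mutational usage), selected (translation-
optimized usage) and alien (GC-shifted usage emulating recently transferred
genes) — plus a gradient mode where each gene mixes the null and selected
tables with its own weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_core import GeneRecord, GeneticCode
from .scoring_tables import CodonFrequencyTable

__all__ = [
    "SyntheticSpec",
    "generate",
    "write_fasta",
    "default_aa_composition",
    "default_null_table",
    "default_selected_table",
    "gc_shift_table",
    "mix_tables",
]

# Typical bacterial proteome composition (E. coli-like, rounded).
_DEFAULT_AA_COMPOSITION = {
    "A": 0.095, "R": 0.055, "N": 0.040, "D": 0.052, "C": 0.012,
    "Q": 0.044, "E": 0.058, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.106, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.015, "Y": 0.029, "V": 0.071,
}


def default_aa_composition() -> dict[str, float]:
    return dict(_DEFAULT_AA_COMPOSITION)


def default_null_table(code: GeneticCode) -> CodonFrequencyTable:
    """A moderately AT-biased background table (mutational-bias-like).

    Within each family codons are weighted by exp(0.4 * #AT), giving ~2.2:1
    preference between the extreme codons of a 2-fold family — comparable to
    genome-wide third-position skews in AT-biased bacteria.
    """
    freqs: dict[str, float] = {}
    for aa, codons in code.families.items():
        w = np.array([math.exp(0.4 * sum(b in "AT" for b in c)) for c in codons])
        w /= w.sum()
        freqs.update(zip(codons, w))
    return CodonFrequencyTable(
        freqs=freqs, code=code, role="f_n", source="synthetic null (AT-biased)"
    )


def default_selected_table(code: GeneticCode) -> CodonFrequencyTable:
    """A translation-optimized table: one strongly preferred codon per family.

    The pyrimidine-C-ending codon (else G-ending, else first) carries weight
    6 against 1 for its synonyms, i.e. ~86% optimal-codon usage in 2-fold
    families — the degree of bias seen in ribosomal-protein genes of fast-
    growing bacteria.
    """
    freqs: dict[str, float] = {}
    for aa, codons in code.families.items():
        ending_c = [c for c in codons if c.endswith("C")]
        ending_g = [c for c in codons if c.endswith("G")]
        preferred = (ending_c or ending_g or list(codons))[0]
        w = np.array([6.0 if c == preferred else 1.0 for c in codons])
        w /= w.sum()
        freqs.update(zip(codons, w))
    return CodonFrequencyTable(
        freqs=freqs, code=code, role="f_o", source="synthetic selected (C-ending)"
    )


def gc_shift_table(
    table: CodonFrequencyTable, beta: float = 1.0
) -> CodonFrequencyTable:
    """Reweight a table toward GC-rich codons: w *= exp(beta * #GC).

    Models the compositionally distinct usage of laterally acquired genes.
    """
    code = table.code
    freqs: dict[str, float] = {}
    for aa, codons in code.families.items():
        w = np.array(
            [table.freqs[c] * math.exp(beta * sum(b in "GC" for b in c)) for c in codons]
        )
        w /= w.sum()
        freqs.update(zip(codons, w))
    return CodonFrequencyTable(
        freqs=freqs,
        code=code,
        role=table.role,
        source=f"GC-shifted(beta={beta}) {table.source}",
    )


def mix_tables(
    a: CodonFrequencyTable, b: CodonFrequencyTable, weight_b: float
) -> dict[str, float]:
    """Convex per-codon mixture (stays family-normalized)."""
    return {
        c: (1 - weight_b) * a.freqs[c] + weight_b * b.freqs[c]
        for c in a.code.sense_codons
    }


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic CDS set.

    Lengths (in codons) follow a truncated log-normal matching real ORF
    length skew; set ``length_sigma=0`` for fixed-length genes.
    """

    n_genes: int = 1000
    length_mean: int = 300
    length_sigma: float = 0.45
    length_min: int = 50
    length_max: int = 1500
    aa_composition: dict[str, float] = field(default_factory=default_aa_composition)
    null_table: CodonFrequencyTable | None = None
    selected_table: CodonFrequencyTable | None = None
    selected_fraction: float = 0.0
    selection_gradient: bool = False
    alien_fraction: float = 0.0
    alien_table: CodonFrequencyTable | None = None
    alien_gc_shift: float = 1.0
    seed: int = 0
    code: GeneticCode | None = None

    def resolve(self) -> "SyntheticSpec":
        if self.code is None:
            self.code = GeneticCode.from_ncbi_id(11)
        if self.null_table is None:
            self.null_table = default_null_table(self.code)
        if (self.selected_fraction > 0 or self.selection_gradient) and (
            self.selected_table is None
        ):
            raise ValueError("selected genes requested but no selected table given")
        if self.alien_fraction > 0 and self.alien_table is None:
            self.alien_table = gc_shift_table(self.null_table, self.alien_gc_shift)
        if self.selected_fraction + self.alien_fraction > 1:
            raise ValueError("class fractions sum to more than 1")
        if self.selected_fraction < 0 or self.alien_fraction < 0:
            raise ValueError("class fractions must be non-negative")
        return self


def _draw_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    if spec.length_sigma <= 0:
        return spec.length_mean
    for _ in range(1000):
        length = int(round(rng.lognormal(math.log(spec.length_mean), spec.length_sigma)))
        if spec.length_min <= length <= spec.length_max:
            return length
    return int(np.clip(spec.length_mean, spec.length_min, spec.length_max))


def generate(spec: SyntheticSpec) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Sample a CDS set; returns gene records (with sequences) and a truth-
    label table (gene_id, label, weight). Deterministic given the seed."""
    spec = spec.resolve()
    code = spec.code
    rng = np.random.default_rng(spec.seed)

    aas = sorted(spec.aa_composition)
    aa_p = np.array([spec.aa_composition[a] for a in aas])
    aa_p = aa_p / aa_p.sum()

    n_alien = int(round(spec.alien_fraction * spec.n_genes))
    n_sel = int(round(spec.selected_fraction * spec.n_genes))
    labels = ["alien"] * n_alien + ["selected"] * n_sel
    labels += ["null"] * (spec.n_genes - len(labels))
    labels = [labels[i] for i in rng.permutation(spec.n_genes)]

    width = len(str(spec.n_genes))
    genes: list[GeneRecord] = []
    rows = []
    for i, label in enumerate(labels):
        gene_id = f"g{i:0{width}d}"
        weight = 0.0
        if label == "alien":
            table = spec.alien_table.freqs
        elif label == "selected":
            weight = 1.0
            table = spec.selected_table.freqs
        elif spec.selection_gradient:
            weight = float(rng.random())
            table = mix_tables(spec.null_table, spec.selected_table, weight)
        else:
            table = spec.null_table.freqs

        length = _draw_length(spec, rng)
        aa_counts_vec = rng.multinomial(length, aa_p)
        codon_counts: dict[str, int] = {}
        aa_counts: dict[str, int] = {}
        codon_list: list[str] = []
        for aa, c_i in zip(aas, aa_counts_vec):
            if c_i == 0:
                continue
            fam = code.families[aa]
            p = np.array([table[c] for c in fam])
            draws = rng.multinomial(int(c_i), p / p.sum())
            aa_counts[aa] = int(c_i)
            for cdn, n in zip(fam, draws):
                if n:
                    codon_counts[cdn] = int(n)
                    codon_list.extend([cdn] * int(n))
        order = rng.permutation(len(codon_list))
        seq = "".join(codon_list[j] for j in order)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                codon_counts=codon_counts,
                aa_counts=aa_counts,
                n_codons_total=int(sum(codon_counts.values())),
                sequence=seq,
            )
        )
        rows.append({"gene_id": gene_id, "label": label, "weight": weight})
    return genes, pd.DataFrame(rows)


def write_fasta(
    genes: Sequence[GeneRecord],
    path: str | Path,
    labels: pd.DataFrame | None = None,
    width: int = 70,
) -> None:
    """Write genes as multi-FASTA CDS with an ATG start and TAA stop appended.

    Headers carry the gene id plus truth-label key=value pairs when labels
    are supplied; round-trips exactly through ``parse_cds_fasta``.
    """
    if not genes:
        raise ValueError("empty gene list")
    meta = {}
    if labels is not None:
        meta = {
            r["gene_id"]: f" label={r['label']} weight={r['weight']:.4f}"
            for _, r in labels.iterrows()
        }
    with open(path, "w") as fh:
        for g in genes:
            if g.sequence is None:
                raise ValueError(f"{g.gene_id}: no sequence to write")
            fh.write(f">{g.gene_id}{meta.get(g.gene_id, '')}\n")
            seq = "ATG" + g.sequence + "TAA"
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
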