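"""Established codon-bias statistics used as benchmarks and seed criteria.

CAI (Sharp & Li), GCB (length-normalized summed codon bias), Wright's ENC
and its background-corrected variant ENC', a per-codon Pearson chi-square of
codon usage, and Karlin's two atypicality measures (dinucleotide relative-
abundance distance and the B metric of codon-usage distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .codon_core import GeneRecord, GeneticCode, pool_counts
from .scoring_tables import CodonFrequencyTable, DeltaTable
from .ace_stats import scb

__all__ = [
    "cai",
    "cai_weights",
    "gcb",
    "enc",
    "enc_prime",
    "codon_usage_chi2",
    "GenomeSignature",
    "karlin_dinucleotide_distance",
    "karlin_b",
]

_NUCS = "ACGT"
_DINUCS = tuple(a + b for a in _NUCS for b in _NUCS)


def cai_weights(
    reference: Sequence[GeneRecord],
    code: GeneticCode,
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """Sharp-Li relative adaptiveness w_ij from a reference gene set.

    w_ij = RSCU_ij / max_j RSCU_ij, which reduces to the ratio of codon
    counts to the family's maximum count; zero counts get the pseudocount.
    """
    if not reference:
        raise ValueError("empty reference set")
    pooled = pool_counts(reference)
    w: dict[str, float] = {}
    for aa, codons in code.families.items():
        counts = [max(float(pooled.codon_counts.get(c, 0)), pseudocount) for c in codons]
        mx = max(counts)
        for c, n in zip(codons, counts):
            w[c] = n / mx
    return w


def cai(
    gene: GeneRecord,
    reference: Sequence[GeneRecord],
    code: GeneticCode,
    pseudocount: float = 0.5,
) -> float:
    """Codon Adaptation Index: geometric mean of w over the gene's codons,
    ignoring single-codon families (Met, Trp in the standard code)."""
    w = cai_weights(reference, code, pseudocount)
    log_sum = 0.0
    n = 0
    for cdn, c in gene.codon_counts.items():
        if code.synonym_count[code.codon_to_aa[cdn]] == 1:
            continue
        log_sum += c * math.log(w[cdn])
        n += c
    if n == 0:
        raise ValueError(f"{gene.gene_id}: no degenerate codons for CAI")
    return math.exp(log_sum / n)


def gcb(gene: GeneRecord, delta: DeltaTable) -> float:
    """Merkl's General Codon Bias: the SCB divided by the codon count."""
    if gene.n_codons_total == 0:
        raise ValueError(f"{gene.gene_id}: gene has no codons")
    return scb(gene, delta) / gene.n_codons_total


def _wright_f(counts: np.ndarray) -> float | None:
    """Wright's codon homozygosity F-hat for one family; None if inestimable."""
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    f = (n * float(p @ p) - 1.0) / (n - 1.0)
    return f if f > 0 else None


def _combine_enc(
    f_by_class: dict[int, list[float]], code: GeneticCode
) -> float:
    """Wright's weighted combination sum_k n_k / F-bar_k, with his averaging
    convention for missing degeneracy classes."""
    class_sizes: dict[int, int] = {}
    for aa, n_i in code.synonym_count.items():
        class_sizes[n_i] = class_sizes.get(n_i, 0) + 1
    means = {k: float(np.mean(v)) for k, v in f_by_class.items() if v}
    if not means:
        raise ValueError("too few codons to estimate any family homozygosity")
    enc_val = float(class_sizes.get(1, 0))
    for k, n_k in sorted(class_sizes.items()):
        if k == 1:
            continue
        if k in means:
            fbar = means[k]
        elif k == 3 and 2 in means and 4 in means:
            fbar = (means[2] + means[4]) / 2.0  # Wright's Ile convention
        else:
            fbar = float(np.mean(list(means.values())))
        enc_val += n_k / fbar
    return float(np.clip(enc_val, 20.0, 61.0))


def enc(gene: GeneRecord, code: GeneticCode) -> float:
    """Wright's Effective Number of Codons (2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
    in the standard code), clamped to [20, 61]."""
    f_by_class: dict[int, list[float]] = {}
    for aa, codons in code.families.items():
        if len(codons) == 1:
            continue
        counts = np.array([gene.codon_counts.get(c, 0) for c in codons], float)
        f = _wright_f(counts)
        if f is not None:
            f_by_class.setdefault(len(codons), []).append(f)
    return _combine_enc(f_by_class, code)


def enc_prime(
    gene: GeneRecord, f_n: CodonFrequencyTable, code: GeneticCode
) -> float:
    """Novembre's background-corrected ENC.

    Homozygosity is replaced by F'_i = (chi2_i + C_i - N_i) / (N_i (C_i - 1))
    where chi2_i measures the deviation of observed counts from the expected
    frequencies f_n, so a gene matching the background scores ~61.
    """
    f_by_class: dict[int, list[float]] = {}
    for aa, codons in code.families.items():
        n_i = len(codons)
        if n_i == 1:
            continue
        counts = np.array([gene.codon_counts.get(c, 0) for c in codons], float)
        c_i = counts.sum()
        if c_i < 2:
            continue
        e = c_i * np.array([f_n.freqs[c] for c in codons])
        chi2 = float(((counts - e) ** 2 / e).sum())
        f = (chi2 + c_i - n_i) / (n_i * (c_i - 1.0))
        f = min(max(f, 1.0 / n_i), 1.0)
        f_by_class.setdefault(n_i, []).append(f)
    return _combine_enc(f_by_class, code)


def codon_usage_chi2(gene: GeneRecord, f_n: CodonFrequencyTable) -> float:
    """Per-codon Pearson chi-square of within-family usage against f_n.

    Summed over amino-acid families present in the gene and divided by the
    total codon count, giving a scale-free ranking score. Single-codon
    families contribute zero to the numerator but count in the divisor.
    """
    if gene.n_codons_total == 0:
        raise ValueError(f"{gene.gene_id}: gene has no codons")
    code = f_n.code
    total = 0.0
    for aa, codons in code.families.items():
        c_i = gene.aa_counts.get(aa, 0)
        if c_i == 0 or len(codons) == 1:
            continue
        o = np.array([gene.codon_counts.get(c, 0) for c in codons], float)
        e = c_i * np.array([f_n.freqs[c] for c in codons])
        total += float(((o - e) ** 2 / e).sum())
    return total / gene.n_codons_total


# ---------------------------------------------------------------------------
# Karlin compositional atypicality


@dataclass
class GenomeSignature:
    """Mono- and dinucleotide frequencies of a sequence pool (coding strand,
    overlapping dinucleotides)."""

    mono: np.ndarray  # (4,) frequencies, ACGT order
    dinuc: np.ndarray  # (16,) frequencies, AA..TT order

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "GenomeSignature":
        mono = np.zeros(4)
        dinuc = np.zeros(16)
        idx = {b: i for i, b in enumerate(_NUCS)}
        for seq in seqs:
            s = seq.upper()
            codes = np.array([idx.get(b, -1) for b in s])
            codes = codes[codes >= 0]
            if len(codes) == 0:
                continue
            np.add.at(mono, codes, 1)
            if len(codes) >= 2:
                np.add.at(dinuc, codes[:-1] * 4 + codes[1:], 1)
        if dinuc.sum() == 0:
            raise ValueError("pooled sequence shorter than 2 nt")
        return cls(mono=mono / mono.sum(), dinuc=dinuc / dinuc.sum())

    def rho(self) -> np.ndarray:
        """Dinucleotide relative abundances rho(XY) = f(XY)/(f(X) f(Y))."""
        expected = np.outer(self.mono, self.mono).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(expected > 0, self.dinuc / expected, 0.0)
        return r


def karlin_dinucleotide_distance(
    gene: GeneRecord | str, genome: GenomeSignature
) -> float:
    """Karlin's delta* atypicality: (1/16) sum_XY |rho_gene - rho_genome|.

    Computed on the coding strand only, since inputs are strand-resolved CDS.
    """
    seq = gene if isinstance(gene, str) else gene.sequence
    if seq is None or len(seq) < 2:
        raise ValueError("gene sequence missing or shorter than 2 nt")
    sig = GenomeSignature.from_sequences([seq])
    return float(np.abs(sig.rho() - genome.rho()).mean())


def karlin_b(gene: GeneRecord, reference: CodonFrequencyTable) -> float:
    """Karlin's B codon-usage distance from a reference frequency table.

    B = sum_aa p_aa(gene) * sum_j |f_gene(cdn_ij) - f_ref(cdn_ij)|, where
    p_aa is the amino acid's share of the gene's codons. Zero iff the gene's
    within-family frequencies match the reference for every amino acid
    present; invariant to gene length at fixed frequencies.
    """
    if gene.n_codons_total == 0:
        raise ValueError(f"{gene.gene_id}: gene has no codons")
    code = reference.code
    total = 0.0
    for aa, codons in code.families.items():
        c_i = gene.aa_counts.get(aa, 0)
        if c_i == 0:
            continue
        p_aa = c_i / gene.n_codons_total
        f_gene = np.array([gene.codon_counts.get(c, 0) for c in codons]) / c_i
        f_ref = np.array([reference.freqs[c] for c in codons])
        total += p_aa * float(np.abs(f_gene - f_ref).sum())
    return total
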