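"""Deriving the two reference codon tables from genome sequence alone.

``refine_fn`` purifies the unselected background set by stripping
compositionally atypical genes (lateral transfers, strongly selected genes)
in 1% steps, stopping when the per-codon score shifts stop agreeing with the
direction established at the first step (exact binomial test against 0.5).

``seed_fo`` picks an initial candidate set of translation-optimized genes by
an a priori criterion (Translation40 gene names, low ENC/ENC', or high codon
usage chi-square), and ``iterate_fo`` refines it: every round all genes are
rescored by ACE_u against the current f_o, and the top genes are kept under
a codon budget that shrinks geometrically to the target table size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binomtest, rankdata

from .codon_core import FeatureTable, GeneRecord, GeneticCode
from .scoring_tables import (
    CodonFrequencyTable,
    DeltaTable,
    build_delta_table,
    build_frequency_table,
    table_from_counts,
)
from .ace_stats import score_genes
from . import comparators

__all__ = [
    "TRANSLATION40_GENES",
    "RefinementStep",
    "RefinementTrace",
    "IterationState",
    "refine_fn",
    "seed_fo",
    "iterate_fo",
]

# tufA, tsf, fusA, rplA-rplF, rplI-rplT, rpsB-rpsT: the 40 ribosomal-protein
# and translation-elongation genes used as an a priori optimized set.
TRANSLATION40_GENES: tuple[str, ...] = (
    ("tufA", "tsf", "fusA")
    + tuple(f"rpl{c}" for c in "ABCDEF")
    + tuple(f"rpl{c}" for c in "IJKLMNOPQRST")
    + tuple(f"rps{c}" for c in "BCDEFGHIJKLMNOPQRST")
)
assert len(TRANSLATION40_GENES) == 40


@dataclass
class RefinementStep:
    fraction_retained: float
    removed_ids: tuple[str, ...]
    directions: np.ndarray  # per-sense-codon sign of the delta shift
    n_agree: int | None
    n_compared: int | None
    p_value: float | None
    accepted: bool


@dataclass
class RefinementTrace:
    steps: list[RefinementStep]
    final_ids: tuple[str, ...]
    final_fraction: float
    stop_reason: str = ""


@dataclass
class IterationState:
    round_index: int
    gene_ids: tuple[str, ...]
    codon_total: int
    ranking: tuple[str, ...]  # all genes, best ACE_u first


# ---------------------------------------------------------------------------
# vectorized atypicality scores


class _GenePool:
    """Precomputed per-gene count matrices for fast pool-relative scoring."""

    def __init__(self, genes: Sequence[GeneRecord], code: GeneticCode, need_seq: bool):
        self.code = code
        self.cod = np.stack([g.codon_vector(code) for g in genes])
        self.aa_of = code.aa_of_codon_array()
        self.totals = self.cod.sum(axis=1)
        if need_seq:
            idx = {b: i for i, b in enumerate("ACGT")}
            n = len(genes)
            self.mono = np.zeros((n, 4))
            self.dinuc = np.zeros((n, 16))
            for i, g in enumerate(genes):
                if not g.sequence or len(g.sequence) < 2:
                    raise ValueError(
                        f"{g.gene_id}: dinucleotide criterion needs sequences"
                    )
                codes = np.array([idx[b] for b in g.sequence if b in idx])
                np.add.at(self.mono[i], codes, 1)
                np.add.at(self.dinuc[i], codes[:-1] * 4 + codes[1:], 1)

    def _rho(self, mono: np.ndarray, dinuc: np.ndarray) -> np.ndarray:
        monof = mono / mono.sum(axis=-1, keepdims=True)
        dinucf = dinuc / dinuc.sum(axis=-1, keepdims=True)
        expected = monof[..., :, None] * monof[..., None, :]
        return dinucf / expected.reshape(*expected.shape[:-2], 16)

    def dinuc_atypicality(self, mask: np.ndarray) -> np.ndarray:
        """Karlin dinucleotide distance in excess of its sampling expectation.

        Raw |rho_gene - rho_pool| scales as 1/sqrt(gene length), so short
        genes look atypical by noise alone; subtracting the half-normal
        expectation of the null distance makes ranks length-unbiased.
        """
        rho_pool = self._rho(self.mono[mask].sum(0), self.dinuc[mask].sum(0))
        rho_gene = self._rho(self.mono, self.dinuc)
        raw = np.abs(rho_gene - rho_pool).mean(axis=1)
        monof = self.mono / self.mono.sum(axis=1, keepdims=True)
        dinucf = self.dinuc / self.dinuc.sum(axis=1, keepdims=True)
        n = self.dinuc.sum(axis=1, keepdims=True)
        expected_f = (monof[:, :, None] * monof[:, None, :]).reshape(-1, 16)
        sd_rho = np.sqrt(
            np.maximum(dinucf * (1 - dinucf), 0.0) / n
        ) / np.maximum(expected_f, 1e-9)
        return raw - (np.sqrt(2 / np.pi) * sd_rho).mean(axis=1)

    def pool_freqs(self, mask: np.ndarray, pseudocount: float) -> np.ndarray:
        """Within-family frequencies of the pooled retained genes."""
        counts = self.cod[mask].sum(0)
        counts = np.where(counts > 0, counts, pseudocount)
        fam_tot = np.zeros(len(self.code.amino_acids))
        np.add.at(fam_tot, self.aa_of, counts)
        return counts / fam_tot[self.aa_of]

    def karlin_b_atypicality(
        self, mask: np.ndarray, pseudocount: float
    ) -> np.ndarray:
        """Karlin B distance in excess of its sampling expectation.

        Under multinomial sampling from the pool frequencies, a family with
        n codons has E|f_hat - p| ~= sqrt(2 p (1-p) / (pi n)) per codon
        (half-normal approximation); subtracting that expectation removes
        the strong short-gene bias of the raw B distance.
        """
        f_ref = self.pool_freqs(mask, pseudocount)
        fam_counts = np.zeros((self.cod.shape[0], len(self.code.amino_acids)))
        np.add.at(fam_counts.T, self.aa_of, self.cod.T)
        present = fam_counts[:, self.aa_of] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            f_gene = np.nan_to_num(self.cod / fam_counts[:, self.aa_of])
            null_e = np.nan_to_num(
                np.sqrt(2 * f_ref * (1 - f_ref) / (np.pi * fam_counts[:, self.aa_of]))
            )
        weight = fam_counts[:, self.aa_of] / self.totals[:, None]
        diff = np.abs(f_gene - f_ref) - null_e
        diff[~present] = 0.0
        return (weight * diff).sum(axis=1)


def refine_fn(
    genes: Sequence[GeneRecord],
    code: GeneticCode | None = None,
    step: float = 0.01,
    alpha: float = 0.05,
    criterion: str = "both",
    floor: float = 0.5,
    pseudocount: float = 0.5,
) -> tuple[list[GeneRecord], RefinementTrace]:
    """Shrink a gene set toward a selection- and transfer-free background.

    At each step the most atypical ``step`` fraction of genes (by Karlin
    dinucleotide distance, Karlin B codon-usage distance, or their combined
    rank) is removed from the pool and the per-codon scores recomputed. The
    first removal fixes the reference shift direction for each codon; later
    removals are kept only while a significant majority of codons keep
    shifting the same way (one-sided exact binomial, success prob 0.5).
    Atypicality is re-ranked against the shrinking pool, and the set never
    drops below the ``floor`` fraction.
    """
    if criterion not in {"dinucleotide", "karlin_b", "both"}:
        raise ValueError(f"unknown criterion: {criterion}")
    n = len(genes)
    if n < 200:
        raise ValueError(f"need at least 200 genes for 1% steps, got {n}")
    code = code or GeneticCode.from_ncbi_id(11)
    pool = _GenePool(genes, code, need_seq=criterion in {"dinucleotide", "both"})
    deg = np.array(
        [code.synonym_count[code.codon_to_aa[c]] > 1 for c in code.sense_codons]
    )

    def log_fn(mask: np.ndarray) -> np.ndarray:
        return np.log(pool.pool_freqs(mask, pseudocount))

    def atypicality(mask: np.ndarray) -> np.ndarray:
        if criterion == "dinucleotide":
            return pool.dinuc_atypicality(mask)
        if criterion == "karlin_b":
            return pool.karlin_b_atypicality(mask, pseudocount)
        return rankdata(pool.dinuc_atypicality(mask)) + rankdata(
            pool.karlin_b_atypicality(mask, pseudocount)
        )

    n_remove = max(1, round(step * n))
    retained = np.ones(n, bool)
    prev_log_fn = log_fn(retained)
    ref_signs: np.ndarray | None = None
    steps: list[RefinementStep] = []
    stop_reason = "floor reached"
    while retained.sum() - n_remove >= floor * n:
        scores = np.where(retained, atypicality(retained), -np.inf)
        drop = np.argsort(scores)[::-1][:n_remove]
        trial = retained.copy()
        trial[drop] = False
        new_log_fn = log_fn(trial)
        # delta = ln f_o - ln f_n, so the shift direction is -(change in ln f_n)
        directions = np.sign(prev_log_fn - new_log_fn)
        frac = trial.sum() / n
        removed = tuple(genes[i].gene_id for i in sorted(drop))
        if ref_signs is None:
            # the first 1% removal is assumed beneficial and fixes the
            # reference directions
            ref_signs = directions.copy()
            steps.append(
                RefinementStep(frac, removed, directions, None, None, None, True)
            )
            retained, prev_log_fn = trial, new_log_fn
            continue
        valid = deg & (ref_signs != 0) & (directions != 0)
        k = int((directions[valid] == ref_signs[valid]).sum())
        m = int(valid.sum())
        p = binomtest(k, m, 0.5, alternative="greater").pvalue if m else 1.0
        accepted = p < alpha
        steps.append(
            RefinementStep(frac, removed, directions, k, m, float(p), accepted)
        )
        if not accepted:
            stop_reason = "non-significant shift agreement"
            break
        retained, prev_log_fn = trial, new_log_fn
    kept = [g for g, r in zip(genes, retained) if r]
    trace = RefinementTrace(
        steps=steps,
        final_ids=tuple(g.gene_id for g in kept),
        final_fraction=retained.sum() / n,
        stop_reason=stop_reason,
    )
    return kept, trace


# ---------------------------------------------------------------------------
# selected-set seeding and iteration


def seed_fo(
    genes: Sequence[GeneRecord],
    criterion: str,
    annotations: FeatureTable | None = None,
    k: int = 40,
    f_n: CodonFrequencyTable | None = None,
    code: GeneticCode | None = None,
) -> list[GeneRecord]:
    """Pick an initial candidate set of translation-optimized genes.

    ``translation40`` matches annotated gene names against the fixed list of
    ribosomal-protein/elongation-factor genes; the comparator criteria take
    the top-k genes (low ENC or ENC', high codon-usage chi-square).
    """
    code = code or GeneticCode.from_ncbi_id(11)
    if criterion == "translation40":
        if annotations is None:
            raise ValueError("translation40 seeding requires annotations")
        wanted = set(TRANSLATION40_GENES)
        named = {f.name for f in annotations.records if f.name in wanted}
        by_id = {g.gene_id: g for g in genes}
        matched = [by_id[name] for name in sorted(named) if name in by_id]
        if not matched:
            raise ValueError("no Translation40 genes found in the input")
        if len(matched) < 20:
            warnings.warn(
                f"only {len(matched)} Translation40 genes matched", stacklevel=2
            )
        return matched
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} available genes")
    if criterion in {"enc_prime", "chi2"} and f_n is None:
        f_n = build_frequency_table(list(genes), code, role="f_n")
    if criterion == "enc":
        scored = [(comparators.enc(g, code), g) for g in genes]
        scored.sort(key=lambda t: (t[0], t[1].gene_id))
    elif criterion == "enc_prime":
        scored = [(comparators.enc_prime(g, f_n, code), g) for g in genes]
        scored.sort(key=lambda t: (t[0], t[1].gene_id))
    elif criterion == "chi2":
        scored = [(comparators.codon_usage_chi2(g, f_n), g) for g in genes]
        scored.sort(key=lambda t: (-t[0], t[1].gene_id))
    else:
        raise ValueError(f"unknown criterion: {criterion}")
    return [g for _, g in scored[:k]]


def iterate_fo(
    genes: Sequence[GeneRecord],
    seed_set: Sequence[GeneRecord],
    f_n: CodonFrequencyTable,
    target_codons: int = 10000,
    n_rounds: int = 15,
    start_fraction: float = 0.40,
    pseudocount: float = 0.5,
) -> tuple[list[GeneRecord], CodonFrequencyTable, list[IterationState]]:
    """Iteratively refine the optimized reference set.

    Round 0 builds f_o from the seed. Each subsequent round scores ALL genes
    by ACE_u against (current f_o, fixed f_n) and fills a codon budget with
    the top-ranked genes; budgets interpolate geometrically from
    ``start_fraction`` of the genome's codons down to ``target_codons``.
    Re-entry of previously dropped genes is allowed since every round
    rescores the whole genome. Ties break by gene id for reproducibility.
    """
    if not seed_set:
        raise ValueError("empty seed set")
    code = f_n.code
    genes = list(genes)
    seed_codons = sum(g.n_codons_total for g in seed_set)
    if target_codons >= seed_codons:
        raise ValueError(
            f"target_codons={target_codons} is not below the seed's "
            f"{seed_codons} codons"
        )
    total_codons = sum(g.n_codons_total for g in genes)
    start_budget = start_fraction * total_codons
    if start_budget <= target_codons:
        raise ValueError("start budget does not exceed the target table size")

    f_o = build_frequency_table(
        list(seed_set), code, role="f_o", pseudocount=pseudocount, source="seed"
    )
    current_ids = tuple(g.gene_id for g in seed_set)
    states = [
        IterationState(0, current_ids, seed_codons, tuple(sorted(current_ids)))
    ]
    by_id = {g.gene_id: g for g in genes}
    final_set: list[GeneRecord] = list(seed_set)
    max_extra = 10  # post-schedule rounds at the target budget
    r = 0
    while True:
        r += 1
        if r > n_rounds + max_extra:
            warnings.warn(
                "iteration did not stabilize; returning the last state",
                stacklevel=2,
            )
            break
        delta = build_delta_table(f_o, f_n)
        if np.abs(delta.as_array()).max() < 1e-9:
            raise ValueError(
                "degenerate iteration: f_o equals f_n, all delta scores are 0"
            )
        budget = start_budget * (target_codons / start_budget) ** (
            min(r, n_rounds) / n_rounds
        )
        df = score_genes(genes, delta, f_n)
        df = df.sort_values(
            ["ace_u", "gene_id"], ascending=[False, True], na_position="last"
        )
        picked: list[str] = []
        acc = 0
        for gid, n_cod in zip(df["gene_id"], df["n_codons"]):
            if acc >= budget:
                break
            picked.append(gid)
            acc += n_cod
        final_set = [by_id[gid] for gid in picked]
        f_o = build_frequency_table(
            final_set,
            code,
            role="f_o",
            pseudocount=pseudocount,
            source=f"iteration round {r}",
        )
        previous_ids, current_ids = current_ids, tuple(picked)
        states.append(
            IterationState(r, current_ids, acc, tuple(df["gene_id"]))
        )
        if r >= n_rounds and set(current_ids) == set(previous_ids):
            break
    return final_set, f_o, states
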