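"""The ACE statistical core.

A gene's Summed Codon Bias (SCB) is the sum of per-codon adaptiveness scores
delta over all its codons. Under the null model — codon identities drawn
independently within each amino-acid family from the unselected frequencies
P_ij = f_n(cdn_ij), conditional on the gene's amino-acid counts C_i — the SCB
has analytic moments:

    E[SCB]   = sum_i C_i * mu_i,          mu_i    = sum_j P_ij * delta_ij
    Var[SCB] = sum_i C_i * (sum_j P_ij * delta_ij^2 - mu_i^2)

The Adaptive Codon Enrichment is ACE = SCB - E[SCB]; ACE_z standardizes by
the null standard deviation, and ACE_u normalizes per informative codon by
dividing by sum_i C_i * sigma_i (each family weighted by the null standard
deviation it contributes). Squared Z-scores averaged over a gene set give the
genome-wide ACE chi-square, which equals 1.0 in the absence of codon
selection.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import GeneRecord, GeneticCode
from .scoring_tables import CodonFrequencyTable, DeltaTable

__all__ = [
    "AceResult",
    "GenomeSummary",
    "NullSample",
    "scb",
    "null_moments",
    "ace_scores",
    "error_variance",
    "gene_ttest",
    "genome_chi2",
    "monte_carlo_null",
    "normality_check",
    "score_genes",
]

_VAR_TOL = 1e-12


@dataclass
class AceResult:
    """Per-gene ACE statistics; ``ace_z``/``ace_u`` are None when the null
    variance is zero (e.g. f_o = f_n, or a gene of only Met/Trp codons)."""

    gene_id: str
    scb: float
    expected_scb: float
    variance_scb: float
    ace: float
    ace_z: float | None
    ace_u: float | None
    error_variance: float
    n_informative: int
    n_codons: int
    u_denominator: float = 0.0

    @property
    def defined(self) -> bool:
        return self.ace_z is not None

    @property
    def ace_u_error_variance(self) -> float | None:
        """Error variance on the ACE_u scale (for between-gene t-tests)."""
        if self.u_denominator <= 0:
            return None
        return self.error_variance / self.u_denominator**2


@dataclass
class GenomeSummary:
    """Gene-set-level ACE chi-square: the mean squared per-gene Z-score."""

    ace_chi2: float
    n_genes: int
    z_scores: list[float]
    departure_z: float
    source: str = ""


@dataclass
class NullSample:
    gene_id: str
    scb_values: np.ndarray
    seed: int
    mean: float = field(init=False)
    variance: float = field(init=False)
    skewness: float = field(init=False)
    kurtosis: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.scb_values))
        self.variance = float(np.var(self.scb_values, ddof=1))
        if np.ptp(self.scb_values) == 0:  # degenerate; moments undefined
            self.skewness = float("nan")
            self.kurtosis = float("nan")
        else:
            self.skewness = float(stats.skew(self.scb_values))
            self.kurtosis = float(stats.kurtosis(self.scb_values))


# ---------------------------------------------------------------------------
# family-level moment arrays


def _family_moments(
    delta: DeltaTable, f_n: CodonFrequencyTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-amino-acid (mu_i, var_i, sigma_i) under the null P_ij = f_n."""
    code = delta.code
    d = delta.as_array()
    p = f_n.as_array()
    aa_of = code.aa_of_codon_array()
    n_aa = len(code.amino_acids)
    mu = np.zeros(n_aa)
    e2 = np.zeros(n_aa)
    np.add.at(mu, aa_of, p * d)
    np.add.at(e2, aa_of, p * d * d)
    var = np.clip(e2 - mu * mu, 0.0, None)
    return mu, var, np.sqrt(var)


def scb(gene: GeneRecord, delta: DeltaTable) -> float:
    """Summed Codon Bias: sum over amino acids of alpha_i = sum_j C_ij delta_ij."""
    if gene.n_codons_total == 0:
        raise ValueError(f"{gene.gene_id}: gene has no codons")
    return float(gene.codon_vector(delta.code) @ delta.as_array())


def null_moments(
    gene: GeneRecord, delta: DeltaTable, f_n: CodonFrequencyTable
) -> tuple[float, float]:
    """Analytic null expectation and variance of the SCB given C_i."""
    mu, var, _ = _family_moments(delta, f_n)
    c = gene.aa_vector(delta.code)
    return float(c @ mu), float(c @ var)


def ace_scores(
    gene: GeneRecord, delta: DeltaTable, f_n: CodonFrequencyTable
) -> AceResult:
    """All per-gene ACE statistics in one pass.

    Zero null variance is a signal, not a crash: ACE is still reported (it is
    0 when delta is identically 0) and the normalized forms are None.
    """
    code = delta.code
    mu, var, sigma = _family_moments(delta, f_n)
    c = gene.aa_vector(code)
    observed = scb(gene, delta)
    expected = float(c @ mu)
    variance = float(c @ var)
    ace = observed - expected
    denom = float(c @ sigma)
    informative = int(c[sigma > 0].sum())
    if variance > _VAR_TOL:
        ace_z = ace / math.sqrt(variance)
        ace_u = ace / denom
    else:
        ace_z = ace_u = None
    return AceResult(
        gene_id=gene.gene_id,
        scb=observed,
        expected_scb=expected,
        variance_scb=variance,
        ace=ace,
        ace_z=ace_z,
        ace_u=ace_u,
        error_variance=error_variance(gene, delta),
        n_informative=informative,
        n_codons=gene.n_codons_total,
        u_denominator=denom,
    )


def error_variance(gene: GeneRecord, delta: DeltaTable) -> float:
    """Sampling-error variance of a gene's ACE.

    The null-variance formula evaluated with P_ij set to the gene's own
    observed within-family codon frequencies: the variance the SCB would show
    if the gene's usage were the true underlying frequencies. Divide by the
    square of the ACE_u denominator for the ACE_u-scale error variance.
    """
    if gene.n_codons_total == 0:
        raise ValueError(f"{gene.gene_id}: gene has no codons")
    code = delta.code
    total = 0.0
    for aa, codons in code.families.items():
        c_i = gene.aa_counts.get(aa, 0)
        if c_i == 0 or len(codons) == 1:
            continue
        p_obs = np.array([gene.codon_counts.get(c, 0) for c in codons]) / c_i
        d = np.array([delta.delta[c] for c in codons])
        mu = float(p_obs @ d)
        total += c_i * (float(p_obs @ (d * d)) - mu * mu)
    return max(total, 0.0)


def gene_ttest(a: AceResult, b: AceResult) -> tuple[float, float]:
    """Two-sample t-test on ACE_u values using their error variances.

    Welch-style: t = (u_a - u_b)/sqrt(v_a + v_b) with Welch-Satterthwaite
    degrees of freedom, per-gene df = n_informative - 1.
    """
    for r in (a, b):
        if r.ace_u is None:
            raise ValueError(f"{r.gene_id}: ACE_u undefined (zero null variance)")
    va, vb = a.ace_u_error_variance, b.ace_u_error_variance
    if va is None or vb is None or va + vb <= 0:
        if a.ace_u == b.ace_u:
            return 0.0, 1.0
        raise ValueError("non-positive error variance with unequal ACE_u")
    t = (a.ace_u - b.ace_u) / math.sqrt(va + vb)
    df_a = max(a.n_informative - 1, 1)
    df_b = max(b.n_informative - 1, 1)
    df = (va + vb) ** 2 / (va**2 / df_a + vb**2 / df_b)
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def genome_chi2(results: list[AceResult], source: str = "") -> GenomeSummary:
    """Mean squared ACE_z over a gene set (Eq.-style normalized chi-square).

    Also reports the departure from the no-selection value 1.0 as a Z
    statistic using the chi-square(1) sampling variance of 2 per gene:
    Z = (ACEchi2 - 1) * sqrt(n/2).
    """
    if not results:
        raise ValueError("empty result list")
    undefined = [r.gene_id for r in results if r.ace_z is None]
    if undefined:
        raise ValueError(
            f"{len(undefined)} gene(s) with undefined ACE_z, e.g. {undefined[0]}"
        )
    z = np.array([r.ace_z for r in results])
    chi2 = float(np.mean(z**2))
    departure = (chi2 - 1.0) * math.sqrt(len(z) / 2.0)
    return GenomeSummary(
        ace_chi2=chi2,
        n_genes=len(z),
        z_scores=z.tolist(),
        departure_z=departure,
        source=source,
    )


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    # per-gene stream keyed by a stable hash so results do not depend on
    # iteration order
    return np.random.default_rng([seed, zlib.crc32(gene_id.encode())])


def monte_carlo_null(
    gene: GeneRecord,
    delta: DeltaTable,
    f_n: CodonFrequencyTable,
    n_reps: int = 2000,
    seed: int = 0,
) -> NullSample:
    """Resample the gene's codons within families from P_ij = f_n.

    Amino-acid counts are held fixed (the same conditioning as the analytic
    moments); replicate SCBs are deterministic under a fixed seed.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    code = delta.code
    rng = _gene_rng(seed, gene.gene_id)
    reps = np.zeros(n_reps)
    for aa, codons in code.families.items():
        c_i = gene.aa_counts.get(aa, 0)
        if c_i == 0:
            continue
        p = np.array([f_n.freqs[c] for c in codons])
        d = np.array([delta.delta[c] for c in codons])
        draws = rng.multinomial(c_i, p / p.sum(), size=n_reps)
        reps += draws @ d
    return NullSample(gene_id=gene.gene_id, scb_values=reps, seed=seed)


def normality_check(sample: NullSample) -> tuple[float, float, float, float]:
    """D'Agostino-Pearson omnibus normality test on the replicate SCBs.

    Returns (skewness, excess kurtosis, K-squared, p-value).
    """
    x = sample.scb_values
    if len(x) < 20:
        raise ValueError("normality check needs at least 20 replicates")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) null sample")
    k2, p = stats.normaltest(x)
    return sample.skewness, sample.kurtosis, float(k2), float(p)


# ---------------------------------------------------------------------------
# vectorized batch scoring (used by genome summaries and the iteration
# algorithms; numerically identical to the per-gene path)


def score_genes(
    genes: list[GeneRecord],
    delta: DeltaTable,
    f_n: CodonFrequencyTable,
) -> pd.DataFrame:
    """Score a gene list in one pass; one row per gene.

    Columns: gene_id, n_codons, n_informative, scb, expected_scb,
    variance_scb, ace, ace_z, ace_u, error_variance (NaN z/u where the null
    variance is zero).
    """
    code = delta.code
    d = delta.as_array()
    mu, var, sigma = _family_moments(delta, f_n)
    aa_of = code.aa_of_codon_array()

    cod = np.stack([g.codon_vector(code) for g in genes])  # (n, 61)
    caa = np.stack([g.aa_vector(code) for g in genes])  # (n, 20)

    observed = cod @ d
    expected = caa @ mu
    variance = caa @ var
    denom = caa @ sigma
    ace = observed - expected
    with np.errstate(divide="ignore", invalid="ignore"):
        ace_z = np.where(variance > _VAR_TOL, ace / np.sqrt(variance), np.nan)
        ace_u = np.where(variance > _VAR_TOL, ace / denom, np.nan)

    # error variance: within-family moments under each gene's observed freqs
    fam_counts = np.zeros((len(genes), len(code.amino_acids)))
    np.add.at(fam_counts.T, aa_of, cod.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = cod / fam_counts[:, aa_of]
    p_obs = np.nan_to_num(p_obs)
    mu_obs = np.zeros((len(genes), len(code.amino_acids)))
    e2_obs = np.zeros_like(mu_obs)
    np.add.at(mu_obs.T, aa_of, (p_obs * d).T)
    np.add.at(e2_obs.T, aa_of, (p_obs * d * d).T)
    err = np.clip((caa * np.clip(e2_obs - mu_obs**2, 0, None)).sum(axis=1), 0, None)

    informative = caa[:, sigma > 0].sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "n_codons": [g.n_codons_total for g in genes],
            "n_informative": informative,
            "scb": observed,
            "expected_scb": expected,
            "variance_scb": variance,
            "ace": ace,
            "ace_z": ace_z,
            "ace_u": ace_u,
            "error_variance": err,
        }
    )
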