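# Methods notes

This note records the modeling assumptions, parameter choices and numerical
conventions behind `codonace`, at the level of detail a user needs to judge
what results do and do not mean.

## The stochastic null model

All ACE statistics condition on each gene's amino-acid counts `C_i` and
treat the codon identity at every site as an independent draw from the
within-family background frequencies `P_ij = f_n(cdn_ij)`. Expectation and
variance of the summed score follow directly (sums of independent per-site
terms); the Z-score `ACE_z` relies on the central limit theorem across
sites. The approximation is excellent for genes with ≥ 100 degenerate
codons and degrades for very short genes or extremely skewed backgrounds —
the `monte_carlo_null` / `normality_check` pair (codon resampling within
families, D'Agostino–Pearson K² omnibus test) exists to diagnose exactly
this. The Monte Carlo holds amino-acid composition fixed, matching the
conditioning of the analytic moments.

What the null deliberately ignores: codon–codon dependence along the
sequence, site-to-site variation in selection strength, amino-acid
composition as a random quantity, and strand- or position-specific
mutational heterogeneity. These are properties of real genomes that the
framework treats as either negligible or out of scope; consequently a
significant `ACE_z` says "usage departs from the background table", not
"translational selection specifically caused it".

## Normalizations

* `delta = ln(f_o/f_n)` uses natural logarithms. No downstream statistic
  depends on the base (it rescales `SCB`, `E[SCB]` and the `ACE_u`
  denominator identically and cancels in `ACE_z`).
* The `ACE_u` denominator is the scalar `Σ_i C_i σ_i`. This form is the one
  consistent with defining an `ACE_u` error variance as the ACE error
  variance divided by the square of that denominator, which is how the
  between-gene t-test is built. A per-family average of individual Z-values
  would differ whenever the σ_i differ and would not compose with that
  error-variance definition, so it is not offered.
* `genome_chi2` reports a departure statistic
  `Z = (ACEχ² − 1)·sqrt(n/2)`, using Var(χ²₁) = 2 per gene under the null.
* Zero null variance (identical tables, or a gene of only Met/Trp codons)
  yields `ACE = 0` with `ace_z`/`ace_u` undefined (`None`/NaN) rather than
  an exception or NaN propagation: it is a signal that the gene carries no
  information about codon selection.
* Display tables (per-family maximum shown as 1.000) are presentation-only;
  δ columns are max-normalized on exp(δ), which is monotone and sign-free.
  All computation uses raw frequencies.

## Tables and pseudocounts

Frequency tables are normalized within amino-acid families; the three
six-codon families (Leu, Ser, Arg) are single families, grouped by encoded
residue rather than codon box. Codons absent from a source gene set receive
a pseudocount of 0.5 before normalization — applied to any table, not only
`f_o`: genome-scale `f_n` sets rarely need it, but small custom background
sets do, and the statistics require strictly positive frequencies. A
degenerate family with no observations at all is an error rather than a
pseudocount-only estimate. Parsing drops the first codon of every CDS
positionally (non-ATG starts would otherwise distort Val/Leu counts), drops
a terminal stop, and is strict by default: frame errors and internal stops
reject the record, because silent truncation can hide frame corruption.
Lenient mode truncates/skips with flags instead.

## Reference-set algorithms

**Background refinement (`refine_fn`).** Atypicality can be measured by
Karlin's dinucleotide distance δ* (coding strand only, since inputs are
strand-resolved CDS), Karlin's B codon-usage distance against the pool, or
their combined rank. Both raw distances scale like 1/√(gene length), so
short genes dominate raw rankings by noise alone; the ranking therefore
uses each distance **in excess of its half-normal sampling expectation**
(`E|f̂−p| ≈ sqrt(2p(1−p)/(πn))` per codon, and the analogous expression for
ρ), which removes the length bias without changing what the statistic
measures. Atypicality is re-ranked against the shrinking pool at every
step, since the pool average itself is being purified. The first 1% removal
is accepted by assumption and fixes each codon's reference shift direction;
note that for any fixed `f_o`, the direction of a δ shift equals minus the
shift of `ln f_n`, so the choice of `f_o` cancels and the algorithm needs
no optimized table. Subsequent removals are kept while a one-sided exact
binomial test (success probability 0.5, over degenerate codons with
non-zero shifts) gives p < α = 0.05. A floor of 50% of genes prevents
runaway removal. Note the dinucleotide criterion targets dinucleotide
*association* atypicality; gene classes that differ mainly in mononucleotide
(GC) composition are better caught by the codon-usage criterion, because ρ
normalizes mononucleotide frequencies out.

**Optimized-set iteration (`iterate_fo`).** Seeds: the fixed list of 40
translation genes (tufA, tsf, fusA, rplA–rplF, rplI–rplT, rpsB–rpsT)
matched by annotated gene name, or the top-k genes by low ENC, low ENC', or
high per-codon codon-usage χ². Each round rescoring covers **all** genes
(dropped genes may re-enter), ranked by `ACE_u` with ties broken by gene id
for bit-reproducibility; the codon budget interpolates geometrically from
40% of the genome's codons down to the 10 000-codon target across 15
rounds (geometric, to avoid cliff effects from linear schedules), then
continues at the target budget (up to 10 extra rounds) until the selected
set repeats; failure to stabilize returns the last state with a warning. A
seed whose table equals `f_n` (e.g. the whole genome) makes every δ zero
and is rejected as degenerate.

## Comparators

* CAI: Sharp–Li weights `w_ij = count_ij / max_j count_ij` from the pooled
  reference (0.5 for zero counts), geometric mean over the gene's codons
  excluding single-codon families; accumulated in log space to avoid
  underflow on long genes.
* ENC: Wright's estimator `Σ_k n_k / F̄_k` with per-family homozygosity
  `F̂ = (nΣp̂² − 1)/(n − 1)`, families grouped by degeneracy (2/9, 3/1, 4/5,
  6/3 in the standard code, with the six-codon families as single
  families); a missing 3-fold class is imputed as (F̄₂+F̄₄)/2, other missing
  classes by the mean of available class averages; clamped to [20, 61].
* ENC': Novembre's correction, `F' = (χ² + C − N)/(N(C − 1))` with χ²
  against the `f_n` expectations, `F'` clamped to [1/N, 1].
* Codon-usage χ²: Pearson χ² of within-family counts against `C_i·P_ij`,
  divided by total codons (single-codon families contribute only to the
  divisor), giving a length-free ranking score.
* Karlin δ*: `(1/16)Σ|ρ_gene − ρ_ref|` with `ρ(XY) = f(XY)/(f(X)f(Y))`,
  overlapping dinucleotides, coding strand only — a deliberate divergence
  from whole-genome signature practice (which symmetrizes strands) because
  the inputs here are CDS.
* Karlin B: `Σ_aa p_aa Σ_j |f_gene − f_ref|` with `p_aa` the amino acid's
  share of the gene's codons.

## Synthetic genomes

The generator embodies the null model itself: amino acids iid from a fixed
composition (default: an E. coli-like proteome profile), codons iid within
families from a class table, lengths from a truncated log-normal (mean 300
codons, σ = 0.45, bounds [50, 1500] — matching real ORF length skew; σ = 0
gives fixed lengths). Default tables, chosen once as field-realistic
conditions: the background weights codons by `exp(0.4·#AT)` within families
(AT-mutational bias, ≈ 2.2:1 between extreme codons of a 2-fold family);
the selected table gives one preferred codon (C-ending, else G-ending) 6:1
weight (≈ 86% optimal usage, like ribosomal proteins of fast growers); the
alien class reweights the background by `exp(1.0·#GC)`, emulating the
compositional shift of recently transferred genes. Gradient mode mixes
background and selected tables with a per-gene uniform weight.

What passing tests on these genomes do **not** show: robustness to
codon–codon correlation, isochores/strand asymmetry, amino-acid usage
covarying with expression, or annotation errors — none of which the
generator produces. They validate the statistical machinery (calibration,
moments, recovery of planted structure), not performance on any particular
real genome.

## Problem sizes and determinism

The shipped experiments use 300–1000-gene genomes and 300-codon genes:
large enough that the null ACEχ² standard error (√(2/n)) is a few percent,
small enough to run interactively. Calibration uses 1000 × 300 fixed-length
genes. All randomness flows from one integer seed; per-gene Monte Carlo
streams are keyed by a CRC of the gene id so results are independent of
iteration order. Between-gene t-tests use Welch–Satterthwaite degrees of
freedom with per-gene df = (informative codons − 1).

## Known limitations

* `f_n`/`f_o` quality bounds everything; the refinement algorithms reduce
  but cannot remove estimation error in the tables, and `ACE_z` treats the
  tables as known constants.
* The normal approximation is unreliable below ~100 degenerate codons
  (use the Monte Carlo machinery there).
* ENC/ENC' use amino-acid families rather than codon boxes; values are not
  numerically interchangeable with box-based implementations, though
  orderings agree.
* The CLI handles user-supplied expression tables but ships no expression
  or divergence datasets; ortholog detection, dS estimation and tRNA-pool
  modeling are out of scope.
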