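"""ACE statistics: frozen toy values, brute-force oracles, null calibration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from codonace import (
    GeneRecord,
    SyntheticSpec,
    ace_scores,
    build_delta_table,
    error_variance,
    gene_ttest,
    generate,
    genome_chi2,
    monte_carlo_null,
    normality_check,
    null_moments,
    scb,
    score_genes,
)
from codonace.ace_stats import NullSample

from conftest import make_table, random_table


# frozen values for the shared Lys toy, hand-verified:
#   delta(AAA) = ln(0.5/0.75), delta(AAG) = ln(2); gene = 2xAAA + 2xAAG
TOY_SCB = 2 * math.log(2 / 3) + 2 * math.log(2)  # 0.57536...
TOY_EXPECTED = 4 * (0.75 * math.log(2 / 3) + 0.25 * math.log(2))  # -0.52325...
_TOY_MU = 0.75 * math.log(2 / 3) + 0.25 * math.log(2)
TOY_VARIANCE = 4 * (
    0.75 * math.log(2 / 3) ** 2 + 0.25 * math.log(2) ** 2 - _TOY_MU**2
)  # 0.90521...


def brute_force_moments(gene, delta, f_n, code):
    """Exhaustive enumeration of every codon assignment of the gene.

    Independent of the analytic path: sums p(assignment) * SCB(assignment)
    over the full product space of within-family codon choices.
    """
    sites = []
    for aa, c_i in sorted(gene.aa_counts.items()):
        sites.extend([aa] * c_i)
    e1 = e2 = 0.0
    for combo in itertools.product(*(code.families[aa] for aa in sites)):
        p = math.prod(f_n.freqs[c] for c in combo)
        s = sum(delta.delta[c] for c in combo)
        e1 += p * s
        e2 += p * s * s
    return e1, e2 - e1 * e1


class TestWorkedToy:
    def test_scb(self, lys_toy):
        assert scb(lys_toy.gene, lys_toy.delta) == pytest.approx(TOY_SCB, abs=1e-12)
        assert TOY_SCB == pytest.approx(0.5754, abs=1e-4)

    def test_null_moments(self, lys_toy):
        e, v = null_moments(lys_toy.gene, lys_toy.delta, lys_toy.f_n)
        assert e == pytest.approx(TOY_EXPECTED, abs=1e-12)
        assert v == pytest.approx(TOY_VARIANCE, abs=1e-12)
        assert e == pytest.approx(-0.5232, abs=1e-4)
        assert v == pytest.approx(0.9053, abs=1e-4)

    def test_ace_scores(self, lys_toy):
        r = ace_scores(lys_toy.gene, lys_toy.delta, lys_toy.f_n)
        assert r.ace == pytest.approx(TOY_SCB - TOY_EXPECTED, abs=1e-12)
        assert r.ace == pytest.approx(1.0986, abs=1e-4)
        assert r.ace_z == pytest.approx(r.ace / math.sqrt(TOY_VARIANCE), abs=1e-12)
        assert r.ace_z == pytest.approx(1.1547, abs=1e-4)
        assert r.ace_u == pytest.approx(1.0986 / (4 * math.sqrt(TOY_VARIANCE / 4)), abs=1e-4)
        assert r.ace_u == pytest.approx(0.5774, abs=1e-4)
        assert r.n_informative == 4

    def test_error_variance(self, lys_toy):
        # observed Lys frequencies are 0.5/0.5
        da, dg = math.log(2 / 3), math.log(2)
        hand = 4 * (0.5 * da**2 + 0.5 * dg**2 - (0.5 * da + 0.5 * dg) ** 2)
        ev = error_variance(lys_toy.gene, lys_toy.delta)
        assert ev == pytest.approx(hand, abs=1e-12)
        assert ev == pytest.approx(1.2069, abs=1e-4)


class TestDegenerateInputs:
    def test_identical_tables_give_zero_scb_and_undefined_z(self, code, lys_toy):
        f = make_table(code, {}, "f_n")
        d = build_delta_table(f, f)
        assert scb(lys_toy.gene, d) == 0.0
        assert null_moments(lys_toy.gene, d, f) == (0.0, 0.0)
        r = ace_scores(lys_toy.gene, d, f)
        assert r.ace == 0.0 and r.ace_z is None and r.ace_u is None

    def test_met_only_gene(self, lys_toy):
        gene = GeneRecord("met", {"ATG": 10}, {"M": 10}, 10)
        assert scb(gene, lys_toy.delta) == 0.0
        r = ace_scores(gene, lys_toy.delta, lys_toy.f_n)
        assert r.ace == 0.0 and r.ace_z is None

    def test_empty_gene_errors(self, lys_toy):
        with pytest.raises(ValueError, match="no codons"):
            scb(GeneRecord("x", {}, {}, 0), lys_toy.delta)

    def test_gene_at_exact_expectation_has_zero_ace(self, code):
        f_n = make_table(code, {"AAA": 0.75, "AAG": 0.25}, "f_n")
        f_o = make_table(code, {"AAA": 0.5, "AAG": 0.5}, "f_o")
        d = build_delta_table(f_o, f_n)
        gene = GeneRecord("e", {"AAA": 3, "AAG": 1}, {"K": 4}, 4)
        r = ace_scores(gene, d, f_n)
        assert r.ace == pytest.approx(0.0, abs=1e-12)


class TestMetTrpIndifference:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 500))
    def test_adding_met_trp_changes_nothing(self, code, seed, n_extra):
        rng = np.random.default_rng(seed)
        f_n = random_table(rng, code)
        d = build_delta_table(random_table(rng, code, "f_o"), f_n)
        gene = GeneRecord("g", {"AAA": 2, "AAG": 2, "GGT": 3}, {"K": 4, "G": 3}, 7)
        base = ace_scores(gene, d, f_n)
        padded = GeneRecord(
            "g+met",
            dict(gene.codon_counts, ATG=n_extra, TGG=n_extra),
            dict(gene.aa_counts, M=n_extra, W=n_extra),
            gene.n_codons_total + 2 * n_extra,
        )
        out = ace_scores(padded, d, f_n)
        assert out.ace == pytest.approx(base.ace, abs=1e-12)
        assert out.ace_z == pytest.approx(base.ace_z, abs=1e-12)
        assert out.ace_u == pytest.approx(base.ace_u, abs=1e-12)
        assert out.error_variance == pytest.approx(base.error_variance, abs=1e-12)
        assert out.n_informative == base.n_informative


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "counts",
        [
            {"AAA": 2, "AAG": 1, "GGT": 2, "GGC": 1, "TTT": 2},  # 8 degenerate
            {"CTG": 2, "CTT": 1, "ATT": 2, "CAA": 1, "CAG": 2},  # 8 degenerate
            {"AAA": 3, "CCG": 2, "CCA": 1, "TGG": 2, "ATG": 1},  # Met/Trp mixed in
        ],
    )
    def test_enumeration_matches_analytic_moments(self, code, counts):
        aa_counts: dict[str, int] = {}
        for cdn, n in counts.items():
            aa = code.codon_to_aa[cdn]
            aa_counts[aa] = aa_counts.get(aa, 0) + n
        gene = GeneRecord("bf", counts, aa_counts, sum(counts.values()))
        rng = np.random.default_rng(99)
        f_n = random_table(rng, code)
        d = build_delta_table(random_table(rng, code, "f_o"), f_n)
        e_brute, v_brute = brute_force_moments(gene, d, f_n, code)
        e, v = null_moments(gene, d, f_n)
        assert e == pytest.approx(e_brute, abs=1e-10)
        assert v == pytest.approx(v_brute, abs=1e-10)

    def test_exactness_ace_equals_scb_minus_expectation(self, code):
        rng = np.random.default_rng(17)
        for _ in range(20):
            f_n = random_table(rng, code)
            d = build_delta_table(random_table(rng, code, "f_o"), f_n)
            counts = {
                c: int(rng.integers(0, 5))
                for c in rng.choice(code.sense_codons, 12, replace=False)
            }
            counts = {c: n for c, n in counts.items() if n}
            if not counts:
                continue
            aa_counts: dict[str, int] = {}
            for cdn, n in counts.items():
                aa = code.codon_to_aa[cdn]
                aa_counts[aa] = aa_counts.get(aa, 0) + n
            gene = GeneRecord("r", counts, aa_counts, sum(counts.values()))
            r = ace_scores(gene, d, f_n)
            assert r.ace == r.scb - r.expected_scb  # exact identity


class TestMonteCarlo:
    def test_toy_mc_matches_analytic_moments(self, lys_toy):
        ns = monte_carlo_null(lys_toy.gene, lys_toy.delta, lys_toy.f_n, 2000, seed=1)
        se_mean = math.sqrt(TOY_VARIANCE / 2000)
        assert abs(ns.mean - TOY_EXPECTED) < 3 * se_mean
        assert abs(ns.variance - TOY_VARIANCE) < 0.1 * TOY_VARIANCE

    def test_larger_gene_mc_within_3_se(self, code):
        rng = np.random.default_rng(2)
        f_n = random_table(rng, code)
        d = build_delta_table(random_table(rng, code, "f_o"), f_n)
        counts = {c: int(rng.integers(1, 20)) for c in code.sense_codons}
        aa_counts: dict[str, int] = {}
        for cdn, n in counts.items():
            aa = code.codon_to_aa[cdn]
            aa_counts[aa] = aa_counts.get(aa, 0) + n
        gene = GeneRecord("big", counts, aa_counts, sum(counts.values()))
        e, v = null_moments(gene, d, f_n)
        ns = monte_carlo_null(gene, d, f_n, 2000, seed=5)
        assert abs(ns.mean - e) < 3 * math.sqrt(v / 2000)
        # sampling SE of a variance estimate ~ v * sqrt(2/(n-1))
        assert abs(ns.variance - v) < 3 * v * math.sqrt(2 / 1999)

    def test_identical_tables_give_all_zero_replicates(self, code, lys_toy):
        f = make_table(code, {}, "f_n")
        d = build_delta_table(f, f)
        ns = monte_carlo_null(lys_toy.gene, d, f, 50, seed=3)
        assert np.all(ns.scb_values == 0.0)

    def test_same_seed_reproduces_replicates(self, lys_toy):
        a = monte_carlo_null(lys_toy.gene, lys_toy.delta, lys_toy.f_n, 100, seed=7)
        b = monte_carlo_null(lys_toy.gene, lys_toy.delta, lys_toy.f_n, 100, seed=7)
        assert np.array_equal(a.scb_values, b.scb_values)

    def test_too_few_replicates_error(self, lys_toy):
        with pytest.raises(ValueError):
            monte_carlo_null(lys_toy.gene, lys_toy.delta, lys_toy.f_n, 1, seed=0)


class TestMonotonicity:
    def test_swapping_to_preferred_codon_increases_all_scores(self, lys_toy):
        # replace one AAA (delta<0) by AAG (delta>0)
        worse = ace_scores(lys_toy.gene, lys_toy.delta, lys_toy.f_n)
        better_gene = GeneRecord("G2", {"AAA": 1, "AAG": 3}, {"K": 4}, 4)
        better = ace_scores(better_gene, lys_toy.delta, lys_toy.f_n)
        assert better.scb > worse.scb
        assert better.ace > worse.ace
        assert better.ace_z > worse.ace_z
        assert better.ace_u > worse.ace_u


class TestErrorVarianceProperties:
    def test_single_codon_per_family_gives_zero(self, lys_toy):
        gene = GeneRecord("mono", {"AAA": 5, "GGT": 4}, {"K": 5, "G": 4}, 9)
        assert error_variance(gene, lys_toy.delta) == 0.0

    def test_doubling_counts_doubles_error_variance(self, lys_toy):
        g1 = lys_toy.gene
        g2 = GeneRecord("G1x2", {"AAA": 4, "AAG": 4}, {"K": 8}, 8)
        assert error_variance(g2, lys_toy.delta) == pytest.approx(
            2 * error_variance(g1, lys_toy.delta), abs=1e-12
        )


class TestGeneTtest:
    def test_identical_genes(self, lys_toy):
        r = ace_scores(lys_toy.gene, lys_toy.delta, lys_toy.f_n)
        t, p = gene_ttest(r, r)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_undefined_ace_u_errors(self, code, lys_toy):
        f = make_table(code, {}, "f_n")
        d = build_delta_table(f, f)
        r0 = ace_scores(lys_toy.gene, d, f)
        r1 = ace_scores(lys_toy.gene, lys_toy.delta, lys_toy.f_n)
        with pytest.raises(ValueError, match="undefined"):
            gene_ttest(r0, r1)

    def test_planted_difference_detected_and_matches_permutation_oracle(self, code):
        # two 500-codon genes with genuinely different synonymous usage
        from codonace.synthetic_genomes import (
            default_null_table,
            default_selected_table,
        )

        f_n = default_null_table(code)
        f_o = default_selected_table(code)
        d = build_delta_table(f_o, f_n)
        rng = np.random.default_rng(42)

        def sample_gene(name, table, n=500):
            counts: dict[str, int] = {}
            aa_counts: dict[str, int] = {}
            aas = [a for a in code.amino_acids if code.synonym_count[a] > 1]
            per = n // len(aas)
            for aa in aas:
                fam = code.families[aa]
                p = np.array([table.freqs[c] for c in fam])
                draws = rng.multinomial(per, p / p.sum())
                aa_counts[aa] = per
                for cdn, k in zip(fam, draws):
                    if k:
                        counts[cdn] = int(k)
            return GeneRecord(name, counts, aa_counts, sum(counts.values()))

        g_null = sample_gene("null", f_n)
        g_sel = sample_gene("sel", f_o)
        ra = ace_scores(g_sel, d, f_n)
        rb = ace_scores(g_null, d, f_n)
        t, p = gene_ttest(ra, rb)
        assert p < 0.01

        # permutation oracle: reshuffle the pooled codons within families
        observed = abs(ra.ace_u - rb.ace_u)
        n_extreme = 0
        n_perm = 200
        for _ in range(n_perm):
            pa, pb = {}, {}
            aa_a, aa_b = {}, {}
            for aa in set(g_null.aa_counts) | set(g_sel.aa_counts):
                fam = code.families[aa]
                pooled = np.array(
                    [
                        g_null.codon_counts.get(c, 0) + g_sel.codon_counts.get(c, 0)
                        for c in fam
                    ]
                )
                na = g_sel.aa_counts.get(aa, 0)
                draw = rng.multivariate_hypergeometric(pooled, na)
                for c, k_a, k_tot in zip(fam, draw, pooled):
                    if k_a:
                        pa[c] = int(k_a)
                    if k_tot - k_a:
                        pb[c] = int(k_tot - k_a)
                aa_a[aa] = na
                aa_b[aa] = int(pooled.sum() - na)
            ga = GeneRecord("pa", pa, {k: v for k, v in aa_a.items() if v}, sum(pa.values()))
            gb = GeneRecord("pb", pb, {k: v for k, v in aa_b.items() if v}, sum(pb.values()))
            ua = ace_scores(ga, d, f_n).ace_u
            ub = ace_scores(gb, d, f_n).ace_u
            if abs(ua - ub) >= observed:
                n_extreme += 1
        assert (n_extreme + 1) / (n_perm + 1) < 0.01


class TestGenomeChi2:
    def test_mean_of_squared_z(self, lys_toy):
        from dataclasses import replace

        r = ace_scores(lys_toy.gene, lys_toy.delta, lys_toy.f_n)
        r1 = replace(r, ace_z=1.0)
        r2 = replace(r, ace_z=-1.0)
        summary = genome_chi2([r1, r2])
        assert summary.ace_chi2 == pytest.approx(1.0, abs=1e-12)
        assert summary.departure_z == pytest.approx(0.0, abs=1e-12)

    def test_empty_and_undefined_inputs_error(self, code, lys_toy):
        with pytest.raises(ValueError, match="empty"):
            genome_chi2([])
        f = make_table(code, {}, "f_n")
        d = build_delta_table(f, f)
        r = ace_scores(lys_toy.gene, d, f)
        with pytest.raises(ValueError, match="undefined"):
            genome_chi2([r])

    def test_null_calibration_ks_and_chi2(self, calibration_genome):
        """For null genes with >=100 degenerate codons, ACE_z ~ N(0,1)."""
        genes, delta, f_n = calibration_genome
        df = score_genes(genes[:500], delta, f_n)
        assert (df.n_informative >= 100).all()
        ks = stats.kstest(df.ace_z, "norm")
        assert ks.pvalue > 0.01
        chi2 = float((df.ace_z**2).mean())
        assert abs(chi2 - 1.0) < 3 * math.sqrt(2 / 500)


class TestAminoAcidCompositionInvariance:
    def test_null_ace_u_distribution_insensitive_to_composition(self, code):
        from codonace.synthetic_genomes import default_aa_composition

        comp2 = default_aa_composition()
        # shift composition: more Lys/Glu, less Leu/Ala
        comp2["K"] += 0.04
        comp2["E"] += 0.04
        comp2["L"] -= 0.04
        comp2["A"] -= 0.04
        spec_a = SyntheticSpec(n_genes=200, length_sigma=0.0, seed=61, code=code)
        spec_b = SyntheticSpec(
            n_genes=200, length_sigma=0.0, seed=62, aa_composition=comp2, code=code
        )
        genes_a, _ = generate(spec_a)
        genes_b, _ = generate(spec_b)
        from codonace.synthetic_genomes import default_selected_table

        f_n = spec_a.null_table
        d = build_delta_table(default_selected_table(code), f_n)
        ua = score_genes(genes_a, d, f_n).ace_u
        ub = score_genes(genes_b, d, f_n).ace_u
        ks = stats.ks_2samp(ua, ub)
        assert ks.pvalue > 0.01


class TestNormalityCheck:
    def test_type_one_error_rate_on_true_normals(self):
        rng = np.random.default_rng(13)
        n_reject = 0
        for i in range(100):
            x = rng.normal(size=2000)
            ns = NullSample("n", x, seed=i)
            *_, p = normality_check(ns)
            if p < 0.05:
                n_reject += 1
        assert 0 <= n_reject <= 12  # ~5% expected

    def test_skewed_sample_strongly_rejected(self):
        rng = np.random.default_rng(14)
        ns = NullSample("exp", rng.exponential(size=2000), seed=0)
        skew, kurt, k2, p = normality_check(ns)
        assert p < 0.001
        assert skew > 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError, match="20 replicates"):
            normality_check(NullSample("s", np.arange(10.0), seed=0))
        with pytest.raises(ValueError, match="degenerate"):
            normality_check(NullSample("c", np.ones(50), seed=0))


class TestBatchConsistency:
    def test_score_genes_matches_per_gene_path(self, selection_genome):
        genes, _, spec, f_n = selection_genome
        from codonace.synthetic_genomes import default_selected_table

        d = build_delta_table(default_selected_table(f_n.code), f_n)
        df = score_genes(genes[:25], d, f_n)
        for g, row in zip(genes[:25], df.itertuples()):
            r = ace_scores(g, d, f_n)
            assert row.scb == pytest.approx(r.scb, rel=1e-12)
            assert row.ace_z == pytest.approx(r.ace_z, rel=1e-9)
            assert row.ace_u == pytest.approx(r.ace_u, rel=1e-9)
            assert row.error_variance == pytest.approx(r.error_variance, rel=1e-9)
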