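"""Command-line interface and report assembly.

Thin wrappers over the library: ``simulate`` writes synthetic CDS sets,
``build-tables`` derives f_n/f_o/delta tables, ``score`` produces per-gene
ACE and comparator tables plus the genome summary, ``refine-fn`` and
``iterate-fo`` run the reference-set algorithms, and ``correlate`` relates a
codon statistic to expression values. Exit codes: 0 success, 2 usage error,
3 data error. All outputs are TSV with a provenance header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import NamedTuple

import click
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .codon_core import CdsParseError, GeneticCode, parse_cds_fasta
from .scoring_tables import (
    CodonFrequencyTable,
    build_delta_table,
    build_frequency_table,
)
from .ace_stats import genome_chi2, score_genes, AceResult
from . import comparators, reference_sets, synthetic_genomes

log = logging.getLogger("codonace")

__all__ = ["correlate_expression", "CorrelationResult", "cli", "main"]


class CorrelationResult(NamedTuple):
    r: float
    n: int
    n_dropped: int
    spearman_r: float | None = None


def correlate_expression(
    ace_table: pd.DataFrame | str | Path,
    expression: pd.DataFrame | str | Path,
    statistic: str = "ace_u",
    spearman: bool = False,
) -> CorrelationResult:
    """Pearson correlation between a codon statistic and ln(expression).

    Expression values are log-transformed first (codon statistics built from
    log-scores are linear on that scale); non-positive values are dropped and
    counted. Requires at least 3 genes shared by id.
    """
    if not isinstance(ace_table, pd.DataFrame):
        ace_table = pd.read_csv(ace_table, sep="\t", comment="#")
    if not isinstance(expression, pd.DataFrame):
        expression = pd.read_csv(
            expression, sep="\t", comment="#", header=None,
            names=["gene_id", "expression"],
        )
        if expression.iloc[0]["gene_id"] == "gene_id":  # optional header row
            expression = expression.iloc[1:]
        expression["expression"] = expression["expression"].astype(float)
    merged = ace_table.merge(expression, on="gene_id")
    n_dropped = int((merged["expression"] <= 0).sum())
    merged = merged[merged["expression"] > 0].dropna(subset=[statistic])
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} genes shared between the tables; need >= 3"
        )
    x = merged[statistic].to_numpy(float)
    y = np.log(merged["expression"].to_numpy(float))
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic) if spearman else None
    return CorrelationResult(r=r, n=len(merged), n_dropped=n_dropped, spearman_r=rho)


# ---------------------------------------------------------------------------
# output helpers


def _config_hash(params: dict) -> str:
    blob = json.dumps({k: str(v) for k, v in sorted(params.items())})
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    header = (
        f"# codonace v{__version__} config_hash={_config_hash(params)} "
        f"seed={params.get('seed', 'none')}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def _load_table_or_ids(
    genes, code, table_path, ids_path, role, pseudocount
) -> CodonFrequencyTable:
    if table_path:
        return CodonFrequencyTable.from_tsv(table_path, code)
    if ids_path:
        wanted = set(Path(ids_path).read_text().split())
        subset = [g for g in genes if g.gene_id in wanted]
        if not subset:
            raise ValueError(f"no genes matched the ids in {ids_path}")
    else:
        subset = genes
    return build_frequency_table(subset, code, role=role, pseudocount=pseudocount)


def _common_params(**kwargs) -> dict:
    return {k: v for k, v in kwargs.items() if v is not None}


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Adaptive Codon Enrichment: codon-selection statistics for genomes."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
    )


def _code_option(f):
    return click.option(
        "--genetic-code", type=int, default=11, show_default=True,
        help="NCBI translation table id",
    )(f)


def _pseudocount_option(f):
    return click.option(
        "--pseudocount", type=float, default=0.5, show_default=True,
        help="count assigned to codons absent from a reference set",
    )(f)


def _read_spec_file(path: str) -> dict:
    """Plain-text key=value generation spec (int/float/bool coerced)."""
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, value = (s.strip() for s in line.split("=", 1))
        if value.lower() in {"true", "false"}:
            out[key] = value.lower() == "true"
        else:
            try:
                out[key] = int(value)
            except ValueError:
                try:
                    out[key] = float(value)
                except ValueError:
                    out[key] = value
    return out


@cli.command()
@click.option("--spec-file", type=click.Path(exists=True), default=None,
              help="key=value file overriding the options below")
@click.option("--n-genes", type=int, default=1000, show_default=True)
@click.option("--length-mean", type=int, default=300, show_default=True)
@click.option("--length-sigma", type=float, default=0.45, show_default=True)
@click.option("--selected-fraction", type=float, default=0.0, show_default=True)
@click.option("--alien-fraction", type=float, default=0.0, show_default=True)
@click.option("--gradient/--no-gradient", default=False)
@click.option("--seed", type=int, default=0, show_default=True)
@_code_option
@click.option("--out-fasta", type=click.Path(), required=True)
@click.option("--out-labels", type=click.Path(), required=True)
def simulate(
    spec_file, n_genes, length_mean, length_sigma, selected_fraction,
    alien_fraction, gradient, seed, genetic_code, out_fasta, out_labels,
) -> None:
    """Generate a synthetic CDS FASTA plus truth labels."""
    params = dict(
        n_genes=n_genes,
        length_mean=length_mean,
        length_sigma=length_sigma,
        selected_fraction=selected_fraction,
        selection_gradient=gradient,
        alien_fraction=alien_fraction,
        seed=seed,
    )
    if spec_file:
        overrides = _read_spec_file(spec_file)
        genetic_code = overrides.pop("genetic_code", genetic_code)
        unknown = set(overrides) - set(params) - {"length_min", "length_max", "alien_gc_shift"}
        if unknown:
            raise click.UsageError(f"unknown spec keys: {sorted(unknown)}")
        params.update(overrides)
    code = GeneticCode.from_ncbi_id(genetic_code)
    selected = None
    if params["selected_fraction"] > 0 or params["selection_gradient"]:
        selected = synthetic_genomes.default_selected_table(code)
    spec = synthetic_genomes.SyntheticSpec(
        selected_table=selected, code=code, **params
    )
    seed = params["seed"]
    n_genes = params["n_genes"]
    genes, labels = synthetic_genomes.generate(spec)
    synthetic_genomes.write_fasta(genes, out_fasta, labels)
    _write_tsv(labels, Path(out_labels), _common_params(seed=seed, n_genes=n_genes))
    log.info("wrote %d genes to %s", len(genes), out_fasta)


@cli.command("build-tables")
@click.option("--cds", type=click.Path(exists=True), required=True)
@click.option("--fo-ids", type=click.Path(exists=True), default=None,
              help="file of gene ids for the optimized set")
@click.option("--fn-ids", type=click.Path(exists=True), default=None,
              help="file of gene ids for the unselected set (default: all genes)")
@click.option("--strict/--lenient", default=True, show_default=True)
@_code_option
@_pseudocount_option
@click.option("--out-dir", type=click.Path(), required=True)
def build_tables(cds, fo_ids, fn_ids, strict, genetic_code, pseudocount, out_dir):
    """Build f_n, f_o and delta tables from a CDS FASTA."""
    if pseudocount < 0:
        raise click.UsageError(f"pseudocount must be non-negative: {pseudocount}")
    code = GeneticCode.from_ncbi_id(genetic_code)
    genes = parse_cds_fasta(cds, code, strict=strict)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    f_n = _load_table_or_ids(genes, code, None, fn_ids, "f_n", pseudocount)
    f_n.to_tsv(out / "fn.tsv")
    if fo_ids:
        f_o = _load_table_or_ids(genes, code, None, fo_ids, "f_o", pseudocount)
        f_o.to_tsv(out / "fo.tsv")
        build_delta_table(f_o, f_n).to_tsv(out / "delta.tsv")
    log.info("tables written to %s", out)


_COMPARATOR_CHOICES = ("cai", "gcb", "enc", "enc_prime", "chi2")


@cli.command()
@click.option("--cds", type=click.Path(exists=True), required=True)
@click.option("--fo-table", type=click.Path(exists=True), default=None)
@click.option("--fn-table", type=click.Path(exists=True), default=None)
@click.option("--fo-ids", type=click.Path(exists=True), default=None)
@click.option("--fn-ids", type=click.Path(exists=True), default=None)
@click.option("--comparators", "comparator_list", default="",
              help="comma-separated subset of: " + ",".join(_COMPARATOR_CHOICES))
@click.option("--strict/--lenient", default=True, show_default=True)
@_code_option
@_pseudocount_option
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), required=True)
def score(cds, fo_table, fn_table, fo_ids, fn_ids, comparator_list, strict,
          genetic_code, pseudocount, seed, out_dir):
    """Score every gene: per-gene ACE table, comparators, genome summary."""
    if pseudocount < 0:
        raise click.UsageError(f"pseudocount must be non-negative: {pseudocount}")
    if not (fo_table or fo_ids):
        raise click.UsageError("provide --fo-table or --fo-ids")
    code = GeneticCode.from_ncbi_id(genetic_code)
    genes = parse_cds_fasta(cds, code, strict=strict)
    params = _common_params(
        cds=cds, genetic_code=genetic_code, pseudocount=pseudocount, seed=seed
    )
    f_n = _load_table_or_ids(genes, code, fn_table, fn_ids, "f_n", pseudocount)
    f_o = _load_table_or_ids(genes, code, fo_table, fo_ids, "f_o", pseudocount)
    delta = build_delta_table(f_o, f_n)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = score_genes(genes, delta, f_n)
    _write_tsv(df, out / "genes.tsv", params)

    wanted = [c for c in comparator_list.split(",") if c]
    unknown = set(wanted) - set(_COMPARATOR_CHOICES)
    if unknown:
        raise click.UsageError(f"unknown comparators: {sorted(unknown)}")
    if wanted:
        rows = []
        for g in genes:
            row: dict = {"gene_id": g.gene_id}
            if "cai" in wanted:
                row["cai"] = comparators.cai(g, genes, code, pseudocount)
            if "gcb" in wanted:
                row["gcb"] = comparators.gcb(g, delta)
            if "enc" in wanted:
                row["enc"] = comparators.enc(g, code)
            if "enc_prime" in wanted:
                row["enc_prime"] = comparators.enc_prime(g, f_n, code)
            if "chi2" in wanted:
                row["chi2"] = comparators.codon_usage_chi2(g, f_n)
            rows.append(row)
        _write_tsv(pd.DataFrame(rows), out / "comparators.tsv", params)

    defined = df.dropna(subset=["ace_z"])
    results = [
        AceResult(
            gene_id=r.gene_id, scb=r.scb, expected_scb=r.expected_scb,
            variance_scb=r.variance_scb, ace=r.ace, ace_z=r.ace_z, ace_u=r.ace_u,
            error_variance=r.error_variance, n_informative=int(r.n_informative),
            n_codons=int(r.n_codons),
        )
        for r in defined.itertuples()
    ]
    summary = genome_chi2(results, source=str(cds))
    _write_tsv(
        pd.DataFrame(
            [{
                "set": Path(cds).name,
                "n_genes": summary.n_genes,
                "ace_chi2": summary.ace_chi2,
                "departure_z": summary.departure_z,
            }]
        ),
        out / "summary.tsv",
        params,
    )
    log.info("ACE chi2 = %.4f over %d genes", summary.ace_chi2, summary.n_genes)


@cli.command("refine-fn")
@click.option("--cds", type=click.Path(exists=True), required=True)
@click.option("--criterion", type=click.Choice(["dinucleotide", "karlin_b", "both"]),
              default="both", show_default=True)
@click.option("--step", type=float, default=0.01, show_default=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@_code_option
@_pseudocount_option
@click.option("--out-dir", type=click.Path(), required=True)
def refine_fn_cmd(cds, criterion, step, alpha, genetic_code, pseudocount, out_dir):
    """Refine the unselected gene set by removing atypical genes."""
    code = GeneticCode.from_ncbi_id(genetic_code)
    genes = parse_cds_fasta(cds, code)
    kept, trace = reference_sets.refine_fn(
        genes, code, step=step, alpha=alpha, criterion=criterion,
        pseudocount=pseudocount,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "fraction_retained": s.fraction_retained,
            "n_removed": len(s.removed_ids),
            "n_agree": s.n_agree,
            "n_compared": s.n_compared,
            "p_value": s.p_value,
            "accepted": s.accepted,
        }
        for s in trace.steps
    ]
    _write_tsv(pd.DataFrame(rows), out / "refine_trace.tsv",
               _common_params(cds=cds, criterion=criterion, step=step, alpha=alpha))
    (out / "fn_ids.txt").write_text("\n".join(trace.final_ids) + "\n")
    log.info("retained %.1f%% of genes (%s)",
             100 * trace.final_fraction, trace.stop_reason)


@cli.command("iterate-fo")
@click.option("--cds", type=click.Path(exists=True), required=True)
@click.option("--seed-criterion", type=click.Choice(["enc", "enc_prime", "chi2"]),
              default="chi2", show_default=True)
@click.option("--k", type=int, default=40, show_default=True)
@click.option("--target-codons", type=int, default=10000, show_default=True)
@click.option("--n-rounds", type=int, default=15, show_default=True)
@click.option("--start-fraction", type=float, default=0.40, show_default=True)
@_code_option
@_pseudocount_option
@click.option("--out-dir", type=click.Path(), required=True)
def iterate_fo_cmd(cds, seed_criterion, k, target_codons, n_rounds,
                   start_fraction, genetic_code, pseudocount, out_dir):
    """Derive the optimized reference set by ACE_u iteration."""
    code = GeneticCode.from_ncbi_id(genetic_code)
    genes = parse_cds_fasta(cds, code)
    f_n = build_frequency_table(genes, code, role="f_n", pseudocount=pseudocount)
    seed_set = reference_sets.seed_fo(
        genes, seed_criterion, k=k, f_n=f_n, code=code
    )
    final, f_o, states = reference_sets.iterate_fo(
        genes, seed_set, f_n, target_codons=target_codons, n_rounds=n_rounds,
        start_fraction=start_fraction, pseudocount=pseudocount,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    f_o.to_tsv(out / "fo.tsv")
    f_n.to_tsv(out / "fn.tsv")
    (out / "fo_ids.txt").write_text(
        "\n".join(g.gene_id for g in final) + "\n"
    )
    rows = [
        {"round": s.round_index, "n_genes": len(s.gene_ids),
         "codon_total": s.codon_total}
        for s in states
    ]
    _write_tsv(pd.DataFrame(rows), out / "iterations.tsv",
               _common_params(cds=cds, seed_criterion=seed_criterion, k=k))
    log.info("final optimized set: %d genes, %d codons",
             len(final), states[-1].codon_total)


@cli.command()
@click.option("--genes-tsv", type=click.Path(exists=True), required=True,
              help="per-gene table written by `score`")
@click.option("--expression", type=click.Path(exists=True), required=True,
              help="two-column TSV: gene_id, expression value")
@click.option("--statistic", default="ace_u", show_default=True)
@click.option("--spearman/--no-spearman", default=False)
def correlate(genes_tsv, expression, statistic, spearman):
    """Correlate a codon statistic with log-transformed expression."""
    res = correlate_expression(genes_tsv, expression, statistic, spearman)
    click.echo(f"pearson_r\t{res.r:.4f}")
    click.echo(f"n\t{res.n}")
    click.echo(f"n_dropped_nonpositive\t{res.n_dropped}")
    if res.spearman_r is not None:
        click.echo(f"spearman_r\t{res.spearman_r:.4f}")


def main() -> None:
    try:
        cli(standalone_mode=False)
    except click.UsageError as exc:
        exc.show()
        sys.exit(2)
    except click.ClickException as exc:
        exc.show()
        sys.exit(exc.exit_code)
    except click.exceptions.Abort:
        sys.exit(1)
    except (ValueError, CdsParseError, OSError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        sys.exit(3)


if __name__ == "__main__":
    main()
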