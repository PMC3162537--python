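"""Genetic-code model, CDS parsing, codon counting and annotation utilities.

Every other module consumes the two containers defined here: a
:class:`GeneticCode` (the mapping from sense codons to amino acids plus the
synonymous-family structure) and a :class:`GeneRecord` (one gene's codon and
amino-acid counts, start codon excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "GeneRecord",
    "FeatureRecord",
    "FeatureTable",
    "parse_cds_fasta",
    "count_codons",
    "pool_counts",
    "count_trna_genes",
    "read_feature_table",
    "write_counts_tsv",
    "read_counts_tsv",
]

_DNA = frozenset("ACGT")


class CdsParseError(ValueError):
    """Raised when a CDS record violates the strict parsing contract."""


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table restricted to its 61/3 sense/stop partition.

    Synonymous families group codons by encoded amino acid, so the three
    six-codon families (Leu, Ser, Arg in the standard code) are each a single
    family rather than two codon boxes.
    """

    code_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    sense_codons: tuple[str, ...] = field(init=False)
    amino_acids: tuple[str, ...] = field(init=False)
    families: Mapping[str, tuple[str, ...]] = field(init=False)
    synonym_count: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        sense = tuple(sorted(self.codon_to_aa))
        if set(sense) & set(self.stop_codons):
            raise ValueError("sense and stop codons overlap")
        if len(sense) + len(self.stop_codons) != 64:
            raise ValueError("sense + stop codons must cover all 64 codons")
        fams: dict[str, list[str]] = {}
        for cdn in sense:
            fams.setdefault(self.codon_to_aa[cdn], []).append(cdn)
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "amino_acids", tuple(sorted(fams)))
        object.__setattr__(
            self, "families", {aa: tuple(c) for aa, c in fams.items()}
        )
        object.__setattr__(
            self, "synonym_count", {aa: len(c) for aa, c in fams.items()}
        )
        object.__setattr__(
            self, "_codon_index", {c: i for i, c in enumerate(sense)}
        )
        object.__setattr__(
            self, "_aa_index", {a: i for i, a in enumerate(self.amino_acids)}
        )

    @classmethod
    def from_ncbi_id(cls, code_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        return cls(
            code_id=code_id,
            codon_to_aa=dict(table.forward_table),
            stop_codons=frozenset(table.stop_codons),
        )

    @property
    def codon_index(self) -> Mapping[str, int]:
        return self._codon_index  # type: ignore[attr-defined]

    @property
    def aa_index(self) -> Mapping[str, int]:
        return self._aa_index  # type: ignore[attr-defined]

    def aa_of_codon_array(self) -> np.ndarray:
        """Index of each sense codon's amino acid, aligned to sense_codons."""
        return np.array(
            [self.aa_index[self.codon_to_aa[c]] for c in self.sense_codons]
        )


@dataclass
class GeneRecord:
    """One gene's codon counts C_ij and derived amino-acid counts C_i.

    The start codon is excluded positionally and the terminal stop codon is
    never counted; ``flags`` records parsing irregularities.
    """

    gene_id: str
    codon_counts: dict[str, int]
    aa_counts: dict[str, int]
    n_codons_total: int
    flags: list[str] = field(default_factory=list)
    sequence: str | None = None  # counted codons, concatenated 5'->3'

    def codon_vector(self, code: GeneticCode) -> np.ndarray:
        v = np.zeros(len(code.sense_codons))
        for cdn, n in self.codon_counts.items():
            v[code.codon_index[cdn]] = n
        return v

    def aa_vector(self, code: GeneticCode) -> np.ndarray:
        v = np.zeros(len(code.amino_acids))
        for aa, n in self.aa_counts.items():
            v[code.aa_index[aa]] = n
        return v


def count_codons(
    gene_id: str,
    sequence: str,
    code: GeneticCode,
    strict: bool = True,
    drop_start: bool = True,
) -> GeneRecord:
    """Tally sense codons of an in-frame CDS into a :class:`GeneRecord`.

    The first codon is dropped regardless of identity (non-ATG starts would
    otherwise distort Val/Leu counts), a terminal stop is dropped, ambiguous
    codons are skipped with a flag, and internal stops are rejected (strict)
    or skipped with a flag (lenient).
    """
    seq = sequence.upper().replace("U", "T")
    flags: list[str] = []
    if drop_start:
        seq = seq[3:]
    if len(seq) % 3 != 0:
        if strict:
            raise CdsParseError(
                f"{gene_id}: length {len(seq)} after start removal is not a "
                "multiple of 3"
            )
        flags.append(f"truncated {len(seq) % 3} trailing nt")
        seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons.pop()
    counts: dict[str, int] = {}
    kept: list[str] = []
    for pos, cdn in enumerate(codons):
        if not set(cdn) <= _DNA:
            flags.append(f"skipped ambiguous codon {cdn} at {pos}")
            continue
        if cdn in code.stop_codons:
            if strict:
                raise CdsParseError(
                    f"{gene_id}: internal stop codon {cdn} at codon {pos}"
                )
            flags.append(f"skipped internal stop {cdn} at {pos}")
            continue
        counts[cdn] = counts.get(cdn, 0) + 1
        kept.append(cdn)
    aa_counts: dict[str, int] = {}
    for cdn, n in counts.items():
        aa = code.codon_to_aa[cdn]
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    return GeneRecord(
        gene_id=gene_id,
        codon_counts=counts,
        aa_counts=aa_counts,
        n_codons_total=sum(counts.values()),
        flags=flags,
        sequence="".join(kept),
    )


def parse_cds_fasta(
    path: str | Path,
    code: GeneticCode | None = None,
    strict: bool = True,
) -> list[GeneRecord]:
    """Read a multi-FASTA of strand-resolved, frame-0 CDS into gene records.

    In strict mode records with frame errors or internal stops are rejected
    with a reported reason; in lenient mode they are truncated/skipped and
    flagged. An empty file is an error.
    """
    code = code or GeneticCode.from_ncbi_id(11)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise CdsParseError(f"{path}: no FASTA records found")
    genes: list[GeneRecord] = []
    for rec in records:
        try:
            genes.append(count_codons(rec.id, str(rec.seq), code, strict=strict))
        except CdsParseError:
            if strict:
                raise
    return genes


def pool_counts(genes: Sequence[GeneRecord]) -> GeneRecord:
    """Element-wise sum of codon counts over a non-empty gene list."""
    if not genes:
        raise ValueError("cannot pool an empty gene list")
    counts: dict[str, int] = {}
    aa_counts: dict[str, int] = {}
    for g in genes:
        for cdn, n in g.codon_counts.items():
            counts[cdn] = counts.get(cdn, 0) + n
        for aa, n in g.aa_counts.items():
            aa_counts[aa] = aa_counts.get(aa, 0) + n
    return GeneRecord(
        gene_id=f"pool(n={len(genes)})",
        codon_counts=counts,
        aa_counts=aa_counts,
        n_codons_total=sum(counts.values()),
    )


# ---------------------------------------------------------------------------
# annotation features


@dataclass
class FeatureRecord:
    feature_type: str
    name: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    product: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"feature {self.name}: non-positive length")


@dataclass
class FeatureTable:
    records: list[FeatureRecord]

    def of_type(self, *types: str) -> list[FeatureRecord]:
        return [r for r in self.records if r.feature_type in types]


_RNA_TYPES = ("tRNA", "rRNA", "ncRNA", "misc_RNA", "tmRNA")


def _is_sec_trna(feature: FeatureRecord) -> bool:
    text = f"{feature.name} {feature.product}".lower()
    return "selenocystein" in text or "trna-sec" in text or "selc" in text


def count_trna_genes(
    features: FeatureTable,
    min_len: int = 60,
    max_len: int = 100,
) -> int:
    """Count structural-RNA genes of tRNA-like size (60-100 bp), excluding
    the selenocysteine tRNA."""
    rnas = features.of_type(*_RNA_TYPES)
    if not rnas:
        warnings.warn("no RNA features present; tRNA count is 0", stacklevel=2)
        return 0
    return sum(
        1
        for r in rnas
        if min_len <= r.length <= max_len and not _is_sec_trna(r)
    )


def read_feature_table(path: str | Path, fmt: str | None = None) -> FeatureTable:
    """Load a GenBank flat file or GFF3 into a :class:`FeatureTable`."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "genbank"
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown feature format: {fmt}")


def _read_genbank(path: Path) -> FeatureTable:
    records: list[FeatureRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type == "source":
                continue
            quals = feat.qualifiers
            name = (
                quals.get("gene", quals.get("locus_tag", [""]))[0]
            )
            records.append(
                FeatureRecord(
                    feature_type=feat.type,
                    name=name,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    product=quals.get("product", [""])[0],
                )
            )
    return FeatureTable(records)


def _read_gff3(path: Path) -> FeatureTable:
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            records.append(
                FeatureRecord(
                    feature_type=parts[2],
                    name=attrs.get("gene", attrs.get("Name", attrs.get("ID", ""))),
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6],
                    product=attrs.get("product", ""),
                )
            )
    return FeatureTable(records)


# ---------------------------------------------------------------------------
# TSV dialect: gene_id followed by the 61 sense codons in alphabetical order


def write_counts_tsv(
    genes: Iterable[GeneRecord], path: str | Path, code: GeneticCode
) -> None:
    rows = {g.gene_id: g.codon_vector(code).astype(int) for g in genes}
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(code.sense_codons)
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, code: GeneticCode) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    genes = []
    for gene_id, row in df.iterrows():
        counts = {c: int(row[c]) for c in code.sense_codons if row[c] > 0}
        aa_counts: dict[str, int] = {}
        for cdn, n in counts.items():
            aa = code.codon_to_aa[cdn]
            aa_counts[aa] = aa_counts.get(aa, 0) + n
        genes.append(
            GeneRecord(
                gene_id=str(gene_id),
                codon_counts=counts,
                aa_counts=aa_counts,
                n_codons_total=sum(counts.values()),
            )
        )
    return genes
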