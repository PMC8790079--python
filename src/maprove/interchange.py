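"""Readers, writers and domain records for every format the pipeline touches.

All on-disk formats are plain text: FASTA for protein sequences, tab-separated
tables for mutations / growth assays / scores, one-id-per-line text for
essential-gene lists, and JSON for gene models.  Protein variants are written
in the HGVS protein subset without the ``p.`` prefix (the input style PROVEAN
itself accepts): ``A123T``, ``K45del``, ``K45_L46del``, ``K45_L46insQ``,
``A12dup``, ``A12_K14dup``, ``A12delinsGG``, ``A12_Y20delinsGG``.

Coordinates are 1-based inclusive everywhere, for genomic positions and for
protein residues alike.  Genomic indels use the anchored VCF convention (first
reference base shared between ref and alt).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

MUTATION_COLUMNS = ["line_id", "gene_id", "position", "ref", "alt"]
ANCESTRAL_COLUMNS = ["gene_id", "position", "ref", "alt"]
GROWTH_COLUMNS = [
    "line_id", "role", "ancestor_id", "environment", "block", "replicate",
    "growth_rate",
]
SCORE_COLUMNS = [
    "line_id", "gene_id", "protein_id", "variant", "score", "classification",
    "n_clusters", "n_supporting", "flags",
]


class InterchangeError(ValueError):
    """Raised for malformed inputs; readers reject rather than coerce."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Exon structure, strand and genomic sequence for one transcript.

    ``genomic_seq`` covers the model's span; ``seq_start`` is the 1-based
    genomic coordinate of its first base (so exon intervals and variant
    positions live in the same genomic coordinate system).
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    genomic_seq: str
    seq_start: int = 1

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InterchangeError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        last_end = None
        span_end = self.seq_start + len(self.genomic_seq) - 1
        for start, end in exons:
            if start > end:
                raise InterchangeError(
                    f"{self.transcript_id}: exon ({start},{end}) start exceeds end")
            if start < self.seq_start or end > span_end:
                raise InterchangeError(
                    f"{self.transcript_id}: exon ({start},{end}) outside the "
                    f"genomic sequence span [{self.seq_start},{span_end}]")
            if last_end is not None and start <= last_end:
                raise InterchangeError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({start},{end})")
            last_end = end
        seq = self.genomic_seq.upper()
        object.__setattr__(self, "genomic_seq", seq)
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise InterchangeError(
                f"{self.transcript_id}: non-ACGT characters in genomic sequence: {sorted(bad)}")


@dataclass(frozen=True)
class GenomicVariantRecord:
    """One mutation call in one MA line, anchored VCF-style."""

    line_id: str
    gene_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise InterchangeError(
                f"{self.line_id}/{self.gene_id}@{self.position}: empty alleles are "
                "forbidden; use the anchored VCF representation")
        if self.ref == self.alt:
            raise InterchangeError(
                f"{self.line_id}/{self.gene_id}@{self.position}: ref equals alt")
        for allele in (self.ref, self.alt):
            if set(allele) - set(NUCLEOTIDES):
                raise InterchangeError(
                    f"{self.line_id}/{self.gene_id}@{self.position}: non-ACGT allele {allele!r}")
        if self.position < 1:
            raise InterchangeError(
                f"{self.line_id}/{self.gene_id}: position {self.position} is not 1-based")


@dataclass(frozen=True)
class ProteinVariantRecord:
    """A protein change description plus the mutant sequence it produces."""

    protein_id: str
    description: str
    query_len: int
    mutant_seq: str


@dataclass
class GrowthTable:
    """Replicated growth-rate measurements for MA lines and their controls."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GROWTH_COLUMNS if c not in self.data.columns]
        if missing:
            raise InterchangeError(f"growth table lacks mandatory columns: {missing}")
        if not pd.api.types.is_numeric_dtype(self.data["growth_rate"]):
            raise InterchangeError("growth_rate column is not numeric")
        if not self.data["growth_rate"].map(pd.notna).all() or \
                not pd.Series(self.data["growth_rate"]).map(lambda x: x == x and abs(x) != float("inf")).all():
            raise InterchangeError("growth_rate contains non-finite values")
        roles = set(self.data["role"])
        if not roles <= {"ma", "control"}:
            raise InterchangeError(f"unknown roles in growth table: {sorted(roles - {'ma', 'control'})}")
        ma = self.data[self.data["role"] == "ma"]
        controls = set(self.data.loc[self.data["role"] == "control", "ancestor_id"])
        if controls:
            orphans = set(ma["ancestor_id"]) - controls
            if orphans:
                raise InterchangeError(
                    f"MA lines reference ancestors with no control rows: {sorted(orphans)}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence map.

    Sequences are uppercased and gap characters stripped; duplicate ids and
    empty files are hard errors.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise InterchangeError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("-", "").replace(".", "")
    if not out:
        raise InterchangeError(f"{path}: empty or invalid FASTA")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# HGVS-subset protein variant notation
# ---------------------------------------------------------------------------

_RE_SUB = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_RE_RANGE_OP = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?(del|dup|delins|ins)([A-Z]*)$")


def _check_residue(query: str, pos: int, letter: str, description: str) -> None:
    if pos < 1 or pos > len(query):
        raise InterchangeError(
            f"{description}: position {pos} outside query of length {len(query)}")
    if query[pos - 1] != letter:
        raise InterchangeError(
            f"{description}: query has {query[pos - 1]} at position {pos}, not {letter}")


def apply_description(description: str, query_seq: str) -> str:
    """Apply an HGVS-subset protein change to ``query_seq``.

    Reference residues named in the description are verified against the
    query; mismatches raise with the offending position named.
    """
    q = query_seq
    m = _RE_SUB.match(description)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        _check_residue(q, pos, ref, description)
        if ref == alt:
            raise InterchangeError(f"{description}: substitution to the same residue")
        return q[:pos - 1] + alt + q[pos:]

    m = _RE_RANGE_OP.match(description)
    if not m:
        raise InterchangeError(f"unparseable variant description {description!r}")
    ref1, pos1, ref2, pos2, op, payload = (
        m.group(1), int(m.group(2)), m.group(3), m.group(4), m.group(5), m.group(6))
    pos2 = int(pos2) if pos2 is not None else pos1
    ref2 = ref2 if ref2 is not None else ref1
    _check_residue(q, pos1, ref1, description)
    _check_residue(q, pos2, ref2, description)
    if pos2 < pos1:
        raise InterchangeError(f"{description}: inverted range {pos1}_{pos2}")

    if op == "del":
        if payload:
            raise InterchangeError(f"{description}: del takes no inserted residues")
        return q[:pos1 - 1] + q[pos2:]
    if op == "dup":
        if payload:
            raise InterchangeError(f"{description}: dup takes no inserted residues")
        return q[:pos2] + q[pos1 - 1:pos2] + q[pos2:]
    if op == "ins":
        if pos2 != pos1 + 1:
            raise InterchangeError(
                f"{description}: insertion flanks must be adjacent residues")
        if not payload:
            raise InterchangeError(f"{description}: insertion without residues")
        return q[:pos1] + payload + q[pos1:]
    # delins
    if not payload:
        raise InterchangeError(f"{description}: delins without replacement residues")
    return q[:pos1 - 1] + payload + q[pos2:]


def parse_variant(description: str, query_seq: str) -> ProteinVariantRecord:
    """Parse a description against a query, returning the mutant it encodes."""
    mutant = apply_description(description, query_seq)
    return ProteinVariantRecord(
        protein_id="", description=description, query_len=len(query_seq),
        mutant_seq=mutant)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise InterchangeError(f"{path}: missing mandatory columns {missing}")
    return df


def read_mutation_table(path: str | Path) -> list[GenomicVariantRecord]:
    df = _read_tsv(path, MUTATION_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        try:
            position = int(row.position)
        except ValueError:
            raise InterchangeError(
                f"{path}: malformed position {row.position!r} for line {row.line_id}")
        records.append(GenomicVariantRecord(
            line_id=str(row.line_id), gene_id=str(row.gene_id),
            position=position, ref=str(row.ref), alt=str(row.alt)))
    return records


def write_mutation_table(records: Iterable[GenomicVariantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.line_id, r.gene_id, r.position, r.ref, r.alt) for r in records],
        columns=MUTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_ancestral_table(path: str | Path) -> pd.DataFrame:
    """Ancestor-vs-reference variant table; optional ``ancestor_id`` column."""
    df = _read_tsv(path, ANCESTRAL_COLUMNS)
    df["position"] = df["position"].astype(int)
    if "ancestor_id" not in df.columns:
        df["ancestor_id"] = "ancestor"
    return df


def read_growth_table(path: str | Path) -> GrowthTable:
    df = _read_tsv(path, GROWTH_COLUMNS)
    try:
        df["growth_rate"] = df["growth_rate"].astype(float)
    except ValueError as exc:
        raise InterchangeError(f"{path}: malformed growth_rate: {exc}")
    return GrowthTable(df)


def write_growth_table(table: GrowthTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Score table as a DataFrame; unknown columns ride along untouched."""
    df = _read_tsv(path, SCORE_COLUMNS)
    df["score"] = df["score"].astype(float)  # NaN for unscored rows
    for col in ("n_clusters", "n_supporting"):
        df[col] = df[col].astype(int)
    df["flags"] = df["flags"].fillna("")
    return df


def read_essential_genes(path: str | Path) -> set[str]:
    """Plain-text essential-gene list, one id per line, '#' comments ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def write_essential_genes(gene_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_ids)))


# ---------------------------------------------------------------------------
# Gene models (JSON)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    raw = json.loads(Path(path).read_text())
    models = []
    for entry in raw:
        models.append(GeneModel(
            gene_id=entry["gene_id"], transcript_id=entry["transcript_id"],
            strand=entry["strand"],
            exons=tuple((int(s), int(e)) for s, e in entry["exons"]),
            genomic_seq=entry["genomic_seq"],
            seq_start=int(entry.get("seq_start", 1))))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    payload = [
        {
            "gene_id": m.gene_id, "transcript_id": m.transcript_id,
            "strand": m.strand, "exons": [list(e) for e in m.exons],
            "genomic_seq": m.genomic_seq, "seq_start": m.seq_start,
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
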