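"""From genomic mutations to mutant proteins and HGVS-subset descriptions.

The in-silico mutagenesis path mirrors how MA-line genotypes are turned into
scoreable protein variants: splice the coding sequence out of the gene model,
apply all of a line's mutations in that gene jointly, translate, and express
the protein-level change as a compact edit against the query (ancestor)
protein.  Premature stop codons truncate the protein; frameshifts therefore
surface as long delins/truncation edits rather than errors, because the
scoring stage is expected to handle (and typically heavily penalise) them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .interchange import (
    GeneModel,
    GenomicVariantRecord,
    InterchangeError,
    ProteinVariantRecord,
    apply_description,
)

logger = logging.getLogger(__name__)


class MutagenesisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splicing and translation
# ---------------------------------------------------------------------------

def splice_cds(model: GeneModel) -> str:
    """Concatenate exons in transcript order; reverse-complement on '-'."""
    parts = []
    for start, end in model.exons:
        lo = start - model.seq_start
        hi = end - model.seq_start + 1
        parts.append(model.genomic_seq[lo:hi])
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def translate_cds(cds: str, context: str = "") -> str:
    """Translate with the standard code, stopping at the first stop codon.

    A trailing partial codon is dropped with a logged warning (frameshifted
    coding sequences routinely end mid-codon); ambiguous nucleotides are a
    hard error.
    """
    if len(cds) < 3:
        raise MutagenesisError(f"{context}: coding sequence shorter than one codon")
    bad = set(cds) - set("ACGT")
    if bad:
        raise MutagenesisError(f"{context}: ambiguous nucleotides {sorted(bad)}")
    usable = len(cds) - len(cds) % 3
    if usable != len(cds):
        logger.warning("%s: dropping trailing partial codon of %d nt", context, len(cds) - usable)
    return str(Seq(cds[:usable]).translate(to_stop=True))


# ---------------------------------------------------------------------------
# Applying genomic variants
# ---------------------------------------------------------------------------

def apply_genomic_variants(
    exons: tuple[tuple[int, int], ...],
    genomic_seq: str,
    variants: list[GenomicVariantRecord],
    seq_start: int = 1,
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Apply one line's variants in one gene to the genomic sequence.

    Edits are applied from the highest genomic position to the lowest so that
    earlier coordinates stay valid.  Because indels change the length of the
    sequence, exon boundaries downstream of each edit are shifted by the
    length difference; the adjusted exon intervals are returned alongside the
    mutated sequence.  Reference-allele mismatches and overlapping variants
    are hard errors.
    """
    seq = genomic_seq
    new_exons = [list(e) for e in exons]
    ordered = sorted(variants, key=lambda v: v.position, reverse=True)
    prev_start = None
    for var in ordered:
        lo = var.position - seq_start
        hi = lo + len(var.ref)
        if lo < 0 or hi > len(seq):
            raise MutagenesisError(
                f"{var.line_id}/{var.gene_id}: variant at {var.position} outside the gene span")
        if prev_start is not None and var.position + len(var.ref) - 1 >= prev_start:
            raise MutagenesisError(
                f"{var.line_id}/{var.gene_id}: overlapping variants at {var.position}")
        prev_start = var.position
        observed = seq[lo:hi]
        if observed != var.ref:
            raise MutagenesisError(
                f"{var.line_id}/{var.gene_id}: reference mismatch at position "
                f"{var.position}: sequence has {observed!r}, table says {var.ref!r}")
        seq = seq[:lo] + var.alt + seq[hi:]
        delta = len(var.alt) - len(var.ref)
        if delta != 0:
            var_end = var.position + len(var.ref) - 1
            for exon in new_exons:
                if exon[0] > var_end:
                    exon[0] += delta
                    exon[1] += delta
                elif exon[1] >= var_end and exon[0] <= var.position:
                    exon[1] += delta
                elif exon[0] <= var.position <= exon[1] or exon[0] <= var_end <= exon[1]:
                    raise MutagenesisError(
                        f"{var.line_id}/{var.gene_id}: variant at {var.position} spans an "
                        "exon boundary; splice-site effects are out of scope")
    return seq, tuple((a, b) for a, b in new_exons)


# ---------------------------------------------------------------------------
# Protein diffing
# ---------------------------------------------------------------------------

def diff_proteins(query: str, mutant: str, protein_id: str = "") -> ProteinVariantRecord | None:
    """Describe ``mutant`` as a single HGVS-subset edit against ``query``.

    Returns ``None`` for identical sequences (a synonymous change at the
    protein level — nothing to score).  The longest common prefix is trimmed
    first, then the longest common suffix of the remainder, which places
    ambiguous indels at their 3'-most equivalent position.  Truncations come
    out as deletions running to the query's last residue; everything else is
    classified as substitution / del / ins / dup / delins.
    """
    if query == mutant:
        return None
    if not query:
        raise MutagenesisError(f"{protein_id}: empty query protein")

    p = 0
    while p < len(query) and p < len(mutant) and query[p] == mutant[p]:
        p += 1
    s = 0
    while (s < len(query) - p and s < len(mutant) - p
           and query[len(query) - 1 - s] == mutant[len(mutant) - 1 - s]):
        s += 1
    q_mid = query[p:len(query) - s]
    m_mid = mutant[p:len(mutant) - s]
    i, j = p + 1, len(query) - s  # 1-based query range of the edit

    if len(q_mid) == 1 and len(m_mid) == 1:
        desc = f"{q_mid}{i}{m_mid}"
    elif not m_mid:  # deletion
        if i == j:
            desc = f"{q_mid}{i}del"
        else:
            desc = f"{query[i - 1]}{i}_{query[j - 1]}{j}del"
    elif not q_mid:  # insertion between query positions p and p+1
        run = query[p - len(m_mid):p] if p >= len(m_mid) else ""
        if run == m_mid:  # duplication of the immediately preceding run
            lo = p - len(m_mid) + 1
            if len(m_mid) == 1:
                desc = f"{query[p - 1]}{p}dup"
            else:
                desc = f"{query[lo - 1]}{lo}_{query[p - 1]}{p}dup"
        elif 1 <= p < len(query):
            desc = f"{query[p - 1]}{p}_{query[p]}{p + 1}ins{m_mid}"
        elif p == 0:  # insertion before the first residue: fold into a delins
            desc = f"{query[0]}1delins{m_mid}{query[0]}"
        else:  # insertion after the last residue
            desc = f"{query[-1]}{len(query)}delins{query[-1]}{m_mid}"
    else:  # delins
        if i == j:
            desc = f"{q_mid}{i}delins{m_mid}"
        else:
            desc = f"{query[i - 1]}{i}_{query[j - 1]}{j}delins{m_mid}"

    # Internal consistency: the description must reproduce the mutant.
    rebuilt = apply_description(desc, query)
    if rebuilt != mutant:
        raise MutagenesisError(
            f"{protein_id}: internal error — description {desc} does not rebuild mutant")
    return ProteinVariantRecord(
        protein_id=protein_id, description=desc, query_len=len(query), mutant_seq=mutant)


def variant_kind(description: str) -> str:
    """Classify a description: substitution / duplication / deletion / insertion / complex.

    ``delins`` edits involve both a deletion and an insertion and are filed as
    complex, as are proteins whose (combined) change cannot be expressed as a
    single simple edit.
    """
    if description.endswith("delins") or "delins" in description:
        return "complex"
    if description.endswith("dup"):
        return "duplication"
    if description.endswith("del"):
        return "deletion"
    if "ins" in description:
        return "insertion"
    return "single aa substitution"


# ---------------------------------------------------------------------------
# Ancestor query correction
# ---------------------------------------------------------------------------

def build_ancestor_query(reference_protein: str, ancestral_descriptions: list[str]) -> str:
    """Fold ancestor-vs-reference protein changes into the query sequence.

    MA-line variants must be diffed against the true ancestor, never the
    reference: shared divergence would otherwise contaminate every score
    (reference bias).  Descriptions are verified against the reference and
    applied from the highest position down so coordinates stay valid.
    """
    def anchor(desc: str) -> int:
        import re as _re
        m = _re.match(r"^[A-Z](\d+)", desc)
        if not m:
            raise MutagenesisError(f"unparseable ancestral description {desc!r}")
        return int(m.group(1))

    query = reference_protein
    for desc in sorted(ancestral_descriptions, key=anchor, reverse=True):
        query = apply_description(desc, query)
    return query


# ---------------------------------------------------------------------------
# Study-level driver
# ---------------------------------------------------------------------------

@dataclass
class MutantProtein:
    """One line x transcript mutant protein ready for scoring."""

    line_id: str
    gene_id: str
    transcript_id: str
    record: ProteinVariantRecord | None  # None: synonymous at protein level
    query_seq: str


def mutate_study(
    gene_models: list[GeneModel],
    mutations: list[GenomicVariantRecord],
    ancestral_variants: list[GenomicVariantRecord] | None = None,
) -> tuple[list[MutantProtein], dict[str, str]]:
    """Run the full mutagenesis stage for a study.

    Ancestral variants (ancestor vs reference, genomic) are applied first to
    build per-transcript query proteins; each line's mutations in a gene are
    then applied jointly on top of the ancestral genomic sequence, and every
    affected transcript is diffed against its query.  Returns the mutant
    records and the query-protein FASTA map.
    """
    by_transcript: dict[str, GeneModel] = {m.transcript_id: m for m in gene_models}
    by_gene: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_gene.setdefault(m.gene_id, []).append(m)

    anc_by_gene: dict[str, list[GenomicVariantRecord]] = {}
    for v in ancestral_variants or []:
        anc_by_gene.setdefault(v.gene_id, []).append(v)

    # Per-transcript ancestral genomic state and query protein.
    anc_state: dict[str, tuple[str, tuple[tuple[int, int], ...], str]] = {}
    queries: dict[str, str] = {}
    for model in gene_models:
        anc = anc_by_gene.get(model.gene_id, [])
        seq, exons = apply_genomic_variants(model.exons, model.genomic_seq, anc, model.seq_start)
        query = translate_cds(
            splice_cds(GeneModel(model.gene_id, model.transcript_id, model.strand,
                                 exons, seq, model.seq_start)),
            context=model.transcript_id)
        anc_state[model.transcript_id] = (seq, exons, query)
        queries[model.transcript_id] = query

    out: list[MutantProtein] = []
    by_line_gene: dict[tuple[str, str], list[GenomicVariantRecord]] = {}
    for v in mutations:
        by_line_gene.setdefault((v.line_id, v.gene_id), []).append(v)

    for (line_id, gene_id), vars_here in sorted(by_line_gene.items()):
        models = by_gene.get(gene_id)
        if not models:
            raise MutagenesisError(f"{line_id}: mutations in unknown gene {gene_id}")
        for model in models:
            anc_seq, anc_exons, query = anc_state[model.transcript_id]
            # MA-line coordinates refer to the reference; translate them onto the
            # ancestral sequence only when ancestral indels exist upstream.
            shifted = _lift_positions(vars_here, anc_by_gene.get(gene_id, []))
            mut_seq, mut_exons = apply_genomic_variants(
                anc_exons, anc_seq, shifted, model.seq_start)
            mutant = translate_cds(
                splice_cds(GeneModel(gene_id, model.transcript_id, model.strand,
                                     mut_exons, mut_seq, model.seq_start)),
                context=f"{line_id}/{model.transcript_id}")
            if not mutant:
                # Protein abolished (stop in codon 1): keep an unscoreable stub.
                record = ProteinVariantRecord(
                    protein_id=model.transcript_id,
                    description=f"{query[0]}1_{query[-1]}{len(query)}del",
                    query_len=len(query), mutant_seq="")
            else:
                record = diff_proteins(query, mutant, protein_id=model.transcript_id)
            out.append(MutantProtein(line_id, gene_id, model.transcript_id, record, query))
    return out, queries


def _lift_positions(
    variants: list[GenomicVariantRecord],
    ancestral: list[GenomicVariantRecord],
) -> list[GenomicVariantRecord]:
    """Shift reference coordinates across ancestral indels (upstream only)."""
    if not ancestral:
        return variants
    out = []
    for v in variants:
        shift = sum(
            len(a.alt) - len(a.ref)
            for a in ancestral
            if a.position + len(a.ref) - 1 < v.position)
        if shift:
            v = GenomicVariantRecord(v.line_id, v.gene_id, v.position + shift, v.ref, v.alt)
        out.append(v)
    return out
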