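"""Synthetic MA studies: protein families, gene models, mutations, growth.

The generator emulates the structure the pipeline expects from a real
mutation-accumulation (MA) study, end to end and fully seeded:

* protein families with site-specific conservation — supporting sequences
  derive from the query by per-site substitution with probability
  proportional to the site's tolerance, so conserved sites exist and
  substitutions there score worse than at tolerant sites;
* gene models with 1-3 exons on either strand whose spliced translation
  reproduces the designed protein exactly;
* MA lines carrying Poisson numbers of mutations (nonsynonymous codon
  changes, occasionally in-frame codon deletions) whose true fitness
  effects follow a configurable model: a constant effect per mutant protein,
  an effect proportional to the variant's realized delta score, or a
  thresholded version of the latter;
* ancestral (ancestor-vs-reference) variants drawn at tolerant sites — the
  selection-screened tail — at a configurable rate;
* replicated growth assays with block effects and matched controls.

Everything latent (true fitness, per-mutation effects, realized scores) is
kept in a truth record for recovery tests.  Mutation tables are expressed
against the ancestor's genome, the coordinate frame the pipeline diffs in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .interchange import (
    AMINO_ACIDS,
    GeneModel,
    GenomicVariantRecord,
    GrowthTable,
)
from .mutagenesis import apply_genomic_variants, splice_cds, translate_cds
from .scoring import ScoringConfig, build_supporting_set, delta_score

logger = logging.getLogger(__name__)

# Codon table restricted to unambiguous sense codons.
_CODONS: dict[str, list[str]] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; the seed is mandatory.

    Defaults describe a desk-scale study: six ancestral backgrounds of 14
    lines each, ~6 coding mutations per line, proteins around 120 residues
    with a dozen homologs each, half of all sites strongly conserved, an
    assay of 10 replicates over 4 blocks with replicate noise an order of
    magnitude above the per-mutation effect.
    """

    seed: int
    n_ancestors: int = 6
    n_lines_per_ancestor: int = 14
    n_proteins: int = 40
    protein_length_mean: int = 120
    n_supporting_per_protein: int = 12
    conservation_profile: tuple[float, float, float] = (0.02, 0.35, 0.5)
    # (tolerance at conserved sites, at variable sites, fraction conserved)
    mutation_rate_per_line: float = 6.0
    codon_deletion_prob: float = 0.05
    nonsense_prob: float = 0.05  # premature stop: truncation, extreme scores
    effect_model: str = "uniform_per_mutation"
    effect_size: float = -0.02
    effect_threshold: float = -2.0  # used by effect_model='score_linked_threshold'
    replicate_sd: float = 0.1
    n_replicates: int = 10
    n_blocks: int = 4
    block_sd: float = 0.05
    control_replicates: int = 40
    ancestral_variant_rate: float = 0.15
    essential_fraction: float = 0.2
    baseline_growth: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_model not in {"uniform_per_mutation", "score_linked",
                                     "score_linked_threshold"}:
            raise ValueError(f"unknown effect_model {self.effect_model!r}")
        for name in ("mutation_rate_per_line", "replicate_sd", "block_sd",
                     "ancestral_variant_rate", "codon_deletion_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def evaluation_config(seed: int, effect_model: str = "uniform_per_mutation",
                      **overrides) -> SimulationConfig:
    """Desk-scale study conditions used for the pipeline's own evaluation runs.

    Smaller than the defaults (3 ancestors x 8 lines, 25 proteins of ~60
    residues, 8 homologs each, ~5 mutations per line) so that replicated
    end-to-end runs complete quickly while preserving the study structure.
    """
    params = dict(
        seed=seed, effect_model=effect_model,
        n_ancestors=3, n_lines_per_ancestor=8,
        n_proteins=25, protein_length_mean=60,
        n_supporting_per_protein=8, mutation_rate_per_line=5.0)
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------

def simulate_family(
    rng: np.random.Generator,
    length: int,
    n_supporting: int,
    conservation_profile: tuple[float, float, float],
) -> tuple[str, list[str], np.ndarray]:
    """One query protein plus homologous supporting sequences.

    Returns (query, supporting sequences, per-site tolerance).  Tolerance 0
    everywhere reproduces the query in every homolog.
    """
    tol_low, tol_high, frac_low = conservation_profile
    aa = np.array(list(AMINO_ACIDS))
    query_idx = rng.integers(0, len(aa), size=length)
    query = "".join(aa[query_idx])
    tolerance = np.where(rng.random(length) < frac_low, tol_low, tol_high)
    supports = []
    for _ in range(n_supporting):
        divergence = rng.uniform(0.4, 1.0)
        seq_idx = query_idx.copy()
        flip = rng.random(length) < np.minimum(tolerance * divergence, 0.95)
        for pos in np.nonzero(flip)[0]:
            choices = np.delete(np.arange(len(aa)), seq_idx[pos])
            seq_idx[pos] = rng.choice(choices)
        supports.append("".join(aa[seq_idx]))
    return query, supports, tolerance


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _encode_protein(rng: np.random.Generator, protein: str) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein) + "TAA"


def simulate_gene_model(
    rng: np.random.Generator, gene_id: str, transcript_id: str, protein: str
) -> GeneModel:
    """A 1-3 exon gene model whose spliced translation is ``protein``."""
    cds = _encode_protein(rng, protein)
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else []
    pieces = []
    prev = 0
    for cut in list(cuts) + [len(cds)]:
        pieces.append(cds[prev:cut])
        prev = cut
    introns = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(12, 30))))
               for _ in range(len(pieces) - 1)]
    pre_mrna = pieces[0]
    tx_exons = [(1, len(pieces[0]))]  # transcript-orientation coordinates
    for piece, intron in zip(pieces[1:], introns):
        pre_mrna += intron
        start = len(pre_mrna) + 1
        pre_mrna += piece
        tx_exons.append((start, len(pre_mrna)))
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        genomic_seq = pre_mrna
        exons = tuple(tx_exons)
    else:
        genomic_seq = str(Seq(pre_mrna).reverse_complement())
        L = len(pre_mrna)
        exons = tuple(sorted((L - e + 1, L - s + 1) for s, e in tx_exons))
    return GeneModel(gene_id=gene_id, transcript_id=transcript_id, strand=strand,
                     exons=exons, genomic_seq=genomic_seq)


def simulate_gene_models(rng: np.random.Generator, proteins: dict[str, str]) -> list[GeneModel]:
    models = []
    for tid, protein in proteins.items():
        gene_id = tid.split(".")[0]
        models.append(simulate_gene_model(rng, gene_id, tid, protein))
    return models


def _cds_genomic_coords(model: GeneModel) -> list[int]:
    """Genomic coordinate of every CDS base, in transcript order."""
    coords: list[int] = []
    for start, end in model.exons:
        coords.extend(range(start, end + 1))
    if model.strand == "-":
        coords.reverse()
    return coords


def _transcript_edit_to_genomic(
    model: GeneModel, genomic_seq: str, tx_pos: int, old_codon: str, new_codon: str,
    line_id: str,
) -> list[GenomicVariantRecord]:
    """SNV records realising a codon change at transcript position ``tx_pos``."""
    coords = _cds_genomic_coords(model)
    records = []
    for k, (o, n) in enumerate(zip(old_codon, new_codon)):
        if o == n:
            continue
        gpos = coords[tx_pos + k]
        if model.strand == "-":
            ref = str(Seq(o).reverse_complement())
            alt = str(Seq(n).reverse_complement())
        else:
            ref, alt = o, n
        assert genomic_seq[gpos - model.seq_start] == ref
        records.append(GenomicVariantRecord(line_id, model.gene_id, gpos, ref, alt))
    return records


def _codon_deletion_to_genomic(
    model: GeneModel, genomic_seq: str, tx_pos: int, line_id: str
) -> list[GenomicVariantRecord] | None:
    """Anchored deletion of the codon at ``tx_pos``; None if not representable."""
    coords = _cds_genomic_coords(model)
    trio = sorted(coords[tx_pos:tx_pos + 3])
    if trio[2] - trio[0] != 2:
        return None  # codon spans an intron
    anchor = trio[0] - 1
    lo = anchor - model.seq_start
    if lo < 0:
        return None
    # the anchor must sit in the same exon so the edit does not cross a boundary
    if not any(s <= anchor and trio[2] <= e for s, e in model.exons):
        return None
    ref = genomic_seq[lo:lo + 4]
    return [GenomicVariantRecord(line_id, model.gene_id, anchor, ref, ref[0])]


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    gene_models: list[GeneModel]
    mutations: list[GenomicVariantRecord]
    ancestral_variants: dict[str, list[GenomicVariantRecord]]  # by ancestor
    growth: GrowthTable
    support: dict[str, list[str]]       # transcript id -> supporting sequences
    queries: dict[str, dict[str, str]]  # ancestor -> transcript id -> query protein
    essential_genes: set[str]
    truth: dict

    @property
    def line_to_ancestor(self) -> dict[str, str]:
        return dict(zip(self.truth["lines"]["line_id"],
                        self.truth["lines"]["ancestor_id"]))


def simulate_ma_study(
    config: SimulationConfig, scoring_config: ScoringConfig | None = None
) -> SimulatedStudy:
    """Generate a complete study: genomes, mutations, scores-linked fitness, assays.

    All MA lines of one ancestor share that ancestor's genome (reference plus
    its ancestral variants); per-line mutation coordinates refer to the
    ancestral sequence.  True line fitness is the sum of per-mutation effects
    under ``config.effect_model``; measured growth adds block effects and
    replicate noise, with matched control rows per ancestor.
    """
    rng = np.random.default_rng(config.seed)
    scoring_config = scoring_config or ScoringConfig()
    need_scores = config.effect_model != "uniform_per_mutation"

    # Families and gene models (shared across ancestors).
    proteins: dict[str, str] = {}
    support: dict[str, list[str]] = {}
    tolerances: dict[str, np.ndarray] = {}
    for i in range(config.n_proteins):
        tid = f"g{i:03d}.t1"
        length = max(30, int(rng.poisson(config.protein_length_mean)))
        query, supports, tol = simulate_family(
            rng, length, config.n_supporting_per_protein, config.conservation_profile)
        proteins[tid] = query
        support[tid] = supports
        tolerances[tid] = tol
    gene_models = simulate_gene_models(rng, proteins)
    by_tid = {m.transcript_id: m for m in gene_models}

    # Ancestral variants: substitutions at tolerant sites (selection-screened).
    ancestral: dict[str, list[GenomicVariantRecord]] = {}
    anc_state: dict[str, dict[str, tuple[str, str]]] = {}
    # ancestor -> tid -> (ancestral genomic seq, ancestral spliced CDS)
    ancestors = [f"anc{a + 1}" for a in range(config.n_ancestors)]
    for anc in ancestors:
        ancestral[anc] = []
        anc_state[anc] = {}
        for tid, model in by_tid.items():
            records: list[GenomicVariantRecord] = []
            if rng.random() < config.ancestral_variant_rate:
                tol = tolerances[tid]
                tolerant_sites = np.nonzero(tol > np.min(tol))[0]
                if tolerant_sites.size:
                    site = int(rng.choice(tolerant_sites))
                    cds = splice_cds(model)
                    old_codon = cds[3 * site:3 * site + 3]
                    old_aa = str(Seq(old_codon).translate())
                    # selection-screened variation looks like standing
                    # variation: prefer residues already present among the
                    # homologs at this site
                    standing = sorted({s[site] for s in support[tid]
                                       if site < len(s) and s[site] != old_aa})
                    if standing:
                        new_aa = str(rng.choice(standing))
                    else:
                        new_aa = str(rng.choice([a for a in AMINO_ACIDS if a != old_aa]))
                    new_codon = str(rng.choice(_CODONS[new_aa]))
                    records = _transcript_edit_to_genomic(
                        model, model.genomic_seq, 3 * site, old_codon, new_codon, anc)
            ancestral[anc].extend(records)
            seq, exons = apply_genomic_variants(
                model.exons, model.genomic_seq, records, model.seq_start)
            cds = splice_cds(GeneModel(model.gene_id, tid, model.strand, exons,
                                       seq, model.seq_start))
            anc_state[anc][tid] = (seq, cds)

    queries = {
        anc: {tid: translate_cds(cds, context=tid)
              for tid, (_, cds) in anc_state[anc].items()}
        for anc in ancestors
    }

    # Supporting-set structure is reused for every variant of a protein.
    sets = {}

    def realized_score(anc: str, tid: str, mutant: str) -> float | None:
        if tid not in sets:
            sets[tid] = build_supporting_set(tid, queries[anc][tid], support[tid],
                                             scoring_config)
        from .interchange import ProteinVariantRecord
        res = delta_score(queries[anc][tid],
                          ProteinVariantRecord(tid, "sim", len(queries[anc][tid]), mutant),
                          sets[tid], scoring_config)
        return res.score

    mutations: list[GenomicVariantRecord] = []
    truth_lines = []
    truth_muts = []
    tids = list(proteins)
    for anc in ancestors:
        for li in range(config.n_lines_per_ancestor):
            line_id = f"{anc}_L{li + 1:02d}"
            n_mut = int(rng.poisson(config.mutation_rate_per_line))
            n_mut = min(n_mut, len(tids))
            chosen = rng.choice(len(tids), size=n_mut, replace=False)
            fitness = 0.0
            for ti in chosen:
                tid = tids[ti]
                model = by_tid[tid]
                anc_seq, anc_cds = anc_state[anc][tid]
                query = queries[anc][tid]
                site = int(rng.integers(0, len(query)))
                records: list[GenomicVariantRecord] = []
                mutant: str | None = None
                kind_draw = rng.random()
                if kind_draw < config.codon_deletion_prob:
                    recs = _codon_deletion_to_genomic(
                        _shifted_model(model), anc_seq, 3 * site, line_id)
                    if recs is not None:
                        records = recs
                        mutant = query[:site] + query[site + 1:]
                elif kind_draw < config.codon_deletion_prob + config.nonsense_prob:
                    # premature stop codon: the protein truncates at the site,
                    # the class of variant behind the extreme negative scores
                    old_codon = anc_cds[3 * site:3 * site + 3]
                    records = _transcript_edit_to_genomic(
                        model, anc_seq, 3 * site, old_codon, "TAA", line_id)
                    mutant = query[:site]
                if mutant is None:
                    old_codon = anc_cds[3 * site:3 * site + 3]
                    old_aa = query[site]
                    new_aa = str(rng.choice([a for a in AMINO_ACIDS if a != old_aa]))
                    new_codon = str(rng.choice(_CODONS[new_aa]))
                    records = _transcript_edit_to_genomic(
                        model, anc_seq, 3 * site, old_codon, new_codon, line_id)
                    mutant = query[:site] + new_aa + query[site + 1:]
                mutations.extend(records)
                score = realized_score(anc, tid, mutant) if need_scores else None
                effect = _mutation_effect(config, score)
                fitness += effect
                truth_muts.append({"line_id": line_id, "transcript_id": tid,
                                   "site": site + 1, "effect": effect,
                                   "score": score})
            truth_lines.append({"line_id": line_id, "ancestor_id": anc,
                                "true_fitness": fitness, "n_mutations": n_mut})

    growth = _simulate_growth(rng, config, truth_lines, ancestors)
    gene_ids = sorted({m.gene_id for m in gene_models})
    n_ess = int(round(config.essential_fraction * len(gene_ids)))
    essential = set(rng.choice(gene_ids, size=n_ess, replace=False)) if n_ess else set()
    truth = {
        "lines": pd.DataFrame(truth_lines),
        "mutations": pd.DataFrame(truth_muts),
        "effect_model": config.effect_model,
        "effect_size": config.effect_size,
    }
    return SimulatedStudy(config, gene_models, mutations, ancestral, growth,
                          support, queries, essential, truth)


def _shifted_model(model: GeneModel) -> GeneModel:
    return model


def _mutation_effect(config: SimulationConfig, score: float | None) -> float:
    if config.effect_model == "uniform_per_mutation":
        return config.effect_size
    if score is None:
        return 0.0
    if config.effect_model == "score_linked_threshold" and score >= config.effect_threshold:
        return 0.0
    return config.effect_size * (-score) / 2.5


def _simulate_growth(
    rng: np.random.Generator,
    config: SimulationConfig,
    truth_lines: list[dict],
    ancestors: list[str],
) -> GrowthTable:
    block_effects = rng.normal(0.0, config.block_sd, size=config.n_blocks)
    rows = []
    for rec in truth_lines:
        for r in range(config.n_replicates):
            b = r % config.n_blocks
            value = (config.baseline_growth + rec["true_fitness"]
                     + block_effects[b] + rng.normal(0.0, config.replicate_sd))
            rows.append((rec["line_id"], "ma", rec["ancestor_id"], "benign",
                         f"b{b + 1}", r + 1, value))
    for anc in ancestors:
        for r in range(config.control_replicates):
            b = r % config.n_blocks
            value = (config.baseline_growth + block_effects[b]
                     + rng.normal(0.0, config.replicate_sd))
            rows.append((f"{anc}_ctrl", "control", anc, "benign",
                         f"b{b + 1}", r + 1, value))
    df = pd.DataFrame(rows, columns=[
        "line_id", "role", "ancestor_id", "environment", "block", "replicate",
        "growth_rate"])
    return GrowthTable(df)
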