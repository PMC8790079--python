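"""Delta-alignment variant scoring against clustered supporting sequences.

The score of a protein variant is the difference between the mean alignment
score of the mutant and of the query (wild-type / ancestor) protein against a
set of homologous supporting sequences: the supporting set is greedily
clustered at a percent-identity cutoff (default 75%), the clusters most
similar to the query (default top 30) are retained, and the score is the
across-cluster mean of the within-cluster mean score differences.  Variants
scoring below a preset threshold (default −2.5) are classified deleterious.

Supporting sets are an input here (in the original tool they come from a
BLAST search of NCBI nr); any FASTA of homologs works, including the
synthetic families produced by :mod:`maprove.synthetic_data`.

Alignment flavour: affine gaps (gap of length L costs ``gap_open +
(L-1)*gap_extend``) over a substitution matrix (default BLOSUM62).  The
shorter sequence is aligned end to end; terminal overhangs of the longer
sequence are free.  Equal-length pairs are aligned globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

from .interchange import ProteinVariantRecord
from .mutagenesis import variant_kind

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = -2.5
MIN_CLUSTERS = 30   # below this, scoring accuracy degrades
MIN_SUPPORT = 50    # below this many supporting sequences, likewise


class ScoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _load_matrix(name: str) -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load(name)
    alphabet = "".join(mat.alphabet)
    return alphabet, np.asarray(mat, dtype=np.float64)


@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the scoring stage; defaults mirror the original tool."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    cluster_identity: float = 0.75
    max_clusters: int = 30
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_identity <= 1.0):
            raise ScoringError("cluster_identity must be in (0, 1]")
        if self.max_clusters < 1:
            raise ScoringError("max_clusters must be >= 1")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ScoringError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ScoringError("gap_extend must not exceed gap_open")

    @property
    def matrix(self) -> tuple[str, np.ndarray]:
        return _load_matrix(self.substitution_matrix)


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

_NEG = -1.0e30


@njit(cache=True)
def _gotoh(ai, bi, S, gap_open, gap_ext, free_b_ends):  # pragma: no cover - jitted
    n = ai.shape[0]
    m = bi.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # a residue vs gap (always penalised)
    Y = np.full((n + 1, m + 1), _NEG)  # gap vs b residue (free at b's ends)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        if free_b_ends:
            Y[0, j] = 0.0
        else:
            prev = M[0, j - 1] - gap_open if j == 1 else Y[0, j - 1] - gap_ext
            Y[0, j] = prev
    for i in range(1, n + 1):
        X[i, 0] = M[0, 0] - gap_open if i == 1 else X[i - 1, 0] - gap_ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            h = M[i - 1, j - 1]
            if X[i - 1, j - 1] > h:
                h = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > h:
                h = Y[i - 1, j - 1]
            M[i, j] = h + S[ai[i - 1], bi[j - 1]]
            x = M[i - 1, j] - gap_open
            if Y[i - 1, j] - gap_open > x:
                x = Y[i - 1, j] - gap_open
            if X[i - 1, j] - gap_ext > x:
                x = X[i - 1, j] - gap_ext
            X[i, j] = x
            y = M[i, j - 1] - gap_open
            if X[i, j - 1] - gap_open > y:
                y = X[i, j - 1] - gap_open
            if Y[i, j - 1] - gap_ext > y:
                y = Y[i, j - 1] - gap_ext
            Y[i, j] = y
    if free_b_ends:
        best = _NEG
        for j in range(m + 1):
            for v in (M[n, j], X[n, j], Y[n, j]):
                if v > best:
                    best = v
        return best
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
    if Y[n, m] > best:
        best = Y[n, m]
    return best


def _encode(seq: str, alphabet: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ScoringError(f"unknown residue {exc.args[0]!r} in sequence") from None


class _Aligner:
    """Caches the encoded substitution matrix for repeated calls."""

    def __init__(self, config: ScoringConfig):
        self.config = config
        self.alphabet, self.S = config.matrix
        self.index = {c: i for i, c in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> float:
        if not a or not b:
            raise ScoringError("cannot align an empty sequence")
        # shorter sequence is aligned globally; the longer one's terminal
        # overhangs are free.  Equal lengths: plain global alignment.
        if len(a) > len(b):
            a, b = b, a
        ai = _encode(a, self.alphabet, self.index)
        bi = _encode(b, self.alphabet, self.index)
        return float(_gotoh(ai, bi, self.S, self.config.gap_open,
                            self.config.gap_extend, len(a) < len(b)))


def align_score(a: str, b: str, config: ScoringConfig | None = None) -> float:
    """Optimal affine-gap alignment score of two protein sequences."""
    return _Aligner(config or ScoringConfig()).score(a, b)


# ---------------------------------------------------------------------------
# Percent identity and greedy clustering
# ---------------------------------------------------------------------------

def percent_identity(a: str, b: str) -> float:
    """Matches / alignment columns of the unit-cost global alignment."""
    if not a or not b:
        raise ScoringError("cannot compute identity of an empty sequence")
    res = edlib.align(a, b, task="path")
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            k = int(num)
            num = ""
            columns += k
            if ch == "=":
                matches += k
    return matches / columns


def greedy_cluster(sequences: list[str], cluster_identity: float) -> list[list[int]]:
    """CD-HIT-style greedy clustering by decreasing length.

    Each sequence joins the first existing cluster whose representative (its
    founding, longest member) shares at least ``cluster_identity`` identity,
    else founds a new cluster.  Length ties in the greedy order are broken
    lexicographically so the partition does not depend on input order.
    Returns clusters as lists of input indices in founding order.
    """
    if not sequences:
        raise ScoringError("cannot cluster an empty sequence list")
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), sequences[i]))
    clusters: list[list[int]] = []
    for i in order:
        for cluster in clusters:
            rep = sequences[cluster[0]]
            if percent_identity(rep, sequences[i]) >= cluster_identity:
                cluster.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def select_top_clusters(
    clusters: list[list[int]],
    sequences: list[str],
    query: str,
    max_clusters: int,
) -> list[int]:
    """Indices of the clusters most similar to the query, capped.

    Ranked by the representative's percent identity to the query, descending;
    ties broken by longer representative, then founding order.
    """
    if not clusters:
        raise ScoringError("no clusters to select from")
    keyed = []
    for ci, cluster in enumerate(clusters):
        rep = sequences[cluster[0]]
        keyed.append((-percent_identity(rep, query), -len(rep), ci))
    keyed.sort()
    return [ci for _, _, ci in keyed[:max_clusters]]


# ---------------------------------------------------------------------------
# Supporting sets and the delta score
# ---------------------------------------------------------------------------

@dataclass
class SupportingSet:
    """A query's supporting sequences with cluster structure and selection."""

    query_id: str
    sequences: list[str]
    clusters: list[list[int]]
    selected: list[int]
    _query_means: list[float] | None = field(default=None, repr=False)


def build_supporting_set(
    query_id: str, query: str, sequences: list[str], config: ScoringConfig
) -> SupportingSet:
    if not sequences:
        return SupportingSet(query_id, [], [], [])
    clusters = greedy_cluster(sequences, config.cluster_identity)
    selected = select_top_clusters(clusters, sequences, query, config.max_clusters)
    return SupportingSet(query_id, list(sequences), clusters, selected)


@dataclass(frozen=True)
class ScoreResult:
    """Delta score, classification and diagnostics for one protein variant."""

    protein_id: str
    variant: str
    score: float | None
    classification: str | None
    n_clusters: int
    n_supporting: int
    flags: frozenset[str]
    line_id: str = ""
    gene_id: str = ""

    @property
    def scored(self) -> bool:
        return "unscored" not in self.flags


def _diag_flags(n_clusters: int, n_supporting: int) -> set[str]:
    flags = set()
    if n_clusters < MIN_CLUSTERS:
        flags.add("few_clusters")
    if n_supporting < MIN_SUPPORT:
        flags.add("few_support")
    return flags


def classify(score: float, threshold: float) -> str:
    """Deleterious strictly below the threshold, else neutral."""
    return "deleterious" if score < threshold else "neutral"


def delta_score(
    query: str,
    variant: ProteinVariantRecord | str,
    supporting_set: SupportingSet,
    config: ScoringConfig,
) -> ScoreResult:
    """Score one variant: across-cluster mean of within-cluster mean deltas.

    An empty supporting set, or a mutant too degenerate to align (e.g. a
    protein abolished by an immediate stop codon), yields an ``unscored``
    result rather than a number.
    """
    if isinstance(variant, ProteinVariantRecord):
        mutant, desc = variant.mutant_seq, variant.description
        protein_id = variant.protein_id or supporting_set.query_id
    else:
        from .interchange import apply_description
        mutant, desc = apply_description(variant, query), variant
        protein_id = supporting_set.query_id

    n_support = len(supporting_set.sequences)
    n_clusters = len(supporting_set.clusters)
    flags = _diag_flags(n_clusters, n_support)
    if n_support == 0 or not supporting_set.selected or not mutant:
        flags.add("unscored")
        return ScoreResult(protein_id, desc, None, None, n_clusters, n_support,
                           frozenset(flags))

    aligner = _Aligner(config)
    if supporting_set._query_means is None:
        supporting_set._query_means = [
            float(np.mean([aligner.score(query, supporting_set.sequences[i])
                           for i in supporting_set.clusters[ci]]))
            for ci in supporting_set.selected
        ]
    deltas = []
    for qmean, ci in zip(supporting_set._query_means, supporting_set.selected):
        mmean = float(np.mean([aligner.score(mutant, supporting_set.sequences[i])
                               for i in supporting_set.clusters[ci]]))
        deltas.append(mmean - qmean)
    score = float(np.mean(deltas))
    return ScoreResult(protein_id, desc, score, classify(score, config.threshold),
                       n_clusters, n_support, frozenset(flags))


def gene_level_score(transcript_results: list[ScoreResult]) -> ScoreResult:
    """Reduce alternative-transcript results to the minimum score.

    The classification is recomputed from the winning score; if every
    transcript is unscored, the gene is unscored.
    """
    if not transcript_results:
        raise ScoringError("no transcript results to reduce")
    scored = [r for r in transcript_results if r.scored]
    if not scored:
        return transcript_results[0]
    return min(scored, key=lambda r: r.score)


# ---------------------------------------------------------------------------
# Study-level driver, summaries, diagnostics
# ---------------------------------------------------------------------------

def score_variants(
    mutants: list,  # list[mutagenesis.MutantProtein]
    support: dict[str, list[str]],
    config: ScoringConfig,
    reduce_by_gene: bool = True,
) -> list[ScoreResult]:
    """Score every mutant protein of a study, reusing per-protein structure.

    ``support`` maps transcript id to its supporting sequences.  When a gene
    has several mutated transcripts in a line, the minimum score across them
    is reported for the gene (``reduce_by_gene``).
    """
    # queries can differ between ancestral backgrounds, so the cache key is
    # (transcript, query), not the transcript alone
    sets: dict[tuple[str, str], SupportingSet] = {}
    results: list[ScoreResult] = []
    by_line_gene: dict[tuple[str, str], list[ScoreResult]] = {}
    for mp in mutants:
        if mp.record is None:
            continue  # synonymous at the protein level: nothing to score
        key = (mp.transcript_id, mp.query_seq)
        if key not in sets:
            sets[key] = build_supporting_set(
                mp.transcript_id, mp.query_seq, support.get(mp.transcript_id, []), config)
        res = delta_score(mp.query_seq, mp.record, sets[key], config)
        res = replace(res, line_id=mp.line_id, gene_id=mp.gene_id)
        by_line_gene.setdefault((mp.line_id, mp.gene_id), []).append(res)
    for (line_id, gene_id), group in sorted(by_line_gene.items()):
        if reduce_by_gene:
            results.append(gene_level_score(group))
        else:
            results.extend(group)
    return results


def results_to_frame(results: list[ScoreResult]) -> pd.DataFrame:
    rows = [
        (r.line_id, r.gene_id, r.protein_id, r.variant,
         np.nan if r.score is None else r.score,
         r.classification or "", r.n_clusters, r.n_supporting,
         ",".join(sorted(r.flags)))
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "line_id", "gene_id", "protein_id", "variant", "score",
        "classification", "n_clusters", "n_supporting", "flags"])


def summarize_by_variant_type(results: list[ScoreResult]) -> pd.DataFrame:
    """Per-variant-type counts and score extremes (Table-2-style summary).

    Each scored result is assigned to exactly one of: single aa substitution,
    duplication, deletion, insertion, complex.  A delins — more than one kind
    of change in the same protein — is complex.
    """
    scored = [r for r in results if r.scored]
    rows = []
    kinds = ["single aa substitution", "duplication", "deletion", "insertion", "complex"]
    by_kind: dict[str, list[float]] = {k: [] for k in kinds}
    for r in scored:
        by_kind[variant_kind(r.variant)].append(r.score)
    for kind in kinds:
        scores = by_kind[kind]
        if scores:
            rows.append((kind, len(scores), max(scores), min(scores)))
    return pd.DataFrame(rows, columns=["type", "count", "max_score", "min_score"])


def cluster_support_report(results: list[ScoreResult]) -> dict:
    """QC report: how often scoring rested on thin supporting evidence.

    Percentages are also reported rounded to the nearest whole percent, the
    precision at which such diagnostics are conventionally quoted.
    """
    n_total = len(results)
    if n_total == 0:
        raise ScoringError("no results to report on")
    n_few_clusters = sum(1 for r in results if "few_clusters" in r.flags)
    n_few_support = sum(1 for r in results if "few_support" in r.flags)
    n_unscored = sum(1 for r in results if not r.scored)
    return {
        "n_total": n_total,
        "n_few_clusters": n_few_clusters,
        "pct_few_clusters": round(100.0 * n_few_clusters / n_total),
        "n_few_support": n_few_support,
        "pct_few_support": round(100.0 * n_few_support / n_total),
        "n_unscored": n_unscored,
    }
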