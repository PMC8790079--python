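"""Collapse per-variant scores into per-line summary statistics.

Per MA line the pipeline reports:

* ``psi_tot`` — number of scored mutant proteins (each protein once per line);
* ``psi_del`` — those with score strictly below the deleterious threshold;
* ``psi_abs`` — those with |score| strictly above |threshold| (a +3 score
  enters ``psi_abs`` but not ``psi_del`` at the default −2.5);
* ``psi_non_del`` — ``psi_tot − psi_del``;
* ``*_ess`` — the same counts restricted to an essential-gene list;
* ``sigma_tot`` — log(1 − sum of scores), a log-compressed aggregate of the
  raw scores (undefined and flagged when the sum reaches 1, which a large
  positive score can produce).

Unscored proteins are excluded from every statistic and tallied separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ScoreResult

logger = logging.getLogger(__name__)


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class LineSummary:
    line_id: str
    ancestor_id: str
    psi_tot: int
    psi_del: int
    psi_abs: int
    psi_non_del: int
    psi_tot_ess: int
    psi_del_ess: int
    psi_abs_ess: int
    sigma_tot: float | None
    sigma_tot_ess: float | None
    n_unscored: int
    relative_genome_size: float = 1.0


def _sigma(scores: list[float]) -> float | None:
    total = float(sum(scores))
    if total >= 1.0:
        return None  # log argument non-positive: flagged, never silently dropped
    return math.log(1.0 - total)


def summarize_line(
    results: list[ScoreResult],
    essential_genes: set[str] | None = None,
    threshold: float = -2.5,
    ancestor_id: str = "",
    relative_genome_size: float = 1.0,
    line_id: str = "",
) -> LineSummary:
    """Summary statistics for one MA line's scored mutant proteins.

    An empty result list is legal — a line whose mutations were all
    synonymous still belongs in the study, with every count at zero.
    """
    line_ids = {r.line_id for r in results if r.line_id}
    if len(line_ids) > 1:
        raise AggregationError(f"mixed line ids in one summary: {sorted(line_ids)}")
    if line_ids:
        found = line_ids.pop()
        if line_id and line_id != found:
            raise AggregationError(f"results belong to {found!r}, not {line_id!r}")
        line_id = found
    essential_genes = essential_genes or set()

    scored = [r for r in results if r.scored]
    unscored = [r for r in results if not r.scored]
    scores = [r.score for r in scored]
    ess = [r for r in scored if r.gene_id in essential_genes or r.protein_id in essential_genes]
    cut = abs(threshold)

    def counts(rs):
        tot = len(rs)
        dele = sum(1 for r in rs if r.score < threshold)
        absn = sum(1 for r in rs if abs(r.score) > cut)
        return tot, dele, absn

    psi_tot, psi_del, psi_abs = counts(scored)
    psi_tot_e, psi_del_e, psi_abs_e = counts(ess)
    return LineSummary(
        line_id=line_id, ancestor_id=ancestor_id,
        psi_tot=psi_tot, psi_del=psi_del, psi_abs=psi_abs,
        psi_non_del=psi_tot - psi_del,
        psi_tot_ess=psi_tot_e, psi_del_ess=psi_del_e, psi_abs_ess=psi_abs_e,
        sigma_tot=_sigma(scores),
        sigma_tot_ess=_sigma([r.score for r in ess]),
        n_unscored=len(unscored),
        relative_genome_size=relative_genome_size,
    )


def summaries_to_frame(summaries: list[LineSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append((
            s.line_id, s.ancestor_id, s.psi_tot, s.psi_del, s.psi_abs,
            s.psi_non_del, s.psi_tot_ess, s.psi_del_ess, s.psi_abs_ess,
            np.nan if s.sigma_tot is None else s.sigma_tot,
            np.nan if s.sigma_tot_ess is None else s.sigma_tot_ess,
            s.n_unscored, s.relative_genome_size))
    return pd.DataFrame(rows, columns=[
        "line_id", "ancestor_id", "psi_tot", "psi_del", "psi_abs",
        "psi_non_del", "psi_tot_ess", "psi_del_ess", "psi_abs_ess",
        "sigma_tot", "sigma_tot_ess", "n_unscored", "relative_genome_size"])


# ---------------------------------------------------------------------------
# Study-level bookkeeping
# ---------------------------------------------------------------------------

STUDY_COLUMNS = [
    "ancestor_id", "n_mutated_proteins", "n_with_prior_variants",
    "n_lines", "n_protein_variants",
]


def summarize_study(
    results: list[ScoreResult],
    line_to_ancestor: dict[str, str],
    prior_variant_proteins: set[str] | None = None,
) -> pd.DataFrame:
    """Per-ancestor accounting of mutated proteins, lines and variants.

    Per ancestor: the number of distinct mutated proteins (each protein
    counted once even if several of the ancestor's MA lines mutate it), how
    many of those carried prior ancestor-vs-reference variants, the number of
    MA lines, and the number of protein variants submitted (every change in
    any line counted).  A ``Total`` row of column sums is appended.
    """
    prior = prior_variant_proteins or set()
    per_anc: dict[str, dict] = {}
    for r in results:
        if r.line_id not in line_to_ancestor:
            raise AggregationError(f"line {r.line_id!r} has no ancestor mapping")
        anc = line_to_ancestor[r.line_id]
        slot = per_anc.setdefault(anc, {"proteins": set(), "lines": set(), "variants": 0})
        slot["proteins"].add(r.protein_id)
        slot["lines"].add(r.line_id)
        slot["variants"] += 1
    rows = []
    for anc in sorted(per_anc):
        slot = per_anc[anc]
        rows.append((anc, len(slot["proteins"]),
                     len(slot["proteins"] & prior),
                     len(slot["lines"]), slot["variants"]))
    table = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    return add_total_row(table)


def add_total_row(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``Total`` row equal to the column-wise sums."""
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise AggregationError(f"study table lacks columns {missing}")
    body = table[table["ancestor_id"] != "Total"]
    total = ["Total"] + [int(body[c].sum()) for c in STUDY_COLUMNS[1:]]
    return pd.concat([body, pd.DataFrame([total], columns=STUDY_COLUMNS)],
                     ignore_index=True)


def combine_study_counts(tables: list[pd.DataFrame]) -> dict[str, int]:
    """Sum the Total rows of several per-dataset study tables.

    Proteins are counted per dataset; a protein mutated in two datasets
    counts in each (the tables do not share protein identities).
    """
    out = {c: 0 for c in STUDY_COLUMNS[1:]}
    for table in tables:
        total = table[table["ancestor_id"] == "Total"]
        if len(total) != 1:
            raise AggregationError("study table lacks a Total row")
        for c in out:
            out[c] += int(total.iloc[0][c])
    return out


def apply_exclusions(
    lines: list[str] | pd.DataFrame,
    exclusion_list: dict[str, str],
) -> list[str] | pd.DataFrame:
    """Drop excluded lines, logging each with its reason.

    Unknown ids in the exclusion list are warnings, not errors.
    """
    if isinstance(lines, pd.DataFrame):
        present = set(lines["line_id"])
    else:
        present = set(lines)
    for line_id, reason in exclusion_list.items():
        if line_id in present:
            logger.info("excluding line %s: %s", line_id, reason)
        else:
            logger.warning("exclusion list names unknown line %s (%s); ignored",
                           line_id, reason)
    keep = present - set(exclusion_list)
    if isinstance(lines, pd.DataFrame):
        return lines[lines["line_id"].isin(keep)].reset_index(drop=True)
    return [l for l in lines if l in keep]
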