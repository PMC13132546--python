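"""Top-k overlap scoring of co-dependency lists and candidate selection.

The screen's statistic is a plain count: a gene's overlap score S is the
number of distinct seed genes whose top-k co-dependency list contains it.
Genes recurrently co-dependent with many independent anchors of a pathway
are strong guilt-by-association candidates for that pathway. The score
universe is the set of genes appearing in at least one list, and the
cutoff is either fixed (score >= 3 is the conventional choice) or derived
so that the retained genes make up at most a target top fraction of the
scored universe (about the top 5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codependency import CoDependencyTable
from .errors import ParameterError, ValidationError
from .io_formats import GeneId, SeedList

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3
DEFAULT_TOP_FRACTION = 0.05


@dataclass
class ScoreRecord:
    """Overlap score of one gene with its supporting evidence."""

    gene: GeneId
    score: int
    supporting_seeds: list[tuple[GeneId, float, int]]  # (seed, r, rank in list)
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if self.score != len({s.symbol for s, _, _ in self.supporting_seeds}):
            raise ValidationError(
                f"score of {self.gene.symbol} does not equal its distinct "
                f"supporting-seed count")


@dataclass
class ScreenResult:
    """Scored genes sorted by (score desc, symbol asc) plus the cutoff."""

    records: list[ScoreRecord]
    cutoff: int
    top_fraction_achieved: float
    parameters: dict = field(default_factory=dict)
    seed_symbols: set[str] = field(default_factory=set)

    def scores_dataframe(self) -> pd.DataFrame:
        """Documented column order: gene, entrez, score, n_positive_r,
        n_negative_r, supporting_seeds, is_seed."""
        rows = [{
            "gene": rec.gene.symbol,
            "entrez": rec.gene.entrez_id,
            "score": rec.score,
            "n_positive_r": rec.n_positive,
            "n_negative_r": rec.n_negative,
            "supporting_seeds": ";".join(
                s.symbol for s, _, _ in rec.supporting_seeds),
            "is_seed": rec.gene.symbol in self.seed_symbols,
        } for rec in self.records]
        return pd.DataFrame(rows, columns=[
            "gene", "entrez", "score", "n_positive_r", "n_negative_r",
            "supporting_seeds", "is_seed"])


def overlap_scores(table: CoDependencyTable) -> list[ScoreRecord]:
    """Score every gene appearing in at least one seed's top-k list.

    Each seed contributes at most once per gene; the returned records are
    sorted by score descending, then symbol/Entrez ascending.
    """
    if not table.lists:
        raise ValidationError("empty co-dependency table")
    support: dict[GeneId, list[tuple[GeneId, float, int]]] = {}
    for seed, entries in table.lists.items():
        seen_here: set[GeneId] = set()
        for e in entries:
            if e.partner in seen_here:  # impossible by construction; checked
                logger.warning("duplicate partner %s in list of %s ignored",
                               e.partner.symbol, seed.symbol)
                continue
            seen_here.add(e.partner)
            support.setdefault(e.partner, []).append((seed, e.r, e.rank))
    records = []
    for gene, sup in support.items():
        n_pos = sum(1 for _, r, _ in sup if r > 0)
        n_neg = sum(1 for _, r, _ in sup if r < 0)
        records.append(ScoreRecord(
            gene=gene, score=len({s.symbol for s, _, _ in sup}),
            supporting_seeds=sorted(sup, key=lambda t: t[0].sort_key),
            n_positive=n_pos, n_negative=n_neg))
    records.sort(key=lambda rec: (-rec.score, rec.gene.sort_key))
    return records


def score_cutoff(records: list[ScoreRecord], top_fraction: float) -> int:
    """Smallest achieved score c whose tail (S >= c) is at most the target
    fraction of all scored genes.

    If no achieved score has a small enough tail (e.g. all scores equal),
    returns max score + 1 with a warning — the candidate set is then empty.
    """
    if not records:
        raise ValidationError("no score records")
    if not (0.0 < top_fraction < 1.0):
        raise ParameterError("top_fraction must be in (0, 1)")
    scores = np.array([rec.score for rec in records])
    n = len(scores)
    for c in sorted(set(scores)):
        if (scores >= c).sum() / n <= top_fraction:
            return int(c)
    logger.warning("no score threshold reaches the top %.3g fraction; "
                   "returning max score + 1", top_fraction)
    return int(scores.max()) + 1


def screen_from_table(table: CoDependencyTable,
                      seeds: SeedList | None = None,
                      cutoff: int | None = DEFAULT_CUTOFF,
                      top_fraction: float = DEFAULT_TOP_FRACTION
                      ) -> ScreenResult:
    """Score a co-dependency table and resolve the candidate cutoff.

    An explicit ``cutoff`` takes precedence; pass ``cutoff=None`` to derive
    it from ``top_fraction``. The achieved top fraction is always reported.
    """
    records = overlap_scores(table)
    if cutoff is None:
        cutoff = score_cutoff(records, top_fraction)
    n = len(records)
    achieved = sum(1 for rec in records if rec.score >= cutoff) / n
    seed_symbols = (seeds.symbols if seeds is not None
                    else {g.symbol for g in table.seeds})
    return ScreenResult(
        records=records, cutoff=int(cutoff), top_fraction_achieved=achieved,
        parameters={"k": table.k, "ranking": table.ranking,
                    "min_pairs": table.min_pairs, "cutoff": int(cutoff),
                    "top_fraction": top_fraction},
        seed_symbols=seed_symbols)


def run_screen(matrix, seeds: SeedList, k: int = 100,
               ranking: str = "absolute", min_pairs: int = 25,
               cutoff: int | None = DEFAULT_CUTOFF,
               top_fraction: float = DEFAULT_TOP_FRACTION) -> ScreenResult:
    """End-to-end screen: correlations -> top-k lists -> overlap scores."""
    from .codependency import build_codependency_table
    table = build_codependency_table(matrix, seeds, k=k, ranking=ranking,
                                     min_pairs=min_pairs)
    return screen_from_table(table, seeds=seeds, cutoff=cutoff,
                             top_fraction=top_fraction)


def candidate_hits(result: ScreenResult, exclude_seeds: bool = True,
                   known_gene_annotations: dict[str, str] | None = None
                   ) -> pd.DataFrame:
    """Genes at or above the cutoff, ranked; optionally minus the seeds.

    ``known_gene_annotations`` (symbol -> free-text note) is a pass-through
    column for the manual novelty triage; nothing is computed from it.
    """
    df = result.scores_dataframe()
    df = df[df["score"] >= result.cutoff]
    if exclude_seeds:
        df = df[~df["is_seed"]]
    df = df.copy()
    notes = known_gene_annotations or {}
    df["annotation"] = [notes.get(g, "") for g in df["gene"]]
    return df.reset_index(drop=True)
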