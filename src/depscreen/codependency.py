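"""Gene-gene co-dependency correlations and ranked top-k partner lists.

Two genes are "co-dependent" when their dependency profiles across cell
lines correlate: cell lines that need one tend to need the other, the
classic guilt-by-association signal for shared pathway membership. This
module computes pairwise-complete Pearson correlations over a gene-effect
matrix and, for each query ("seed") gene, the top-k co-dependent partners.

Ranking conventions
-------------------
``absolute`` (default) ranks partners by |r| so that strong negative
co-dependencies (e.g. an inhibitor of the seed's pathway) are retained;
``signed_positive`` ranks by r descending. Ties are broken
deterministically by (symbol, Entrez id) ascending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeneLookupError, ParameterError, ValidationError
from .io_formats import EffectMatrix, GeneId, SeedList, read_table

logger = logging.getLogger(__name__)

DEFAULT_K = 100
DEFAULT_MIN_PAIRS = 25

#: a profile is treated as constant when its variance falls below this
#: fraction of its mean square (guards catastrophic cancellation)
_VAR_TOL = 1e-12


@dataclass(frozen=True)
class CoDependencyEntry:
    """One ranked partner of a seed gene."""

    partner: GeneId
    r: float
    rank: int
    n_pairs: int


@dataclass
class CoDependencyTable:
    """Per-seed ranked top-k co-dependency lists plus the run parameters."""

    lists: dict[GeneId, list[CoDependencyEntry]]
    k: int
    ranking: str
    min_pairs: int
    skipped_seeds: list[GeneId] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lists:
            raise ValidationError("co-dependency table has no seed lists")

    @property
    def seeds(self) -> list[GeneId]:
        return list(self.lists)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Combined long-format table (one row per seed x partner)."""
        rows = []
        for seed, entries in self.lists.items():
            for e in entries:
                rows.append({
                    "seed": seed.symbol,
                    "seed_entrez": seed.entrez_id,
                    "partner": e.partner.symbol,
                    "partner_entrez": e.partner.entrez_id,
                    "r": e.r,
                    "rank": e.rank,
                    "n_pairs": e.n_pairs,
                })
        return pd.DataFrame(
            rows, columns=["seed", "seed_entrez", "partner", "partner_entrez",
                           "r", "rank", "n_pairs"])


def _masked_moments(x: np.ndarray, Y: np.ndarray):
    """Pairwise-complete first/second moments of column x against matrix Y."""
    vx = np.isfinite(x)
    VY = np.isfinite(Y)
    V = vx[:, None] & VY
    x0 = np.where(vx, x, 0.0)
    Y0 = np.where(VY, Y, 0.0)
    # all reductions use the same np.sum path so that swapping the two
    # genes gives bitwise-identical moments (exact r symmetry)
    n = V.sum(axis=0)
    sx = (x0[:, None] * V).sum(axis=0)
    sy = (Y0 * V).sum(axis=0)
    sxx = ((x0 * x0)[:, None] * V).sum(axis=0)
    syy = (Y0 * Y0 * V).sum(axis=0)
    sxy = (Y0 * (x0[:, None] * V)).sum(axis=0)
    return n, sx, sy, sxx, syy, sxy


def correlation_vector(matrix: EffectMatrix, seed: GeneId | str,
                       min_pairs: int = DEFAULT_MIN_PAIRS) -> np.ndarray:
    """Pearson correlation of one gene against every column of the matrix.

    Entries are NaN where fewer than ``min_pairs`` cell lines observe both
    genes, or where either profile is constant on the shared lines.
    """
    if min_pairs < 3:
        raise ParameterError("min_pairs must be >= 3")
    j = matrix.column_index(seed)
    x = matrix.values[:, j]
    n, sx, sy, sxx, syy, sxy = _masked_moments(x, matrix.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r = cov / np.sqrt(varx * vary)
    bad = (n < min_pairs) | (varx <= _VAR_TOL * sxx) | (vary <= _VAR_TOL * syy)
    r = np.where(bad, np.nan, r)
    # exact correlations can exceed |1| by one ulp; clip, preserving NaN
    return np.clip(r, -1.0, 1.0)


def pairwise_correlation(matrix: EffectMatrix, gene_a: GeneId | str,
                         gene_b: GeneId | str,
                         min_pairs: int = DEFAULT_MIN_PAIRS) -> float:
    """Pairwise-complete Pearson r between two gene profiles.

    Returns NaN when fewer than ``min_pairs`` shared observations exist or
    either profile has zero variance on the shared lines. The computation
    is exactly symmetric in its two arguments.
    """
    r = correlation_vector(matrix, gene_a, min_pairs=min_pairs)
    return float(r[matrix.column_index(gene_b)])


def _ranking_key(ranking: str):
    if ranking == "absolute":
        return lambda e: (-abs(e[1]), e[0].sort_key)
    if ranking == "signed_positive":
        return lambda e: (-e[1], e[0].sort_key)
    raise ParameterError(f"unknown ranking: {ranking}")


def top_k_codependencies(matrix: EffectMatrix, seed: GeneId | str,
                         k: int = DEFAULT_K, ranking: str = "absolute",
                         min_pairs: int = DEFAULT_MIN_PAIRS
                         ) -> list[CoDependencyEntry]:
    """The seed gene's ranked top-k co-dependent partners.

    The seed column itself is excluded; the list is shorter than k only
    when the usable gene universe is smaller.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    j = matrix.column_index(seed)
    r = correlation_vector(matrix, seed, min_pairs=min_pairs)
    x = matrix.values[:, j]
    vx = np.isfinite(x)
    n_shared = (vx[:, None] & np.isfinite(matrix.values)).sum(axis=0)
    candidates = [
        (matrix.genes[i], float(r[i]), int(n_shared[i]))
        for i in range(matrix.n_genes)
        if i != j and math.isfinite(r[i])
    ]
    if not candidates:
        logger.warning("no partner of %s meets min_pairs=%d",
                       matrix.genes[j].symbol, min_pairs)
        return []
    candidates.sort(key=_ranking_key(ranking))
    return [
        CoDependencyEntry(partner=g, r=rv, rank=i + 1, n_pairs=np_)
        for i, (g, rv, np_) in enumerate(candidates[:k])
    ]


def build_codependency_table(matrix: EffectMatrix, seeds: SeedList,
                             k: int = DEFAULT_K, ranking: str = "absolute",
                             min_pairs: int = DEFAULT_MIN_PAIRS
                             ) -> CoDependencyTable:
    """One top-k list per seed present in the matrix.

    Seeds absent from the matrix are skipped (recorded in
    ``skipped_seeds`` and logged); an all-absent seed list is an error.
    """
    lists: dict[GeneId, list[CoDependencyEntry]] = {}
    skipped: list[GeneId] = []
    for seed in seeds:
        try:
            j = matrix.column_index(seed)
        except GeneLookupError:
            skipped.append(seed)
            continue
        resolved = matrix.genes[j]
        lists[resolved] = top_k_codependencies(
            matrix, resolved, k=k, ranking=ranking, min_pairs=min_pairs)
    if skipped:
        logger.warning("skipped %d seed(s) absent from matrix: %s",
                       len(skipped), ", ".join(g.symbol for g in skipped))
    if not lists:
        raise ValidationError("no seed gene is present in the matrix")
    return CoDependencyTable(lists, k=k, ranking=ranking,
                             min_pairs=min_pairs, skipped_seeds=skipped)


def load_precomputed_table(paths: dict[str, str | Path], k: int,
                           ranking: str = "precomputed") -> CoDependencyTable:
    """Build a CoDependencyTable from externally supplied per-seed top-k files.

    Each file is a TSV with columns ``partner``, ``partner_entrez``, ``r``,
    ``rank`` (``n_pairs`` optional), e.g. portal exports; this bypasses the
    correlation engine entirely for exact reproduction of portal-era lists.
    """
    lists: dict[GeneId, list[CoDependencyEntry]] = {}
    for seed_symbol, path in paths.items():
        df = read_table(path).sort_values("rank")
        entries = []
        for _, row in df.iterrows():
            entrez = row.get("partner_entrez")
            entrez = None if pd.isna(entrez) else int(entrez)
            entries.append(CoDependencyEntry(
                partner=GeneId(str(row["partner"]), entrez),
                r=float(row["r"]), rank=int(row["rank"]),
                n_pairs=int(row["n_pairs"]) if "n_pairs" in df.columns else 0,
            ))
        lists[GeneId.parse(seed_symbol)] = entries[:k]
    return CoDependencyTable(lists, k=k, ranking=ranking, min_pairs=0)


def write_per_seed_tables(table: CoDependencyTable, out_dir: str | Path) -> None:
    """One TSV per seed (partner, partner_entrez, r, rank, n_pairs)."""
    from .io_formats import write_table
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long = table.to_long_dataframe()
    for seed, sub in long.groupby("seed", sort=False):
        write_table(
            sub[["partner", "partner_entrez", "r", "rank", "n_pairs"]],
            out_dir / f"codependency_{seed}.tsv",
        )
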