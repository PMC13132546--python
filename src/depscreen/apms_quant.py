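"""NSAF normalization and bait-vs-control enrichment for AP-MS runs.

The normalized spectral abundance factor divides a protein's spectral
count by its length (SAF = SpC/L, longer proteins yield more peptides)
and normalizes SAFs to sum to one within a run:

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)

pNSAF is the same quantity as a percentage. Enrichment against control
pull-downs is summarized as a pseudocounted log2 fold of bait NSAF over
the mean control NSAF. This ranking statistic is a deliberately simple
stand-in for formal enrichment-significance modelling and makes no
p-value claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, ParameterError, ValidationError
from .io_formats import SpectralCountTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_FOLD = 2.0


@dataclass(frozen=True)
class NsafRecord:
    protein_id: str
    spectral_count: int
    length_aa: int
    saf: float
    nsaf: float
    pnsaf: float


@dataclass(frozen=True)
class EnrichmentRecord:
    protein_id: str
    bait_nsaf: float
    mean_control_nsaf: float
    log2_fold_enrichment: float
    enriched: bool


def nsaf_normalize(table: SpectralCountTable, run_label: str
                   ) -> list[NsafRecord]:
    """NSAF/pNSAF values for every protein of one run.

    Zero-count proteins get NSAF 0; a run whose counts are all zero is
    degenerate (nothing to normalize).
    """
    run = table.run(run_label)
    spc = run["spectral_count"].to_numpy(dtype=int)
    length = run["length_aa"].to_numpy(dtype=int)
    if not np.any(spc > 0):
        raise DegenerateFitError(f"run {run_label!r} has all-zero counts")
    saf = spc / length
    # the normalized ratio is computed in exact rational arithmetic so that
    # rescaling every count by a common integer (sequencing depth) leaves
    # NSAF values bit-identical
    from fractions import Fraction
    fsaf = [Fraction(int(c), int(l)) for c, l in zip(spc, length)]
    total = sum(fsaf)
    nsaf = np.array([float(f / total) for f in fsaf])
    return [
        NsafRecord(protein_id=str(p), spectral_count=int(c), length_aa=int(l),
                   saf=float(s), nsaf=float(n), pnsaf=float(100.0 * n))
        for p, c, l, s, n in zip(run["protein_id"], spc, length, saf, nsaf)
    ]


def nsaf_table(table: SpectralCountTable) -> pd.DataFrame:
    """NSAF records for every run, long format.

    Column order: run_label, protein_id, spectral_count, length_aa, saf,
    nsaf, pnsaf, is_control.
    """
    frames = []
    controls = dict(zip(table.records["run_label"], table.records["is_control"]))
    for run_label in table.run_labels:
        recs = nsaf_normalize(table, run_label)
        df = pd.DataFrame([r.__dict__ for r in recs])
        df.insert(0, "run_label", run_label)
        df["is_control"] = bool(controls[run_label])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def default_pseudocount(runs: list[list[NsafRecord]]) -> float:
    """Half the smallest nonzero NSAF observed across all runs."""
    nonzero = [r.nsaf for run in runs for r in run if r.nsaf > 0]
    if not nonzero:
        raise DegenerateFitError("no nonzero NSAF value in any run")
    return min(nonzero) / 2.0


def enrichment_vs_controls(bait_run: list[NsafRecord],
                           control_runs: list[list[NsafRecord]],
                           pseudocount: float | None = None,
                           min_fold: float = DEFAULT_MIN_FOLD
                           ) -> list[EnrichmentRecord]:
    """Pseudocounted log2 fold of bait NSAF over mean control NSAF.

    Proteins absent from a run contribute NSAF 0 there. A protein is
    flagged enriched when its fold change is at least ``min_fold`` and it
    is present in the bait run. Records are sorted by fold descending,
    then protein id.
    """
    if not control_runs:
        raise ValidationError("at least one control run is required")
    if pseudocount is None:
        pseudocount = default_pseudocount([bait_run, *control_runs])
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    bait = {r.protein_id: r.nsaf for r in bait_run}
    controls = [{r.protein_id: r.nsaf for r in run} for run in control_runs]
    proteins = sorted(set(bait) | {p for run in controls for p in run})
    out = []
    for p in proteins:
        b = bait.get(p, 0.0)
        c = float(np.mean([run.get(p, 0.0) for run in controls]))
        fold = float(np.log2((b + pseudocount) / (c + pseudocount)))
        out.append(EnrichmentRecord(
            protein_id=p, bait_nsaf=b, mean_control_nsaf=c,
            log2_fold_enrichment=fold,
            enriched=bool(fold >= np.log2(min_fold) and b > 0)))
    out.sort(key=lambda r: (-r.log2_fold_enrichment, r.protein_id))
    return out


def enrichment_dataframe(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Column order: protein_id, bait_nsaf, mean_control_nsaf,
    log2_fold_enrichment, enriched."""
    return pd.DataFrame([r.__dict__ for r in records], columns=[
        "protein_id", "bait_nsaf", "mean_control_nsaf",
        "log2_fold_enrichment", "enriched"])
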