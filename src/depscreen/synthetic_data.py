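"""Ground-truth-known generators for every analysis stage.

Three forward models, all bit-reproducible from an integer seed:

* gene-effect matrices with planted correlated modules — a latent-factor
  (spiked covariance) model: each module m has a standard-normal factor
  f_m over cell lines, each member gene g loads on it with loading(g,m),
  and independent Gaussian noise is added, so within-module correlation
  is loading^2/(loading^2 + noise_sd^2) by construction;
* 1:1-model sensorgrams with known (kon, koff, Rmax) at several analyte
  concentrations, including matched reference and zero-analyte curves so
  double reference subtraction can be exercised;
* multinomial spectral-count tables with count probability proportional
  to abundance x length, plus control runs from a background abundance.

Every generator returns the data alongside a ``SimTruth`` record holding
the parameters, serializable to the flat key=value sidecar format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .io_formats import (EffectMatrix, GeneId, Sensorgram, SensorgramSet,
                         SpectralCountTable)
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted correlated gene module.

    ``loading`` is either one float shared by all members or a per-member
    sequence; negative loadings plant anti-correlated members.
    """

    member_genes: tuple[str, ...]
    loading: float | tuple[float, ...] = 1.0
    label: str = "module"

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValidationError("a module needs >= 2 member genes")
        loadings = self.loadings()
        if any(l == 0 for l in loadings):
            raise ValidationError("module loadings must be nonzero")

    def loadings(self) -> tuple[float, ...]:
        if isinstance(self.loading, (int, float)):
            return tuple(float(self.loading) for _ in self.member_genes)
        if len(self.loading) != len(self.member_genes):
            raise ValidationError("per-member loadings must match member count")
        return tuple(float(l) for l in self.loading)


@dataclass
class SimTruth:
    """Generator parameters and latent ground truth, test-assertable."""

    kind: str
    params: dict = field(default_factory=dict)

    def to_config(self) -> dict[str, object]:
        flat: dict[str, object] = {"kind": self.kind}
        for k, v in self.params.items():
            if isinstance(v, (list, tuple)):
                flat[k] = ",".join(str(x) for x in v)
            else:
                flat[k] = v
        return flat


def default_gene_universe(n_genes: int) -> list[GeneId]:
    """Synthetic symbols G0001.. with synthetic Entrez ids."""
    width = max(4, len(str(n_genes)))
    return [GeneId(f"G{i + 1:0{width}d}", 900000 + i + 1)
            for i in range(n_genes)]


def simulate_effect_matrix(n_genes: int, n_lines: int,
                           modules: Sequence[ModuleSpec] = (),
                           noise_sd: float = 0.5,
                           missing_rate: float = 0.0,
                           rng_seed: int = 0
                           ) -> tuple[EffectMatrix, SimTruth]:
    """Gene-effect matrix with planted modules on a Gaussian background.

    value(line, gene) = sum_m loading(gene, m) * f_m(line) + noise, with
    latent factors f_m and noise standard normal (noise scaled by
    ``noise_sd``). Genes outside every module are pure noise. Cells are
    masked missing independently at ``missing_rate``.
    """
    if n_lines < 4:
        raise ValidationError("need at least 4 cell lines")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if not (0.0 <= missing_rate < 1.0):
        raise ParameterError("missing_rate must be in [0, 1)")
    genes = default_gene_universe(n_genes)
    symbols = {g.symbol: i for i, g in enumerate(genes)}
    membership: dict[int, list[tuple[int, float]]] = {}
    for m_idx, mod in enumerate(modules):
        for sym, loading in zip(mod.member_genes, mod.loadings()):
            if sym not in symbols:
                raise ValidationError(
                    f"module member {sym} outside the gene universe")
            gi = symbols[sym]
            lst = membership.setdefault(gi, [])
            if lst:
                logger.info("gene %s belongs to multiple modules", sym)
            lst.append((m_idx, loading))
    rng = np.random.default_rng(rng_seed)
    factors = rng.standard_normal((n_lines, max(len(modules), 1)))
    values = noise_sd * rng.standard_normal((n_lines, n_genes))
    for gi, loads in membership.items():
        for m_idx, loading in loads:
            values[:, gi] += loading * factors[:, m_idx]
    if missing_rate > 0:
        mask = rng.random((n_lines, n_genes)) < missing_rate
        # never blank out a whole column's support
        values = np.where(mask, np.nan, values)
    lines = [f"LINE{i + 1:04d}" for i in range(n_lines)]
    truth = SimTruth(kind="effect_matrix", params={
        "n_genes": n_genes, "n_lines": n_lines, "noise_sd": noise_sd,
        "missing_rate": missing_rate, "rng_seed": rng_seed,
        "modules": [
            {"label": m.label, "members": list(m.member_genes),
             "loadings": list(m.loadings())} for m in modules],
    })
    return EffectMatrix(lines, genes, values), truth


def simulate_sensorgrams(kon: float, koff: float, rmax: float,
                         concentrations: Sequence[float],
                         t_assoc_s: float = 300.0,
                         t_dissoc_s: float = 300.0,
                         dt_s: float = 0.1,
                         noise_sd: float = 0.0,
                         drift_per_s: float = 0.0,
                         rng_seed: int = 0,
                         t_baseline_s: float = 10.0,
                         ligand_label: str = "ligand"
                         ) -> tuple[SensorgramSet, SimTruth]:
    """1:1-model titration with matched reference and zero-analyte curves.

    Association begins at t = 0 (baseline occupies negative times) and
    follows R(t) = Req*(1 - exp(-kobs t)) with Req = Rmax*C/(KD+C) and
    kobs = kon*C + koff; dissociation decays from the response reached at
    the end of association with rate koff. A deterministic linear drift
    (shared by the matched reference curves, so subtraction cancels it)
    and i.i.d. Gaussian noise are added on top.

    Defaults mimic a slow-kinetics titration on an 8-channel instrument:
    5-minute association/dissociation sampled at 10 Hz.
    """
    if kon <= 0 or koff < 0 or rmax <= 0:
        raise ParameterError("kon and Rmax must be positive, koff nonnegative")
    if not concentrations:
        raise ParameterError("at least one analyte concentration is required")
    if any(c <= 0 for c in concentrations):
        raise ParameterError("analyte concentrations must be positive")
    if dt_s >= min(t_assoc_s, t_dissoc_s):
        raise ParameterError("dt must be smaller than each phase duration")
    rng = np.random.default_rng(rng_seed)
    kd = koff / kon
    t = np.arange(-t_baseline_s, t_assoc_s + t_dissoc_s, dt_s)
    baseline = t < 0
    assoc = (t >= 0) & (t < t_assoc_s)
    diss = t >= t_assoc_s
    drift = drift_per_s * (t - t[0])

    def make_curve(conc: float, signal: np.ndarray, is_ref: bool,
                   label: str) -> Sensorgram:
        noise = noise_sd * rng.standard_normal(t.size) if noise_sd > 0 else 0.0
        return Sensorgram(
            time_s=t.copy(), response=signal + drift + noise,
            analyte_concentration_M=conc,
            association_start_s=0.0, dissociation_start_s=t_assoc_s,
            is_reference=is_ref, is_zero_analyte=(conc == 0), label=label)

    curves: list[Sensorgram] = []
    true_kobs, true_req = [], []
    for i, conc in enumerate(concentrations):
        kobs = kon * conc + koff
        req = rmax * conc / (kd + conc)
        signal = np.zeros_like(t)
        signal[assoc] = req * -np.expm1(-kobs * t[assoc])
        rend = req * -np.expm1(-kobs * t_assoc_s)
        signal[diss] = rend * np.exp(-koff * (t[diss] - t_assoc_s))
        curves.append(make_curve(conc, signal, False, f"sample_{i:02d}"))
        curves.append(make_curve(conc, np.zeros_like(t), True, f"ref_{i:02d}"))
        true_kobs.append(kobs)
        true_req.append(req)
    zero = np.zeros_like(t)
    curves.append(make_curve(0.0, zero, False, "zero_sample"))
    curves.append(make_curve(0.0, zero, True, "zero_ref"))
    truth = SimTruth(kind="sensorgrams", params={
        "kon": kon, "koff": koff, "rmax": rmax, "kd": kd,
        "concentrations_M": list(concentrations),
        "true_kobs": true_kobs, "true_req": true_req,
        "t_assoc_s": t_assoc_s, "t_dissoc_s": t_dissoc_s, "dt_s": dt_s,
        "noise_sd": noise_sd, "drift_per_s": drift_per_s,
        "rng_seed": rng_seed,
    })
    return SensorgramSet(curves, ligand_label=ligand_label), truth


def simulate_spectral_counts(true_abundance: Sequence[float],
                             lengths: Sequence[int],
                             total_spectra: int,
                             n_control_runs: int = 0,
                             rng_seed: int = 0,
                             background_abundance: Sequence[float] | None = None,
                             protein_ids: Sequence[str] | None = None
                             ) -> tuple[SpectralCountTable, SimTruth]:
    """Multinomial spectral counts with P(protein) ∝ abundance x length.

    The bait run samples from ``true_abundance``; control runs sample from
    ``background_abundance`` (default: the same vector, i.e. a null
    experiment). Counts in each run sum exactly to ``total_spectra``.
    """
    ab = np.asarray(true_abundance, dtype=float)
    ln = np.asarray(lengths, dtype=int)
    if ab.shape != ln.shape:
        raise ParameterError("abundance and length vectors must match")
    if total_spectra <= 0:
        raise ParameterError("total_spectra must be positive")
    if np.any(ab < 0):
        raise ParameterError("abundances must be nonnegative")
    if np.any(ln <= 0):
        raise ParameterError("protein lengths must be positive")
    bg = ab if background_abundance is None else np.asarray(
        background_abundance, dtype=float)
    if bg.shape != ab.shape:
        raise ParameterError("background abundance vector must match")
    ids = (list(protein_ids) if protein_ids is not None
           else [f"P{i + 1:04d}" for i in range(ab.size)])
    rng = np.random.default_rng(rng_seed)

    def draw(weights: np.ndarray) -> np.ndarray:
        p = weights * ln
        return rng.multinomial(total_spectra, p / p.sum())

    rows = []
    for run_label, weights, is_control in (
            [("bait", ab, False)]
            + [(f"control_{j + 1}", bg, True) for j in range(n_control_runs)]):
        counts = draw(weights)
        for pid, c, l in zip(ids, counts, ln):
            rows.append({"protein_id": pid, "spectral_count": int(c),
                         "length_aa": int(l), "run_label": run_label,
                         "is_control": is_control})
    table = SpectralCountTable(pd.DataFrame(rows))
    truth = SimTruth(kind="spectral_counts", params={
        "true_abundance": list(map(float, ab)),
        "background_abundance": list(map(float, bg)),
        "lengths": list(map(int, ln)), "total_spectra": total_spectra,
        "n_control_runs": n_control_runs, "rng_seed": rng_seed,
        "protein_ids": ids,
    })
    return table, truth
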