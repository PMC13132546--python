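"""Readers and writers for every on-disk artifact of the toolkit.

Formats are deliberately plain text:

* gene-effect matrices — comma-delimited, cell lines on rows by default,
  column headers in the DepMap convention ``"SYMBOL (ENTREZ_ID)"``;
* seed gene lists — one symbol per line, ``#`` comments allowed;
* result tables — tab-delimited, floats at 6 significant digits;
* sensorgrams — one tab-delimited ``time_s``/``response_nm`` file per curve
  plus a flat key–value metadata sidecar;
* spectral-count tables — tab-delimited long format;
* configuration / truth sidecars — flat ``key = value`` text.

Missing matrix cells may be encoded as empty fields or ``NA``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GeneLookupError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"^(?P<symbol>\S+)\s*\((?P<entrez>\d+)\)$")

#: Strings treated as missing values in matrix bodies.
NA_VALUES = ("", "NA")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneId:
    """A gene identified by HGNC-style symbol, optionally with an Entrez id.

    Ordering is lexicographic by symbol, then by Entrez id (absent id sorts
    first); this is the deterministic tie-break used throughout ranking code.
    """

    symbol: str
    entrez_id: int | None = None

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise ValidationError(f"invalid gene symbol: {self.symbol!r}")
        if self.entrez_id is not None and self.entrez_id < 0:
            raise ValidationError(f"negative Entrez id for {self.symbol}")

    @classmethod
    def parse(cls, token: str) -> "GeneId":
        """Parse ``"SYMBOL (1234)"`` or a bare ``"SYMBOL"`` header token."""
        token = token.strip()
        m = _HEADER_RE.match(token)
        if m:
            return cls(m.group("symbol"), int(m.group("entrez")))
        if not token or " " in token or "(" in token or ")" in token:
            raise FormatError(f"malformed gene header token: {token!r}")
        return cls(token)

    def header(self) -> str:
        """Render back to the DepMap header convention."""
        if self.entrez_id is None:
            return self.symbol
        return f"{self.symbol} ({self.entrez_id})"

    # sort key with explicit placement of absent Entrez ids
    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.symbol, -1 if self.entrez_id is None else self.entrez_id)

    def __str__(self) -> str:
        return self.header()


@dataclass
class EffectMatrix:
    """Cell-line x gene matrix of real-valued dependency scores.

    ``values`` has rows = cell lines, columns = genes, with NaN for missing
    entries. Construction validates label uniqueness and drops columns with
    fewer than two observed values (they cannot support a correlation).
    """

    cell_line_ids: list[str]
    genes: list[GeneId]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_line_ids), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_line_ids)} cell lines x {len(self.genes)} genes"
            )
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise ValidationError("duplicate cell-line ids")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Series([g.header() for g in self.genes])
            dup = dupes[dupes.duplicated()].iloc[0]
            raise ValidationError(f"duplicate gene column: {dup}")
        usable = np.isfinite(self.values).sum(axis=0) >= 2
        if not usable.all():
            dropped = [g.header() for g, u in zip(self.genes, usable) if not u]
            logger.warning(
                "dropping %d gene column(s) with <2 observed values: %s",
                len(dropped), ", ".join(dropped[:10]),
            )
            self.genes = [g for g, u in zip(self.genes, usable) if u]
            self.values = self.values[:, usable]
        if not self.genes:
            raise ValidationError("no usable gene columns (all empty or near-empty)")

    @property
    def n_lines(self) -> int:
        return len(self.cell_line_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def column_index(self, gene: GeneId | str) -> int:
        """Locate a gene column by exact symbol match.

        When several columns share the symbol, the Entrez id of ``gene``
        breaks the tie; without one the lookup is ambiguous and raises.
        """
        symbol = gene if isinstance(gene, str) else gene.symbol
        hits = [i for i, g in enumerate(self.genes) if g.symbol == symbol]
        if not hits:
            raise GeneLookupError(f"gene not in matrix: {symbol}")
        if len(hits) == 1:
            return hits[0]
        wanted = None if isinstance(gene, str) else gene.entrez_id
        if wanted is not None:
            for i in hits:
                if self.genes[i].entrez_id == wanted:
                    return i
        raise GeneLookupError(
            f"ambiguous symbol {symbol}: {len(hits)} columns share it and no "
            f"matching Entrez id was given"
        )

    def column(self, gene: GeneId | str) -> np.ndarray:
        return self.values[:, self.column_index(gene)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.cell_line_ids, name="cell_line"),
            columns=[g.header() for g in self.genes],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EffectMatrix):
            return NotImplemented
        return (
            self.cell_line_ids == other.cell_line_ids
            and self.genes == other.genes
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class SeedList:
    """An ordered, duplicate-free list of query genes."""

    seeds: list[GeneId]
    label: str = "seeds"

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValidationError("seed list is empty")
        seen: set[str] = set()
        unique: list[GeneId] = []
        for g in self.seeds:
            if g.symbol in seen:
                logger.warning("duplicate seed symbol dropped: %s", g.symbol)
                continue
            seen.add(g.symbol)
            unique.append(g)
        self.seeds = unique

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    @property
    def symbols(self) -> set[str]:
        return {g.symbol for g in self.seeds}


@dataclass
class Sensorgram:
    """One BLI trace: response (nm shift) versus time at one analyte
    concentration, with phase boundaries.

    Baseline is ``t < association_start_s``, association runs up to
    ``dissociation_start_s``, dissociation follows.
    """

    time_s: np.ndarray
    response: np.ndarray
    analyte_concentration_M: float
    association_start_s: float
    dissociation_start_s: float
    is_reference: bool = False
    is_zero_analyte: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.response.shape:
            raise ValidationError("time and response vectors must be equal-length 1-D")
        if self.time_s.size < 10:
            raise ValidationError("sensorgram has fewer than 10 points")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time vector is not strictly increasing")
        if not self.dissociation_start_s > self.association_start_s:
            raise ValidationError("dissociation must start after association")
        if (self.analyte_concentration_M == 0) != self.is_zero_analyte:
            raise ValidationError(
                "analyte concentration is zero iff the curve is flagged zero-analyte"
            )
        if self.analyte_concentration_M < 0:
            raise ValidationError("negative analyte concentration")

    def phase_mask(self, phase: str) -> np.ndarray:
        """Boolean mask for 'baseline', 'association' or 'dissociation'."""
        t = self.time_s
        if phase == "baseline":
            return t < self.association_start_s
        if phase == "association":
            return (t >= self.association_start_s) & (t < self.dissociation_start_s)
        if phase == "dissociation":
            return t >= self.dissociation_start_s
        raise ParameterError(f"unknown phase: {phase}")

    def with_response(self, response: np.ndarray) -> "Sensorgram":
        return replace(self, response=np.asarray(response, dtype=float))


@dataclass
class SensorgramSet:
    """A family of sensorgrams measured against one immobilized ligand."""

    curves: list[Sensorgram]
    ligand_label: str = ""

    def __post_init__(self) -> None:
        samples = self.sample_curves()
        concs = [c.analyte_concentration_M for c in samples]
        if any(c <= 0 for c in concs):
            raise ValidationError("sample analyte concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise ValidationError("duplicate analyte concentrations among sample curves")

    def sample_curves(self) -> list[Sensorgram]:
        return [c for c in self.curves
                if not c.is_reference and not c.is_zero_analyte]

    def reference_for(self, sample: Sensorgram) -> Sensorgram:
        for c in self.curves:
            if c.is_reference and not c.is_zero_analyte \
                    and c.analyte_concentration_M == sample.analyte_concentration_M:
                return c
        raise ValidationError(
            f"no reference curve at C={sample.analyte_concentration_M:g} M"
        )

    def zero_analyte(self, reference: bool) -> Sensorgram:
        for c in self.curves:
            if c.is_zero_analyte and c.is_reference == reference:
                return c
        kind = "reference" if reference else "sample"
        raise ValidationError(f"no zero-analyte {kind} curve in set")


@dataclass
class SpectralCountTable:
    """Long-format AP-MS spectral counts across runs.

    One record per (protein, run): spectral count, protein length in amino
    acids, run label and a bait/control flag.
    """

    records: pd.DataFrame

    REQUIRED = ("protein_id", "spectral_count", "length_aa", "run_label", "is_control")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"spectral-count table missing columns: {missing}")
        if df.duplicated(subset=["protein_id", "run_label"]).any():
            raise ValidationError("duplicate (protein_id, run_label) pair")
        if (df["length_aa"] <= 0).any():
            raise ValidationError("protein lengths must be positive")
        if (df["spectral_count"] < 0).any():
            raise ValidationError("negative spectral count")
        df = df.astype({"spectral_count": int, "length_aa": int, "is_control": bool})
        self.records = df.reset_index(drop=True)

    @property
    def run_labels(self) -> list[str]:
        return list(dict.fromkeys(self.records["run_label"]))

    def run(self, run_label: str) -> pd.DataFrame:
        sub = self.records[self.records["run_label"] == run_label]
        if sub.empty:
            raise ValidationError(f"unknown run label: {run_label}")
        return sub


# ---------------------------------------------------------------------------
# Gene-effect matrices
# ---------------------------------------------------------------------------

def read_effect_matrix(path: str | Path,
                       orientation: str = "lines_by_genes") -> EffectMatrix:
    """Read a delimited gene-effect matrix into canonical orientation.

    ``orientation`` declares the file layout: ``lines_by_genes`` (DepMap
    default — cell lines on rows) or ``genes_by_lines`` (transposed). The
    returned matrix is always cell lines x genes.
    """
    if orientation not in ("lines_by_genes", "genes_by_lines"):
        raise ParameterError(f"unknown orientation: {orientation}")
    path = Path(path)
    df = pd.read_csv(path, index_col=0, na_values=list(NA_VALUES),
                     keep_default_na=False, float_precision="round_trip")
    if orientation == "lines_by_genes":
        # pandas mangles duplicate column headers; check the raw header line
        with path.open(encoding="utf-8") as fh:
            raw_labels = fh.readline().rstrip("\n").split(",")[1:]
        if len(set(raw_labels)) != len(raw_labels):
            dup = next(l for l in raw_labels if raw_labels.count(l) > 1)
            raise ValidationError(f"duplicate gene column: {dup}")
        gene_labels = raw_labels
    else:
        df = df.T
        gene_labels = [str(c) for c in df.columns]
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: matrix body is empty")
    genes = [GeneId.parse(c) for c in gene_labels]
    values = df.to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("%s: %d missing cell(s)", path.name, n_missing)
    return EffectMatrix([str(i) for i in df.index], genes, values)


def write_effect_matrix(matrix: EffectMatrix, path: str | Path) -> None:
    """Write in the canonical lines-by-genes CSV layout (round-trip exact)."""
    matrix.to_dataframe().to_csv(Path(path))


# ---------------------------------------------------------------------------
# Seed lists
# ---------------------------------------------------------------------------

def read_seed_list(path: str | Path, label: str | None = None) -> SeedList:
    """One symbol per line; blank lines and ``#`` comments skipped."""
    path = Path(path)
    seeds: list[GeneId] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        seeds.append(GeneId.parse(line))
    if not seeds:
        raise ValidationError(f"{path}: no seed genes after filtering")
    return SeedList(seeds, label or path.stem)


def write_seed_list(seeds: SeedList, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(g.header() for g in seeds) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 TSV with floats at 6 significant digits.

    Column order is the DataFrame's order; callers document theirs. An empty
    table produces a header-only file.
    """
    records.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Flat key = value config / sidecar format
# ---------------------------------------------------------------------------

def write_config(mapping: Mapping[str, object], path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: expected 'key = value', got {raw!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# Sensorgram sets (one file per curve + metadata sidecar)
# ---------------------------------------------------------------------------

def write_sensorgram_set(sset: SensorgramSet, directory: str | Path) -> None:
    """One ``<label>.tsv`` per curve plus a ``metadata.txt`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict[str, object] = {"ligand_label": sset.ligand_label,
                               "n_curves": len(sset.curves)}
    for i, c in enumerate(sset.curves):
        name = c.label or f"curve_{i:03d}"
        pd.DataFrame({"time_s": c.time_s, "response_nm": c.response}).to_csv(
            directory / f"{name}.tsv", sep="\t", index=False
        )
        meta[f"{name}.analyte_concentration_M"] = repr(c.analyte_concentration_M)
        meta[f"{name}.association_start_s"] = repr(c.association_start_s)
        meta[f"{name}.dissociation_start_s"] = repr(c.dissociation_start_s)
        meta[f"{name}.is_reference"] = int(c.is_reference)
        meta[f"{name}.is_zero_analyte"] = int(c.is_zero_analyte)
    write_config(meta, directory / "metadata.txt")


def read_sensorgram_set(directory: str | Path) -> SensorgramSet:
    directory = Path(directory)
    meta = read_config(directory / "metadata.txt")
    names = sorted({k.split(".", 1)[0] for k in meta
                    if "." in k and k.endswith("analyte_concentration_M")})
    curves: list[Sensorgram] = []
    for name in names:
        df = pd.read_csv(directory / f"{name}.tsv", sep="\t")
        curves.append(Sensorgram(
            time_s=df["time_s"].to_numpy(),
            response=df["response_nm"].to_numpy(),
            analyte_concentration_M=float(meta[f"{name}.analyte_concentration_M"]),
            association_start_s=float(meta[f"{name}.association_start_s"]),
            dissociation_start_s=float(meta[f"{name}.dissociation_start_s"]),
            is_reference=bool(int(meta[f"{name}.is_reference"])),
            is_zero_analyte=bool(int(meta[f"{name}.is_zero_analyte"])),
            label=name,
        ))
    return SensorgramSet(curves, ligand_label=meta.get("ligand_label", ""))


# ---------------------------------------------------------------------------
# Spectral-count tables
# ---------------------------------------------------------------------------

def read_spectral_counts(path: str | Path) -> SpectralCountTable:
    df = pd.read_csv(Path(path), sep="\t")
    if "is_control" in df.columns:
        df["is_control"] = df["is_control"].astype(bool)
    return SpectralCountTable(df)


def write_spectral_counts(table: SpectralCountTable, path: str | Path) -> None:
    out = table.records.copy()
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(Path(path), sep="\t", index=False)
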