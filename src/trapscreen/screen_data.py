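"""Data model and I/O for plate-level screen measurements and gene sets.

The screen is stored long-format: one row per well, i.e. per
(clone, dose, replicate) combination, carrying the three luminescence
readouts of the dual assay — dead-cell RLU and total-cell RLU from the
cytotoxicity assay, and β-galactosidase RLU from the reporter assay
(absent for wild-type wells, which carry no β-geo insert).  Live-cell
signal is always derived as ``total − dead``; it is never stored.

Doses are arbitrary non-negative grays so validation doses (2, 10, 15 Gy)
parse without code change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import GmtParseError, QcError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order of a plate table
PLATE_COLUMNS = (
    "clone_id",
    "gene_symbol",
    "dose_gy",
    "replicate",
    "dead_rlu",
    "total_rlu",
    "betagal_rlu",
    "is_wildtype",
)

#: sentinel written in place of a p/q value that underflowed the render precision
UNDERFLOW_SENTINEL = "<1e-300"
_UNDERFLOW_LIMIT = 1e-300


@dataclass(frozen=True)
class CloneAssayRecord:
    """One well measurement of the dual assay."""

    clone_id: str
    gene_symbol: str
    dose_gy: float
    replicate: int
    dead_rlu: float
    total_rlu: float
    betagal_rlu: float | None = None
    is_wildtype: bool = False

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValidationError(f"negative dose {self.dose_gy} Gy for {self.clone_id}")
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be ≥ 1 for {self.clone_id}")
        if self.dead_rlu < 0 or self.total_rlu < 0:
            raise ValidationError(f"negative RLU for {self.clone_id}")
        if self.dead_rlu > self.total_rlu:
            raise QcError(
                f"dead RLU {self.dead_rlu} exceeds total RLU {self.total_rlu} "
                f"for {self.clone_id} at {self.dose_gy} Gy rep {self.replicate}"
            )

    @property
    def live_rlu(self) -> float:
        """Live-cell signal implied by the cytotoxicity assay chemistry."""
        return self.total_rlu - self.dead_rlu


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    member_genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.member_genes)


class GeneSetCollection:
    """An ordered collection of gene sets keyed by term id.

    Gene symbols are stored case-preserved; membership queries are
    case-insensitive because mouse-symbol capitalisation varies across
    annotation sources.
    """

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if not s.member_genes:
                raise ValidationError(f"gene set {s.term_id} is empty")
            if s.term_id in self._sets:
                raise ValidationError(f"duplicate term id {s.term_id}")
            self._sets[s.term_id] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._sets

    def restricted_to(self, background: Iterable[str]) -> "GeneSetCollection":
        """Intersect every member set with *background* (case-insensitive).

        Terms left empty are dropped.  Returned member symbols use the
        background's capitalisation so downstream overlap counts are
        consistent with the assayed gene list.
        """
        canon = {g.casefold(): g for g in background}
        kept = []
        for s in self:
            members = frozenset(
                canon[g.casefold()] for g in s.member_genes if g.casefold() in canon
            )
            if members:
                kept.append(GeneSet(s.term_id, s.term_name, members))
        return GeneSetCollection(kept)


@dataclass
class ScreenDataset:
    """A validated screen: well table, declared dose set, assayed genes.

    ``records`` is a long-format frame with the :data:`PLATE_COLUMNS`
    columns; ``excluded`` holds wells removed during QC together with a
    ``qc_reason`` column.
    """

    records: pd.DataFrame
    dose_set: tuple[float, ...]
    background_genes: frozenset[str]
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(PLATE_COLUMNS) + ["qc_reason"])
    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def clones(self) -> pd.DataFrame:
        return self.records[~self.records["is_wildtype"]]

    @property
    def wildtype(self) -> pd.DataFrame:
        return self.records[self.records["is_wildtype"]]

    def iter_records(self) -> Iterator[CloneAssayRecord]:
        for row in self.records.itertuples(index=False):
            bg = row.betagal_rlu
            yield CloneAssayRecord(
                clone_id=row.clone_id,
                gene_symbol=row.gene_symbol,
                dose_gy=float(row.dose_gy),
                replicate=int(row.replicate),
                dead_rlu=float(row.dead_rlu),
                total_rlu=float(row.total_rlu),
                betagal_rlu=None if pd.isna(bg) else float(bg),
                is_wildtype=bool(row.is_wildtype),
            )


def _coerce_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = col.astype(str).str.strip().str.casefold().map(mapping)
    if out.isna().any():
        raise SchemaError("is_wildtype column contains values not parseable as boolean")
    return out.astype(bool)


def dataset_from_frame(df: pd.DataFrame) -> ScreenDataset:
    """Validate a long-format well frame and build a :class:`ScreenDataset`.

    QC rule ``dead_rlu ≤ total_rlu`` excludes (and logs) offending wells
    rather than aborting the run; structural problems — missing columns,
    a non-wild-type clone with no β-gal signal, a clone without its 0-Gy
    reference, duplicated well keys — raise.
    """
    missing = [c for c in PLATE_COLUMNS if c not in df.columns and c != "betagal_rlu"]
    if missing:
        raise SchemaError(f"plate table is missing required columns: {missing}")
    df = df.copy()
    if "betagal_rlu" not in df.columns:
        df["betagal_rlu"] = np.nan
    df = df[list(PLATE_COLUMNS)]

    for col in ("dose_gy", "dead_rlu", "total_rlu", "betagal_rlu"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    df["is_wildtype"] = _coerce_bool(df["is_wildtype"])
    df["clone_id"] = df["clone_id"].astype(str)
    df["gene_symbol"] = df["gene_symbol"].astype(str)

    if (df["dose_gy"] < 0).any():
        bad = df.loc[df["dose_gy"] < 0, "clone_id"].unique().tolist()
        raise ValidationError(f"negative doses for clones {bad}")

    # non-wild-type wells must carry a reporter signal
    missing_bg = df[~df["is_wildtype"] & df["betagal_rlu"].isna()]
    if len(missing_bg):
        clones = sorted(missing_bg["clone_id"].unique())
        raise ValidationError(
            f"betagal_rlu missing for non-wild-type clones: {clones}"
        )

    keys = df[["clone_id", "dose_gy", "replicate"]]
    if keys.duplicated().any():
        dup = df.loc[keys.duplicated(), ["clone_id", "dose_gy", "replicate"]]
        raise ValidationError(
            f"duplicated (clone_id, dose, replicate) wells:\n{dup.to_string(index=False)}"
        )

    bad_mask = df["dead_rlu"] > df["total_rlu"]
    excluded = df[bad_mask].copy()
    if len(excluded):
        excluded["qc_reason"] = "dead_rlu > total_rlu"
        for row in excluded.itertuples(index=False):
            logger.warning(
                "QC exclusion: %s at %s Gy rep %s (dead %s > total %s)",
                row.clone_id, row.dose_gy, row.replicate, row.dead_rlu, row.total_rlu,
            )
        df = df[~bad_mask]
    else:
        excluded = pd.DataFrame(columns=list(PLATE_COLUMNS) + ["qc_reason"])

    # every clone needs its unirradiated reference
    has_ref = df.groupby("clone_id")["dose_gy"].apply(lambda d: (d == 0).any())
    if not has_ref.all():
        orphans = sorted(has_ref.index[~has_ref])
        raise ValidationError(f"clones with no 0-Gy reference well: {orphans}")

    dose_set = tuple(sorted(df["dose_gy"].unique()))
    background = frozenset(df.loc[~df["is_wildtype"], "gene_symbol"].unique())
    return ScreenDataset(
        records=df.reset_index(drop=True),
        dose_set=dose_set,
        background_genes=background,
        excluded=excluded.reset_index(drop=True),
    )


def read_plate_table(path: str | Path, sep: str | None = None) -> ScreenDataset:
    """Read a delimited plate table (TSV by default, CSV for ``.csv``)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return dataset_from_frame(df)


def write_plate_table(dataset: ScreenDataset, path: str | Path, sep: str = "\t") -> None:
    dataset.records.to_csv(path, sep=sep, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file: ``term<TAB>description<TAB>gene...``.

    Duplicate genes within a line collapse (set semantics); a line with
    fewer than three fields is a parse error reported with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"GMT line {lineno} has {len(fields)} field(s); "
                    "expected term, description, and at least one gene",
                    line_number=lineno,
                )
            term_id, term_name, *genes = fields
            members = frozenset(g.strip() for g in genes if g.strip())
            if not members:
                raise GmtParseError(
                    f"GMT line {lineno} ({term_id}) lists no genes", line_number=lineno
                )
            sets.append(GeneSet(term_id, term_name, members))
    return GeneSetCollection(sets)


def _render_pvalue(x: float) -> str:
    if pd.isna(x):
        return ""
    if x < _UNDERFLOW_LIMIT:
        # never print a silent 0 — flag underflow explicitly
        return UNDERFLOW_SENTINEL
    return f"{x:.3e}"


def write_results(results: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a result table as delimited text with stable column order.

    Probability-like columns (named ``p``/``q`` or ending ``_p``/``_q``)
    are rendered in scientific notation with four significant figures;
    values below 1e-300 are written as the :data:`UNDERFLOW_SENTINEL`
    so underflow is never mistaken for an exact zero.
    """
    if results is None:
        raise ValueError("results table is None")
    out = results.copy()
    for col in out.columns:
        if _is_probability_column(col):
            out[col] = out[col].map(_render_pvalue)
    out.to_csv(path, sep=sep, index=False)


def _is_probability_column(name: str) -> bool:
    return name in ("p", "q") or name.endswith("_p") or name.endswith("_q")


def read_results(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_results`.

    Underflow sentinels parse as NaN (the true value is only known to be
    below 1e-300; use the accompanying ``log10_p`` column instead).
    """
    df = pd.read_csv(path, sep=sep)
    for col in df.columns:
        if _is_probability_column(col) and df[col].dtype == object:
            cleaned = df[col].mask(df[col] == UNDERFLOW_SENTINEL)
            df[col] = pd.to_numeric(cleaned, errors="coerce")
    return df
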