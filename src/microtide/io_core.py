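"""Reading OTU count tables and clinical metadata, and assembling the tidy micro set.

An OTU table in the classic layout has taxa as rows and sequencing libraries as
columns; a clinical table has one row per library.  :func:`build_micro_set`
merges any number of OTU tables with one clinical table into a single long
("tidy") table with one row per (OTU table, taxon, library), carrying the raw
count (``cts``), the library's total reads for that table (``Total``), relative
abundance in percent (``ra``), the centered log-ratio value (``clr``), a 0/1
presence indicator (``bin``), and every clinical covariate repeated per row.

The CLR uses a uniform 1/depth pseudocount added to every taxon's count before
taking logs, so zero counts stay finite while the transform of a positive
vector still sums to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("microtide")

__all__ = [
    "OtuTable",
    "ClinicalTable",
    "MicroSet",
    "ParseError",
    "read_otu_table",
    "read_clinical",
    "clr_transform",
    "build_micro_set",
    "write_otu_table",
    "read_micro_set",
]

#: Fixed columns of the long table, in order, before the clinical covariates.
CORE_COLUMNS = ["Table", "Taxa", "Lib", "cts", "Total", "ra", "clr", "bin"]


class ParseError(ValueError):
    """A malformed input file (bad cell, duplicate ID, empty table)."""


@dataclass
class OtuTable:
    """One taxonomic-rank count matrix (taxa x libraries) with a table name.

    Parameters
    ----------
    name : str
        Label for the taxonomic rank, e.g. ``"Genus"``.
    taxa : list of str
        Taxon labels, typically rank paths like ``"Bacteria/Firmicutes/..."``.
    libraries : list of str
        Sequencing-library IDs (column order preserved from the file).
    counts : ndarray of int, shape (n_taxa, n_libraries)
    """

    name: str
    taxa: list[str]
    libraries: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if len(self.taxa) < 1 or len(self.libraries) < 1:
            raise ParseError(f"OTU table {self.name!r} is empty")
        if self.counts.shape != (len(self.taxa), len(self.libraries)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.libraries)} libraries"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ParseError(f"duplicate taxon labels in table {self.name!r}: {dup}")
        if len(set(self.libraries)) != len(self.libraries):
            dup = sorted({l for l in self.libraries if self.libraries.count(l) > 1})
            raise ParseError(f"duplicate library IDs in table {self.name!r}: {dup}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError(f"negative counts in table {self.name!r}")

    @property
    def depths(self) -> np.ndarray:
        """Per-library total reads (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class ClinicalTable:
    """Per-library covariates with typed columns.

    ``frame`` is indexed by library ID.  Numeric columns are floats; everything
    else is stored as pandas Categorical whose level order is first-seen order
    (the first level acts as the modeling reference).
    """

    id_column: str
    frame: pd.DataFrame

    @property
    def libraries(self) -> list[str]:
        return list(self.frame.index)

    @property
    def covariates(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class MicroSet:
    """Tidy long micro set: one row per (table, taxon, library).

    Attributes
    ----------
    data : DataFrame
        Columns ``Table, Taxa, Lib, cts, Total, ra, clr, bin`` followed by the
        clinical covariates.
    tables : dict
        Table name -> ordered list of taxon labels.
    clinical_cols : list of str
    """

    data: pd.DataFrame
    tables: dict[str, list[str]] = field(default_factory=dict)
    clinical_cols: list[str] = field(default_factory=list)

    def libraries(self, table: str | None = None) -> list[str]:
        d = self.data if table is None else self.data[self.data["Table"] == table]
        return list(pd.unique(d["Lib"]))

    def table_data(self, table: str) -> pd.DataFrame:
        if table not in self.tables:
            raise KeyError(f"unknown OTU table {table!r}; have {list(self.tables)}")
        return self.data[self.data["Table"] == table]

    def wide(self, table: str, value: str = "cts") -> pd.DataFrame:
        """Libraries x taxa matrix of one derived column for one table."""
        d = self.table_data(table)
        w = d.pivot(index="Lib", columns="Taxa", values=value)
        return w.reindex(index=self.libraries(table), columns=self.tables[table])

    def clinical_frame(self, table: str) -> pd.DataFrame:
        """One row of clinical covariates per library of `table`."""
        d = self.table_data(table)
        first = d.drop_duplicates("Lib").set_index("Lib")
        return first[self.clinical_cols].reindex(self.libraries(table))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_otu_table(path, name: str, delimiter: str | None = None) -> OtuTable:
    """Read a classic-layout OTU table (first column = taxon, header = library IDs).

    Leading lines starting with ``#`` are skipped, except a header beginning
    with ``#OTU ID`` which is taken as the header row itself.  The delimiter is
    auto-detected (tab, then comma) unless given.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines: list[str] = []
    header: str | None = None
    for ln in raw:
        if not lines and header is None:
            if ln.startswith("#OTU ID"):
                header = ln
                continue
            if ln.startswith("#") or not ln.strip():
                continue
            header = ln
            continue
        if ln.strip():
            lines.append(ln)
    if header is None:
        raise ParseError(f"{path}: no header line found")
    delim = delimiter or _sniff_delimiter(header)
    head = header.split(delim)
    libraries = [c.strip() for c in head[1:]]
    if not libraries:
        raise ParseError(f"{path}: header has no library columns")
    taxa: list[str] = []
    rows: list[list[int]] = []
    for i, ln in enumerate(lines, start=2):
        cells = ln.split(delim)
        if len(cells) != len(head):
            raise ParseError(
                f"{path}: row {i} has {len(cells)} fields, expected {len(head)}"
            )
        taxa.append(cells[0].strip())
        row = []
        for j, cell in enumerate(cells[1:], start=2):
            cell = cell.strip()
            try:
                val = int(cell)
            except ValueError:
                try:
                    f = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric count {cell!r} at row {i}, "
                        f"column {j} (library {libraries[j - 2]!r})"
                    ) from None
                if not f.is_integer():
                    raise ParseError(
                        f"{path}: non-integer count {cell!r} at row {i}, column {j}"
                    ) from None
                val = int(f)
            row.append(val)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: table has no taxa rows")
    return OtuTable(name=name, taxa=taxa, libraries=libraries,
                    counts=np.array(rows, dtype=np.int64))


def write_otu_table(otu: OtuTable, path, delimiter: str = "\t") -> None:
    """Write an OtuTable back to the classic layout (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(["#OTU ID"] + list(otu.libraries)) + "\n")
        for t, row in zip(otu.taxa, otu.counts):
            fh.write(delimiter.join([t] + [str(int(c)) for c in row]) + "\n")


def _infer_column(series: pd.Series) -> pd.Series:
    """Numeric if every non-missing value parses; else categorical, first-seen order."""
    non_na = series.dropna()
    try:
        as_num = pd.to_numeric(non_na)
    except (ValueError, TypeError):
        as_num = None
    if as_num is not None and len(non_na):
        out = pd.to_numeric(series, errors="coerce").astype(float)
        return out
    levels = list(pd.unique(non_na.astype(str)))
    return pd.Categorical(series.astype("string").astype(object), categories=levels)


def read_clinical(path, id_column: str, delimiter: str | None = None) -> ClinicalTable:
    """Read the clinical table; one row per library, typed columns.

    Columns where every non-missing value parses as a number become floats;
    all others become categoricals whose level order is first-seen order.
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ParseError(f"{path}: empty file")
    delim = delimiter or _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim, dtype=str, skip_blank_lines=True)
    if id_column not in df.columns:
        raise ParseError(
            f"{path}: id column {id_column!r} not found; columns are {list(df.columns)}"
        )
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    ids = df[id_column].astype(str)
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path}: duplicated library IDs: {dup}")
    out = pd.DataFrame(index=pd.Index(ids, name=id_column))
    for col in df.columns:
        if col == id_column:
            continue
        inferred = _infer_column(df[col])
        out[col] = (
            pd.Series(inferred, index=out.index)
            if isinstance(inferred, pd.Categorical)
            else inferred.to_numpy()
        )
    return ClinicalTable(id_column=id_column, frame=out)


def clr_transform(counts, depth: float) -> np.ndarray:
    """Centered log-ratio of one library's full taxa count vector.

    Each count receives a uniform pseudocount of ``1/depth``:
    ``X_p = cts_p + 1/depth``; then ``Z_p = ln X_p - mean(ln X)``, which equals
    ``ln(X_p / g(X))`` with ``g`` the geometric mean, computed in log space.
    The result of any positive vector sums to zero.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a non-empty 1-D vector")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    logx = np.log(counts + 1.0 / depth)
    return logx - logx.mean()


def build_micro_set(
    otu_tables: dict[str, OtuTable] | list[OtuTable],
    clinical: ClinicalTable,
    complete_clin: bool = False,
) -> MicroSet:
    """Merge OTU tables with clinical data into the tidy long format.

    Parameters
    ----------
    otu_tables : dict or list of OtuTable
        Table blocks appear in the given order.
    clinical : ClinicalTable
    complete_clin : bool
        When True, perform an inner join on library ID: libraries without
        clinical data and clinical rows without sequence data are dropped,
        with the dropped IDs logged.  When False all OTU libraries are kept
        (missing clinical values become NA).
    """
    if isinstance(otu_tables, dict):
        tables = [(nm, t) for nm, t in otu_tables.items()]
    else:
        tables = [(t.name, t) for t in otu_tables]
    if not tables:
        raise ValueError("no OTU tables given")

    clin_ids = set(clinical.libraries)
    all_otu_libs: set[str] = set()
    for _, t in tables:
        all_otu_libs.update(t.libraries)
    if not (all_otu_libs & clin_ids):
        raise ValueError("no overlap between OTU table libraries and clinical IDs")

    if complete_clin:
        no_clin = sorted(all_otu_libs - clin_ids)
        no_seq = sorted(clin_ids - all_otu_libs)
        if no_clin:
            logger.warning(
                "complete_clin: dropping %d librar%s without clinical data: %s",
                len(no_clin), "y" if len(no_clin) == 1 else "ies", no_clin,
            )
        if no_seq:
            logger.warning(
                "complete_clin: dropping %d clinical row%s without sequence data: %s",
                len(no_seq), "" if len(no_seq) == 1 else "s", no_seq,
            )

    blocks: list[pd.DataFrame] = []
    table_taxa: dict[str, list[str]] = {}
    for nm, otu in tables:
        if nm in table_taxa:
            raise ValueError(f"duplicate OTU table name {nm!r}")
        keep = [
            (j, lib)
            for j, lib in enumerate(otu.libraries)
            if (not complete_clin) or lib in clin_ids
        ]
        if not keep:
            raise ValueError(f"table {nm!r}: no libraries retained")
        cols = [j for j, _ in keep]
        libs = [lib for _, lib in keep]
        counts = otu.counts[:, cols]
        depths = counts.sum(axis=0)
        zero = [lib for lib, d in zip(libs, depths) if d == 0]
        if zero:
            raise ValueError(f"table {nm!r}: zero sequencing depth for libraries {zero}")
        clr = np.column_stack(
            [clr_transform(counts[:, k], depths[k]) for k in range(len(libs))]
        )
        ra = 100.0 * counts / depths
        n_taxa, n_lib = counts.shape
        block = pd.DataFrame(
            {
                "Table": nm,
                "Taxa": np.repeat(otu.taxa, n_lib),
                "Lib": np.tile(libs, n_taxa),
                "cts": counts.ravel(),
                "Total": np.tile(depths, n_taxa),
                "ra": ra.ravel(),
                "clr": clr.ravel(),
                "bin": (counts.ravel() > 0).astype(np.int64),
            }
        )
        blocks.append(block)
        table_taxa[nm] = list(otu.taxa)

    data = pd.concat(blocks, ignore_index=True)
    clin = clinical.frame
    joined = data.join(clin, on="Lib")
    for col in clin.columns:  # preserve declared level order through the join
        if isinstance(clin[col].dtype, pd.CategoricalDtype):
            joined[col] = pd.Categorical(
                joined[col], categories=clin[col].cat.categories
            )
    return MicroSet(data=joined, tables=table_taxa,
                    clinical_cols=list(clin.columns))


def read_micro_set(path) -> MicroSet:
    """Load a micro set previously written with :meth:`MicroSet.to_csv`.

    Clinical column types are re-inferred (numeric if all values parse, else
    categorical in first-seen order).
    """
    df = pd.read_csv(path, dtype={"Table": str, "Taxa": str, "Lib": str})
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing micro-set columns {missing}")
    clin_cols = [c for c in df.columns if c not in CORE_COLUMNS]
    for col in clin_cols:
        ser = df[col]
        if not np.issubdtype(ser.dtype, np.number):
            df[col] = pd.Categorical(
                ser.astype("string").astype(object),
                categories=list(pd.unique(ser.dropna().astype(str))),
            )
    tables: dict[str, list[str]] = {}
    for nm in pd.unique(df["Table"]):
        tables[nm] = list(pd.unique(df.loc[df["Table"] == nm, "Taxa"]))
    return MicroSet(data=df, tables=tables, clinical_cols=clin_cols)


def split_rank_path(taxon: str, delimiter: str = "/") -> list[str]:
    """Split a taxon rank path, e.g. 'Bacteria/Firmicutes/Bacilli'."""
    return taxon.split(delimiter)


def phylum_of(taxon: str, delimiter: str = "/", index: int = 1) -> str:
    """Phylum element of a rank path (2nd element by default); whole label if too short."""
    parts = split_rank_path(taxon, delimiter)
    return parts[index] if len(parts) > index else parts[-1]
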