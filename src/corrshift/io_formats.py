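"""Readers, writers, and validated containers for the pipeline's tabular formats.

Three plain-text formats carry all inputs:

* expression matrix — TSV, genes in rows, samples in columns, one header row
  of sample IDs, first column gene symbols, non-negative FPKM-like values;
* sample sheet — two-column TSV (``sample_id``, ``group``) assigning every
  sample to ``control`` or ``cancer``;
* gene sets — standard GMT (set name, description, tab-separated members).

All readers validate strictly and raise :class:`FormatError` naming the
offending record; all writers round-trip exactly through the matching reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("corrshift")

CONTROL = "control"
CANCER = "cancer"
VALID_GROUPS = (CONTROL, CANCER)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A dense genes × samples abundance matrix (FPKM-like, unitless).

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene symbols
    and whose columns hold unique sample IDs. Values must be finite and
    non-negative; every (gene, sample) cell is present.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise FormatError("expression matrix must have at least one gene and one sample")
        dup_genes = data.index[data.index.duplicated()].unique().tolist()
        if dup_genes:
            raise FormatError(f"duplicate gene ID(s): {', '.join(map(str, dup_genes))}")
        dup_samples = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise FormatError(f"duplicate sample ID(s): {', '.join(map(str, dup_samples))}")
        values = data.to_numpy(dtype=float, copy=True)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid value {data.iat[i, j]!r} at gene {data.index[i]!r}, "
                f"sample {data.columns[j]!r} (row {i + 2}, column {j + 2} of the file): "
                "values must be finite and >= 0"
            )
        self._data = pd.DataFrame(values, index=data.index.astype(str), columns=data.columns.astype(str))

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def values_for(self, genes: Sequence[str], samples: Sequence[str]) -> np.ndarray:
        """Return a (len(genes), len(samples)) float array for the given labels."""
        return self._data.loc[list(genes), list(samples)].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass(frozen=True)
class SampleGroups:
    """Assignment of each sample to the control or cancer group."""

    assignment: Mapping[str, str]

    def __post_init__(self):
        bad = {s: g for s, g in self.assignment.items() if g not in VALID_GROUPS}
        if bad:
            sample, group = next(iter(bad.items()))
            raise FormatError(
                f"unknown group label {group!r} for sample {sample!r}; "
                f"labels must be one of {VALID_GROUPS}"
            )

    def samples_in(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [s for s, g in self.assignment.items() if g == group]

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(CONTROL)

    @property
    def cancer_samples(self) -> list[str]:
        return self.samples_in(CANCER)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check every matrix sample is labeled and both groups are non-empty."""
        missing = [s for s in matrix.sample_ids if s not in self.assignment]
        if missing:
            raise FormatError(f"sample sheet is missing matrix sample(s): {', '.join(missing)}")
        for group in VALID_GROUPS:
            if not any(self.assignment.get(s) == group for s in matrix.sample_ids):
                raise FormatError(f"group {group!r} has no samples in the matrix")


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set (one GMT line)."""

    name: str
    source_id: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.genes:
            raise FormatError(f"pathway {self.name!r} has no member genes")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV into a validated :class:`ExpressionMatrix`.

    Row and column order are preserved from the file. Duplicate gene IDs,
    negative, missing, or non-numeric cells are hard errors that name the
    offending gene/sample coordinates.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression matrix file") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: expression matrix has no data rows/columns")
    bad = raw.apply(pd.to_numeric, errors="coerce").isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} (row {i + 2}, column {j + 2})"
        )
    # strtod-exact conversion so write-then-read round trips to the last bit
    values = raw.to_numpy(dtype=str).astype(np.float64)
    numeric = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    try:
        return ExpressionMatrix(numeric)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write the matrix as TSV; exact round trip through :func:`read_expression_matrix`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Sample sheet I/O
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path, matrix: ExpressionMatrix | None = None) -> SampleGroups:
    """Read a two-column ``sample_id<TAB>group`` sheet.

    If ``matrix`` is given, every matrix sample must be present in the sheet
    (missing IDs are a hard error listing them); sheet rows for samples not in
    the matrix are dropped with a warning.
    """
    path = Path(path)
    try:
        sheet = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty sample sheet") from exc
    required = ["sample_id", "group"]
    if list(sheet.columns[:2]) != required:
        raise FormatError(f"{path}: sample sheet header must be {required}, got {list(sheet.columns)}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate sample ID(s) in sheet: {', '.join(dup)}")
    assignment = dict(zip(sheet["sample_id"], sheet["group"]))
    for sample, group in assignment.items():
        if group not in VALID_GROUPS:
            raise FormatError(
                f"{path}: unknown group label {group!r} for sample {sample!r}; "
                f"expected one of {VALID_GROUPS}"
            )
    if matrix is not None:
        missing = [s for s in matrix.sample_ids if s not in assignment]
        if missing:
            raise FormatError(f"{path}: sample sheet is missing matrix sample(s): {', '.join(missing)}")
        extra = [s for s in assignment if s not in set(matrix.sample_ids)]
        if extra:
            logger.warning("sample sheet lists %d sample(s) absent from the matrix; ignored", len(extra))
            assignment = {s: g for s, g in assignment.items() if s not in set(extra)}
    return SampleGroups(assignment)


def write_sample_sheet(groups: SampleGroups, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.assignment.items():
            fh.write(f"{sample}\t{group}\n")
    return path


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Parse a GMT file into :class:`PathwaySet` records, in file order.

    Duplicate members within one line are collapsed with a logged warning;
    a line with fewer than 3 tab-separated fields is a hard error.
    """
    path = Path(path)
    sets: list[PathwaySet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name, source_id, *members = fields
            members = [m for m in members if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "GMT set %r (line %d): %d duplicate member(s) collapsed",
                    name, lineno, len(members) - len(unique),
                )
            sets.append(PathwaySet(name=name, source_id=source_id, genes=unique))
    if not sets:
        raise FormatError(f"{path}: GMT file contains no gene sets")
    return sets


def write_gmt(sets: Iterable[PathwaySet], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, ps.source_id, *sorted(ps.genes)]) + "\n")
    return path


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a result table as TSV with a stable, documented header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")
    return path
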