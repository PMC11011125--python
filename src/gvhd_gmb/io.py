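"""Readers and writers for expression matrices, sample labels, and gene panels.

All file formats are plain tab-separated UTF-8 text. Expression matrices are
stored genes-as-rows (first column the gene identifier, one column per
sample), the dominant convention for targeted-panel FPKM tables. Panels are
one raw symbol per line in printed order; raw symbols may carry a
parenthetical alias ("TFRC (CD71)") or a spreadsheet date-mangling artifact
(a leading run of digits glued onto the symbol, e.g. "43717SEPT9"), both of
which :func:`normalize_symbol` repairs.

Missing values are never imputed: a hole in a matrix is an explicit failure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError

__all__ = [
    "ExpressionMatrix",
    "CohortLabels",
    "GenePanel",
    "normalize_symbol",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_gene_panel",
    "align_panel",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Non-negative FPKM values, genes x samples.

    Thin validated wrapper around a pandas DataFrame (index = gene ids,
    columns = sample ids).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise DomainError("expression matrix contains non-finite or missing values")
        if values.size and (values < 0).any():
            raise DomainError("expression matrix contains negative values")
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Genes x samples float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids), :])


@dataclass
class CohortLabels:
    """Per-sample binary endpoints and sampling timepoint.

    Columns: sample_id (index), timepoint in {pre, post}, agvhd in {0,1},
    alive in {0,1}, onset_day (positive float, only for agvhd == 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in labels")
        required = {"timepoint", "agvhd", "alive"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"labels missing columns: {sorted(missing)}")
        if not df["timepoint"].isin(["pre", "post"]).all():
            raise FormatError("timepoint must be 'pre' or 'post'")
        for col in ("agvhd", "alive"):
            if not df[col].isin([0, 1]).all():
                raise FormatError(f"{col} must be binary 0/1")
        if "onset_day" in df.columns:
            onset = df["onset_day"]
            has_onset = onset.notna()
            if (has_onset & (df["agvhd"] == 0)).any():
                raise FormatError("onset_day present for a sample without aGvHD")
            if (onset[has_onset] <= 0).any():
                raise FormatError("onset_day must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, name: str) -> pd.Series:
        """Binary endpoint vector; for 'survival' 1 encodes death (the event)."""
        if name == "agvhd":
            return self.data["agvhd"].astype(int)
        if name in ("survival", "death"):
            return (1 - self.data["alive"]).astype(int)
        raise KeyError(f"unknown endpoint {name!r}; expected 'agvhd' or 'survival'")

    def subset(self, sample_ids: Iterable[str]) -> "CohortLabels":
        return CohortLabels(self.data.loc[list(sample_ids)])


@dataclass
class GenePanel:
    """An ordered list of normalized gene symbols with optional aliases."""

    name: str
    symbols: list[str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            seen: set[str] = set()
            dupes = [s for s in self.symbols if s in seen or seen.add(s)]  # type: ignore[func-returns-value]
            raise FormatError(f"duplicate symbols in panel {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


# ---------------------------------------------------------------------------
# symbol normalization
# ---------------------------------------------------------------------------

_PAREN_RE = re.compile(r"^(?P<sym>[^()]*?)\s*\(\s*(?P<alias>[^()]*?)\s*\)\s*$")
_EXCEL_RE = re.compile(r"^\d+(?=[A-Za-z])")


def normalize_symbol(raw: str) -> tuple[str, str | None]:
    """Normalize a printed gene symbol.

    A parenthetical suffix becomes the alias ("TFRC (CD71)" -> TFRC / CD71).
    A leading run of digits immediately followed by letters is stripped: this
    repairs the spreadsheet artifact that turns symbols such as SEPT9 into a
    date serial glued to the symbol ("43717SEPT9" -> SEPT9). Purely numeric
    tokens are rejected rather than silently emptied. Symbols are uppercased.
    """
    token = raw.strip()
    if not token:
        raise FormatError("empty gene symbol")
    alias: str | None = None
    m = _PAREN_RE.match(token)
    if m:
        token = m.group("sym").strip()
        alias = m.group("alias").strip().upper() or None
    token = _EXCEL_RE.sub("", token).strip().upper()
    if not token:
        raise FormatError(f"gene symbol {raw!r} is empty after normalization")
    if token.isdigit():
        # the digit-stripping rule applies only when letters follow, so a
        # purely numeric identifier is rejected rather than silently emptied
        raise FormatError(f"gene symbol {raw!r} is purely numeric")
    return token, alias


# ---------------------------------------------------------------------------
# expression matrix files
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-as-rows FPKM table.

    First column holds gene identifiers, the header row sample identifiers.
    Duplicate identifiers, negative values, and ragged/missing cells are
    rejected with the offending line or value named.
    """
    if dialect != "tsv":
        raise FormatError(f"unknown expression dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        # +2: one for the header row, one for 1-based numbering
        lines = [int(np.where(df.index == d)[0][-1]) + 2 for d in dupes]
        raise FormatError(f"{path}: duplicate gene id(s) {dupes} (line {lines})")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if values.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values (ragged row or empty cell)")
    df = values
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips bit-exactly for finite decimals."""
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> CohortLabels:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CohortLabels(df)


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    df = labels.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene panels
# ---------------------------------------------------------------------------

def read_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a one-symbol-per-line panel file, normalizing every symbol.

    Blank lines are ignored; printed order is preserved; duplicates after
    normalization are a format error.
    """
    path = Path(path)
    symbols: list[str] = []
    aliases: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        symbol, alias = normalize_symbol(line)
        if symbol in symbols:
            raise FormatError(
                f"{path}:{lineno}: duplicate symbol {symbol!r} after normalization"
            )
        symbols.append(symbol)
        if alias:
            aliases[symbol] = alias
    return GenePanel(name=name or path.stem, symbols=symbols, aliases=aliases)


def bundled_panel(which: Literal["agvhd_post", "survival_post"]) -> GenePanel:
    """Load one of the panels shipped with the package.

    ``agvhd_post``: the 92 genes reported to predict acute GvHD from
    post-transplant marrow; ``survival_post``: the 20 genes reported to
    predict overall survival.
    """
    from importlib.resources import files

    fname = {
        "agvhd_post": "panel_agvhd_post_92.txt",
        "survival_post": "panel_survival_post_20.txt",
    }[which]
    resource = files("gvhd_gmb").joinpath("data", fname)
    with resource.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    symbols: list[str] = []
    aliases: dict[str, str] = {}
    for line in lines:
        if not line.strip():
            continue
        symbol, alias = normalize_symbol(line)
        symbols.append(symbol)
        if alias:
            aliases[symbol] = alias
    return GenePanel(name=which, symbols=symbols, aliases=aliases)


def align_panel(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    policy: Literal["strict", "intersect"] = "strict",
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix to the panel's genes, in panel order.

    strict: every panel gene must be present, otherwise an error listing the
    missing genes. intersect: keep the overlap and report the missing genes.
    Returns (submatrix, missing_genes).
    """
    if policy not in ("strict", "intersect"):
        raise DomainError(f"unknown alignment policy {policy!r}")
    present = set(matrix.gene_ids)
    missing = [g for g in panel.symbols if g not in present]
    if policy == "strict" and missing:
        raise DomainError(f"panel genes absent from matrix: {missing}")
    keep = [g for g in panel.symbols if g in present]
    return ExpressionMatrix(matrix.data.loc[keep, :]), missing
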