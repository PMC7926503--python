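"""Domain types and readers/writers shared by every pipeline stage.

The in-memory containers are thin, validated wrappers around pandas objects:

* :class:`ExpressionMatrix` — genes x samples log2 expression with
  canonicalized, unique gene symbols;
* :class:`MarkerSignature` — a directed marker gene list (the packaged
  claudin-low signature has 17 entries);
* :class:`LabeledReference` — a reference expression panel with a CL/other
  label per sample, used to train the centroid classifier;
* clinical tables are plain DataFrames validated by :func:`read_clinical` /
  :func:`validate_clinical`.

File formats: expression as TSV (gene column + one column per sample) or
GCT 1.2; gene sets as GMT; clinical as TSV with columns
``sample_id, time, event, cohort``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Symbol aliases collapsed during canonicalization. Kept deliberately short:
#: silent fuzzy matching is worse than a reported miss.
GENE_ALIASES: dict[str, str] = {"TACSTD1": "EPCAM"}

CL_LABEL = "CL"
OTHER_LABEL = "other"


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SignatureIntegrityError(ValueError):
    """The packaged marker signature failed its integrity check."""


def canonicalize_symbol(symbol: str) -> str:
    """Uppercase, strip whitespace, and resolve known aliases."""
    s = str(symbol).strip().upper()
    return GENE_ALIASES.get(s, s)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    ``data`` is indexed by canonical gene symbol (unique) with one column per
    sample id (unique); all values must be finite. ``cohort`` optionally maps
    each sample to a cohort label.
    """

    data: pd.DataFrame
    cohort: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(
                f"duplicate gene symbol {dup!r}; collapse duplicates first "
                "(ExpressionMatrix.from_dataframe does this by mean)"
            )
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.cohort is not None:
            self.cohort = self.cohort.reindex(self.data.columns)
            if self.cohort.isna().any():
                missing = self.cohort.index[self.cohort.isna()][0]
                raise ValueError(f"sample {missing!r} has no cohort label")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cohort: pd.Series | None = None,
        canonicalize: bool = True,
    ) -> "ExpressionMatrix":
        """Build a matrix from a genes x samples DataFrame.

        Gene symbols are canonicalized and duplicate rows collapsed by
        arithmetic mean on the log2 scale, preserving first-occurrence order.
        """
        df = df.copy()
        if canonicalize:
            df.index = [canonicalize_symbol(g) for g in df.index]
        if df.index.duplicated().any():
            df = df.groupby(level=0, sort=False).mean()
        return cls(df.astype(float), cohort=cohort)

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (canonicalized), keeping their given order."""
        wanted = [canonicalize_symbol(g) for g in genes]
        present = [g for g in wanted if g in self.data.index]
        if not present:
            raise ValueError("no requested genes present in the matrix")
        return ExpressionMatrix(self.data.loc[present], cohort=self.cohort)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        cohort = self.cohort.loc[list(samples)] if self.cohort is not None else None
        return ExpressionMatrix(self.data[list(samples)], cohort=cohort)


# ---------------------------------------------------------------------------
# Expression readers / writers
# ---------------------------------------------------------------------------


def _numeric_body(raw: pd.DataFrame, header_lines: int) -> pd.DataFrame:
    """Coerce a string-typed body to floats, naming the first offending line."""

    def to_float(col: pd.Series) -> pd.Series:
        # numpy's parser is correctly rounded, so written files round-trip
        try:
            return pd.Series(col.to_numpy(dtype=float), index=col.index)
        except (TypeError, ValueError):
            return pd.to_numeric(col, errors="coerce")

    body = raw.apply(to_float)
    bad = ~np.isfinite(body.to_numpy(dtype=float))
    if bad.any():
        row = int(np.where(bad.any(axis=1))[0][0])
        col = int(np.where(bad[row])[0][0])
        raise ParseError(
            f"non-numeric or non-finite value {raw.iloc[row, col]!r} for gene "
            f"{raw.index[row]!r}",
            line=header_lines + row + 1,
        )
    return body


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``gct`` (1.2) format.

    Gene symbols are canonicalized (uppercased, whitespace-stripped, aliases
    resolved) and duplicate gene rows are collapsed by mean.
    """
    path = Path(path)
    if format == "tsv":
        try:
            raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"cannot parse TSV: {exc}") from exc
        if raw.shape[1] == 0 or raw.shape[0] == 0:
            raise ParseError("empty expression matrix", line=1)
        if pd.Index(raw.columns).duplicated().any():
            raise ParseError("duplicate sample id in header", line=1)
        body = _numeric_body(raw, header_lines=1)
        return ExpressionMatrix.from_dataframe(body)
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"expected GCT version line '#1.2', got {version!r}", line=1)
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError("malformed GCT dimensions line", line=2)
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise ParseError("malformed GCT dimensions line", line=2) from exc
        raw = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=str)
        if raw.shape[0] != n_genes or raw.shape[1] - 1 != n_samples:
            raise ParseError(
                f"GCT header declares {n_genes} genes x {n_samples} samples but body "
                f"is {raw.shape[0]} x {raw.shape[1] - 1}",
                line=2,
            )
        raw = raw.drop(columns=raw.columns[0])  # Description column
        body = _numeric_body(raw, header_lines=3)
        return ExpressionMatrix.from_dataframe(body)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as TSV or GCT 1.2 at full stored precision."""
    path = Path(path)
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
        return
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.17g")
        return
    raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Gene lists / signatures
# ---------------------------------------------------------------------------


@dataclass
class MarkerSignature:
    """A named list of marker genes with expected direction (up/down)."""

    entries: tuple[tuple[str, str], ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        entries = tuple((canonicalize_symbol(g), d) for g, d in self.entries)
        genes = [g for g, _ in entries]
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        for g, d in entries:
            if d not in ("up", "down"):
                raise ValueError(f"direction for {g} must be 'up' or 'down', got {d!r}")
        if not entries:
            raise ValueError("empty signature")
        self.entries = entries

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == "up"]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == "down"]

    def direction(self, gene: str) -> str:
        gene = canonicalize_symbol(gene)
        for g, d in self.entries:
            if g == gene:
                return d
        raise KeyError(gene)


def load_cl_signature() -> MarkerSignature:
    """Load the packaged 17-gene claudin-low marker signature.

    The signature lists the tight/adherens-junction and epithelial
    differentiation genes lost in claudin-low tumors (claudins 3/4/7,
    E-cadherin, occludin, CD24, EPCAM, MUC1) and the EMT / stemness markers
    they gain (vimentin, SNAI1/2, TWIST1/2, ZEB1/2, CD44, ALDH1A1).
    """
    ref = resources.files("claudinlow.data").joinpath("cl_signature.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns) != ["gene", "direction"]:
        raise SignatureIntegrityError("packaged signature has unexpected columns")
    entries = tuple((str(g), str(d)) for g, d in zip(df["gene"], df["direction"]))
    try:
        sig = MarkerSignature(entries, name="claudin_low_17")
    except ValueError as exc:
        raise SignatureIntegrityError(str(exc)) from exc
    if len(sig.entries) != 17:
        raise SignatureIntegrityError(
            f"packaged claudin-low signature must have 17 genes, found {len(sig.entries)}"
        )
    return sig


def intersect_genes(
    matrix: ExpressionMatrix, gene_list: Sequence[str]
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Restrict ``matrix`` to the genes of ``gene_list`` present in it.

    Returns ``(sub_matrix, kept, missing)`` with ``kept`` in ``gene_list``
    order. Raises if the intersection is empty (usually a symbol
    canonicalization problem).
    """
    if len(gene_list) == 0:
        raise ValueError("gene_list is empty")
    wanted = [canonicalize_symbol(g) for g in gene_list]
    index = set(matrix.data.index)
    kept = [g for g in wanted if g in index]
    missing = [g for g in wanted if g not in index]
    if not kept:
        raise ValueError(
            "no genes of the requested list are present in the matrix; check that "
            "both use canonical HGNC-style symbols (uppercase, alias-resolved)"
        )
    if missing:
        logger.warning(
            "%d of %d requested genes missing from matrix (%.1f%%)",
            len(missing), len(wanted), 100 * len(missing) / len(wanted),
        )
    return matrix.restrict(kept), kept, missing


# ---------------------------------------------------------------------------
# Labeled reference panel
# ---------------------------------------------------------------------------


@dataclass
class LabeledReference:
    """Reference expression panel with one CL/other label per sample."""

    matrix: ExpressionMatrix
    labels: pd.Series
    gene_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.matrix.samples)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()][0]
            raise ValueError(f"reference sample {missing!r} has no label")
        bad = set(self.labels.unique()) - {CL_LABEL, OTHER_LABEL}
        if bad:
            raise ValueError(f"reference labels must be {{CL, other}}, found {sorted(bad)}")
        if not self.gene_list:
            self.gene_list = self.matrix.genes
        else:
            self.gene_list = [canonicalize_symbol(g) for g in self.gene_list]


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["sample_id", "time", "event", "cohort"]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: positive times, 0/1 events, unique ids."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = df.copy()
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    df["event"] = df["event"].astype(int)
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time, event, cohort."""
    df = pd.read_csv(path, sep="\t")
    try:
        return validate_clinical(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    "GMT line needs at least name, description and one member",
                    line=lineno,
                )
            name = parts[0].strip()
            if name in sets:
                raise ParseError(f"duplicate gene set name {name!r}", line=lineno)
            members = [canonicalize_symbol(g) for g in parts[2:] if g.strip()]
            sets[name] = list(dict.fromkeys(members))
    if not sets:
        raise ParseError("empty GMT file")
    return sets


def load_toy_gene_sets() -> dict[str, list[str]]:
    """Load the packaged 5-set toy collection built from the CL signature."""
    ref = resources.files("claudinlow.data").joinpath("toy_sets.gmt")
    sets: dict[str, list[str]] = {}
    with ref.open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [canonicalize_symbol(g) for g in parts[2:] if g.strip()]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
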