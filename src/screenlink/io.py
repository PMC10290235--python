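"""Data model and table I/O.

Two screen types share one carrier, :class:`DependencyMatrix`: a real-valued
entities x cell-lines matrix.  For a CRISPR screen the entities are genes and
the values are gene-effect scores (dimensionless; more negative = stronger
dependency); for a drug screen the entities are drugs and the values are
log-fold changes in viability (negative = growth inhibition).  Missing entries
are retained as NaN and handled per-operation (pairwise-complete statistics);
they are never imputed, because sparse drug screens would be distorted by any
imputation scheme.

Table dialects
--------------
Matrices are CSV/TSV with a header row of cell-line IDs and a first column of
entity labels; missing-value tokens are the empty string, ``NA`` and ``NaN``.
DepMap-style gene labels of the form ``"SYMBOL (EntrezID)"`` are reduced to
the bare symbol when ``strip_entrez`` is on, so that annotations keyed by
symbol match.  All writers emit TSV with ``#`` comment lines recording the
tool version and the parameters used.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

MISSING_TOKENS = ["", "NA", "NaN"]

#: matches DepMap-style labels "CDK6 (1021)"
_ENTREZ_SUFFIX = re.compile(r"^(.*\S)\s+\(\d+\)$")

GENE_EFFECT = "gene_effect"
DRUG_RESPONSE = "drug_response"
_KINDS = (GENE_EFFECT, DRUG_RESPONSE)


def _comment_header(params: dict) -> str:
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# screenlink {__version__} {items}".rstrip() + "\n"


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class DependencyMatrix:
    """Entities x cell lines matrix of one screen type.

    ``data`` is a float DataFrame indexed by entity ID with cell-line ID
    columns; NaN marks a missing measurement.
    """

    kind: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DataError(f"unknown matrix kind {self.kind!r}; expected one of {_KINDS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate entity IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate cell-line IDs: {dups[:5]}")
        if self.data.shape[1] < 2:
            raise DataError(f"need at least 2 cell lines, got {self.data.shape[1]}")
        self.data = self.data.astype(float)

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def row(self, entity: str) -> np.ndarray:
        if entity not in self.data.index:
            raise DataError(f"unknown entity {entity!r} in {self.kind} matrix")
        return self.data.loc[entity].to_numpy()


@dataclass(frozen=True)
class TargetAnnotation:
    """One drug's annotated target genes and clinical development phase."""

    drug_id: str
    target_genes: frozenset[str]
    clinical_phase: str | None = None

    def pairs(self) -> list[tuple[str, str]]:
        return [(self.drug_id, g) for g in sorted(self.target_genes)]


@dataclass
class SignatureMatrix:
    """Genes x perturbagens matrix of perturbation-signature z-scores."""

    z: pd.DataFrame  # index genes, columns perturbagen IDs

    def __post_init__(self) -> None:
        if self.z.index.has_duplicates:
            raise DataError("duplicate gene IDs in signature matrix")
        if self.z.isna().to_numpy().any():
            raise DataError("signature matrix must not contain missing values after load")
        self.z = self.z.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def perturbagen_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class ChemTable:
    """Drug ID -> canonical SMILES."""

    smiles: dict[str, str] = field(default_factory=dict)

    def items(self):
        return self.smiles.items()

    def __len__(self) -> int:
        return len(self.smiles)


@dataclass(frozen=True)
class EssentialitySummary:
    gene: str
    cutoff: float
    n_assayed: int
    n_essential: int
    lineage_medians: pd.Series  # sorted ascending (strongest dependency first)


def _check_rect(path: str | Path, sep: str) -> None:
    """Reject ragged tables: every row must have the header's column count."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        width = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#") and width is None):
                continue
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise DataError(
                    f"ragged table {path}: line {lineno} has {len(row)} fields, header has {width}"
                )


def _read_table(path: str | Path, sep: str, **kwargs) -> pd.DataFrame:
    if not Path(path).exists():
        raise DataError(f"input file not found: {path}")
    _check_rect(path, sep)
    return pd.read_csv(
        path,
        sep=sep,
        comment="#",
        na_values=MISSING_TOKENS,
        keep_default_na=False,
        **kwargs,
    )


def strip_entrez_suffix(label: str) -> str:
    m = _ENTREZ_SUFFIX.match(label)
    return m.group(1) if m else label


def read_dependency_matrix(
    path: str | Path,
    kind: str,
    *,
    dialect: str | None = None,
    strip_entrez: bool = False,
) -> DependencyMatrix:
    """Read an entities x cell-lines matrix from CSV/TSV.

    Parameters
    ----------
    kind : {"gene_effect", "drug_response"}
    dialect : force "csv" or "tsv"; default inferred from the file suffix.
    strip_entrez : reduce DepMap-style ``"SYMBOL (1234)"`` labels to ``"SYMBOL"``.
    """
    sep = _sep_for(path, dialect)
    df = _read_table(path, sep, index_col=0)
    if df.index.isna().any() or df.columns.isna().any():
        raise DataError(f"malformed header or entity column in {path}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if strip_entrez:
        df.index = df.index.map(strip_entrez_suffix)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric value in matrix {path}: {exc}") from exc
    m = DependencyMatrix(kind=kind, data=df)
    logger.info(
        "read %s matrix %s: %d entities x %d cell lines, %d missing",
        kind, path, len(m.entity_ids), len(m.cell_line_ids), m.n_missing,
    )
    return m


def write_dependency_matrix(m: DependencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "dependency_matrix", "kind": m.kind}))
        m.data.to_csv(fh, sep="\t", index_label="entity_id", na_rep="NA")


def harmonize(
    a: DependencyMatrix, b: DependencyMatrix, min_common: int = 3
) -> tuple[DependencyMatrix, DependencyMatrix, list[str]]:
    """Restrict two matrices to their common cell lines, column-aligned.

    The common cell-line list is sorted lexicographically so the output is
    deterministic regardless of input column order.  Idempotent.
    """
    common = sorted(set(a.cell_line_ids) & set(b.cell_line_ids))
    if len(common) < min_common:
        raise DataError(
            f"only {len(common)} common cell lines between matrices of "
            f"{len(a.cell_line_ids)} and {len(b.cell_line_ids)}; need >= {min_common}"
        )
    a2 = DependencyMatrix(kind=a.kind, data=a.data[common])
    b2 = DependencyMatrix(kind=b.kind, data=b.data[common])
    return a2, b2, common


def read_cell_line_meta(path: str | Path, *, dialect: str | None = None) -> pd.Series:
    """Read cell-line metadata; returns a Series mapping cell_line_id -> lineage."""
    sep = _sep_for(path, dialect)
    df = _read_table(path, sep, dtype=str)
    for col in ("cell_line_id", "lineage"):
        if col not in df.columns:
            raise DataError(f"cell-line metadata {path} missing required column {col!r}")
    if df["cell_line_id"].duplicated().any():
        raise DataError(f"duplicate cell_line_id in {path}")
    if df["lineage"].isna().any() or (df["lineage"].str.len() == 0).any():
        raise DataError(f"empty lineage label in {path}")
    return pd.Series(df["lineage"].values, index=df["cell_line_id"].values, name="lineage")


def write_cell_line_meta(meta: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "cell_line_meta"}))
        meta.rename_axis("cell_line_id").rename("lineage").to_csv(fh, sep="\t")


def read_target_annotations(
    path: str | Path,
    *,
    dialect: str | None = None,
    delimiter_in_cell: str = ", ",
) -> list[TargetAnnotation]:
    """Read drug->targets annotations.

    Expects columns ``drug_id``, ``targets`` and ``phase``; the targets cell
    holds multiple gene symbols split by ``delimiter_in_cell``.  Records with
    an empty target set are dropped with a warning; the expanded (drug, gene)
    pair count is logged.
    """
    sep = _sep_for(path, dialect)
    df = _read_table(path, sep, dtype=str)
    for col in ("drug_id", "targets", "phase"):
        if col not in df.columns:
            raise DataError(f"annotation table {path} missing required column {col!r}")
    if df["drug_id"].duplicated().any():
        raise DataError(f"duplicate drug_id in annotation table {path}")
    records: list[TargetAnnotation] = []
    n_pairs = 0
    for row in df.itertuples(index=False):
        raw = "" if pd.isna(row.targets) else str(row.targets)
        genes = frozenset(g.strip() for g in raw.split(delimiter_in_cell) if g.strip())
        if not genes:
            logger.warning("dropping drug %s: empty target set", row.drug_id)
            continue
        phase = None if pd.isna(row.phase) or not str(row.phase) else str(row.phase)
        records.append(TargetAnnotation(str(row.drug_id), genes, phase))
        n_pairs += len(genes)
    logger.info("read %d drugs with %d drug-target pairs from %s", len(records), n_pairs, path)
    return records


def write_target_annotations(
    annotations: Iterable[TargetAnnotation], path: str | Path, *, delimiter_in_cell: str = ", "
) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "target_annotations"}))
        fh.write("drug_id\ttargets\tphase\n")
        for ann in annotations:
            targets = delimiter_in_cell.join(sorted(ann.target_genes))
            fh.write(f"{ann.drug_id}\t{targets}\t{ann.clinical_phase or ''}\n")


def expand_pairs(annotations: Iterable[TargetAnnotation]) -> set[tuple[str, str]]:
    """Expand annotations to the set of (drug_id, gene) pairs."""
    out: set[tuple[str, str]] = set()
    for ann in annotations:
        out.update(ann.pairs())
    return out


def read_signature_matrix(path: str | Path, *, dialect: str | None = None) -> SignatureMatrix:
    """Read a genes x perturbagens z-score matrix; rows with any missing value
    are dropped and logged."""
    sep = _sep_for(path, dialect)
    df = _read_table(path, sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df = df.astype(float)
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d signature rows with missing values: %s",
            int(incomplete.sum()), list(df.index[incomplete][:5]),
        )
        df = df[~incomplete]
    return SignatureMatrix(z=df)


def write_signature_matrix(sig: SignatureMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "signature_matrix"}))
        sig.z.to_csv(fh, sep="\t", index_label="gene_id")


def read_chem_table(
    path: str | Path, *, dialect: str | None = None, validate: bool = True
) -> ChemTable:
    """Read a drug_id -> SMILES table; unparseable SMILES are rejected with a
    logged reason when ``validate`` is on (requires the chemistry backend)."""
    sep = _sep_for(path, dialect)
    df = _read_table(path, sep, dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise DataError(f"chemistry table {path} missing required column {col!r}")
    table: dict[str, str] = {}
    if validate:
        from .chem import parse_smiles  # lazy: chemistry backend optional at import

    for row in df.itertuples(index=False):
        drug, smi = str(row.drug_id), str(row.smiles)
        if drug in table:
            raise DataError(f"duplicate drug_id {drug!r} in chemistry table {path}")
        if validate:
            try:
                parse_smiles(smi)
            except DataError as exc:
                logger.warning("rejecting %s: %s", drug, exc)
                continue
        table[drug] = smi
    return ChemTable(smiles=table)


def write_chem_table(table: ChemTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "chem_table"}))
        fh.write("drug_id\tsmiles\n")
        for drug, smi in table.items():
            fh.write(f"{drug}\t{smi}\n")


def essentiality_summary(
    m: DependencyMatrix,
    meta: pd.Series | None,
    gene: str,
    cutoff: float = -1.0,
) -> EssentialitySummary:
    """Summarize one gene's dependency profile.

    A cell line counts as dependent ("essential" for this gene) when its
    non-missing gene-effect score falls below ``cutoff`` (default -1, the
    conventional essentiality threshold).  Per-lineage median scores are
    returned sorted ascending, i.e. most-dependent lineage first.
    """
    scores = pd.Series(m.row(gene), index=m.cell_line_ids)
    assayed = scores.dropna()
    n_essential = int((assayed < cutoff).sum())
    if meta is not None:
        lineages = pd.Series(meta).reindex(assayed.index)
        medians = assayed.groupby(lineages).median().sort_values()
    else:
        medians = pd.Series(dtype=float)
    return EssentialitySummary(
        gene=gene,
        cutoff=cutoff,
        n_assayed=int(assayed.size),
        n_essential=n_essential,
        lineage_medians=medians,
    )
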