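"""Pairwise-complete Pearson correlation within and between screens.

A gene knockout and a drug treatment that act through the same mechanism
inhibit the same cell lines, so their dependency profiles correlate
positively across the panel.  Correlations are computed pairwise-complete:
for each pair of profiles, cell lines missing in either are dropped and the
sample Pearson coefficient is taken over the remaining n observations.
Significance comes from the exact t transform

    t = rho * sqrt((n - 2) / (1 - rho**2)),   t ~ Student-t(n - 2)

two-sided by default.  Pairs with fewer than ``min_pairs`` complete
observations (default 30, below which the t approximation is unstable) or
with zero variance are skipped and logged rather than reported.

The all-pairs path uses a missing-aware matrix formulation (indicator-masked
cross-products); its contract is numerical equality with the scalar
:func:`pearson_pair` on every pair, which the test suite enforces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import DependencyMatrix, GENE_EFFECT, _comment_header

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIRS = 30

GENE_GENE = "gene_gene"
DRUG_DRUG = "drug_drug"
GENE_DRUG = "gene_drug"

_VAR_TOL = 1e-300  # zero-variance guard on sums of squares


@dataclass(frozen=True)
class CorrelationRecord:
    entity_a: str
    entity_b: str
    edge_class: str
    rho: float
    n: int
    p: float


@dataclass
class CorrelationTable:
    """A collection of correlation records over a stated cell-line scope."""

    records: pd.DataFrame  # columns: entity_a, entity_b, edge_class, rho, n, p
    scope: str = "all"

    COLUMNS = ("entity_a", "entity_b", "edge_class", "rho", "n", "p")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"correlation table missing columns {missing}")
        self.records = self.records[list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def of_class(self, edge_class: str) -> pd.DataFrame:
        return self.records[self.records["edge_class"] == edge_class]

    @staticmethod
    def concat(tables: Iterable["CorrelationTable"], scope: str = "all") -> "CorrelationTable":
        frames = [t.records for t in tables]
        return CorrelationTable(pd.concat(frames, ignore_index=True), scope=scope)

    def to_tsv(self, path: str | Path, params: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(_comment_header({"table": "correlations", "scope": self.scope, **(params or {})}))
            self.records.to_csv(fh, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path) -> "CorrelationTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return CorrelationTable(df)


def pearson_pair(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[float, int, float]:
    """Pearson correlation over pairwise-complete observations.

    Returns ``(rho, n, p)``; raises :class:`DataError` when fewer than
    ``min_pairs`` complete pairs remain or either vector has zero variance.
    ``rho = +/-1`` reports ``p = 0`` exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"vector length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_pairs:
        raise DataError(f"only {n} complete pairs; need >= {min_pairs}")
    xs, ys = x[ok], y[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= _VAR_TOL or vy <= _VAR_TOL:
        raise DataError("zero variance in one of the vectors")
    rho = float(np.clip((xc @ yc) / np.sqrt(vx * vy), -1.0, 1.0))
    return rho, n, _p_from_rho(rho, n)


def _p_from_rho(rho: float | np.ndarray, n: int | np.ndarray) -> float | np.ndarray:
    """Two-sided p-value of the Pearson t transform; |rho|=1 -> p=0."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def _edge_class(kind_a: str, kind_b: str) -> str:
    gene_a = kind_a == GENE_EFFECT
    gene_b = kind_b == GENE_EFFECT
    if gene_a and gene_b:
        return GENE_GENE
    if not gene_a and not gene_b:
        return DRUG_DRUG
    return GENE_DRUG


def _pairwise_stats(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Missing-aware all-pairs Pearson between rows of A and rows of B.

    Returns (rho, n) arrays of shape (A rows, B rows); entries with
    undefined correlation (n < 2 or zero variance) are NaN in rho.
    """
    MA = (~np.isnan(A)).astype(float)
    MB = (~np.isnan(B)).astype(float)
    A0 = np.nan_to_num(A)
    B0 = np.nan_to_num(B)
    n = MA @ MB.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = A0 @ MB.T
        sy = MA @ B0.T
        sxx = (A0 * A0) @ MB.T
        syy = MA @ (B0 * B0).T
        sxy = A0 @ B0.T
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        # numerical floor: tiny negative values from cancellation are zero variance
        vx = np.where(vx < _VAR_TOL, np.nan, vx)
        vy = np.where(vy < _VAR_TOL, np.nan, vy)
        rho = cov / np.sqrt(vx * vy)
    rho = np.clip(rho, -1.0, 1.0)
    return rho, n.astype(int)


def _require_harmonized(a: DependencyMatrix, b: DependencyMatrix) -> None:
    if a.cell_line_ids != b.cell_line_ids:
        raise DataError(
            "matrices are not harmonized (cell-line columns differ or are ordered "
            "differently); call io.harmonize first"
        )


def correlate_cross(
    a: DependencyMatrix,
    b: DependencyMatrix,
    pairs: str | Sequence[tuple[str, str]] = "all",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    scope: str = "all",
) -> CorrelationTable:
    """Correlate every requested (row of a, row of b) pair.

    ``pairs`` is ``"all"`` or an explicit list of (entity_a, entity_b) IDs.
    Pairs failing the ``min_pairs`` floor or with zero variance are skipped
    with a logged count.
    """
    _require_harmonized(a, b)
    edge_class = _edge_class(a.kind, b.kind)
    rho, n = _pairwise_stats(a.values, b.values)

    ia = {e: i for i, e in enumerate(a.entity_ids)}
    ib = {e: i for i, e in enumerate(b.entity_ids)}
    if isinstance(pairs, str):
        if pairs != "all":
            raise DataError(f"pairs must be 'all' or an explicit list, got {pairs!r}")
        rows, cols = np.meshgrid(np.arange(len(ia)), np.arange(len(ib)), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
    else:
        idx = []
        for ea, eb in pairs:
            if ea not in ia:
                raise DataError(f"unknown entity {ea!r} in first matrix")
            if eb not in ib:
                raise DataError(f"unknown entity {eb!r} in second matrix")
            idx.append((ia[ea], ib[eb]))
        rows = np.array([i for i, _ in idx], dtype=int)
        cols = np.array([j for _, j in idx], dtype=int)

    r = rho[rows, cols]
    nn = n[rows, cols]
    keep = (nn >= min_pairs) & ~np.isnan(r)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info(
            "skipped %d pairs (fewer than %d complete observations or zero variance)",
            n_skipped, min_pairs,
        )
    ent_a = np.asarray(a.entity_ids, dtype=object)[rows[keep]]
    ent_b = np.asarray(b.entity_ids, dtype=object)[cols[keep]]
    df = pd.DataFrame(
        {
            "entity_a": ent_a,
            "entity_b": ent_b,
            "edge_class": edge_class,
            "rho": r[keep],
            "n": nn[keep],
            "p": _p_from_rho(r[keep], nn[keep]),
        }
    )
    return CorrelationTable(df, scope=scope)


def correlate_within(
    m: DependencyMatrix,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    scope: str = "all",
) -> CorrelationTable:
    """All unordered entity pairs within one matrix (self-pairs excluded)."""
    full = correlate_cross(m, m, "all", min_pairs=min_pairs, scope=scope)
    order = {e: i for i, e in enumerate(m.entity_ids)}
    df = full.records
    upper = df["entity_a"].map(order) < df["entity_b"].map(order)
    return CorrelationTable(df[upper].reset_index(drop=True), scope=scope)


def _subset_lineage(
    m: DependencyMatrix, meta: pd.Series, lineage: str
) -> DependencyMatrix:
    lines = [c for c in m.cell_line_ids if meta.get(c) == lineage]
    if not lines:
        raise DataError(f"no cell lines with lineage {lineage!r}")
    return DependencyMatrix(kind=m.kind, data=m.data[lines])


def top_k_neighbors(
    query: str,
    a: DependencyMatrix,
    b: DependencyMatrix,
    k: int = 10,
    *,
    meta: pd.Series | None = None,
    lineage: str | None = None,
    ranking: str = "signed_desc",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.DataFrame:
    """Rank partners (rows of ``b``) by correlation with ``query`` (row of ``a``).

    With a ``lineage`` scope, correlations are recomputed over that lineage's
    cell lines only (requires ``meta``).  ``ranking`` is ``signed_desc``
    (most positive rho first; a drug mimicking a knockout correlates
    positively) or ``absolute_desc``.  Ties break lexicographically on the
    partner ID.  ``k`` exceeding the partner count returns all partners.
    """
    if ranking not in ("signed_desc", "absolute_desc"):
        raise DataError(f"unknown ranking {ranking!r}")
    if query not in a.entity_ids:
        raise DataError(f"unknown query entity {query!r}")
    scope = "all"
    if lineage is not None:
        if meta is None:
            raise DataError("lineage scoping requires cell-line metadata")
        a = _subset_lineage(a, meta, lineage)
        b = _subset_lineage(b, meta, lineage)
        if len(a.cell_line_ids) < min_pairs:
            raise DataError(
                f"lineage {lineage!r} has {len(a.cell_line_ids)} cell lines; "
                f"need >= {min_pairs}"
            )
        scope = f"lineage:{lineage}"

    qa = DependencyMatrix(kind=a.kind, data=a.data.loc[[query]])
    table = correlate_cross(qa, b, "all", min_pairs=min_pairs, scope=scope)
    df = table.records
    df = df[df["entity_b"] != query]  # exclude self when a is b
    key = df["rho"] if ranking == "signed_desc" else df["rho"].abs()
    df = df.assign(_key=-key).sort_values(["_key", "entity_b"]).drop(columns="_key")
    return df.head(k).reset_index(drop=True)
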