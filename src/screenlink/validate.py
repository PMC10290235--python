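"""Validation of gene-drug correlations against annotated drug targets.

If the correlation analysis recovers real pharmacology, annotated drug-target
pairs should pass a correlation threshold far more often than chance.  For a
threshold ``t`` on the gene-drug coefficient:

* O = number of annotated pairs with rho >= t;
* E = |annotated| * (|passing| / |all pairs|), the count expected when
  annotation status and passing status are independent with the margins
  fixed;
* O/E is the enrichment ratio, and significance is a right-tailed Fisher's
  exact test on the 2x2 table {annotated, not} x {passing, not}, i.e. the
  hypergeometric upper tail P(X >= O).

Passing uses the signed coefficient by default (a drug that mimics its
target's knockout correlates positively); absolute mode is available.  The
hypergeometric tail is evaluated in log space (scipy) so tables with millions
of pairs are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import CorrelationTable, GENE_DRUG
from .errors import DataError
from .io import TargetAnnotation, expand_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationResult:
    threshold: float
    n_annotated_pairs: int
    n_passing_total: int
    n_pairs_total: int
    n_annotated_passing: int  # O
    expected_passing: float  # E
    oe_ratio: float
    fisher_p: float
    phase_scope: str = "all"


@dataclass(frozen=True)
class CoverageResult:
    n_pairs_total: int
    n_pairs_with_scores: int
    coverage_fraction: float  # percent, one decimal
    n_drugs_covered: int


@dataclass(frozen=True)
class HitFractionResult:
    n_drugs_evaluable: int
    n_drugs_hit: int
    fraction: float  # percent, one decimal


def _gene_drug_frame(corr: CorrelationTable) -> pd.DataFrame:
    """Gene-drug records keyed by (drug, gene) regardless of column order."""
    df = corr.of_class(GENE_DRUG)
    if df.empty:
        raise DataError("correlation table has no gene_drug records")
    # entity_a is the gene by construction (gene matrix first); accept either
    return df.assign(drug=df["entity_b"], gene=df["entity_a"])


def _pct1(numer: int, denom: int) -> float:
    """Percentage reported to one decimal."""
    return round(100.0 * numer / denom, 1)


def target_coverage(
    annotations: Sequence[TargetAnnotation], corr: CorrelationTable
) -> CoverageResult:
    """Fraction of annotated (drug, gene) pairs with a computable correlation."""
    if not annotations:
        raise DataError("empty annotation list")
    pairs = expand_pairs(annotations)
    df = _gene_drug_frame(corr)
    have = set(zip(df["drug"], df["gene"]))
    covered = pairs & have
    drugs_covered = {d for d, _ in covered}
    return CoverageResult(
        n_pairs_total=len(pairs),
        n_pairs_with_scores=len(covered),
        coverage_fraction=_pct1(len(covered), len(pairs)),
        n_drugs_covered=len(drugs_covered),
    )


def target_hit_fraction(
    annotations: Sequence[TargetAnnotation],
    corr: CorrelationTable,
    alpha: float = 0.05,
) -> HitFractionResult:
    """Fraction of drugs with >= 1 annotated target significantly correlated.

    A drug is evaluable when at least one of its annotated (drug, gene)
    pairs has a computed correlation; it is a hit when any such pair has
    p < ``alpha``.
    """
    if not (0.0 < alpha <= 1.0):
        raise DataError(f"alpha must be in (0, 1], got {alpha}")
    pairs = expand_pairs(annotations)
    df = _gene_drug_frame(corr)
    keyed = df.set_index(["drug", "gene"])["p"]
    present = keyed.index.intersection(pd.MultiIndex.from_tuples(pairs))
    if len(present) == 0:
        raise DataError("no annotated pair has a computed correlation")
    sub = keyed.loc[present]
    by_drug = sub.groupby(level="drug").min()
    n_eval = len(by_drug)
    n_hit = int((by_drug < alpha).sum())
    return HitFractionResult(n_eval, n_hit, _pct1(n_hit, n_eval))


def fisher_right_tail(O: int, n_annotated: int, n_passing: int, n_total: int) -> float:
    """Right-tailed Fisher's exact test on the 2x2 margins, P(X >= O) under
    Hypergeometric(n_total, n_annotated, n_passing)."""
    return float(stats.hypergeom.sf(O - 1, n_total, n_annotated, n_passing))


def observed_expected(
    corr: CorrelationTable,
    annotated_pairs: set[tuple[str, str]],
    threshold: float,
    *,
    signed_mode: str = "signed",
    phase_scope: str = "all",
) -> ValidationResult:
    """O/E enrichment of annotated pairs above a correlation threshold."""
    if not (-1.0 <= threshold <= 1.0):
        raise DataError(f"threshold must be in [-1, 1], got {threshold}")
    df = _gene_drug_frame(corr)
    keys = set(zip(df["drug"], df["gene"]))
    unknown = annotated_pairs - keys
    if unknown:
        raise DataError(
            f"{len(unknown)} annotated pairs absent from the correlation table, "
            f"e.g. {sorted(unknown)[:3]}; restrict annotations first"
        )
    rho = df["rho"]
    passing = rho >= threshold if signed_mode == "signed" else rho.abs() >= threshold
    is_ann = pd.Series(
        [pair in annotated_pairs for pair in zip(df["drug"], df["gene"])],
        index=df.index,
    )
    n_total = len(df)
    n_pass = int(passing.sum())
    n_ann = int(is_ann.sum())
    O = int((passing & is_ann).sum())
    if n_pass == 0:
        return ValidationResult(threshold, n_ann, 0, n_total, 0, 0.0, float("nan"), 1.0, phase_scope)
    E = n_ann * (n_pass / n_total)
    return ValidationResult(
        threshold=threshold,
        n_annotated_pairs=n_ann,
        n_passing_total=n_pass,
        n_pairs_total=n_total,
        n_annotated_passing=O,
        expected_passing=E,
        oe_ratio=O / E if E > 0 else float("nan"),
        fisher_p=fisher_right_tail(O, n_ann, n_pass, n_total),
        phase_scope=phase_scope,
    )


def threshold_sweep(
    corr: CorrelationTable,
    annotated_pairs: set[tuple[str, str]],
    thresholds: Sequence[float] | None = None,
    *,
    signed_mode: str = "signed",
) -> list[ValidationResult]:
    """One O/E result per threshold (default 0.0 to 0.7 in steps of 0.05)."""
    if thresholds is None:
        thresholds = [round(0.05 * i, 2) for i in range(15)]
    return [
        observed_expected(corr, annotated_pairs, t, signed_mode=signed_mode)
        for t in thresholds
    ]


def phase_stratified(
    annotations: Sequence[TargetAnnotation],
    corr: CorrelationTable,
    threshold: float,
    phase: str,
    *,
    signed_mode: str = "signed",
) -> ValidationResult:
    """O/E restricted to drugs of one clinical phase.

    Only the annotated set is restricted; the passing universe (all computed
    gene-drug pairs) is unchanged.
    """
    sub = [a for a in annotations if a.clinical_phase == phase]
    if not sub:
        raise DataError(f"no drugs with clinical phase {phase!r}")
    pairs = expand_pairs(sub)
    df = _gene_drug_frame(corr)
    keys = set(zip(df["drug"], df["gene"]))
    pairs &= keys  # pairs without scores cannot pass or be counted
    if not pairs:
        raise DataError(f"no annotated pair of phase {phase!r} has a computed correlation")
    return observed_expected(
        corr, pairs, threshold, signed_mode=signed_mode, phase_scope=phase
    )


def results_frame(results: Iterable[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
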