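"""Synthetic joint screens, annotations, signatures and chemistry.

The generator plants known gene-drug links in a Gaussian latent-factor model
so that every downstream module can be exercised against ground truth:

* each planted link (g, d) carries its own latent viability factor over the
  cell-line panel, ``f ~ N(0, 1)`` per cell line, representing the shared
  mechanism; the gene row is ``g = f + eps`` and the drug row
  ``d = a*f + eps'`` with independent ``eps ~ N(0, sigma^2)`` noise and
  effect ``a`` in (0, 1];
* unlinked rows are independent noise with matching marginal variance.

Factors are independent across links, so each planted drug is correlated
with its own gene only — the rank-1 recovery checks are well-posed.

The expected Pearson correlation of a planted pair has the closed form

    rho = a / sqrt((1 + sigma^2) * (a^2 + sigma^2))

which the test suite uses as an oracle.  Drug-matrix entries are masked
missing completely at random at rate ``missing_frac`` (informative
missingness is out of scope).  Lineage labels are assigned round-robin from
a fixed 10-label list.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .io import (
    ChemTable,
    DependencyMatrix,
    DRUG_RESPONSE,
    GENE_EFFECT,
    SignatureMatrix,
    TargetAnnotation,
)

LINEAGES = (
    "myeloma",
    "leukemia",
    "neuroblastoma",
    "skin",
    "lung",
    "breast",
    "colon",
    "ovary",
    "pancreas",
    "CNS",
)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    links: (gene_id, drug_id, effect a) triples;
    lineage_map: cell_line_id -> lineage;
    signature_sets: drug_id -> planted perturbed gene set (shift delta);
    chem_pairs: (drug_id, drug_id, expected_high_similarity) triples.
    """

    links: list[tuple[str, str, float]] = field(default_factory=list)
    lineage_map: dict[str, str] = field(default_factory=dict)
    signature_sets: dict[str, list[str]] = field(default_factory=dict)
    signature_shift: float = 0.0
    chem_pairs: list[tuple[str, str, bool]] = field(default_factory=list)

    def linked_drug(self, gene: str) -> str | None:
        for g, d, _ in self.links:
            if g == gene:
                return d
        return None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "links": [list(t) for t in self.links],
            "lineage_map": self.lineage_map,
            "signature_sets": self.signature_sets,
            "signature_shift": self.signature_shift,
            "chem_pairs": [list(t) for t in self.chem_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return PlantedTruth(
            links=[tuple(t) for t in d["links"]],
            lineage_map=d["lineage_map"],
            signature_sets={k: list(v) for k, v in d["signature_sets"].items()},
            signature_shift=d.get("signature_shift", 0.0),
            chem_pairs=[(a, b, bool(f)) for a, b, f in d["chem_pairs"]],
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_screens(
    n_genes: int,
    n_drugs: int,
    n_cells: int,
    n_links: int,
    effect: float = 0.6,
    noise: float = 0.6,
    missing_frac: float = 0.0,
    seed: int = 0,
    lineage_effect: dict[str, float] | None = None,
) -> tuple[DependencyMatrix, DependencyMatrix, pd.Series, PlantedTruth]:
    """Generate paired gene-effect and drug-response screens with planted links.

    Link ``i`` connects gene ``G{i}`` to drug ``D{i}`` with effect ``a``.
    ``lineage_effect`` optionally scales ``a`` per lineage (default off).
    Requires ``n_cells >= 30`` (correlations over fewer lines are not the
    regime the generator emulates) and ``missing_frac`` in [0, 0.5).
    """
    if n_cells < 30:
        raise DataError(f"n_cells must be >= 30, got {n_cells}")
    if not (0.0 <= missing_frac < 0.5):
        raise DataError(f"missing_frac must be in [0, 0.5), got {missing_frac}")
    if n_links > min(n_genes, n_drugs):
        raise DataError(
            f"cannot plant {n_links} links with {n_genes} genes and {n_drugs} drugs"
        )
    if not (0.0 < effect <= 1.0):
        raise DataError(f"planted effect must be in (0, 1], got {effect}")

    rng = np.random.default_rng(seed)
    genes = _ids("G", n_genes)
    drugs = _ids("D", n_drugs)
    cells = _ids("CL", n_cells)
    lineage_map = {c: LINEAGES[i % len(LINEAGES)] for i, c in enumerate(cells)}
    meta = pd.Series({c: lineage_map[c] for c in cells}, name="lineage")

    a_scale = np.full(n_cells, effect)
    if lineage_effect:
        for i, c in enumerate(cells):
            a_scale[i] *= lineage_effect.get(lineage_map[c], 1.0)

    sigma = noise
    # marginal variances match planted rows so linked and unlinked rows are
    # indistinguishable by scale alone
    gene_sd = np.sqrt(1.0 + sigma**2)
    drug_sd = np.sqrt(effect**2 + sigma**2)

    G = rng.standard_normal((n_genes, n_cells)) * gene_sd
    D = rng.standard_normal((n_drugs, n_cells)) * drug_sd
    links: list[tuple[str, str, float]] = []
    for i in range(n_links):
        f = rng.standard_normal(n_cells)  # this link's latent mechanism
        G[i] = f + rng.standard_normal(n_cells) * sigma
        D[i] = a_scale * f + rng.standard_normal(n_cells) * sigma
        links.append((genes[i], drugs[i], effect))

    if missing_frac > 0:
        mask = rng.random((n_drugs, n_cells)) < missing_frac
        D = np.where(mask, np.nan, D)

    gene_m = DependencyMatrix(GENE_EFFECT, pd.DataFrame(G, index=genes, columns=cells))
    drug_m = DependencyMatrix(DRUG_RESPONSE, pd.DataFrame(D, index=drugs, columns=cells))
    truth = PlantedTruth(links=links, lineage_map=lineage_map)
    return gene_m, drug_m, meta, truth


def planted_annotations(truth: PlantedTruth, phase: str = "Planted") -> list[TargetAnnotation]:
    """Turn planted links into a drug->target annotation list."""
    by_drug: dict[str, set[str]] = {}
    for g, d, _ in truth.links:
        by_drug.setdefault(d, set()).add(g)
    return [
        TargetAnnotation(d, frozenset(gs), phase) for d, gs in sorted(by_drug.items())
    ]


def expected_planted_rho(effect: float, noise: float) -> float:
    """Closed-form Pearson correlation of a planted pair under the model."""
    return effect / np.sqrt((1.0 + noise**2) * (effect**2 + noise**2))


def generate_signatures(
    n_genes: int,
    n_perturbagens: int,
    planted: dict[str, list[str]] | None = None,
    shift: float = 3.0,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[SignatureMatrix, PlantedTruth]:
    """Generate a genes x perturbagens z-score signature matrix.

    Background entries are N(0, 1); for each planted perturbagen, its planted
    genes are shifted by ``-shift`` (knock-down-like down-regulation).
    ``planted`` maps perturbagen IDs to gene-ID lists drawn from the
    generated genes.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids if gene_ids is not None else _ids("G", n_genes)
    if len(genes) != n_genes:
        raise DataError("gene_ids length must equal n_genes")
    perts = _ids("P", n_perturbagens)
    Z = rng.standard_normal((n_genes, n_perturbagens))
    gidx = {g: i for i, g in enumerate(genes)}
    planted = planted or {}
    for pert, gene_set in planted.items():
        if pert not in perts:
            raise DataError(f"planted perturbagen {pert!r} not among generated IDs")
        if len(gene_set) > n_genes:
            raise DataError("planted gene set larger than n_genes")
        for g in gene_set:
            if g not in gidx:
                raise DataError(f"planted gene {g!r} not among generated genes")
            Z[gidx[g], perts.index(pert)] -= shift
    sig = SignatureMatrix(z=pd.DataFrame(Z, index=genes, columns=perts))
    truth = PlantedTruth(
        signature_sets={k: list(v) for k, v in planted.items()},
        signature_shift=shift if planted else 0.0,
    )
    return sig, truth


#: fixed chemistry panel: two analogue pairs differing by one substituent
#: (acid vs methyl ester; N7-methyl vs N7-H xanthine) plus dissimilar fillers
_CHEM_PANEL: tuple[tuple[str, str], ...] = (
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("ibuprofen-methyl-ester", "CC(C)Cc1ccc(C(C)C(=O)OC)cc1"),
    ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O"),
    ("hexane", "CCCCCC"),
    ("ethanol", "CCO"),
    ("pyridine", "c1ccncc1"),
    ("cyclohexane", "C1CCCCC1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
)

_CHEM_PAIRS: tuple[tuple[str, str, bool], ...] = (
    ("ibuprofen", "ibuprofen-methyl-ester", True),
    ("caffeine", "theophylline", True),
)


def generate_chemistry(seed: int = 0) -> tuple[ChemTable, PlantedTruth]:
    """Fixed panel of valid SMILES with flagged analogue pairs.

    The panel is a deterministic fixture (``seed`` is accepted for interface
    symmetry with the other generators); each flagged analogue pair is
    expected to be mutually rank-1 under combined-fingerprint Tanimoto.
    """
    table = ChemTable(smiles=dict(_CHEM_PANEL))
    truth = PlantedTruth(chem_pairs=list(_CHEM_PAIRS))
    return table, truth
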