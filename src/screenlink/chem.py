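"""SMILES to binary fingerprints and Tanimoto similarity search.

Three fingerprint schemes are supported:

* ``maccs`` — the public 166-key MACCS substructure fingerprint (rdkit);
* ``pubchem`` — an 881-bit substructure-key fingerprint (in-house catalogue,
  see :mod:`screenlink._fp881`);
* ``combined`` — the 1047-bit concatenation, MACCS bits first, then the
  881-bit section at offset 166.

Tanimoto similarity between two fingerprints A, B of the same scheme is
|A n B| / |A u B|; two empty fingerprints score 0 by convention (affects
only degenerate molecules).  Fingerprints are represented as sets of
set-feature indices, so similarity on the combined scheme decomposes exactly
into the per-scheme shared and union counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import CapabilityError, DataError
from .io import ChemTable, _comment_header

logger = logging.getLogger(__name__)

MACCS_LENGTH = 166
PUBCHEM_LENGTH = 881
COMBINED_LENGTH = MACCS_LENGTH + PUBCHEM_LENGTH

SCHEME_LENGTHS = {
    "maccs": MACCS_LENGTH,
    "pubchem": PUBCHEM_LENGTH,
    "combined": COMBINED_LENGTH,
}


@dataclass(frozen=True)
class Fingerprint:
    drug_id: str
    scheme: str
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_LENGTHS:
            raise DataError(f"unknown fingerprint scheme {self.scheme!r}")
        n = SCHEME_LENGTHS[self.scheme]
        bad = [b for b in self.bits if not (0 <= b < n)]
        if bad:
            raise DataError(f"bit indices out of range for {self.scheme}: {sorted(bad)[:5]}")

    @property
    def length(self) -> int:
        return SCHEME_LENGTHS[self.scheme]

    @property
    def n_bits(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class SimilarityHit:
    drug_id: str
    s_tanimoto: float
    n_shared: int
    n_query_bits: int
    n_hit_bits: int


def _require_rdkit():
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is a hard dependency
        raise CapabilityError(
            "the chemistry backend (rdkit) is not installed; SMILES parsing and "
            "fingerprint computation are unavailable"
        ) from exc
    return Chem


def parse_smiles(smiles: str):
    """Parse a SMILES string; raise :class:`DataError` with diagnostics."""
    Chem = _require_rdkit()
    from rdkit import rdBase

    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    Chem = _require_rdkit()
    return Chem.MolToSmiles(parse_smiles(smiles))


def _maccs_bits(mol) -> frozenset[int]:
    from rdkit.Chem import MACCSkeys

    fp = MACCSkeys.GenMACCSKeys(mol)
    # rdkit emits a 167-long vector whose bit 0 is unused; keys 1..166 map
    # to indices 0..165
    return frozenset(b - 1 for b in fp.GetOnBits() if b >= 1)


def smiles_to_fingerprint(
    smiles: str, scheme: str = "combined", drug_id: str = "query"
) -> Fingerprint:
    """Deterministic binary fingerprint of a molecule under the named scheme."""
    if scheme not in SCHEME_LENGTHS:
        raise DataError(f"unknown fingerprint scheme {scheme!r}; choose from {sorted(SCHEME_LENGTHS)}")
    mol = parse_smiles(smiles)
    if scheme == "maccs":
        bits = _maccs_bits(mol)
    elif scheme == "pubchem":
        from . import _fp881

        bits = _fp881.compute_bits(mol)
    else:
        from . import _fp881

        bits = _maccs_bits(mol) | frozenset(
            MACCS_LENGTH + b for b in _fp881.compute_bits(mol)
        )
    return Fingerprint(drug_id=drug_id, scheme=scheme, bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B|; 0 when both fingerprints are empty."""
    if a.scheme != b.scheme:
        raise DataError(f"scheme mismatch: {a.scheme} vs {b.scheme}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def fingerprint_library(table: ChemTable, scheme: str = "combined") -> dict[str, Fingerprint]:
    """Fingerprint every parseable library member; log rejects."""
    out: dict[str, Fingerprint] = {}
    for drug, smi in table.items():
        try:
            out[drug] = smiles_to_fingerprint(smi, scheme, drug_id=drug)
        except DataError as exc:
            logger.warning("skipping %s: %s", drug, exc)
    if not out:
        raise DataError("no valid SMILES in the chemistry library")
    return out


def search_similar(
    query_smiles: str,
    library: ChemTable | dict[str, Fingerprint],
    scheme: str = "combined",
    top_k: int = 10,
) -> list[SimilarityHit]:
    """Rank library drugs by Tanimoto similarity to a query compound.

    Hits are sorted by similarity descending, ties broken lexicographically
    by drug ID; ``top_k`` beyond the library size returns the full ranking.
    """
    query = smiles_to_fingerprint(query_smiles, scheme)
    if isinstance(library, ChemTable):
        fps = fingerprint_library(library, scheme)
    else:
        fps = library
        for fp in fps.values():
            if fp.scheme != scheme:
                raise DataError(
                    f"library fingerprint {fp.drug_id!r} has scheme {fp.scheme}, "
                    f"query uses {scheme}"
                )
    hits = [
        SimilarityHit(
            drug_id=fp.drug_id,
            s_tanimoto=tanimoto(query, fp),
            n_shared=len(query.bits & fp.bits),
            n_query_bits=len(query.bits),
            n_hit_bits=len(fp.bits),
        )
        for fp in fps.values()
    ]
    hits.sort(key=lambda h: (-h.s_tanimoto, h.drug_id))
    return hits[:top_k]


def write_fingerprints(fps: dict[str, Fingerprint], path: str | Path) -> None:
    schemes = {fp.scheme for fp in fps.values()}
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "fingerprints", "schemes": ",".join(sorted(schemes))}))
        fh.write("drug_id\tscheme\tbits\n")
        for drug in sorted(fps):
            fp = fps[drug]
            fh.write(f"{drug}\t{fp.scheme}\t{','.join(map(str, sorted(fp.bits)))}\n")


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    import csv

    out: dict[str, Fingerprint] = {}
    with open(path) as fh:
        rows = [r for r in fh if not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        bits = frozenset(int(b) for b in row["bits"].split(",") if b != "")
        out[row["drug_id"]] = Fingerprint(row["drug_id"], row["scheme"], bits)
    if not out:
        raise DataError(f"no fingerprints in {path}")
    return out
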