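"""In-house 881-bit substructure-key fingerprint.

A fixed, deterministic catalogue of 881 binary structural features, built
from four sections:

1. element counts (115 bits) — thresholded atom counts per element,
   e.g. ">= 4 carbons";
2. ring features (104 bits) — per ring size 3..10, presence/multiplicity of
   any / carbocyclic / aromatic / saturated / unsaturated non-aromatic /
   heteroatom-, N-, O-, S-containing rings (SSSR perception);
3. bonded element pairs (66 bits) — every unordered pair over
   {B, C, N, O, F, Si, P, S, Cl, Br, I} joined by any bond;
4. substructure patterns (596 bits) — a systematically generated SMARTS
   catalogue: two-atom bonded patterns with explicit bond orders, aromatic
   atom pairs, three-atom chains over {C, N, O, S} with single/double bonds,
   and four-atom chains over {C, N, O}.

The section layout mirrors the public 881-bit substructure-key fingerprint
design (hence the length), but the catalogue is this package's own and is
not bit-for-bit compatible with any external fingerprint.  Feature order is
frozen; the module asserts the 881 total at import.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

LENGTH = 881

# --- section 1: element count thresholds (115 bits) ---------------------

_ELEMENT_THRESHOLDS: list[tuple[str, tuple[int, ...]]] = [
    ("H", (2, 4, 8, 16, 32)),
    ("C", (2, 4, 8, 16, 32, 48)),
    ("N", (1, 2, 4, 8, 16)),
    ("O", (1, 2, 4, 8, 16, 24)),
    ("F", (1, 2, 4, 8)),
    ("P", (1, 2, 4)),
    ("S", (1, 2, 4, 8)),
    ("Cl", (1, 2, 4, 8)),
    ("Br", (1, 2, 4)),
    ("I", (1, 2)),
    ("B", (1, 2, 4)),
    ("Si", (1, 2)),
    ("Al", (1, 2)),
    ("Li", (1, 2)),
    ("Na", (1, 2)),
    ("K", (1, 2)),
    ("Rb", (1, 2)),
    ("Cs", (1, 2)),
    ("Be", (1,)),
    ("Mg", (1,)),
    ("Ca", (1,)),
    ("Sr", (1,)),
    ("Ba", (1,)),
    ("Fe", (1, 2)),
    ("Zn", (1, 2)),
    ("Cu", (1, 2)),
    ("Se", (1, 2)),
    ("Sc", (1,)), ("Ti", (1,)), ("V", (1,)), ("Cr", (1,)), ("Mn", (1,)),
    ("Co", (1,)), ("Ni", (1,)), ("Ga", (1,)), ("Ge", (1,)), ("As", (1,)),
    ("Y", (1,)), ("Zr", (1,)), ("Nb", (1,)), ("Mo", (1,)), ("Tc", (1,)),
    ("Ru", (1,)), ("Rh", (1,)), ("Pd", (1,)), ("Ag", (1,)), ("Cd", (1,)),
    ("In", (1,)), ("Sn", (1,)), ("Sb", (1,)), ("Te", (1,)),
    ("La", (1,)), ("Hf", (1,)), ("Ta", (1,)), ("W", (1,)), ("Re", (1,)),
    ("Os", (1,)), ("Ir", (1,)), ("Pt", (1,)), ("Au", (1,)), ("Hg", (1,)),
    ("Tl", (1,)), ("Pb", (1,)), ("Bi", (1,)),
    ("He", (1,)), ("Ne", (1,)), ("Ar", (1,)), ("Kr", (1,)), ("Xe", (1,)),
    ("Gd", (1,)),
]

_N_ELEMENT_BITS = sum(len(t) for _, t in _ELEMENT_THRESHOLDS)

# --- section 2: ring features (104 bits) ---------------------------------

_RING_SIZES = tuple(range(3, 11))
#: (feature key, required count)
_RING_FEATURES: tuple[tuple[str, int], ...] = (
    ("any", 1), ("any", 2),
    ("carbocycle", 1), ("carbocycle", 2),
    ("aromatic", 1), ("aromatic", 2),
    ("saturated", 1),
    ("unsaturated_nonaromatic", 1),
    ("heterocycle", 1),
    ("n_ring", 1), ("n_ring", 2),
    ("o_ring", 1),
    ("s_ring", 1),
)
_N_RING_BITS = len(_RING_SIZES) * len(_RING_FEATURES)

# --- section 3: bonded element pairs (66 bits) ---------------------------

_PAIR_ELEMENTS = ("B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")
_ELEMENT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b)
    for i, a in enumerate(_PAIR_ELEMENTS)
    for b in _PAIR_ELEMENTS[i:]
)
_N_PAIR_BITS = len(_ELEMENT_PAIRS)

# --- section 4: SMARTS catalogue (596 bits) ------------------------------


def _generate_smarts() -> tuple[str, ...]:
    pats: list[str] = []
    els = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    arom = ("c", "n", "o", "s")
    for a in els:
        for b in els:
            for bond in ("-", "=", "#"):
                pats.append(f"[{a}]{bond}[{b}]")
    for a in arom:
        for b in arom:
            pats.append(f"[{a}]:[{b}]")
    chain3 = ("C", "N", "O", "S")
    for a in chain3:
        for b in chain3:
            for c in chain3:
                for b1 in ("-", "="):
                    for b2 in ("-", "="):
                        pats.append(f"[{a}]{b1}[{b}]{b2}[{c}]")
    chain4 = ("C", "N", "O")
    for a in chain4:
        for b in chain4:
            for c in chain4:
                for d in chain4:
                    pats.append(f"[{a}]-[{b}]-[{c}]-[{d}]")
    out: list[str] = []
    seen: set[str] = set()
    for p in pats:
        if p not in seen and Chem.MolFromSmarts(p) is not None:
            seen.add(p)
            out.append(p)
    return tuple(out)


@lru_cache(maxsize=1)
def _smarts_patterns() -> tuple:
    pats = _generate_smarts()
    n_expected = LENGTH - _N_ELEMENT_BITS - _N_RING_BITS - _N_PAIR_BITS
    if len(pats) != n_expected:
        raise RuntimeError(
            f"SMARTS catalogue has {len(pats)} patterns, layout needs {n_expected}"
        )
    return tuple(Chem.MolFromSmarts(p) for p in pats)


def _element_counts(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
    return counts


def _ring_profile(mol: Chem.Mol) -> dict[tuple[int, str], int]:
    """Counts of each ring feature per ring size, from SSSR atom rings."""
    prof: dict[tuple[int, str], int] = {}
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        size = len(ring)
        if size not in _RING_SIZES:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        symbols = {a.GetSymbol() for a in atoms}
        aromatic = all(a.GetIsAromatic() for a in atoms)
        ringset = set(ring)
        bonds = [
            b for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in ringset and b.GetEndAtomIdx() in ringset
        ]
        saturated = not aromatic and all(
            b.GetBondType() == Chem.BondType.SINGLE for b in bonds
        )
        feats = ["any"]
        if symbols == {"C"}:
            feats.append("carbocycle")
        else:
            feats.append("heterocycle")
        if aromatic:
            feats.append("aromatic")
        elif saturated:
            feats.append("saturated")
        else:
            feats.append("unsaturated_nonaromatic")
        if "N" in symbols:
            feats.append("n_ring")
        if "O" in symbols:
            feats.append("o_ring")
        if "S" in symbols:
            feats.append("s_ring")
        for f in feats:
            prof[(size, f)] = prof.get((size, f), 0) + 1
    return prof


def compute_bits(mol: Chem.Mol) -> frozenset[int]:
    """Set-feature indices of the 881-bit substructure-key fingerprint."""
    bits: set[int] = set()
    offset = 0

    counts = _element_counts(mol)
    i = 0
    for sym, thresholds in _ELEMENT_THRESHOLDS:
        have = counts.get(sym, 0)
        for t in thresholds:
            if have >= t:
                bits.add(offset + i)
            i += 1
    offset += _N_ELEMENT_BITS

    prof = _ring_profile(mol)
    i = 0
    for size in _RING_SIZES:
        for feat, need in _RING_FEATURES:
            if prof.get((size, feat), 0) >= need:
                bits.add(offset + i)
            i += 1
    offset += _N_RING_BITS

    pair_index = {p: i for i, p in enumerate(_ELEMENT_PAIRS)}
    for bond in mol.GetBonds():
        a = bond.GetBeginAtom().GetSymbol()
        b = bond.GetEndAtom().GetSymbol()
        key = (a, b) if (a, b) in pair_index else (b, a)
        if key in pair_index:
            bits.add(offset + pair_index[key])
    offset += _N_PAIR_BITS

    for i, pat in enumerate(_smarts_patterns()):
        if mol.HasSubstructMatch(pat):
            bits.add(offset + i)

    return frozenset(bits)


assert _N_ELEMENT_BITS == 115, _N_ELEMENT_BITS
assert _N_RING_BITS == 104, _N_RING_BITS
assert _N_PAIR_BITS == 66, _N_PAIR_BITS
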