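"""2D molecular descriptors: carbon count, TPSA and Kier flexibility.

These three descriptors span the chemical space used to select and profile
the degrader set: size (nC), polarity (TPSA) and conformational freedom
(PHI). TPSA is computed here from Ertl's fragment contributions over N/O
environments (optionally S/P); the implementation is independent of, and
tested against, RDKit's.

All functions accept an RDKit Mol or a SMILES string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

from rdkit import Chem

from .errors import StructureError, UndefinedIndexError

MolLike = Union[Chem.Mol, str]


@dataclass(frozen=True)
class Descriptor2DSet:
    nc: int
    tpsa: float
    phi: float


def _as_mol(structure: MolLike) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"SMILES {structure!r} does not parse")
    return mol


def count_carbons(structure: MolLike) -> int:
    """Number of carbon atoms in the heavy-atom graph (nC)."""
    mol = _as_mol(structure)
    return sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() == 6)


# ---------------------------------------------------------------------------
# TPSA — Ertl fragment contributions (Å² per polar-atom environment)
# ---------------------------------------------------------------------------
# Each atom environment is keyed by
#   (symbol, charge, aromatic, nH, n_single, n_double, n_triple, n_aromatic,
#    in_3_ring)
# where bond counts cover heavy-atom neighbours only. Environments absent
# from the table fall back to Ertl's linear approximation in degree and
# hydrogen count.

_N = "N"
_O = "O"
_S = "S"
_P = "P"

_TPSA_CONTRIB: dict[tuple, float] = {
    # nitrogen, neutral, non-aromatic
    (_N, 0, False, 0, 3, 0, 0, 0, False): 3.24,
    (_N, 0, False, 0, 3, 0, 0, 0, True): 3.01,
    (_N, 0, False, 0, 1, 1, 0, 0, False): 12.36,
    (_N, 0, False, 0, 0, 0, 1, 0, False): 23.79,
    (_N, 0, False, 0, 1, 2, 0, 0, False): 11.68,
    (_N, 0, False, 0, 0, 1, 1, 0, False): 13.60,
    (_N, 0, False, 1, 2, 0, 0, 0, False): 12.03,
    (_N, 0, False, 1, 2, 0, 0, 0, True): 21.94,
    (_N, 0, False, 1, 0, 1, 0, 0, False): 23.85,
    (_N, 0, False, 2, 1, 0, 0, 0, False): 26.02,
    # nitrogen, +1, non-aromatic
    (_N, 1, False, 0, 4, 0, 0, 0, False): 0.00,
    (_N, 1, False, 0, 2, 1, 0, 0, False): 3.01,
    (_N, 1, False, 0, 1, 0, 1, 0, False): 4.36,
    (_N, 1, False, 1, 3, 0, 0, 0, False): 4.44,
    (_N, 1, False, 1, 1, 1, 0, 0, False): 13.97,
    (_N, 1, False, 2, 2, 0, 0, 0, False): 16.61,
    (_N, 1, False, 2, 0, 1, 0, 0, False): 25.59,
    (_N, 1, False, 3, 1, 0, 0, 0, False): 27.64,
    # nitrogen, aromatic
    (_N, 0, True, 0, 0, 0, 0, 2, False): 12.89,
    (_N, 0, True, 0, 0, 0, 0, 3, False): 4.41,
    (_N, 0, True, 0, 1, 0, 0, 2, False): 4.93,
    (_N, 0, True, 0, 0, 1, 0, 2, False): 8.39,
    (_N, 0, True, 1, 0, 0, 0, 2, False): 15.79,
    (_N, 1, True, 0, 0, 0, 0, 3, False): 4.10,
    (_N, 1, True, 0, 1, 0, 0, 2, False): 3.88,
    (_N, 1, True, 1, 0, 0, 0, 2, False): 14.14,
    # oxygen
    (_O, 0, False, 0, 2, 0, 0, 0, False): 9.23,
    (_O, 0, False, 0, 2, 0, 0, 0, True): 12.53,
    (_O, 0, False, 0, 0, 1, 0, 0, False): 17.07,
    (_O, 0, False, 1, 1, 0, 0, 0, False): 20.23,
    (_O, -1, False, 0, 1, 0, 0, 0, False): 23.06,
    (_O, 0, True, 0, 0, 0, 0, 2, False): 13.14,
    # sulfur (opt-in)
    (_S, 0, False, 0, 2, 0, 0, 0, False): 25.30,
    (_S, 0, False, 0, 0, 1, 0, 0, False): 32.09,
    (_S, 0, False, 0, 2, 1, 0, 0, False): 19.21,
    (_S, 0, False, 0, 2, 2, 0, 0, False): 8.38,
    (_S, 0, False, 1, 1, 0, 0, 0, False): 38.80,
    (_S, 0, True, 0, 0, 0, 0, 2, False): 28.24,
    (_S, 0, True, 0, 0, 1, 0, 2, False): 21.70,
    # phosphorus (opt-in)
    (_P, 0, False, 0, 3, 0, 0, 0, False): 13.59,
    (_P, 0, False, 0, 1, 1, 0, 0, False): 34.14,
    (_P, 0, False, 0, 3, 1, 0, 0, False): 9.81,
    (_P, 0, False, 1, 2, 1, 0, 0, False): 23.47,
}


def _atom_environment(atom: Chem.Atom) -> tuple:
    n_single = n_double = n_triple = n_arom = 0
    for bond in atom.GetBonds():
        if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
            n_arom += 1
        elif bond.GetBondType() == Chem.BondType.SINGLE:
            n_single += 1
        elif bond.GetBondType() == Chem.BondType.DOUBLE:
            n_double += 1
        elif bond.GetBondType() == Chem.BondType.TRIPLE:
            n_triple += 1
    return (
        atom.GetSymbol(),
        atom.GetFormalCharge(),
        atom.GetIsAromatic(),
        atom.GetTotalNumHs(),
        n_single,
        n_double,
        n_triple,
        n_arom,
        atom.IsInRingSize(3),
    )


def _fallback_contrib(symbol: str, degree: int, n_h: int) -> float:
    # Ertl's linear approximation for environments missing from the table
    if symbol == _N:
        value = 30.5 - degree * 8.2 + n_h * 1.5
    else:
        value = 28.5 - degree * 8.6 + n_h * 1.5
    return max(value, 0.0)


def compute_tpsa(structure: MolLike, *, include_s_and_p: bool = False) -> float:
    """Topological polar surface area in Å² (Ertl fragment sum).

    By default only N and O environments contribute (the common TPSA
    flavour); ``include_s_and_p=True`` adds S and P contributions. The
    result is invariant to atom order and to input kekulisation because
    environments are read from the sanitised aromatic form.
    """
    mol = _as_mol(structure)
    polar = {_N, _O} | ({_S, _P} if include_s_and_p else set())
    total = 0.0
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in polar:
            continue
        env = _atom_environment(atom)
        contrib = _TPSA_CONTRIB.get(env)
        if contrib is None:
            contrib = _fallback_contrib(symbol, atom.GetDegree() + atom.GetTotalNumHs(),
                                        atom.GetTotalNumHs())
        total += contrib
    return total


# ---------------------------------------------------------------------------
# Kier flexibility index PHI
# ---------------------------------------------------------------------------
# alpha corrections relative to sp3 carbon (covalent-radius ratios, Hall &
# Kier). Aromatic atoms count as sp2.

_KIER_ALPHA: dict[tuple[int, str], float] = {
    (6, "sp3"): 0.00, (6, "sp2"): -0.13, (6, "sp"): -0.22,
    (7, "sp3"): -0.04, (7, "sp2"): -0.20, (7, "sp"): -0.29,
    (8, "sp3"): -0.04, (8, "sp2"): -0.20,
    (9, "sp3"): -0.07, (9, "sp2"): -0.07, (9, "sp"): -0.07,
    (15, "sp3"): 0.43, (15, "sp2"): 0.30,
    (16, "sp3"): 0.35, (16, "sp2"): 0.22,
    (17, "sp3"): 0.29, (17, "sp2"): 0.29, (17, "sp"): 0.29,
    (35, "sp3"): 0.48, (35, "sp2"): 0.48, (35, "sp"): 0.48,
    (53, "sp3"): 0.73, (53, "sp2"): 0.73, (53, "sp"): 0.73,
}

_HYB_NAME = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def _hall_kier_alpha(mol: Chem.Mol) -> float:
    alpha = 0.0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 6 and atom.GetHybridization() == Chem.HybridizationType.SP3:
            continue
        hyb = "sp2" if atom.GetIsAromatic() else _HYB_NAME.get(atom.GetHybridization(), "sp3")
        key = (z, hyb)
        if key in _KIER_ALPHA:
            alpha += _KIER_ALPHA[key]
        elif (z, "sp3") in _KIER_ALPHA:
            alpha += _KIER_ALPHA[(z, "sp3")]
        else:
            warnings.warn(f"no Kier alpha for element Z={z} ({hyb}); using 0.0")
    return alpha


def compute_kier_phi(structure: MolLike) -> float:
    """Kier molecular flexibility index PHI = (1ka * 2ka) / A.

    A is the heavy-atom count, 1P the heavy-atom bond count and 2P the
    number of two-bond paths; the kappa shape indices are alpha-modified by
    the covalent-radius corrections above. For an unbranched alkane of A
    carbons PHI equals A - 1 exactly.
    """
    mol = _as_mol(structure)
    a = mol.GetNumHeavyAtoms()
    p1 = mol.GetNumBonds()
    p2 = sum(d * (d - 1) // 2 for d in (atom.GetDegree() for atom in mol.GetAtoms()))
    if a < 3 or p2 == 0:
        raise UndefinedIndexError(
            f"flexibility index undefined: {a} heavy atoms, {p2} length-2 paths")
    alpha = _hall_kier_alpha(mol)
    kappa1 = (a + alpha) * (a + alpha - 1) ** 2 / (p1 + alpha) ** 2
    kappa2 = (a + alpha - 1) * (a + alpha - 2) ** 2 / (p2 + alpha) ** 2
    return kappa1 * kappa2 / a


def compute_descriptors(structure: MolLike, *, include_s_and_p: bool = False) -> Descriptor2DSet:
    """All three 2D descriptors for one structure."""
    mol = _as_mol(structure)
    return Descriptor2DSet(
        nc=count_carbons(mol),
        tpsa=compute_tpsa(mol, include_s_and_p=include_s_and_p),
        phi=compute_kier_phi(mol),
    )
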