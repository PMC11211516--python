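"""Molecular graph construction from SMILES.

Each drug is represented by an ``R×9`` atom feature matrix ``M`` (one row
per heavy atom) and a binary ``R×R`` adjacency matrix ``A`` (1 where a bond
of any order joins two atoms). Hydrogens are not nodes; they enter through
the total-H-count column.

Feature columns, in fixed order:

====  =======================  ==========================================
col   feature                  encoding
====  =======================  ==========================================
0     atomic number            integer Z
1     chirality                0 none, 1 CW, 2 CCW, 3 other
2     degree                   heavy-atom neighbor count
3     formal charge            signed integer
4     total hydrogen count     implicit + explicit H
5     radical electrons        count of unpaired electrons
6     hybridization            0 s, 1 sp, 2 sp², 3 sp³, 4 sp³d, 5 sp³d², 6 other
7     aromaticity              {0, 1}
8     in-ring                  {0, 1}
====  =======================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "DrugGraph",
    "atom_features",
    "adjacency",
    "build_drug_graph",
    "NUM_ATOM_FEATURES",
]

NUM_ATOM_FEATURES = 9

_CHIRALITY_CODES = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}
_HYBRIDIZATION_CODES = {
    Chem.HybridizationType.S: 0,
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
    Chem.HybridizationType.SP3D: 4,
    Chem.HybridizationType.SP3D2: 5,
}


@dataclass(frozen=True)
class DrugGraph:
    """Atom feature matrix plus binary adjacency for one molecule."""

    drug_id: str
    features_M: np.ndarray
    adjacency_A: np.ndarray

    def __post_init__(self):
        M, A = self.features_M, self.adjacency_A
        if M.ndim != 2 or M.shape[1] != NUM_ATOM_FEATURES:
            raise ValueError(f"feature matrix must be R×{NUM_ATOM_FEATURES}, got {M.shape}")
        R = M.shape[0]
        if A.shape != (R, R):
            raise ValueError(f"adjacency must be {R}×{R}, got {A.shape}")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        if not np.all(np.isfinite(M)):
            raise ValueError("atom features must be finite")

    @property
    def atom_count_R(self) -> int:
        return self.features_M.shape[0]


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"SMILES describes an empty molecule: {smiles!r}")
    return mol


def _atom_row(atom: Chem.Atom) -> list[float]:
    return [
        atom.GetAtomicNum(),
        _CHIRALITY_CODES.get(atom.GetChiralTag(), 3),
        atom.GetDegree(),  # heavy-atom neighbor count (implicit Hs excluded)
        atom.GetFormalCharge(),
        atom.GetTotalNumHs(),
        atom.GetNumRadicalElectrons(),
        _HYBRIDIZATION_CODES.get(atom.GetHybridization(), 6),
        1.0 if atom.GetIsAromatic() else 0.0,
        1.0 if atom.IsInRing() else 0.0,
    ]


def atom_features(smiles: str) -> np.ndarray:
    """R×9 atom feature matrix in the parser's atom order."""
    mol = _parse(smiles)
    return np.array([_atom_row(a) for a in mol.GetAtoms()], dtype=np.float64)


def adjacency(smiles: str) -> np.ndarray:
    """Binary R×R adjacency; 1 wherever any-order bond joins two heavy atoms."""
    mol = _parse(smiles)
    R = mol.GetNumAtoms()
    A = np.zeros((R, R), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return A


def build_drug_graph(drug_id: str, smiles: str) -> DrugGraph:
    """Parse once and assemble a consistent DrugGraph (shared atom order)."""
    mol = _parse(smiles)
    M = np.array([_atom_row(a) for a in mol.GetAtoms()], dtype=np.float64)
    R = mol.GetNumAtoms()
    A = np.zeros((R, R), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return DrugGraph(drug_id=drug_id, features_M=M, adjacency_A=A)
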