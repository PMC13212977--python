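"""SMILES to featurized atom-bond graph conversion for the drug encoder.

Molecules are parsed with RDKit (implicit hydrogens, fragments kept).  Atoms
carry an 85-dimensional feature vector and each chemical bond is stored as
two directed edges carrying a 10-dimensional feature vector.  The exact
feature layout is declarative (`FeatureScheme`): ordered one-hot blocks plus
scalar slots, shipped with a default covering atom/bond types, degree,
formal charge, hybridization, chirality, aromaticity, ring membership and
scaled atomic mass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "FeatureScheme",
    "DEFAULT_SCHEME",
    "DrugGraph",
    "featurize_drug",
    "featurize_table",
    "morgan_fingerprint",
]

# 49 elements + "unknown" slot = 50; organic subset first, then common hetero/metals
_ATOM_TYPES = [
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "Na", "K", "Li", "Ca", "Mg", "Zn", "Fe", "Cu",
    "Mn", "Co", "Ni", "Cr", "Mo", "V", "Ti", "Al", "Ga", "Ge",
    "As", "Sb", "Sn", "Pb", "Bi", "Te", "Cd", "Hg", "Ag", "Au",
    "Pt", "Pd", "Ru", "Rh", "W", "Zr", "Ba", "Sr", "H",
]

_HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2"]
_CHIRAL_TAGS = ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW", "CHI_OTHER"]
_BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
_BOND_STEREO = ["STEREONONE", "STEREOZ", "STEREOE", "STEREO_OTHER"]


def _one_hot(value, vocab: list, unknown_last: bool = True) -> list[float]:
    vec = [0.0] * len(vocab)
    try:
        vec[vocab.index(value)] = 1.0
    except ValueError:
        if unknown_last:
            vec[-1] = 1.0
    return vec


@dataclass
class FeatureScheme:
    """Declarative atom/bond feature layout.

    Widths are derived from the vocabularies; the shipped default sums to
    exactly (85, 10).  Alternative widths are permitted but flagged with a
    warning, because downstream model configs assume the defaults.
    """

    atom_types: list[str] = field(default_factory=lambda: list(_ATOM_TYPES))
    max_degree: int = 10                       # one-hot 0..10 -> 11 slots
    formal_charges: list[int] = field(default_factory=lambda: [-2, -1, 0, 1, 2])  # +other -> 6
    hybridizations: list[str] = field(default_factory=lambda: list(_HYBRIDIZATIONS))
    chiral_tags: list[str] = field(default_factory=lambda: list(_CHIRAL_TAGS))
    num_hs: int = 4                            # one-hot 0..4 -> 5 slots
    include_aromatic: bool = True
    include_ring: bool = True
    include_mass: bool = True
    mass_scale: float = 0.01
    bond_types: list[str] = field(default_factory=lambda: list(_BOND_TYPES))
    bond_stereo: list[str] = field(default_factory=lambda: list(_BOND_STEREO))

    @property
    def atom_width(self) -> int:
        return (
            (len(self.atom_types) + 1)
            + (self.max_degree + 1)
            + (len(self.formal_charges) + 1)
            + len(self.hybridizations)
            + len(self.chiral_tags)
            + (self.num_hs + 1)
            + int(self.include_aromatic)
            + int(self.include_ring)
            + int(self.include_mass)
        )

    @property
    def bond_width(self) -> int:
        # bond type one-hot + conjugation + ring + stereo one-hot
        return len(self.bond_types) + 2 + len(self.bond_stereo)

    def __post_init__(self) -> None:
        if (self.atom_width, self.bond_width) != (85, 10):
            warnings.warn(
                f"non-default feature widths ({self.atom_width}, {self.bond_width})",
                stacklevel=2,
            )

    def atom_vector(self, atom: Chem.Atom) -> list[float]:
        vec = _one_hot(atom.GetSymbol(), [*self.atom_types, "<unk>"])
        vec += _one_hot(min(atom.GetDegree(), self.max_degree), list(range(self.max_degree + 1)))
        vec += _one_hot(atom.GetFormalCharge(), [*self.formal_charges, "<unk>"])
        vec += _one_hot(str(atom.GetHybridization()), self.hybridizations, unknown_last=False)
        tag = str(atom.GetChiralTag())
        if tag not in self.chiral_tags:
            tag = self.chiral_tags[-1]
        vec += _one_hot(tag, self.chiral_tags)
        vec += _one_hot(min(atom.GetTotalNumHs(), self.num_hs), list(range(self.num_hs + 1)))
        if self.include_aromatic:
            vec.append(float(atom.GetIsAromatic()))
        if self.include_ring:
            vec.append(float(atom.IsInRing()))
        if self.include_mass:
            vec.append(atom.GetMass() * self.mass_scale)
        return vec

    def bond_vector(self, bond: Chem.Bond) -> list[float]:
        vec = _one_hot(str(bond.GetBondType()), self.bond_types, unknown_last=False)
        vec.append(float(bond.GetIsConjugated()))
        vec.append(float(bond.IsInRing()))
        stereo = str(bond.GetStereo())
        if stereo not in self.bond_stereo:
            stereo = self.bond_stereo[-1]
        vec += _one_hot(stereo, self.bond_stereo)
        return vec

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScheme":
        return cls(**json.loads(Path(path).read_text()))


DEFAULT_SCHEME = FeatureScheme()


@dataclass
class DrugGraph:
    """Featurized molecular graph: atoms x 85 features, directed bonds x 10."""

    atom_features: np.ndarray     # (n_atoms, atom_width)
    bond_index: np.ndarray        # (2, n_directed_edges), [source; target]
    bond_features: np.ndarray     # (n_directed_edges, bond_width)
    smiles: str = ""

    def __post_init__(self) -> None:
        if self.atom_features.shape[0] < 1:
            raise ValueError("molecule must have at least one atom")
        n = self.atom_features.shape[0]
        if self.bond_index.size and (self.bond_index.min() < 0 or self.bond_index.max() >= n):
            raise ValueError("bond index out of range")
        if self.bond_features.shape[0] != self.bond_index.shape[1]:
            raise ValueError("bond features must align with bond index")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_index.shape[1] // 2


def featurize_drug(smiles: str, scheme: FeatureScheme = DEFAULT_SCHEME) -> DrugGraph:
    """Parse a SMILES string into a featurized atom-bond graph.

    Hydrogens stay implicit; multi-fragment inputs (salts) are kept whole.
    Raises ``ValueError`` carrying the offending string on parse failure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    atom_feats = np.array([scheme.atom_vector(a) for a in mol.GetAtoms()], dtype=np.float64)
    src, dst, bond_feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        vec = scheme.bond_vector(bond)
        src += [i, j]
        dst += [j, i]
        bond_feats += [vec, vec]
    bond_index = (
        np.array([src, dst], dtype=np.int64) if src else np.zeros((2, 0), dtype=np.int64)
    )
    bond_features = (
        np.array(bond_feats, dtype=np.float64)
        if bond_feats
        else np.zeros((0, scheme.bond_width), dtype=np.float64)
    )
    return DrugGraph(atom_feats, bond_index, bond_features, smiles=smiles)


def featurize_table(
    records, scheme: FeatureScheme = DEFAULT_SCHEME
) -> tuple[dict[str, DrugGraph], dict[str, str]]:
    """Featurize a drug table; returns (graphs by drug_id, failures by drug_id).

    ``records`` is an iterable of (drug_id, smiles) pairs or a DataFrame with
    those columns.  Duplicate drug ids and an empty table are errors; if every
    record fails to parse, that is also an error.
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        pairs = list(zip(records["drug_id"].astype(str), records["smiles"].astype(str)))
    else:
        pairs = [(str(d), str(s)) for d, s in records]
    if not pairs:
        raise ValueError("empty drug table")
    ids = [d for d, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate drug_id in table")
    graphs: dict[str, DrugGraph] = {}
    failures: dict[str, str] = {}
    for drug_id, smi in pairs:
        try:
            graphs[drug_id] = featurize_drug(smi, scheme)
        except ValueError as exc:
            failures[drug_id] = str(exc)
    if not graphs:
        raise ValueError("all SMILES failed to parse")
    return graphs, failures


def morgan_fingerprint(smiles: str, bits: int = 256, radius: int = 2) -> np.ndarray:
    """Morgan circular fingerprint bit vector (RDKit)."""
    if bits not in (128, 256, 512, 1024):
        raise ValueError("bits must be one of 128, 256, 512, 1024")
    if radius not in (1, 2, 3):
        raise ValueError("radius must be 1, 2 or 3")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(bits, dtype=np.int8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr
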