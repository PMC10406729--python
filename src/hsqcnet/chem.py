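"""Supervised chemical targets: fingerprint, molecular weight, class, glycoside.

The fingerprint is a modified Morgan/ECFP scheme: circular atom environments
of radius 0, 1 and 2 are enumerated on the hydrogen-explicit molecular graph
and hash-folded into a fixed 6144-bit presence vector.  Molecular weight is
the average-isotopic weight rounded half-up to two decimals.  The glycoside
flag marks structures carrying a pyranose or furanose ring with an exocyclic
oxygen on the anomeric carbon.  Compound class labels are supplied as data
against a configurable vocabulary (e.g. natural-product superclasses); this
package does not re-derive them from structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FINGERPRINT_DIM",
    "FINGERPRINT_RADIUS",
    "ClassVocabulary",
    "MoleculeRecord",
    "morgan_fingerprint",
    "fingerprint_bit_info",
    "atom_environment_ids",
    "molecular_weight",
    "glycoside_flag",
    "build_record",
]

FINGERPRINT_DIM = 6144
FINGERPRINT_RADIUS = 2

_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_DIM
)

# Anomeric-carbon patterns: a saturated ring carbon bonded to the ring oxygen
# of a pyranose (6-ring) or furanose (5-ring) and to an exocyclic oxygen.
_GLYCOSIDE_PATTERNS = [
    Chem.MolFromSmarts("[CX4;R1]1([OX2;!R])[OX2;R1][CX4;R1][CX4;R1][CX4;R1][CX4;R1]1"),
    Chem.MolFromSmarts("[CX4;R1]1([OX2;!R])[OX2;R1][CX4;R1][CX4;R1][CX4;R1]1"),
]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    return mol


def _mol_with_hs(smiles: str) -> Chem.Mol:
    return Chem.AddHs(_mol_from_smiles(smiles))


def morgan_fingerprint(smiles: str) -> np.ndarray:
    """Binary Morgan fingerprint, radius 0-2 on the H-explicit graph.

    Returns a length-6144 uint8 presence vector.  Deterministic: any SMILES
    writing of the same molecule yields a bit-identical vector.
    """
    fp = _GENERATOR.GetFingerprint(_mol_with_hs(smiles))
    arr = np.zeros(FINGERPRINT_DIM, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def fingerprint_bit_info(smiles: str) -> tuple[np.ndarray, dict[int, tuple[tuple[int, int], ...]]]:
    """Fingerprint plus the environments behind each set bit.

    The second return value maps each set bit index to the tuple of
    ``(center_atom_index, radius)`` environments folded onto it.  Atom
    indices refer to the H-explicit molecule, which preserves the heavy-atom
    numbering of the input SMILES.
    """
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = _GENERATOR.GetFingerprint(_mol_with_hs(smiles), additionalOutput=ao)
    arr = np.zeros(FINGERPRINT_DIM, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr, dict(ao.GetBitInfoMap())


def atom_environment_ids(smiles: str, radius: int = FINGERPRINT_RADIUS) -> dict[int, int]:
    """Unfolded Morgan environment identifier per heavy atom at ``radius``.

    These are the same environment hashes the fingerprint folds into bits;
    symmetry-equivalent atoms share an identifier.  Used by the synthetic
    spectrum simulator so that identical substructures map to identical
    chemical shifts.
    """
    mol = _mol_with_hs(smiles)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    _GENERATOR.GetSparseCountFingerprint(mol, additionalOutput=ao)
    ids: dict[int, int] = {}
    best_radius: dict[int, int] = {}
    for env_id, hits in ao.GetBitInfoMap().items():
        for atom, r in hits:
            if r <= radius and r >= best_radius.get(atom, -1):
                best_radius[atom] = r
                ids[atom] = env_id
    return ids


def molecular_weight(smiles: str) -> float:
    """Average-isotopic molecular weight in daltons, rounded to 2 decimals."""
    mw = Descriptors.MolWt(_mol_from_smiles(smiles))
    return float(Decimal(repr(mw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def glycoside_flag(smiles: str) -> bool:
    """True iff the structure bears a sugar-like anomeric acetal ring."""
    mol = _mol_from_smiles(smiles)
    return any(mol.HasSubstructMatch(p) for p in _GLYCOSIDE_PATTERNS)


@dataclass(frozen=True)
class ClassVocabulary:
    """Ordered compound-class names plus the auxiliary glycoside label."""

    names: tuple[str, ...]
    glycoside_name: str = "glycoside"

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) < 2:
            raise ValueError("class vocabulary needs at least 2 names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in vocabulary") from None


@dataclass(frozen=True)
class MoleculeRecord:
    """A structure with its precomputed supervised targets."""

    id: str
    smiles: str
    fingerprint: np.ndarray
    mw: float
    class_label: int
    glycoside: bool

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        if fp.shape != (FINGERPRINT_DIM,):
            raise ValueError(f"fingerprint must have length {FINGERPRINT_DIM}")
        if not np.isin(fp, (0, 1)).all():
            raise ValueError("truth fingerprints must be binary")
        object.__setattr__(self, "fingerprint", fp)
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        if self.class_label < 0:
            raise ValueError("class label must be a nonnegative vocabulary index")


def build_record(
    id: str,
    smiles: str,
    class_label: int,
    vocabulary: ClassVocabulary | None = None,
    glycoside: bool | None = None,
) -> MoleculeRecord:
    """Assemble fingerprint, MW and glycoside flag into a record.

    ``glycoside`` overrides the substructure-derived flag when labels are
    supplied as data.
    """
    if vocabulary is not None and not 0 <= class_label < len(vocabulary):
        raise ValueError(
            f"class label {class_label} outside vocabulary of size {len(vocabulary)}"
        )
    return MoleculeRecord(
        id=id,
        smiles=smiles,
        fingerprint=morgan_fingerprint(smiles),
        mw=molecular_weight(smiles),
        class_label=class_label,
        glycoside=glycoside_flag(smiles) if glycoside is None else bool(glycoside),
    )
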