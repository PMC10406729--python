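"""Occlusion sensitivity: attribute fingerprint predictions to peaks.

Each peak is removed from the peak list in turn, the reduced spectrum is
re-rasterized and re-predicted, and the change in the 6144 fingerprint
probabilities (occluded minus full) is recorded.  Because fingerprint bits
correspond to circular atom environments of a candidate structure, the
per-bit changes can be mapped back onto atoms: each bit's delta magnitude
is shared equally among the atoms of the environment(s) that set the bit,
yielding a peaks x atoms attribution heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import FINGERPRINT_DIM, _mol_with_hs, fingerprint_bit_info
from .peaks import DEFAULT_BOUNDS, PeakList, SpectrumBounds, rasterize, remove_peak

__all__ = [
    "OcclusionMap",
    "AtomAttribution",
    "occlusion_deltas",
    "bit_atom_map",
    "atom_attribution",
]


@dataclass(frozen=True)
class OcclusionMap:
    """Signed fingerprint-probability changes per occluded peak.

    ``deltas[i]`` is prediction(without peak i) - prediction(full spectrum);
    row order follows the input peak list.  Class-probability and MW changes
    are carried alongside for inspection but are not attributed to atoms.
    """

    deltas: np.ndarray
    class_deltas: np.ndarray | None = None
    mw_deltas: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=np.float64)
        if d.ndim != 2 or d.shape[1] != FINGERPRINT_DIM:
            raise ValueError(f"deltas must be (n_peaks, {FINGERPRINT_DIM})")
        object.__setattr__(self, "deltas", d)

    @property
    def n_peaks(self) -> int:
        return self.deltas.shape[0]


@dataclass(frozen=True)
class AtomAttribution:
    """Nonnegative peaks x atoms attribution scores.

    Atom indexing follows the hydrogen-explicit molecule, which preserves
    the heavy-atom numbering of the input SMILES.
    """

    scores: np.ndarray
    n_heavy_atoms: int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", s)


def occlusion_deltas(
    model,
    pl: PeakList,
    bounds: SpectrumBounds = DEFAULT_BOUNDS,
) -> OcclusionMap:
    """Sequentially remove each peak and record the prediction changes.

    ``model`` is any fitted predictor exposing ``predict_arrays`` over a
    batch of HSQC images (normally :class:`~hsqcnet.model.HSQCNet`).
    """
    if len(pl) == 0:
        raise ValueError("cannot occlude an empty peak list")
    images = [rasterize(pl, bounds)]
    for i in range(len(pl)):
        images.append(rasterize(remove_peak(pl, i), bounds))
    out = model.predict_arrays(images)
    fp = np.asarray(out["fingerprint"], dtype=np.float64)
    deltas = fp[1:] - fp[0]
    class_deltas = mw_deltas = None
    if "class_probs" in out:
        cp = np.asarray(out["class_probs"], dtype=np.float64)
        class_deltas = cp[1:] - cp[0]
    if "mw" in out:
        mw = np.asarray(out["mw"], dtype=np.float64)
        mw_deltas = mw[1:] - mw[0]
    return OcclusionMap(deltas=deltas, class_deltas=class_deltas, mw_deltas=mw_deltas)


def bit_atom_map(smiles: str) -> dict[int, frozenset[int]]:
    """Map each set fingerprint bit to the heavy atoms of its environment(s).

    For every circular environment that set a bit, the member atoms (the
    center plus all atoms within its radius) are collected; hydrogens are
    folded onto their attached heavy atom, so attribution lands on the
    heavy-atom skeleton.  A bit hit by several environments maps to their
    union.  Heavy-atom indices follow the input SMILES ordering.
    """
    _, bit_info = fingerprint_bit_info(smiles)
    mol = _mol_with_hs(smiles)

    def _heavy(idx: int) -> int:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() > 1:
            return idx
        nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        return nbrs[0] if nbrs else idx  # bare H2 has no heavy neighbor

    mapping: dict[int, frozenset[int]] = {}
    for bit, envs in bit_info.items():
        atoms: set[int] = set()
        for center, radius in envs:
            atoms.add(_heavy(center))
            if radius == 0:
                continue
            for b in Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center):
                bond = mol.GetBondWithIdx(b)
                atoms.add(_heavy(bond.GetBeginAtomIdx()))
                atoms.add(_heavy(bond.GetEndAtomIdx()))
        mapping[bit] = frozenset(atoms)
    return mapping


def atom_attribution(
    om: OcclusionMap,
    bam: dict[int, frozenset[int]],
    n_atoms: int | None = None,
    n_heavy: int | None = None,
    signed: bool = False,
) -> AtomAttribution:
    """Share each bit's occlusion delta equally among the bit's atoms.

    ``score[i, a] = sum over bits b with a in bam[b] of |deltas[i, b]| /
    len(bam[b])``; with ``signed=True`` the raw delta is shared instead of
    its magnitude (scores may then be negative).  The total attribution per
    peak equals the total |delta| over atom-mapped bits.
    """
    if n_atoms is None:
        n_atoms = max((max(a) for a in bam.values() if a), default=-1) + 1
    if n_heavy is None:
        n_heavy = n_atoms
    scores = np.zeros((om.n_peaks, n_atoms), dtype=np.float64)
    values = om.deltas if signed else np.abs(om.deltas)
    for bit, atoms in bam.items():
        if not atoms:
            continue
        share = values[:, bit] / len(atoms)
        for a in atoms:
            scores[:, a] += share
    return AtomAttribution(scores=scores, n_heavy_atoms=n_heavy)
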