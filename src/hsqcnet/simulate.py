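"""Synthetic (structure, HSQC peak list) pairs for training and testing.

Real HSQC corpora pair natural-product structures with sparse 2D spectra in
which every proton-bearing carbon contributes one cross-peak whose position
is governed by its local chemical environment.  The simulator reproduces
exactly that statistical structure without any spectrum-prediction
software:

* structures are assembled from a small fragment grammar (aromatic rings,
  aliphatic rings and chains, N-heterocycles, acyl chains, an optional
  pyranose unit) spanning four synthetic compound classes and a
  glycoside/non-glycoside mix;
* each hydrogen-bearing carbon emits one peak; its base (1H, 13C) position
  is a deterministic hash of the carbon's radius-2 Morgan environment into
  the textbook shift window of its chemical category (aromatic CH, anomeric
  O-CH-O, oxygenated CH, carbonyl-adjacent CH, aldehyde, olefinic,
  aliphatic CH/CH2/CH3), so identical substructures always produce
  identical peaks — the regularity a spectrum-reading network exploits;
* Gaussian ppm noise (default sd 0.02 ppm 1H / 0.4 ppm 13C, under half a
  pixel of the 128x128 raster) emulates solvent and referencing scatter;
* multiplicity-edited phase follows attached-proton count: CH2 negative,
  CH and CH3 positive; quaternary carbons are silent.

Because the simulator keys shifts on the same environment identifiers the
fingerprint folds into bits, the fingerprint-from-spectrum task is solvable
in principle from these data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem import (
    ClassVocabulary,
    MoleculeRecord,
    atom_environment_ids,
    build_record,
    molecular_weight,
)
from .peaks import (
    DEFAULT_BOUNDS,
    Peak,
    PeakList,
    Phase,
    parse_peak_table,
    serialize_peak_table,
)

__all__ = [
    "DEFAULT_SHIFT_WINDOWS",
    "SYNTHETIC_VOCABULARY",
    "SimulatorConfig",
    "SyntheticExample",
    "generate_structures",
    "simulate_hsqc",
    "make_dataset",
    "load_dataset",
]

#: Textbook 1H/13C shift windows per carbon category: (h_lo, h_hi, c_lo, c_hi).
DEFAULT_SHIFT_WINDOWS: dict[str, tuple[float, float, float, float]] = {
    "aldehyde": (9.2, 10.1, 185.0, 208.0),
    "aromatic": (6.0, 8.6, 100.0, 150.0),
    "olefinic": (4.9, 6.8, 105.0, 145.0),
    "anomeric": (4.0, 5.6, 88.0, 112.0),
    "o_ch": (3.1, 4.6, 55.0, 90.0),
    "n_ch": (2.4, 3.8, 40.0, 62.0),
    "carbonyl_adjacent": (1.9, 3.3, 25.0, 52.0),
    "ch3": (0.5, 2.0, 5.0, 32.0),
    "ch2": (0.9, 2.6, 18.0, 48.0),
    "ch": (1.1, 2.9, 25.0, 58.0),
}

SYNTHETIC_VOCABULARY = ClassVocabulary(
    names=("aromatic_polyketide", "terpenoid", "alkaloid", "fatty_acyl")
)


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions of the synthetic corpus."""

    n_molecules: int = 300
    noise_sd_h: float = 0.02
    noise_sd_c: float = 0.4
    seed: int = 0
    glycoside_fraction: float = 0.25
    shift_windows: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SHIFT_WINDOWS)
    )
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if self.noise_sd_h < 0 or self.noise_sd_c < 0:
            raise ValueError("noise standard deviations must be >= 0")
        b = DEFAULT_BOUNDS
        for name, (h0, h1, c0, c1) in self.shift_windows.items():
            if not (b.h_min <= h0 < h1 <= b.h_max and b.c_min <= c0 < c1 <= b.c_max):
                raise ValueError(f"shift window {name!r} outside the raster frame")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "n_molecules": self.n_molecules,
                "noise_sd_h": self.noise_sd_h,
                "noise_sd_c": self.noise_sd_c,
                "seed": self.seed,
                "glycoside_fraction": self.glycoside_fraction,
                "shift_windows": {k: list(v) for k, v in sorted(self.shift_windows.items())},
                "split_fractions": list(self.split_fractions),
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SyntheticExample:
    """A simulated training/evaluation pair with its provenance."""

    record: MoleculeRecord
    peaklist: PeakList
    provenance: str


# -- structure grammar ---------------------------------------------------

_SUGAR = "(OC9OC(CO)C(O)C(O)C9O)"

_SMALL = ["", "(C)", "(CC)", "(O)", "(OC)"]
_AROM_SUB = _SMALL + ["(C(C)C)", "(C=O)", "(C(=O)C)", "(CCO)"]
_ALIPH_SUB = _SMALL + ["(CO)", "(C(C)C)"]
_TAIL = ["", "C", "CC", "O", "OC", "CO", "CCO", "C(C)C"]

_TEMPLATES: dict[str, list[str]] = {
    "aromatic_polyketide": [
        "c1cc{0}cc{1}c1{2}",
        "c1cc{0}c{1}cc1C(=O){2}",
        "c1ccc2c(c1)cc{0}cc2{2}",
        "Oc1cc{0}cc{1}c1{2}",
    ],
    "terpenoid": [
        "CC1(C)CCC{0}C{1}C1{2}",
        "CC1CCC{0}CC1{2}",
        "C1CC{0}C2CCC{1}C2C1{2}",
        "CC(C)=CCC{0}C(C){2}",
    ],
    "alkaloid": [
        "CN1CCC{0}CC1{2}",
        "c1ccc2[nH]c{0}cc2c1{2}",
        "c1cc{0}ncc1{2}",
        "C1CCN{2}C1{0}",
    ],
    "fatty_acyl": [
        "CCCCC{0}CCC(=O)O{2}",
        "CCCC{0}C(=O)N{2}C",
        "CC{0}CC{1}CCC(=O)O{2}",
        "CCCCCC{0}C(O)CC(=O)O{2}",
    ],
}


def _fill_template(template: str, rng: np.random.Generator, want_sugar: bool) -> str:
    subs = _AROM_SUB if template.startswith(("c", "O")) else _ALIPH_SUB
    s0 = subs[rng.integers(len(subs))]
    s1 = subs[rng.integers(len(subs))] if "{1}" in template else ""
    tail = _TAIL[rng.integers(len(_TAIL))]
    if want_sugar:
        s0 = _SUGAR
    out = template.replace("{0}", s0).replace("{1}", s1).replace("{2}", tail)
    return out


def generate_structures(
    n: int, seed: int = 0, glycoside_fraction: float = 0.25
) -> list[tuple[str, str]]:
    """Sample ``n`` parseable (SMILES, class name) pairs from the grammar.

    Classes cycle through the four scaffold families so any n >= 4 covers
    the full vocabulary; a ``glycoside_fraction`` of molecules carry an
    O-linked pyranose.  Deterministic given ``seed``: identical calls yield
    identical lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = SYNTHETIC_VOCABULARY.names
    out: list[tuple[str, str]] = []
    while len(out) < n:
        family = names[len(out) % len(names)]
        templates = _TEMPLATES[family]
        smiles = None
        for _ in range(64):  # redraw until the filled template parses
            t = templates[rng.integers(len(templates))]
            want_sugar = bool(rng.random() < glycoside_fraction) and "{0}" in t
            cand = _fill_template(t, rng, want_sugar)
            mol = Chem.MolFromSmiles(cand)
            if mol is None:
                continue
            if not 50.0 < molecular_weight(cand) < 1500.0:
                continue
            smiles = Chem.MolToSmiles(mol)
            break
        if smiles is None:  # pragma: no cover - grammar always converges
            raise RuntimeError(f"fragment grammar failed to produce a molecule for {family}")
        out.append((smiles, family))
    return out


# -- shift simulation ----------------------------------------------------

_MASK64 = (1 << 64) - 1


def _hash_unit(value: int, salt: int) -> float:
    """Deterministic hash of an integer to [0, 1) (splitmix64 finalizer)."""
    z = (value + (salt + 1) * 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return z / 2**64


def _carbon_category(atom: Chem.Atom, n_h: int) -> str:
    nbrs = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
    n_oxy = sum(1 for n in nbrs if n.GetAtomicNum() == 8)
    has_double_o = any(
        b.GetBondTypeAsDouble() == 2.0 and b.GetOtherAtom(atom).GetAtomicNum() == 8
        for b in atom.GetBonds()
    )
    if has_double_o and n_h >= 1:
        return "aldehyde"
    if atom.GetIsAromatic():
        return "aromatic"
    if str(atom.GetHybridization()) == "SP2":
        return "olefinic"
    if n_oxy >= 2:
        return "anomeric"
    if n_oxy == 1:
        return "o_ch"
    if any(n.GetAtomicNum() == 7 for n in nbrs):
        return "n_ch"
    if any(
        any(
            b.GetBondTypeAsDouble() == 2.0 and b.GetOtherAtom(n).GetAtomicNum() == 8
            for b in n.GetBonds()
        )
        for n in nbrs
        if n.GetAtomicNum() == 6
    ):
        return "carbonyl_adjacent"
    return {1: "ch", 2: "ch2", 3: "ch3"}.get(n_h, "ch")


def simulate_hsqc(
    smiles: str,
    cfg: SimulatorConfig | None = None,
    edited: bool = False,
    rng: np.random.Generator | None = None,
    source_id: str | None = None,
) -> PeakList:
    """Simulate the HSQC peak list of a structure.

    One peak per hydrogen-bearing carbon (quaternary carbons are silent),
    in atom-index order.  The noise-free position depends only on the
    carbon's radius-2 environment identifier; Gaussian noise with the
    config standard deviations is added on top.  Phase is negative iff the
    carbon bears exactly two hydrogens.
    """
    cfg = cfg or SimulatorConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    env_ids = atom_environment_ids(smiles)
    peaks: list[Peak] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        n_h = atom.GetTotalNumHs(includeNeighbors=True)
        if n_h == 0:
            continue
        category = _carbon_category(atom, n_h)
        h0, h1, c0, c1 = cfg.shift_windows[category]
        env = env_ids.get(atom.GetIdx(), atom.GetIdx())
        h = h0 + _hash_unit(env, 0) * (h1 - h0)
        c = c0 + _hash_unit(env, 1) * (c1 - c0)
        if cfg.noise_sd_h > 0:
            h += rng.normal(0.0, cfg.noise_sd_h)
        if cfg.noise_sd_c > 0:
            c += rng.normal(0.0, cfg.noise_sd_c)
        phase = Phase.NEGATIVE if n_h == 2 else Phase.POSITIVE
        peaks.append(Peak(h_shift=h, c_shift=c, phase=phase, intensity=1.0))
    return PeakList(peaks=tuple(peaks), edited=edited, source_id=source_id)


def make_dataset(
    cfg: SimulatorConfig,
    edited: bool = False,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticExample], dict[str, list[int]]]:
    """Generate the full synthetic corpus with seeded train/val/test splits.

    Returns the examples plus disjoint index splits covering all of them.
    When ``out_dir`` is given, writes ``structures.tsv``, one
    ``peaks/<id>.tsv`` per spectrum, ``splits.json`` and ``config.json``.
    """
    structures = generate_structures(
        cfg.n_molecules, seed=cfg.seed, glycoside_fraction=cfg.glycoside_fraction
    )
    noise_rng = np.random.default_rng(cfg.seed + 1)
    provenance = f"seed={cfg.seed},config={cfg.digest()}"
    examples: list[SyntheticExample] = []
    for i, (smiles, class_name) in enumerate(structures):
        mol_id = f"syn{i:05d}"
        record = build_record(
            id=mol_id,
            smiles=smiles,
            class_label=SYNTHETIC_VOCABULARY.index(class_name),
            vocabulary=SYNTHETIC_VOCABULARY,
        )
        pl = simulate_hsqc(smiles, cfg, edited=edited, rng=noise_rng, source_id=mol_id)
        examples.append(SyntheticExample(record=record, peaklist=pl, provenance=provenance))

    split_rng = np.random.default_rng(cfg.seed + 2)
    perm = split_rng.permutation(cfg.n_molecules)
    f_train, f_val, _ = cfg.split_fractions
    n_train = int(round(cfg.n_molecules * f_train))
    n_val = int(round(cfg.n_molecules * f_val))
    splits = {
        "train": sorted(int(i) for i in perm[:n_train]),
        "val": sorted(int(i) for i in perm[n_train : n_train + n_val]),
        "test": sorted(int(i) for i in perm[n_train + n_val :]),
    }

    if out_dir is not None:
        out = Path(out_dir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        rows = ["id\tsmiles\tclass\tglycoside"]
        for ex in examples:
            r = ex.record
            rows.append(
                f"{r.id}\t{r.smiles}\t{SYNTHETIC_VOCABULARY.names[r.class_label]}\t{int(r.glycoside)}"
            )
            (out / "peaks" / f"{r.id}.tsv").write_text(serialize_peak_table(ex.peaklist))
        (out / "structures.tsv").write_text("\n".join(rows) + "\n")
        (out / "splits.json").write_text(json.dumps(splits, indent=1))
        (out / "config.json").write_text(
            json.dumps(
                {
                    "n_molecules": cfg.n_molecules,
                    "noise_sd_h": cfg.noise_sd_h,
                    "noise_sd_c": cfg.noise_sd_c,
                    "seed": cfg.seed,
                    "glycoside_fraction": cfg.glycoside_fraction,
                    "edited": edited,
                    "digest": cfg.digest(),
                },
                indent=1,
            )
        )
    return examples, splits


def load_dataset(
    dataset_dir: str | Path,
) -> tuple[list[SyntheticExample], dict[str, list[int]], bool]:
    """Read a dataset directory written by :func:`make_dataset`.

    Returns (examples, splits, edited).  Records are recomputed from the
    stored SMILES, so fingerprints are bit-identical to the originals.
    """
    d = Path(dataset_dir)
    meta = json.loads((d / "config.json").read_text())
    splits = {k: list(map(int, v)) for k, v in json.loads((d / "splits.json").read_text()).items()}
    edited = bool(meta.get("edited", False))
    provenance = f"seed={meta.get('seed')},config={meta.get('digest')}"
    examples: list[SyntheticExample] = []
    lines = (d / "structures.tsv").read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        mol_id, smiles, class_name, gly = line.split("\t")
        record = build_record(
            id=mol_id,
            smiles=smiles,
            class_label=SYNTHETIC_VOCABULARY.index(class_name),
            vocabulary=SYNTHETIC_VOCABULARY,
            glycoside=bool(int(gly)),
        )
        pl = parse_peak_table(
            (d / "peaks" / f"{mol_id}.tsv").read_text(), edited=edited, source_id=mol_id
        )
        examples.append(SyntheticExample(record=record, peaklist=pl, provenance=provenance))
    return examples, splits, edited
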