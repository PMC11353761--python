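"""Chemical input preparation: 3D structures with van der Waals radii.

Molecules enter the pipeline either as prepared 3D structure files
(SDF/MOL, XYZ, PDB) or as SMILES strings that are embedded into a single
3D conformer with RDKit's ETKDG and relaxed with the Universal Force
Field.  Every atom is assigned an element-specific, environment-independent
van der Waals radius from a packaged table (hydrogen pinned at 1.1 Å);
these radii are the ``a_i`` parameters of the exponential density field
used for surface generation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "MoleculeStructure",
    "RadiusTable",
    "UnknownElementError",
    "SmilesParseError",
    "EmbeddingError",
    "load_structure",
    "embed_from_smiles",
    "generate_conformers",
    "conformer_entropy_spread",
]


class UnknownElementError(KeyError):
    """An element symbol is missing from the radius table."""


class SmilesParseError(ValueError):
    """The SMILES string could not be parsed."""


class EmbeddingError(RuntimeError):
    """RDKit failed to embed a 3D conformer for a valid molecule."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, position (Å) and van der Waals radius (Å)."""

    element: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


@dataclass
class MoleculeStructure:
    """A single conformer of one molecule with radii assigned."""

    id: str
    atoms: list[AtomRecord]
    source: str = "file_loaded"  # or "smiles_embedded"
    conformer_index: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        pos = self.positions
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"molecule {self.id!r} has non-finite coordinates")
        if len(pos) > 1:
            # duplicate-position check; O(n^2) is fine for small molecules
            d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.any(d2 < 1e-12):
                i, j = np.unravel_index(np.argmin(d2), d2.shape)
                raise ValueError(
                    f"molecule {self.id!r}: atoms {i} and {j} are at identical positions"
                )

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)

    def translated(self, shift: Sequence[float]) -> "MoleculeStructure":
        shift = np.asarray(shift, dtype=float)
        atoms = [AtomRecord(a.element, a.position + shift, a.vdw_radius) for a in self.atoms]
        return MoleculeStructure(self.id, atoms, self.source, self.conformer_index)

    def rotated(self, rotation: np.ndarray) -> "MoleculeStructure":
        """Rigidly rotate about the geometric centre by a 3x3 rotation matrix."""
        rotation = np.asarray(rotation, dtype=float)
        centre = self.positions.mean(axis=0)
        atoms = [
            AtomRecord(a.element, centre + rotation @ (a.position - centre), a.vdw_radius)
            for a in self.atoms
        ]
        return MoleculeStructure(self.id, atoms, self.source, self.conformer_index)


@dataclass
class RadiusTable:
    """Element symbol -> van der Waals radius (Å), environment-independent."""

    radii: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not r > 0:
                raise ValueError(f"radius for {el} must be positive, got {r}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} is not in the van der Waals radius table"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.radii

    @classmethod
    def from_csv(cls, path: str | Path) -> "RadiusTable":
        radii: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                radii[row["element"].strip()] = float(row["radius_angstrom"])
        return cls(radii)

    @classmethod
    def default(cls) -> "RadiusTable":
        ref = resources.files("arealaw").joinpath("data/vdw_radii.csv")
        with resources.as_file(ref) as path:
            table = cls.from_csv(path)
        assert abs(table["H"] - 1.1) < 1e-12, "hydrogen radius must be 1.1 Å"
        return table


_DEFAULT_TABLE: RadiusTable | None = None


def default_radius_table() -> RadiusTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = RadiusTable.default()
    return _DEFAULT_TABLE


def _structure_from_elements(
    mol_id: str,
    elements: Iterable[str],
    positions: np.ndarray,
    table: RadiusTable,
    source: str,
    conformer_index: int = 0,
) -> MoleculeStructure:
    atoms = [
        AtomRecord(el, pos, table[el]) for el, pos in zip(elements, np.asarray(positions, float))
    ]
    return MoleculeStructure(mol_id, atoms, source=source, conformer_index=conformer_index)


def _parse_xyz(path: Path) -> tuple[list[str], np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first XYZ line must be an atom count") from None
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ atom line {line!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if len(elements) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(elements)}")
    return elements, np.array(coords)


def load_structure(
    path: str | Path,
    fmt: str | None = None,
    radius_table: RadiusTable | None = None,
) -> MoleculeStructure:
    """Load a prepared 3D structure (SDF/MOL, XYZ or PDB), verbatim coordinates.

    ``fmt`` defaults to the file suffix.  Radii come from ``radius_table``
    (the packaged table when omitted); an element absent from the table
    raises :class:`UnknownElementError` naming the symbol.
    """
    from rdkit import Chem

    path = Path(path)
    table = radius_table or default_radius_table()
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise ValueError(f"{path}: could not parse {fmt.upper()} file")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        positions = mol.GetConformer().GetPositions()
    elif fmt == "pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise ValueError(f"{path}: could not parse PDB file")
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        positions = mol.GetConformer().GetPositions()
    elif fmt == "xyz":
        elements, positions = _parse_xyz(path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r} (expected sdf/mol/xyz/pdb)")
    if len(elements) == 0:
        raise ValueError(f"{path}: no atoms found")
    unknown = sorted({el for el in elements if el not in table})
    if unknown:
        raise UnknownElementError(
            f"{path}: element(s) {', '.join(unknown)} not in the radius table"
        )
    return _structure_from_elements(path.stem, elements, positions, table, "file_loaded")


def _embed_rdkit(smiles: str, seed: int, num_confs: int):
    """Parse, add hydrogens, embed ``num_confs`` conformers, UFF-minimize all."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=num_confs, params=params)
    if len(ids) == 0:
        # fall back to random coordinates before giving up (tiny/odd molecules)
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=num_confs, params=params)
    if len(ids) == 0:
        raise EmbeddingError(f"3D embedding failed for valid SMILES {smiles!r}")
    _separate_fragments(mol, ids)
    energies = []
    for cid in ids:
        try:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
            ff.Minimize(maxIts=2000)
            energies.append(ff.CalcEnergy())
        except Exception:  # pragma: no cover - UFF setup rarely fails
            energies.append(np.inf)
    return mol, list(ids), energies


def _separate_fragments(mol, conf_ids, gap: float = 2.5) -> None:
    """Lay disconnected fragments (salts) side by side along x.

    Embedding can superpose fragments that share no bonds; all fragments
    still contribute to one density field, so they only need non-overlapping
    coordinates, arranged deterministically.
    """
    from rdkit import Chem

    frags = Chem.GetMolFrags(mol)
    if len(frags) < 2:
        return
    for cid in conf_ids:
        conf = mol.GetConformer(cid)
        pos = conf.GetPositions()
        cursor = None
        for frag in frags:
            idx = np.asarray(frag)
            if cursor is not None:
                shift = cursor + gap - pos[idx, 0].min()
                pos[idx, 0] += shift
            cursor = pos[idx, 0].max()
        for i, p in enumerate(pos):
            conf.SetAtomPosition(i, p.tolist())


def embed_from_smiles(
    smiles: str,
    seed: int,
    radius_table: RadiusTable | None = None,
    mol_id: str | None = None,
) -> MoleculeStructure:
    """One UFF-minimized 3D conformer from a SMILES string (explicit hydrogens)."""
    table = radius_table or default_radius_table()
    mol, ids, _ = _embed_rdkit(smiles, seed, num_confs=1)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    positions = mol.GetConformer(ids[0]).GetPositions()
    return _structure_from_elements(
        mol_id or smiles, elements, positions, table, "smiles_embedded"
    )


def heavy_atom_rmsd(mol, conf_a: int, conf_b: int) -> float:
    """Heavy-atom RMSD between two conformers after optimal superposition."""
    from rdkit import Chem
    from rdkit.Chem import rdMolAlign

    heavy = Chem.RemoveHs(mol)
    if heavy.GetNumAtoms() == 0:  # hydrogen-only species
        heavy = mol
    return rdMolAlign.GetBestRMS(heavy, heavy, prbId=conf_a, refId=conf_b)


def generate_conformers(
    smiles: str,
    max_n: int,
    rmsd_min: float = 0.5,
    seed: int = 2024,
    radius_table: RadiusTable | None = None,
    mol_id: str | None = None,
) -> list[MoleculeStructure]:
    """Up to ``max_n`` UFF-minimized conformers, pairwise heavy-atom RMSD >= ``rmsd_min``.

    Conformers are considered in order of increasing UFF energy; a conformer
    is retained only if it superposes at least ``rmsd_min`` Å (heavy atoms,
    optimal alignment) away from every previously retained one, so the
    returned count may fall below ``max_n`` for rigid molecules.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if rmsd_min < 0:
        raise ValueError("rmsd_min must be >= 0")
    table = radius_table or default_radius_table()
    mol, ids, energies = _embed_rdkit(smiles, seed, num_confs=max_n)
    order = [cid for _, cid in sorted(zip(energies, ids))]
    kept: list[int] = []
    for cid in order:
        if rmsd_min > 0 and any(heavy_atom_rmsd(mol, cid, ref) < rmsd_min for ref in kept):
            continue
        kept.append(cid)
        if len(kept) == max_n:
            break
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    structures = []
    for k, cid in enumerate(kept):
        structures.append(
            _structure_from_elements(
                mol_id or smiles,
                elements,
                mol.GetConformer(cid).GetPositions(),
                table,
                "smiles_embedded",
                conformer_index=k,
            )
        )
    logger.info(
        "generate_conformers(%s): %d embedded, %d retained at rmsd_min=%.2f Å",
        smiles, len(ids), len(kept), rmsd_min,
    )
    return structures


def conformer_entropy_spread(entropies: Sequence[float]) -> float:
    """Percent spread 100*(max-min)/mean of per-conformer entropies (J/mol·K)."""
    values = np.asarray(entropies, dtype=float)
    if values.size == 0:
        raise ValueError("entropy list is empty")
    if np.any(values <= 0):
        raise ValueError("entropies must be positive")
    return float(100.0 * (values.max() - values.min()) / values.mean())
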