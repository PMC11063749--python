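"""Structure and table I/O: receptors (PDB/mol2), ligand pose sets (SDF/mol2),
and the delimited feature table used for training and scoring.

Docked pose files are treated as the primary data carrier: every numeric SD
tag whose name starts with the configured prefix (default ``"SCORE"``, the
convention used by rDock for its per-pose energy decomposition) is captured
into :attr:`LigandPose.score_components`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

#: identity / label columns of the feature table, in canonical order.
IDENTITY_COLUMNS = ("pdb_id", "ligand_id", "pose_id", "label")

#: default prefix selecting SD tags that are docking-score components.
SCORE_TAG_PREFIX = "SCORE"

#: residue names dropped from receptors by default (solvent).
WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD"})


class StructureParseError(ValueError):
    """A structure file could not be parsed in the requested format."""


class EmptyStructureError(StructureParseError):
    """The file parsed but contained no atoms."""


class SchemaError(ValueError):
    """Feature rows/tables disagree on their column schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom with its identity and position (Å).

    ``raw_sybyl`` is populated only when the source format carries Tripos
    SYBYL types (mol2); otherwise typing is perceived downstream.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_name: str = ""
    residue_seq: int = 0
    chain: str = ""
    is_hetero: bool = False
    raw_sybyl: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): element must be non-empty")


@dataclass
class ReceptorStructure:
    """A nucleic-acid receptor: ordered atoms plus its source identifier."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"receptor {self.source_id!r} has no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"receptor {self.source_id!r}: duplicate atom serials")
        for a in self.atoms:
            if not a.residue_name:
                raise ValueError(f"receptor atom {a.serial}: residue_name required")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class LigandPose:
    """One docked ligand conformation with connectivity and score tags.

    Bonds are ``(i, j, order)`` with 0-based atom indices; aromatic bonds use
    order 1.5.  ``score_components`` maps SD-tag name -> numeric value in
    file order.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    pose_id: str
    ligand_id: str
    source_id: str = ""
    score_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"pose {self.pose_id}: bond ({i},{j}) out of range for {n} atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def translated(self, offset) -> "LigandPose":
        """Return a copy rigidly translated by ``offset`` (Å)."""
        offset = np.asarray(offset, dtype=float)
        atoms = [
            Atom(a.serial, a.name, a.element, a.coords + offset, a.residue_name,
                 a.residue_seq, a.chain, a.is_hetero, a.raw_sybyl)
            for a in self.atoms
        ]
        return LigandPose(atoms, list(self.bonds), self.pose_id, self.ligand_id,
                          self.source_id, dict(self.score_components))


# ---------------------------------------------------------------------------
# receptor reading
# ---------------------------------------------------------------------------

def read_receptor(path, format: str | None = None, *, keep_waters: bool = False,
                  source_id: str | None = None) -> ReceptorStructure:
    """Read a receptor structure from PDB or Tripos mol2.

    HETATM records are kept (ions and modified residues are needed for
    typing); waters are dropped unless ``keep_waters``.  Coordinates are
    returned exactly as stored — no transformation is applied.  The source
    id (PDB ID) comes from ``source_id``, else the PDB HEADER record, else
    the file stem.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        atoms = _read_pdb_atoms(path)
        source_id = source_id or _pdb_header_id(path)
    elif fmt == "mol2":
        atoms = _read_mol2_atoms(path)
    else:
        raise ValueError(f"unsupported receptor format: {fmt!r}")
    if not keep_waters:
        atoms = [a for a in atoms if a.residue_name.upper() not in WATER_RESIDUES]
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms after parsing")
    return ReceptorStructure(atoms=atoms, source_id=source_id or path.stem)


def _pdb_header_id(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("HEADER"):
                tokens = line.split()
                return tokens[-1] if len(tokens) > 1 else None
            if line.startswith(("ATOM", "HETATM")):
                break
    return None


def _read_pdb_atoms(path: Path) -> list[Atom]:
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:
        _raise_with_offending_pdb_line(path, exc)
        raise  # pragma: no cover — _raise always raises
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip()
        if not element:
            element = "".join(c for c in str(arr.atom_name[i]) if c.isalpha())[:1]
        atoms.append(Atom(
            serial=int(arr.atom_id[i]),
            name=str(arr.atom_name[i]).strip(),
            element=element.capitalize(),
            coords=np.array(arr.coord[i], dtype=float),
            residue_name=str(arr.res_name[i]).strip(),
            residue_seq=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]).strip(),
            is_hetero=bool(arr.hetero[i]),
        ))
    return atoms


def _raise_with_offending_pdb_line(path: Path, exc: Exception):
    """Re-raise a PDB parse failure, pointing at the first malformed record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                bad = len(line.rstrip("\n")) < 54
                if not bad:
                    try:
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    except ValueError:
                        bad = True
                if bad:
                    raise StructureParseError(
                        f"{path}: malformed coordinate record at line {lineno}: {line.rstrip()!r}"
                    ) from exc
    raise StructureParseError(f"{path}: {exc}") from exc


def _read_mol2_atoms(path: Path) -> list[Atom]:
    """Minimal Tripos mol2 ATOM-section reader (receptor use).

    SYBYL types from column 6 are kept verbatim in ``raw_sybyl``; residue
    name/sequence come from the substructure columns with trailing sequence
    digits stripped from the name.
    """
    atoms: list[Atom] = []
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("@<TRIPOS>"):
                section = line[9:].upper()
                continue
            if section != "ATOM" or not line:
                continue
            parts = line.split()
            if len(parts) < 6:
                raise StructureParseError(f"{path}: malformed mol2 atom record at line {lineno}: {line!r}")
            try:
                serial = int(parts[0])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}: malformed mol2 atom record at line {lineno}: {line!r}"
                ) from exc
            sybyl = parts[5]
            element = sybyl.split(".")[0].capitalize()
            res_seq = int(parts[6]) if len(parts) > 6 else 0
            subst = parts[7] if len(parts) > 7 else ""
            res_name = subst.rstrip("0123456789")
            atoms.append(Atom(
                serial=serial, name=parts[1], element=element, coords=xyz,
                residue_name=res_name or subst or "UNK", residue_seq=res_seq,
                raw_sybyl=sybyl,
            ))
    return atoms


# ---------------------------------------------------------------------------
# ligand pose reading / writing
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def sanitize_best_effort(mol: Chem.Mol) -> Chem.Mol:
    """Sanitize an rdkit mol, degrading to partial sanitization (ring/aromaticity
    perception only) for molecules with exotic valences, e.g. organometallics."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_SYMMRINGS
            | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
            | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
            | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION,
            catchErrors=True,
        )
    return mol


def _pose_from_rdkit(mol: Chem.Mol, pose_id: str, ligand_id: str, source_id: str,
                     score_prefix: str, allowlist: set[str] | None) -> LigandPose:
    conf = mol.GetConformer()
    atoms = []
    for idx, at in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(idx)
        atoms.append(Atom(
            serial=idx + 1, name=f"{at.GetSymbol()}{idx + 1}", element=at.GetSymbol(),
            coords=np.array([pos.x, pos.y, pos.z]), residue_name="LIG",
        ))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1.0))
        for b in mol.GetBonds()
    ]
    scores: dict[str, float] = {}
    for tag in mol.GetPropNames():
        if not tag.startswith(score_prefix):
            continue
        if allowlist is not None and tag not in allowlist:
            continue
        try:
            scores[tag] = float(mol.GetProp(tag))
        except ValueError:
            logger.debug("pose %s: non-numeric tag %s ignored", pose_id, tag)
    pose = LigandPose(atoms=atoms, bonds=bonds, pose_id=pose_id, ligand_id=ligand_id,
                      source_id=source_id, score_components=scores)
    pose.mol = mol  # cache for SYBYL perception
    return pose


def read_poses(path, format: str | None = None, *, score_prefix: str = SCORE_TAG_PREFIX,
               score_allowlist: set[str] | None = None, ligand_id: str | None = None) -> list[LigandPose]:
    """Read a multi-record ligand pose file (SDF or mol2), in file order.

    Numeric SD tags starting with ``score_prefix`` become score components
    (optionally restricted to ``score_allowlist``).  A record that fails to
    parse is skipped with a warning; the remaining poses are still returned.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("sdf", "sd", "mol", "mol2"):
        raise ValueError(f"unsupported pose format: {fmt!r}")
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    if fmt == "mol2":
        mols = _read_mol2_mols(path)
    else:
        RDLogger.DisableLog("rdApp.*")
        try:
            supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
            mols = list(supplier)
        finally:
            RDLogger.EnableLog("rdApp.error")
    poses = []
    for i, mol in enumerate(mols):
        if mol is None or mol.GetNumConformers() == 0:
            warnings.warn(f"{path}: record {i} could not be parsed; skipped")
            continue
        mol = sanitize_best_effort(mol)
        name = (mol.GetProp("_Name") if mol.HasProp("_Name") else "").strip()
        pid = mol.GetProp("pose_id") if mol.HasProp("pose_id") else (name or f"{path.stem}_{i}")
        lid = ligand_id or (mol.GetProp("ligand_id") if mol.HasProp("ligand_id") else (name or path.stem))
        poses.append(_pose_from_rdkit(mol, pid, lid, path.stem, score_prefix, score_allowlist))
    return poses


def _read_mol2_mols(path: Path) -> list[Chem.Mol]:
    blocks, current = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@<TRIPOS>MOLECULE") and current:
                blocks.append("".join(current))
                current = []
            current.append(line)
    if current:
        blocks.append("".join(current))
    mols = []
    for block in blocks:
        mols.append(Chem.MolFromMol2Block(block, sanitize=False, removeHs=False))
    return mols


_RDKIT_BOND = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
               3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}


def pose_to_rdkit(pose: LigandPose) -> Chem.Mol:
    """Build (and cache) an rdkit molecule from a pose's atoms and bonds."""
    cached = getattr(pose, "mol", None)
    if cached is not None:
        return cached
    rw = Chem.RWMol()
    for a in pose.atoms:
        rw.AddAtom(Chem.Atom(a.element))
    for i, j, order in pose.bonds:
        rw.AddBond(i, j, _RDKIT_BOND.get(float(order), Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(pose.atoms))
    for idx, a in enumerate(pose.atoms):
        conf.SetAtomPosition(idx, tuple(map(float, a.coords)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol = sanitize_best_effort(mol)
    pose.mol = mol
    return mol


def write_poses(poses: list[LigandPose], path) -> None:
    """Write poses to an SDF file, carrying pose/ligand ids and score tags."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = Chem.Mol(pose_to_rdkit(pose))  # copy: props are per-record
            mol.SetProp("_Name", pose.pose_id)
            mol.SetProp("pose_id", pose.pose_id)
            mol.SetProp("ligand_id", pose.ligand_id)
            for tag, value in pose.score_components.items():
                mol.SetProp(tag, f"{value:.6f}")
            try:
                writer.write(mol)
            except Exception:
                writer.SetKekulize(False)
                writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

@dataclass
class FeatureRow:
    """One pose's feature vector plus identity and (optional) RMSD label."""

    pdb_id: str
    ligand_id: str
    pose_id: str
    values: dict[str, float]
    label: float | None = None


def rows_to_table(rows: list[FeatureRow]) -> pd.DataFrame:
    """Assemble feature rows into a table; all rows must share one schema."""
    if not rows:
        raise SchemaError("no rows to assemble")
    schema = list(rows[0].values)
    for r in rows[1:]:
        if list(r.values) != schema:
            extra = sorted(set(r.values) ^ set(schema))
            raise SchemaError(f"feature rows disagree on columns: {extra[:10]}")
    data = {
        "pdb_id": [r.pdb_id for r in rows],
        "ligand_id": [r.ligand_id for r in rows],
        "pose_id": [r.pose_id for r in rows],
        "label": [np.nan if r.label is None else float(r.label) for r in rows],
    }
    for col in schema:
        data[col] = [r.values[col] for r in rows]
    return pd.DataFrame(data)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-identity) columns of a table, in table order."""
    return [c for c in table.columns if c not in IDENTITY_COLUMNS]


def write_feature_table(table_or_rows, path) -> None:
    """Write the feature table as CSV; floats keep full precision (17
    significant digits) so read-after-write is the identity."""
    table = table_or_rows if isinstance(table_or_rows, pd.DataFrame) else rows_to_table(table_or_rows)
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path, dtype={"pdb_id": str, "ligand_id": str, "pose_id": str})
    missing = [c for c in IDENTITY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing identity columns {missing}")
    return table
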