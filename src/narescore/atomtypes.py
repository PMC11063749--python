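"""Interaction-label assignment.

Receptor atoms map to ``RES_rec`` labels: a residue class in
``{A, C, G, U, N, OTH, Metal}`` (U covers thymine; N is the ribose/phosphate
backbone; OTH is the modified region of non-canonical residues) crossed with
a SYBYL atom-type group.  Ligand atoms map to grouped SYBYL types.  The
default registry yields 26 receptor and 24 ligand labels, i.e. 624 ordered
(receptor, ligand) pairs before pruning.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources

import yaml
from rdkit import Chem

from .structio import Atom, LigandPose, pose_to_rdkit

logger = logging.getLogger(__name__)

RESIDUE_CLASSES = ("A", "C", "G", "U", "N", "OTH", "Metal")

#: fingerprint kind -> exponent of 1/r**p
FINGERPRINT_KINDS = {"inv_r": 1, "inv_r6": 6, "inv_r12": 12}


class RegistryError(ValueError):
    """The type registry violates one of its structural invariants."""


class UnknownTypeError(KeyError):
    """An atom's raw type cannot be mapped to any registry label."""


@dataclass(frozen=True)
class ReceptorTypeLabel:
    residue_class: str
    sybyl_group: str

    def __str__(self) -> str:
        if self.residue_class == "Metal":
            return "Metal"
        return f"{self.residue_class}_{self.sybyl_group}"


@dataclass(frozen=True)
class LigandTypeLabel:
    sybyl_group: str

    def __str__(self) -> str:
        return self.sybyl_group


@dataclass
class TypeRegistry:
    """Configurable raw-atom -> interaction-label mapping (data-driven)."""

    nucleobase_alias: dict[str, str]
    backbone_atoms: dict[str, str]
    base_atoms: dict[str, dict[str, str]]
    oth_element_groups: dict[str, str]
    metal_elements: set[str]
    ligand_sybyl_grouping: dict[str, str]
    receptor_labels: list[str]
    ligand_labels: list[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, labels in (("receptor", self.receptor_labels), ("ligand", self.ligand_labels)):
            if len(set(labels)) != len(labels):
                raise RegistryError(f"duplicate {name} labels")
        bad_alias = set(self.nucleobase_alias.values()) - {"A", "C", "G", "U"}
        if bad_alias:
            raise RegistryError(f"nucleobase_alias targets outside A/C/G/U: {bad_alias}")
        rset = set(self.receptor_labels)
        for base, table in self.base_atoms.items():
            for atom_name, sybyl in table.items():
                if f"{base}_{sybyl}" not in rset:
                    raise RegistryError(f"base atom {base}.{atom_name}: label {base}_{sybyl} not in receptor_labels")
        for atom_name, sybyl in self.backbone_atoms.items():
            if f"N_{sybyl}" not in rset:
                raise RegistryError(f"backbone atom {atom_name}: label N_{sybyl} not in receptor_labels")
        for group in self.oth_element_groups.values():
            if group not in rset:
                raise RegistryError(f"OTH group {group} not in receptor_labels")
        if "Metal" not in rset:
            raise RegistryError("receptor_labels must include Metal")
        lset = set(self.ligand_labels)
        missing = set(self.ligand_sybyl_grouping.values()) - lset
        if missing:
            raise RegistryError(f"ligand grouping targets outside ligand_labels: {missing}")

    @property
    def n_pairs(self) -> int:
        return len(self.receptor_labels) * len(self.ligand_labels)

    def digest(self) -> str:
        """Stable content hash, stored with trained models to pin the schema."""
        payload = yaml.safe_dump({
            "nucleobase_alias": self.nucleobase_alias,
            "backbone_atoms": self.backbone_atoms,
            "base_atoms": self.base_atoms,
            "oth_element_groups": self.oth_element_groups,
            "metal_elements": sorted(self.metal_elements),
            "ligand_sybyl_grouping": self.ligand_sybyl_grouping,
            "receptor_labels": self.receptor_labels,
            "ligand_labels": self.ligand_labels,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_mapping(cls, cfg: dict) -> "TypeRegistry":
        return cls(
            nucleobase_alias={str(k): str(v) for k, v in cfg["nucleobase_alias"].items()},
            backbone_atoms={str(k): str(v) for k, v in cfg["backbone_atoms"].items()},
            base_atoms={str(b): {str(k): str(v) for k, v in t.items()}
                        for b, t in cfg["base_atoms"].items()},
            oth_element_groups={str(k): str(v) for k, v in cfg["oth_element_groups"].items()},
            metal_elements={str(e).upper() for e in cfg["metal_elements"]},
            ligand_sybyl_grouping={str(k): str(v) for k, v in cfg["ligand_sybyl_grouping"].items()},
            receptor_labels=[str(x) for x in cfg["receptor_labels"]],
            ligand_labels=[str(x) for x in cfg["ligand_labels"]],
        )

    @classmethod
    def from_file(cls, path) -> "TypeRegistry":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


_DEFAULT: TypeRegistry | None = None


def default_registry() -> TypeRegistry:
    """The registry shipped with the package (26 receptor / 24 ligand labels)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("narescore.data").joinpath("default_registry.yaml").read_text()
        _DEFAULT = TypeRegistry.from_mapping(yaml.safe_load(text))
    return _DEFAULT


# ---------------------------------------------------------------------------
# receptor labelling
# ---------------------------------------------------------------------------

def assign_receptor_label(atom: Atom, registry: TypeRegistry | None = None) -> ReceptorTypeLabel:
    """Label one receptor atom.

    Precedence: monoatomic metal ion -> ``Metal``; nucleotide backbone atom
    name -> class ``N``; canonical atom of an aliased nucleobase -> that base
    class; everything else (modified regions, unknown residues) -> ``OTH``
    grouped by element.  Never fails: unknown residues fall back to OTH with
    a warning.
    """
    registry = registry or default_registry()
    element = atom.element.upper()
    if element in registry.metal_elements:
        return ReceptorTypeLabel("Metal", element)
    name = atom.name.strip()
    if name in registry.backbone_atoms:
        return ReceptorTypeLabel("N", registry.backbone_atoms[name])
    base = registry.nucleobase_alias.get(atom.residue_name.strip())
    if base is not None:
        sybyl = registry.base_atoms[base].get(name)
        if sybyl is not None:
            return ReceptorTypeLabel(base, sybyl)
        # modified region of an aliased residue
        group = registry.oth_element_groups.get(atom.element.capitalize())
    else:
        logger.warning("residue %r not aliased; atom %s typed OTH", atom.residue_name, name)
        group = registry.oth_element_groups.get(atom.element.capitalize())
    group = group or registry.oth_element_groups["default"]
    return ReceptorTypeLabel("OTH", group.split("_", 1)[-1])


def receptor_label_strings(atoms: list[Atom], registry: TypeRegistry | None = None) -> list[str]:
    registry = registry or default_registry()
    out = []
    for atom in atoms:
        lab = assign_receptor_label(atom, registry)
        s = "Metal" if lab.residue_class == "Metal" else (
            f"OTH_{lab.sybyl_group}" if lab.residue_class == "OTH" else str(lab))
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# ligand labelling (SYBYL perception + grouping)
# ---------------------------------------------------------------------------

def perceive_sybyl(mol: Chem.Mol, metal_elements: set[str]) -> list[str]:
    """Raw SYBYL atom types for an rdkit molecule.

    Covers the type vocabulary the grouping needs (element + aromaticity /
    hybridization, amide and carboxylate/phosphate special cases); not a
    general Tripos typing engine.
    """
    types = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H":
            types.append("H")
            continue
        if sym.upper() in metal_elements:
            types.append("Metal")
            continue
        hyb = atom.GetHybridization()
        double = [b for b in atom.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE]
        triple = [b for b in atom.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE]
        if sym == "C":
            if atom.GetIsAromatic():
                t = "C.ar"
            elif triple or len(double) == 2 or hyb == Chem.HybridizationType.SP:
                t = "C.1"
            elif _is_guanidinium_carbon(atom):
                t = "C.cat"
            elif double or hyb == Chem.HybridizationType.SP2:
                t = "C.2"
            else:
                t = "C.3"
        elif sym == "N":
            if atom.GetIsAromatic():
                t = "N.ar"
            elif triple or hyb == Chem.HybridizationType.SP:
                t = "N.1"
            elif atom.GetTotalNumHs() + atom.GetDegree() >= 4 or (
                    atom.GetFormalCharge() > 0 and not double):
                t = "N.4"
            elif _is_amide_nitrogen(atom):
                t = "N.am"
            elif double:
                t = "N.2"
            elif _is_planar_nitrogen(atom):
                t = "N.pl3"
            else:
                t = "N.3"
        elif sym == "O":
            if _is_co2_oxygen(atom):
                t = "O.co2"
            elif double or atom.GetIsAromatic():
                t = "O.2"
            else:
                t = "O.3"
        elif sym == "S":
            n_oxo = sum(1 for nb in atom.GetNeighbors()
                        if nb.GetSymbol() == "O" and nb.GetDegree() == 1)
            if n_oxo >= 2:
                t = "S.o2"
            elif n_oxo == 1:
                t = "S.o"
            elif double:
                t = "S.2"
            else:
                t = "S.3"
        elif sym == "P":
            t = "P.3"
        else:
            t = sym  # halogens, Se, anything exotic — grouping decides
        types.append(t)
    return types


def _is_guanidinium_carbon(atom) -> bool:
    nbs = [nb for nb in atom.GetNeighbors() if nb.GetSymbol() == "N"]
    return len(nbs) == 3 and any(nb.GetFormalCharge() > 0 for nb in nbs)


def _is_amide_nitrogen(atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() == "C":
            for b in nb.GetBonds():
                other = b.GetOtherAtom(nb)
                if b.GetBondType() == Chem.BondType.DOUBLE and other.GetSymbol() in ("O", "S"):
                    return True
    return False


def _is_planar_nitrogen(atom) -> bool:
    # trigonal N with only single bonds, conjugated to an sp2/aromatic neighbor
    return any(nb.GetIsAromatic() or str(nb.GetHybridization()) == "SP2"
               for nb in atom.GetNeighbors())


def _is_co2_oxygen(atom) -> bool:
    # terminal O on a C/P/S centre that bears at least one other terminal O
    # and a negative-charge/delocalised pattern (carboxylate, phosphate)
    if atom.GetDegree() != 1:
        return False
    centre = atom.GetNeighbors()[0]
    if centre.GetSymbol() not in ("C", "P", "S"):
        return False
    terminal_o = [nb for nb in centre.GetNeighbors()
                  if nb.GetSymbol() == "O" and nb.GetDegree() == 1]
    if len(terminal_o) < 2:
        return False
    if centre.GetSymbol() == "C":
        return any(o.GetFormalCharge() < 0 for o in terminal_o)
    return True  # phosphate / sulfate terminal oxygens


def ligand_label_strings(pose: LigandPose, registry: TypeRegistry | None = None) -> list[str | None]:
    """Grouped ligand labels for every atom of a pose (``None`` for hydrogens).

    mol2-sourced SYBYL types are used verbatim when present; otherwise types
    are perceived from the bond graph.  Unknown raw types raise — the
    registry must be extended explicitly, never guessed.
    """
    registry = registry or default_registry()
    raw: list[str] = []
    if all(a.raw_sybyl for a in pose.atoms):
        for a in pose.atoms:
            raw.append("Metal" if a.element.upper() in registry.metal_elements else a.raw_sybyl)
    else:
        raw = perceive_sybyl(pose_to_rdkit(pose), registry.metal_elements)
    out: list[str | None] = []
    for a, t in zip(pose.atoms, raw):
        if t == "H" or a.element.upper() == "H":
            out.append(None)
            continue
        group = registry.ligand_sybyl_grouping.get(t)
        if group is None:
            raise UnknownTypeError(
                f"pose {pose.pose_id}: no ligand group for SYBYL type {t!r} "
                f"(element {a.element!r}); extend the registry")
        out.append(group)
    return out


def assign_ligand_label(atom: Atom, pose: LigandPose,
                        registry: TypeRegistry | None = None) -> LigandTypeLabel:
    """Label a single ligand atom (convenience wrapper over the pose path)."""
    idx = pose.atoms.index(atom)
    label = ligand_label_strings(pose, registry)[idx]
    if label is None:
        raise UnknownTypeError("hydrogens carry no interaction label")
    return LigandTypeLabel(label)


# ---------------------------------------------------------------------------
# feature-column naming
# ---------------------------------------------------------------------------

def pair_feature_names(registry: TypeRegistry | None = None,
                       kinds: tuple[str, ...] = ("inv_r", "inv_r6")) -> list[str]:
    """Deterministic column names: receptor-major x ligand x kind.

    With the default registry and one kind this is 26 x 24 = 624 names.
    """
    registry = registry or default_registry()
    for k in kinds:
        if k not in FINGERPRINT_KINDS:
            raise ValueError(f"unknown fingerprint kind {k!r}")
    return [f"{r}|{l}|{k}"
            for r in registry.receptor_labels
            for l in registry.ligand_labels
            for k in kinds]


def is_fingerprint_column(name: str) -> bool:
    """Distinguish pair-fingerprint columns from score-component columns."""
    parts = name.split("|")
    return len(parts) == 3 and parts[2] in FINGERPRINT_KINDS


def pair_of_column(name: str) -> tuple[str, str]:
    r, l, _ = name.split("|")
    return r, l
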