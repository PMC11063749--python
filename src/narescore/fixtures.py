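"""Deterministic synthetic fixtures.

Everything the pipeline consumes can be generated here with no downloads:
toy nucleic-acid-like receptors with correctly named backbone/base atoms
(so every typing rule fires), ligand pose ladders at controlled rigid
displacement from a reference (so RMSD labels are known exactly), and
planted-relationship feature tables (so model recovery can be verified
against ground truth).  Geometry is a simple helical placement — not
physically refined; featurization only needs names, types and coordinates.
All outputs are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atomtypes import TypeRegistry, default_registry
from .structio import Atom, LigandPose, ReceptorStructure

#: default residue mix: canonical RNA + DNA, one modified residue, one ion
DEFAULT_RESIDUES = ("A", "DT", "G", "C", "5MC", "MG")

AROMATIC = 1.5


@dataclass
class FixtureSpec:
    """Parameters of one synthetic receptor-ligand fixture."""

    seed: int = 0
    n_residues: int = 6
    residue_names: tuple[str, ...] = DEFAULT_RESIDUES
    ligand_template: str = "ring"  # ring | chain | metal_complex
    n_poses: int = 8
    displacement_ladder: tuple[float, ...] = (0.0, 1.0, 3.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if list(self.displacement_ladder) != sorted(self.displacement_ladder):
            raise ValueError("displacement_ladder must be sorted ascending")


# residues the toy receptor knows how to build: backbone subset + base atoms
_BACKBONE = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")
_BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "DT": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
    # modified cytosine: canonical C atoms plus a methyl in the modified region
    "5MC": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C5A", "C6"),
}
_ALIAS = {"A": "A", "G": "G", "C": "C", "U": "U", "DT": "DT", "5MC": "5MC",
          "DA": "A", "DG": "G", "DC": "C"}


def _element_of(name: str) -> str:
    return "".join(c for c in name if c.isalpha())[:1].capitalize()


def make_toy_complex(spec: FixtureSpec,
                     registry: TypeRegistry | None = None) -> tuple[ReceptorStructure, LigandPose]:
    """Build a toy receptor and the reference ligand pose.

    Residues are placed on a coarse helix (radius 9 Å, twist 36 deg, rise
    2.8 Å) with seeded per-atom scatter; the ligand sits near the helix
    axis so that receptor-ligand contacts exist at typical cutoffs.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(spec.seed)
    names = [spec.residue_names[i % len(spec.residue_names)] for i in range(spec.n_residues)]
    atoms: list[Atom] = []
    serial = 1
    for res_i, res_name in enumerate(names):
        angle = np.deg2rad(36.0 * res_i)
        centre = np.array([9.0 * np.cos(angle), 9.0 * np.sin(angle), 2.8 * res_i])
        if res_name.upper() in registry.metal_elements:  # monoatomic ion
            pos = centre * 0.4 + rng.normal(0, 0.5, 3)
            atoms.append(Atom(serial, res_name, res_name.capitalize(), pos,
                              residue_name=res_name, residue_seq=res_i + 1,
                              chain="A", is_hetero=True))
            serial += 1
            continue
        base = _ALIAS.get(res_name, "U")
        hetero = res_name not in ("A", "C", "G", "U", "DA", "DC", "DG", "DT")
        for name in _BACKBONE + _BASE_ATOMS[base]:
            pos = centre + rng.uniform(-2.0, 2.0, 3)
            atoms.append(Atom(serial, name, _element_of(name), pos,
                              residue_name=res_name, residue_seq=res_i + 1,
                              chain="A", is_hetero=hetero))
            serial += 1
    receptor = ReceptorStructure(atoms=atoms, source_id=f"TOY{spec.seed:04d}")
    centroid = receptor.coords.mean(axis=0)
    reference = _make_ligand(spec.ligand_template, centre=centroid * 0.5,
                             ligand_id=f"LIG{spec.seed:04d}")
    return receptor, reference


def _make_ligand(template: str, centre: np.ndarray, ligand_id: str) -> LigandPose:
    centre = np.asarray(centre, dtype=float)
    if template == "ring":
        # aniline-like: aromatic C6 ring + exocyclic N; the mirror through the
        # substituted axis is a non-trivial graph automorphism.
        ring = [centre + np.array([1.39 * np.cos(np.pi / 3 * i),
                                   1.39 * np.sin(np.pi / 3 * i), 0.0]) for i in range(6)]
        coords = ring + [centre + np.array([2.8, 0.0, 0.0])]
        elements = ["C"] * 6 + ["N"]
        bonds = [(i, (i + 1) % 6, AROMATIC) for i in range(6)] + [(0, 6, 1.0)]
    elif template == "chain":
        coords = [centre + np.array([1.4 * i, 0.15 * i * i, 0.0]) for i in range(5)]
        elements = ["C", "C", "N", "C", "O"]
        bonds = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 2.0)]
    elif template == "metal_complex":
        # ruthenium-polypyridyl-like toy: Ru centre with three N-C arms
        coords = [centre]
        elements = ["Ru"]
        bonds = []
        for arm in range(3):
            angle = 2 * np.pi * arm / 3
            u = np.array([np.cos(angle), np.sin(angle), 0.3 * (arm - 1)])
            coords += [centre + 2.1 * u, centre + 3.5 * u]
            elements += ["N", "C"]
            n_idx = 1 + 2 * arm
            bonds += [(0, n_idx, 1.0), (n_idx, n_idx + 1, 1.0)]
    else:
        raise ValueError(f"unknown ligand template {template!r}")
    atoms = [Atom(i + 1, f"{el}{i + 1}", el, xyz, residue_name="LIG", residue_seq=1)
             for i, (el, xyz) in enumerate(zip(elements, coords))]
    return LigandPose(atoms=atoms, bonds=bonds, pose_id=f"{ligand_id}_ref",
                      ligand_id=ligand_id, source_id=ligand_id)


def make_pose_ladder(reference: LigandPose, spec: FixtureSpec,
                     with_scores: bool = True) -> list[tuple[LigandPose, float]]:
    """Rigid-translation pose ensemble with exactly known RMSD labels.

    The first ``len(displacement_ladder)`` poses are the reference rigidly
    translated along +x by each ladder value, so the symmetry-corrected RMSD
    of pose k equals the k-th ladder value exactly.  Remaining poses (up to
    ``n_poses``) are jittered decoys at seeded random displacements.  When
    ``with_scores`` is set, synthetic docking-score tags (``SCORE``,
    ``SCORE.INTER``, ``SCORE.INTER.POLAR``) loosely tracking the
    displacement are attached, emulating a docking program's output.
    """
    rng = np.random.default_rng(spec.seed + 1)
    out: list[tuple[LigandPose, float]] = []
    displacements = list(spec.displacement_ladder)
    for k in range(spec.n_poses):
        if k < len(displacements):
            d = float(displacements[k])
            pose = reference.translated([d, 0.0, 0.0])
        else:
            d = float(rng.uniform(0.5, 14.0))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pose = reference.translated(d * direction)
        pose.pose_id = f"{reference.ligand_id}_pose{k:03d}"
        if with_scores:
            noisy = d + rng.normal(0, 1.0)
            pose.score_components = {
                "SCORE": round(noisy * 2.0 - 20.0, 6),
                "SCORE.INTER": round(noisy * 1.5 - 12.0, 6),
                "SCORE.INTER.POLAR": round(rng.normal(-2.0, 0.5), 6),
            }
        out.append((pose, d))
    return out


def make_planted_table(n_groups: int = 40, rows_per_group: int = 50,
                       informative_column: str = "G_C.ar|C.ar|inv_r",
                       effect: float = -4.0, noise_sd: float = 0.3,
                       seed: int = 0, n_noise_columns: int = 19,
                       intercept: float = 10.0) -> pd.DataFrame:
    """Feature table with one planted linear signal.

    label = intercept + effect * informative_column + N(0, noise_sd); noise
    columns are sparse non-negative draws mimicking fingerprint statistics
    (most values small, many exact zeros).  Group ids act as pseudo-PDB ids
    for grouped splitting.
    """
    if effect == 0:
        raise ValueError("effect must be non-zero")
    rng = np.random.default_rng(seed)
    n = n_groups * rows_per_group
    informative = rng.uniform(0.0, 2.0, size=n)
    label = intercept + effect * informative + rng.normal(0.0, noise_sd, size=n)
    data = {
        "pdb_id": [f"G{g:03d}" for g in range(n_groups) for _ in range(rows_per_group)],
        "ligand_id": [f"G{g:03d}_L" for g in range(n_groups) for _ in range(rows_per_group)],
        "pose_id": [f"p{i:05d}" for i in range(n)],
        "label": label,
        informative_column: informative,
    }
    noise_names = _noise_column_names(informative_column, n_noise_columns)
    for name in noise_names:
        values = rng.gamma(shape=1.5, scale=0.4, size=n)
        values *= rng.random(size=n) < 0.6  # sparsity: ~40 % exact zeros
        data[name] = values
    return pd.DataFrame(data)


def _noise_column_names(informative_column: str, n: int) -> list[str]:
    registry = default_registry()
    names = []
    for r in registry.receptor_labels:
        for l in registry.ligand_labels:
            for k in ("inv_r", "inv_r6"):
                name = f"{r}|{l}|{k}"
                if name != informative_column:
                    names.append(name)
                if len(names) == n:
                    return names
    return names


# ---------------------------------------------------------------------------
# plain-text writers (PDB) — byte-stable output for round-trip tests
# ---------------------------------------------------------------------------

def write_receptor_pdb(receptor: ReceptorStructure, path) -> None:
    """Write the receptor in fixed-column PDB format (deterministic bytes)."""
    lines = [f"HEADER    SYNTHETIC NA COMPLEX{'':>34s}{receptor.source_id}"]
    for a in receptor.atoms:
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial:>5d} {name:<4.4s} {a.residue_name:>3.3s} "
            f"{(a.chain or 'A'):1.1s}{a.residue_seq:>4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2.2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
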