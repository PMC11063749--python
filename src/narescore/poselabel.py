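"""Pose labelling: symmetry-corrected RMSD against the native ligand, the
success filter, and selection of the training poses.

The RMSD is computed in place (no superposition): docking deviation is
measured in the receptor frame, so realigning the pose onto the reference
would hide exactly the displacement being measured.  Symmetry correction
takes the minimum over all automorphisms of the ligand's molecular graph
(element- and bond-order-preserving), removing artificial RMSD inflation
from chemically equivalent atom relabelings such as a flipped aromatic ring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism

from .structio import LigandPose

logger = logging.getLogger(__name__)

#: a dock is "successful" when its symmetry-corrected RMSD is at most this (Å)
SUCCESS_RMSD = 10.0

#: a pose is "close to native" when its RMSD is at most this (Å)
CLOSE_TO_NATIVE_RMSD = 2.0

#: cap on enumerated graph automorphisms before falling back to identity
MAX_AUTOMORPHISMS = 10_000


class GraphMismatchError(ValueError):
    """Reference and pose are not the same molecule (graphs not isomorphic)."""


def heavy_atom_graph(pose: LigandPose) -> nx.Graph:
    """Molecular graph over heavy atoms: nodes carry the element, edges the
    bond order (aromatic = 1.5)."""
    g = nx.Graph()
    heavy = {i for i, a in enumerate(pose.atoms) if a.element.upper() != "H"}
    for i in heavy:
        g.add_node(i, element=pose.atoms[i].element.upper())
    for i, j, order in pose.bonds:
        if i in heavy and j in heavy:
            g.add_edge(i, j, order=float(order))
    return g


def _matcher(g_ref: nx.Graph, g_pose: nx.Graph) -> isomorphism.GraphMatcher:
    return isomorphism.GraphMatcher(
        g_ref, g_pose,
        node_match=isomorphism.categorical_node_match("element", None),
        edge_match=isomorphism.numerical_edge_match("order", 1.0),
    )


def _inplace_rmsd(ref_xyz: np.ndarray, pose_xyz: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((ref_xyz - pose_xyz) ** 2, axis=1))))


def symmetry_corrected_rmsd(reference: LigandPose, pose: LigandPose,
                            max_automorphisms: int = MAX_AUTOMORPHISMS) -> float:
    """Minimum in-place heavy-atom RMSD over molecular-graph automorphisms.

    Raises :class:`GraphMismatchError` if the two molecular graphs are not
    isomorphic (wrong reference ligand).  Enumeration is capped at
    ``max_automorphisms`` mappings; past the cap the best mapping seen so
    far is used with a warning.
    """
    g_ref = heavy_atom_graph(reference)
    g_pose = heavy_atom_graph(pose)
    matcher = _matcher(g_ref, g_pose)
    ref_nodes = sorted(g_ref.nodes)
    ref_xyz = np.array([reference.atoms[i].coords for i in ref_nodes])
    best = np.inf
    count = 0
    for mapping in matcher.isomorphisms_iter():
        pose_xyz = np.array([pose.atoms[mapping[i]].coords for i in ref_nodes])
        best = min(best, _inplace_rmsd(ref_xyz, pose_xyz))
        count += 1
        if count >= max_automorphisms:
            warnings.warn(
                f"pose {pose.pose_id}: automorphism cap {max_automorphisms} reached; "
                "RMSD is the minimum over the enumerated mappings")
            break
    if count == 0:
        raise GraphMismatchError(
            f"pose {pose.pose_id}: molecular graph does not match reference "
            f"{reference.pose_id} (same ligand required)")
    return best


def naive_rmsd(reference: LigandPose, pose: LigandPose) -> float:
    """Identity-mapping in-place heavy-atom RMSD (no symmetry correction)."""
    heavy = [i for i, a in enumerate(reference.atoms) if a.element.upper() != "H"]
    ref_xyz = np.array([reference.atoms[i].coords for i in heavy])
    pose_xyz = np.array([pose.atoms[i].coords for i in heavy])
    return _inplace_rmsd(ref_xyz, pose_xyz)


def close_to_native(rmsd: float, threshold: float = CLOSE_TO_NATIVE_RMSD) -> bool:
    """Whether a pose counts as close to native (RMSD <= threshold, inclusive)."""
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    return rmsd <= threshold


@dataclass
class LabeledPoseSet:
    """All labelled dock attempts for one ligand."""

    ligand_id: str
    poses: list[tuple[LigandPose, float]]
    attempts: int

    @property
    def successes(self) -> int:
        return sum(1 for _, r in self.poses if r <= SUCCESS_RMSD)


def label_poses(reference: LigandPose, poses: list[LigandPose],
                ligand_id: str | None = None) -> LabeledPoseSet:
    """Label every pose with its symmetry-corrected RMSD to the reference."""
    labelled = [(p, symmetry_corrected_rmsd(reference, p)) for p in poses]
    lid = ligand_id or (poses[0].ligand_id if poses else reference.ligand_id)
    return LabeledPoseSet(ligand_id=lid, poses=labelled, attempts=len(poses))


def filter_and_select(pose_set: LabeledPoseSet, *, success_cut: float = SUCCESS_RMSD,
                      min_successes: int = 100, n_select: int = 100,
                      seed: int = 0, mode: str = "random") -> list[tuple[LigandPose, float]]:
    """Apply the dataset inclusion rule and pick the training poses.

    A ligand enters the dataset only if at least ``min_successes`` of its
    attempts are successful docks (RMSD <= ``success_cut``); it then
    contributes exactly ``n_select`` successful poses, drawn uniformly
    without replacement (``mode="random"``, deterministic in ``seed``) or as
    the first ``n_select`` in file order (``mode="first"``).  An excluded
    ligand yields an empty list.
    """
    successes = [(p, r) for p, r in pose_set.poses if r <= success_cut]
    if len(successes) < min_successes:
        return []
    if len(successes) < n_select:
        # unreachable with the default gate (min_successes >= n_select)
        assert min_successes < n_select, "inclusion gate guarantees n_select successes"
        return list(successes)
    if len(successes) == n_select:
        return list(successes)
    if mode == "first":
        return successes[:n_select]
    if mode != "random":
        raise ValueError(f"unknown selection mode {mode!r}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(successes), size=n_select, replace=False))
    return [successes[i] for i in idx]
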