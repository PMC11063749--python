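import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import narescore as ns
from narescore.atomtypes import ligand_label_strings, receptor_label_strings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return ns.default_registry()


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic toy receptor + reference ligand (ring template)."""
    spec = ns.FixtureSpec(seed=11)
    receptor, reference = ns.make_toy_complex(spec)
    return spec, receptor, reference


def brute_force_fingerprint(receptor, pose, registry, config):
    """Independent O(N*M) double-loop oracle for the fingerprint."""
    from narescore.atomtypes import FINGERPRINT_KINDS, pair_feature_names

    names = pair_feature_names(registry, config.kinds)
    values = dict.fromkeys(names, 0.0)
    rec_labels = receptor_label_strings(receptor.atoms, registry)
    lig_labels = ligand_label_strings(pose, registry)
    for ra, rl in zip(receptor.atoms, rec_labels):
        if ra.element.upper() == "H" and not config.include_hydrogens:
            continue
        for la, ll in zip(pose.atoms, lig_labels):
            if ll is None:
                continue
            d = float(np.linalg.norm(ra.coords - la.coords))
            if d >= config.cutoff_rc:
                continue
            for kind in config.kinds:
                values[f"{rl}|{ll}|{kind}"] += d ** -FINGERPRINT_KINDS[kind]
    return values


def brute_force_symmetry_rmsd(reference, pose):
    """Enumerate *all* element/bond-preserving permutations of a tiny
    molecule and return the minimum in-place RMSD (exponential; <= 9 atoms)."""
    from itertools import permutations

    heavy = [i for i, a in enumerate(reference.atoms) if a.element.upper() != "H"]
    assert len(heavy) <= 9, "oracle is exponential"
    elements = [reference.atoms[i].element for i in heavy]
    adj = {}
    for i, j, order in reference.bonds:
        if i in heavy and j in heavy:
            adj[frozenset((i, j))] = float(order)
    pose_adj = {}
    for i, j, order in pose.bonds:
        if i in heavy and j in heavy:
            pose_adj[frozenset((i, j))] = float(order)
    ref_xyz = np.array([reference.atoms[i].coords for i in heavy])
    best = np.inf
    for perm in permutations(range(len(heavy))):
        if any(elements[k] != pose.atoms[heavy[perm[k]]].element for k in range(len(heavy))):
            continue
        ok = True
        for pair, order in adj.items():
            i, j = tuple(pair)
            ki, kj = heavy.index(i), heavy.index(j)
            mapped = frozenset((heavy[perm[ki]], heavy[perm[kj]]))
            if pose_adj.get(mapped) != order:
                ok = False
                break
        if ok and len(adj) == len(pose_adj):
            pose_xyz = np.array([pose.atoms[heavy[k]].coords for k in perm])
            best = min(best, float(np.sqrt(np.mean(np.sum((ref_xyz - pose_xyz) ** 2, axis=1)))))
    return best


def random_rigid_motion(rng):
    """Random rotation matrix + translation for invariance tests."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1)))
    return rot.as_matrix(), rng.uniform(-20, 20, 3)


def transform_pose(pose, R, t):
    moved = pose.translated([0, 0, 0])
    for atom in moved.atoms:
        atom.coords = R @ atom.coords + t
    if hasattr(moved, "mol"):
        del moved.mol
    return moved


def transform_receptor(receptor, R, t):
    atoms = [
        ns.Atom(a.serial, a.name, a.element, R @ a.coords + t, a.residue_name,
                a.residue_seq, a.chain, a.is_hetero, a.raw_sybyl)
        for a in receptor.atoms
    ]
    return ns.ReceptorStructure(atoms=atoms, source_id=receptor.source_id)
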