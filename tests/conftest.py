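import numpy as np
import pytest
from scipy.spatial.distance import cdist

from iface import Atom, Residue, Structure, make_dimer_complex


@pytest.fixture(scope="session")
def base_complex():
    """C2 dimer + docked ligand with six planted contact residues."""
    return make_dimer_complex(seed=11)


def random_two_chain_structure(rng, n_atoms_a, n_atoms_b, spread=20.0,
                               atoms_per_residue=3):
    """Random toy complex: two chains of random residues inside one box."""
    st = Structure(id="random-toy")
    for cid, n_atoms in (("A", n_atoms_a), ("B", n_atoms_b)):
        residues = []
        coords = rng.uniform(-spread, spread, size=(n_atoms, 3))
        for i, start in enumerate(range(0, n_atoms, atoms_per_residue), start=1):
            block = coords[start:start + atoms_per_residue]
            atoms = [Atom(f"C{j}", "C", xyz) for j, xyz in enumerate(block)]
            residues.append(Residue(cid, i, "", "GLY", atoms))
        st.chains[cid] = residues
    return st


def brute_force_contacts(structure, receptor_chains, ligand_chains, cutoff,
                         heavy_only=True):
    """All-pairs distance scan; the independent oracle for residue_contacts."""
    def side(chains):
        xyz, keys = [], []
        for cid in sorted(chains):
            for res in structure.residues(cid):
                atoms = res.heavy_atoms() if heavy_only else res.atoms
                for atom in atoms:
                    xyz.append(atom.coord)
                    keys.append(res.key)
        return np.asarray(xyz).reshape(-1, 3), keys

    rec_xyz, rec_keys = side(receptor_chains)
    lig_xyz, lig_keys = side(ligand_chains)
    pairs = set()
    if len(rec_xyz) and len(lig_xyz):
        dist = cdist(rec_xyz, lig_xyz)
        for i, j in zip(*np.nonzero(dist <= cutoff)):
            pairs.add((rec_keys[i], lig_keys[j]))
    return pairs


def horn_quaternion_superpose(mobile, reference):
    """Horn's closed-form quaternion superposition; oracle for the Kabsch path.

    Returns (rotation matrix, translation, rmsd) for x -> R x + t mapping
    mobile onto reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    S = mc.T @ rc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(N)
    q = eigvecs[:, -1]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    d = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((d * d).sum(axis=1).mean()))
    return R, t, rmsd
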