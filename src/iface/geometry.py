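"""Superposition and deviation/fluctuation analysis.

Covers the geometric layer of docking-ensemble assessment: least-squares
rigid superposition (Kabsch, reflection excluded), construction of an
average complex from a pose ensemble, interface RMSD of each pose against
that reference, funnel analysis of (docking score, iRMSD) clouds, RMSD
traces along a trajectory with plateau (equilibration) detection, and
per-residue RMSF with a proximal-vs-distant subunit comparison for
interface stabilization.

Conventions. Interface residues are defined on the reference complex as any
residue with a heavy atom within ``interface_cutoff`` (10 Å default) of the
partner; poses are fitted to the reference on receptor Cα atoms and the
iRMSD is then measured over interface Cα atoms without re-fitting on the
interface set. These choices follow common docking-assessment practice and
are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from .errors import CongruenceError, InputError, SymmetryMapError
from .structio import ResidueKey, Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "FunnelSummary",
    "RMSFProfile",
    "kabsch_superpose",
    "average_complex",
    "interface_rmsd",
    "funnel_analysis",
    "rmsd_trace",
    "equilibration_time",
    "rmsf",
    "rmsf_delta",
]


@dataclass
class SuperpositionResult:
    """Rigid transform x ↦ R·x + t minimizing RMSD of mobile onto reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), Å
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Both inputs are (n, 3) arrays with matched point order, n ≥ 3 and not all
    collinear. Reflections are excluded (the rotation determinant is +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise CongruenceError(
            f"point-count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("coordinate sets must have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InputError(f"need at least 3 points, got {n}")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise InputError("degenerate (collinear) point set; superposition underdetermined")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    translation = ref_mean - R @ mob_mean
    # recompute the rmsd from the transformed coordinates: align_vectors'
    # rssd loses precision near zero residual
    d = mobile @ R.T + translation - reference
    rmsd = float(np.sqrt((d * d).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=translation, rmsd=rmsd)


def _ca_mask(structure: Structure, chains: Iterable[str] | None = None) -> np.ndarray:
    return structure.atom_mask(chains=chains, atom_names=("CA",), include_hetero=False)


@dataclass
class AverageComplexResult:
    reference: Structure
    medoid_index: int
    superposed_coords: np.ndarray  # (n_poses, n_atoms, 3) after receptor-CA fit


def average_complex(
    poses: Sequence[Structure], receptor_chains: Iterable[str]
) -> AverageComplexResult:
    """Average complex of a pose ensemble, plus the medoid pose.

    All poses are superposed onto pose 0 on receptor Cα atoms; the reference
    is the per-atom coordinate mean. Coordinate means can be
    stereochemically unphysical, so the medoid (pose minimizing the mean
    all-atom RMSD to the others, computed on the superposed coordinates) is
    reported alongside as the robust representative.
    """
    if len(poses) < 2:
        raise InputError("need at least 2 poses to average")
    n_atoms = poses[0].n_atoms
    mask = _ca_mask(poses[0], chains=set(receptor_chains))
    ref_ca = poses[0].coords()[mask]
    stacked = np.empty((len(poses), n_atoms, 3))
    for i, pose in enumerate(poses):
        coords = pose.coords()
        if coords.shape[0] != n_atoms:
            raise CongruenceError(f"pose {i} has {coords.shape[0]} atoms, expected {n_atoms}")
        fit = kabsch_superpose(coords[mask], ref_ca)
        stacked[i] = fit.apply(coords)
    mean_coords = stacked.mean(axis=0)
    reference = poses[0].with_coords(mean_coords, id="average-complex")

    # medoid: argmin of the mean pairwise RMSD row (no re-fitting per pair)
    n = len(poses)
    rmsd_matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = stacked[i] - stacked[j]
            rmsd_matrix[i, j] = rmsd_matrix[j, i] = float(
                np.sqrt((d * d).sum(axis=1).mean())
            )
    medoid = int(np.argmin(rmsd_matrix.sum(axis=1) / (n - 1)))
    return AverageComplexResult(reference=reference, medoid_index=medoid, superposed_coords=stacked)


def _interface_residues(
    reference: Structure,
    receptor_chains: set[str],
    ligand_chains: set[str],
    cutoff: float,
) -> set[ResidueKey]:
    """Residues (both sides) with a heavy atom within ``cutoff`` of the partner."""
    sides = {}
    for name, chains in (("rec", receptor_chains), ("lig", ligand_chains)):
        xyz, keys = [], []
        for cid in sorted(chains):
            for res in reference.residues(cid):
                for atom in res.heavy_atoms():
                    xyz.append(atom.coord)
                    keys.append(res.key)
        sides[name] = (np.asarray(xyz).reshape(-1, 3), keys)
    rec_xyz, rec_keys = sides["rec"]
    lig_xyz, lig_keys = sides["lig"]
    out: set[ResidueKey] = set()
    if len(rec_xyz) and len(lig_xyz):
        tree = cKDTree(lig_xyz)
        for i, neigh in enumerate(tree.query_ball_point(rec_xyz, r=cutoff)):
            if neigh:
                out.add(rec_keys[i])
                out.update(lig_keys[j] for j in neigh)
    return out


def interface_rmsd(
    pose: Structure,
    reference: Structure,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    interface_cutoff: float = 10.0,
    atoms: str = "CA",
) -> float:
    """Cα RMSD over interface residues after receptor-Cα superposition.

    The interface set is defined on the reference; the pose is fitted to the
    reference on receptor Cα atoms and the deviation is measured over the
    union of receptor and ligand interface residues without re-fitting.
    """
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)
    iface = _interface_residues(reference, receptor_chains, ligand_chains, interface_cutoff)
    if not iface:
        raise InputError(
            f"no interface residues within {interface_cutoff} Å; cutoff too small"
        )
    pose_keys = pose.atom_residue_keys()
    ref_keys = reference.atom_residue_keys()
    if pose_keys != ref_keys:
        raise CongruenceError("pose and reference do not share an atom/residue key space")

    rec_mask = _ca_mask(reference, chains=receptor_chains)
    pose_coords, ref_coords = pose.coords(), reference.coords()
    fit = kabsch_superpose(pose_coords[rec_mask], ref_coords[rec_mask])
    moved = fit.apply(pose_coords)

    name_mask = reference.atom_mask(atom_names=(atoms,), include_hetero=False)
    iface_mask = np.array([k in iface for k in ref_keys]) & name_mask
    d = moved[iface_mask] - ref_coords[iface_mask]
    return float(np.sqrt((d * d).sum(axis=1).mean()))


@dataclass
class FunnelSummary:
    rho: float
    low_score_median_irmsd: float
    global_median_irmsd: float
    is_funnel: bool
    n_points: int
    low_fraction: float


def funnel_analysis(
    points: Sequence[tuple[float, float]],
    low_fraction: float = 0.1,
    rho_threshold: float = 0.4,
) -> FunnelSummary:
    """Detect a docking funnel in a cloud of (score, iRMSD) points.

    Lower scores are better. The cloud is called a funnel when the Spearman
    rank correlation between score and iRMSD reaches ``rho_threshold`` AND
    the median iRMSD of the best-scoring ``low_fraction`` of points lies
    below the global median — i.e. good scores concentrate at small
    deviations from the reference complex.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points must be (score, irmsd) pairs")
    n = pts.shape[0]
    if n < 20:
        raise InputError(f"need at least 20 points for funnel analysis, got {n}")
    scores, irmsd = pts[:, 0], pts[:, 1]
    if np.ptp(scores) == 0:
        raise InputError("constant scores: rank correlation undefined")
    rho = float(spearmanr(scores, irmsd).statistic)
    k = max(1, int(n * low_fraction))
    best = np.argsort(scores, kind="stable")[:k]
    low_med = float(np.median(irmsd[best]))
    glob_med = float(np.median(irmsd))
    return FunnelSummary(
        rho=rho,
        low_score_median_irmsd=low_med,
        global_median_irmsd=glob_med,
        is_funnel=bool(rho >= rho_threshold and low_med < glob_med),
        n_points=n,
        low_fraction=low_fraction,
    )


def rmsd_trace(
    trajectory: Trajectory,
    reference: Structure,
    selection_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after superposition on the selection.

    Returns an (n_frames, 2) array of (time_ps, rmsd_Å). ``selection_mask``
    is a boolean mask over the flat atom order (default: Cα atoms).
    """
    if reference.n_atoms != trajectory.topology.n_atoms:
        raise CongruenceError("reference and trajectory topology differ in atom count")
    if selection_mask is None:
        selection_mask = _ca_mask(reference)
    ref_sel = reference.coords()[selection_mask]
    out = np.empty((trajectory.n_frames, 2))
    for i, frame in enumerate(trajectory.frames):
        fit = kabsch_superpose(frame[selection_mask], ref_sel)
        out[i] = (trajectory.times[i], fit.rmsd)
    return out


@dataclass
class EquilibrationResult:
    time_ps: float | None
    reached: bool


def equilibration_time(
    trace: np.ndarray, window: int = 10, band: float = 0.5
) -> EquilibrationResult:
    """Earliest time after which every sliding window stays within ``band`` Å.

    ``trace`` is the (time, rmsd) array from :func:`rmsd_trace`. The plateau
    start is the earliest index i such that max−min of the RMSD over every
    window of ``window`` frames starting at or after i is ≤ band.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    if window > n:
        raise InputError(f"window {window} exceeds trace length {n}")
    values = trace[:, 1]
    n_windows = n - window + 1
    ranges = np.array(
        [values[j : j + window].max() - values[j : j + window].min() for j in range(n_windows)]
    )
    bad = np.nonzero(ranges > band)[0]
    if bad.size == 0:
        start = 0
    elif bad[-1] == n_windows - 1:
        return EquilibrationResult(time_ps=None, reached=False)
    else:
        start = int(bad[-1]) + 1
    return EquilibrationResult(time_ps=float(trace[start, 0]), reached=True)


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation around the mean structure."""

    values: dict[ResidueKey, float]
    reference: str = "iterative mean structure (2-pass Kabsch fit)"

    def __getitem__(self, key: ResidueKey) -> float:
        return self.values[key]


def rmsf(
    trajectory: Trajectory,
    selection_mask: np.ndarray | None = None,
    align: bool = True,
    n_passes: int = 2,
) -> RMSFProfile:
    """Per-residue RMSF over a trajectory.

    Frames are aligned to the evolving mean structure by an iterative Kabsch
    fit on the selection (2 passes by default); RMSF_i = √⟨|x_i − x̄_i|²⟩.
    With Cα selections the profile has one value per residue.
    """
    if trajectory.n_frames < 2:
        raise InputError("RMSF undefined for a single frame")
    if selection_mask is None:
        selection_mask = _ca_mask(trajectory.topology)
    sel_coords = trajectory.frames[:, selection_mask, :].copy()
    if align:
        for _ in range(n_passes):
            mean = sel_coords.mean(axis=0)
            for i in range(sel_coords.shape[0]):
                fit = kabsch_superpose(sel_coords[i], mean)
                sel_coords[i] = fit.apply(sel_coords[i])
    mean = sel_coords.mean(axis=0)
    dev = sel_coords - mean
    per_atom = np.sqrt((dev * dev).sum(axis=2).mean(axis=0))
    keys = [k for k, m in zip(trajectory.topology.atom_residue_keys(), selection_mask) if m]
    return RMSFProfile(values={k: float(v) for k, v in zip(keys, per_atom)})


@dataclass
class RMSFDeltaResult:
    deltas: dict[ResidueKey, float]  # proximal − distant, Å
    n_lower: int
    fraction_lower: float


def rmsf_delta(
    profile: RMSFProfile,
    symmetry_map: Mapping[ResidueKey, ResidueKey],
    interface_residues: Iterable[ResidueKey],
) -> RMSFDeltaResult:
    """Proximal-minus-distant RMSF per interface residue of a homodimer.

    For each interface residue of the subunit proximal to the binding
    partner, the delta is RMSF(proximal copy) − RMSF(symmetry mate in the
    distant subunit). A negative delta means the partner rigidifies the
    proximal copy; the summary counts how many interface residues show that
    stabilization.
    """
    interface_residues = list(interface_residues)
    if not interface_residues:
        raise InputError("empty interface residue set")
    if len(set(symmetry_map.values())) != len(symmetry_map):
        raise SymmetryMapError("symmetry map is not injective")
    deltas: dict[ResidueKey, float] = {}
    for key in interface_residues:
        if key not in symmetry_map:
            raise SymmetryMapError(f"interface residue {key} missing from symmetry map")
        mate = symmetry_map[key]
        if key not in profile.values or mate not in profile.values:
            raise SymmetryMapError(f"residue {key} or its mate {mate} missing from RMSF profile")
        deltas[key] = profile[key] - profile[mate]
    n_lower = sum(1 for d in deltas.values() if d < 0)
    return RMSFDeltaResult(
        deltas=deltas, n_lower=n_lower, fraction_lower=n_lower / len(deltas)
    )
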