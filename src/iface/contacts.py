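"""Ensemble interface analysis of docked-pose sets.

Given a fixed receptor (here: a C2-symmetric homodimer such as a PAPS
synthase) and an ensemble of docked ligand poses (a sulfotransferase
monomer), these routines detect residue-residue contacts at a distance
cutoff, turn them into per-residue contact prevalence across the ensemble,
fold the two equivalent binding sites of the dimer onto one numbering,
average profiles across ensembles built from different ligand crystal
structures, quantify how strongly the most-contacted residues cluster in
one functional domain, and measure how often the binding site is composite
(built from both dimer subunits at once).

A residue is "in contact" in a pose when the minimum distance between any
selected atom of that residue and any selected atom of any partner residue
is at or below the cutoff (3.0 Å by default, heavy atoms only). Prevalence
counts poses, not atom pairs: a residue touching the partner through four
atoms in one pose still counts once for that pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import CongruenceError, InputError, PartitionError, SymmetryMapError
from .structio import ResidueKey, Structure

__all__ = [
    "ContactSet",
    "PrevalenceProfile",
    "EnsembleProfiles",
    "AveragedProfile",
    "DomainPartition",
    "residue_contacts",
    "prevalence_profile",
    "fold_dimer_symmetry",
    "average_profiles",
    "domain_localization",
    "composite_site_fraction",
]


@dataclass
class ContactSet:
    """Residue-level contacts of one pose, stored once per (receptor, ligand) pair."""

    pairs: frozenset[tuple[ResidueKey, ResidueKey]]
    cutoff: float

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise InputError(f"cutoff must be positive, got {self.cutoff}")

    @property
    def receptor_residues(self) -> frozenset[ResidueKey]:
        return frozenset(r for r, _ in self.pairs)

    @property
    def ligand_residues(self) -> frozenset[ResidueKey]:
        return frozenset(l for _, l in self.pairs)


@dataclass
class PrevalenceProfile:
    """Per-residue contact frequency over an ensemble of poses.

    ``pose_hits`` retains, per residue, the set of pose indices in which the
    residue was in contact; symmetry folding needs this per-pose membership
    (a union over poses cannot be recovered from marginal counts).
    """

    pose_hits: dict[ResidueKey, frozenset[int]]
    n_poses: int
    label: str = ""

    @property
    def frequencies(self) -> dict[ResidueKey, float]:
        return {k: len(v) / self.n_poses for k, v in self.pose_hits.items()}

    @property
    def counts(self) -> dict[ResidueKey, int]:
        return {k: len(v) for k, v in self.pose_hits.items()}

    def __getitem__(self, key: ResidueKey) -> float:
        return len(self.pose_hits[key]) / self.n_poses


@dataclass
class EnsembleProfiles:
    """Receptor-side and ligand-side prevalence from the same ensemble pass."""

    receptor: PrevalenceProfile
    ligand: PrevalenceProfile
    contact_sets: list[ContactSet] = field(default_factory=list)


@dataclass
class AveragedProfile:
    """Per-residue (mean, sample SD) of frequency over ≥2 ensembles."""

    mean: dict[ResidueKey, float]
    sd: dict[ResidueKey, float]
    n_ensembles: int


@dataclass
class DomainPartition:
    """Named residue-number intervals per domain, e.g. APS kinase vs ATP sulfurylase.

    ``intervals`` maps a domain label to a list of (chain_id, start, end)
    author-number ranges, end inclusive. Intervals must not overlap within a
    chain.
    """

    intervals: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self) -> None:
        per_chain: dict[str, list[tuple[int, int, str]]] = {}
        for domain, spans in self.intervals.items():
            for chain, start, end in spans:
                if end < start:
                    raise InputError(f"domain {domain!r}: interval {start}-{end} reversed")
                per_chain.setdefault(chain, []).append((start, end, domain))
        for chain, spans in per_chain.items():
            spans.sort()
            for (s1, e1, d1), (s2, e2, d2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise InputError(
                        f"chain {chain}: domains {d1!r} and {d2!r} overlap "
                        f"({s1}-{e1} vs {s2}-{e2})"
                    )

    def assign(self, key: ResidueKey) -> str:
        chain, number, _ = key
        for domain, spans in self.intervals.items():
            for c, start, end in spans:
                if c == chain and start <= number <= end:
                    return domain
        return "unassigned"


def _side_atoms(
    structure: Structure, chains: set[str], heavy_only: bool
) -> tuple[np.ndarray, list[ResidueKey], list[ResidueKey]]:
    """Selected atom coordinates, their residue keys, and all residue keys of a side."""
    coords: list[np.ndarray] = []
    atom_keys: list[ResidueKey] = []
    all_keys: list[ResidueKey] = []
    for cid in sorted(chains):
        for res in structure.residues(cid):
            all_keys.append(res.key)
            atoms = res.heavy_atoms() if heavy_only else res.atoms
            for atom in atoms:
                coords.append(atom.coord)
                atom_keys.append(res.key)
    return np.asarray(coords, dtype=float).reshape(-1, 3), atom_keys, all_keys


def residue_contacts(
    complex_structure: Structure,
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    cutoff: float = 3.0,
    atoms: str = "heavy",
) -> ContactSet:
    """Residue pairs whose minimum inter-atomic distance is ≤ ``cutoff`` Å.

    ``atoms`` selects ``"heavy"`` (default; hydrogens excluded) or ``"all"``.
    Uses a k-d tree on the ligand atoms; equivalent to the all-pairs distance
    scan but scales with the number of atoms actually near the interface.
    """
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise PartitionError("receptor and ligand chain sets must be non-empty")
    if receptor_chains & ligand_chains:
        raise PartitionError(
            f"receptor/ligand chain sets overlap: {sorted(receptor_chains & ligand_chains)}"
        )
    if not cutoff > 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    if atoms not in ("heavy", "all"):
        raise InputError(f"atoms must be 'heavy' or 'all', got {atoms!r}")
    heavy = atoms == "heavy"

    rec_xyz, rec_keys, _ = _side_atoms(complex_structure, receptor_chains, heavy)
    lig_xyz, lig_keys, _ = _side_atoms(complex_structure, ligand_chains, heavy)

    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    if len(rec_xyz) and len(lig_xyz):
        tree = cKDTree(lig_xyz)
        for i, neighbours in enumerate(tree.query_ball_point(rec_xyz, r=cutoff)):
            for j in neighbours:
                pairs.add((rec_keys[i], lig_keys[j]))
    return ContactSet(pairs=frozenset(pairs), cutoff=cutoff)


def prevalence_profile(
    ensemble: Sequence[Structure],
    receptor_chains: Iterable[str],
    ligand_chains: Iterable[str],
    cutoff: float = 3.0,
    atoms: str = "heavy",
    label: str = "",
) -> EnsembleProfiles:
    """Per-residue contact prevalence over an ensemble of docked poses.

    The receptor residue key space must be identical across poses (the
    receptor is held fixed during docking); the ligand-side profile is
    computed in the same pass.
    """
    if not ensemble:
        raise InputError("ensemble must contain at least one pose")
    receptor_chains, ligand_chains = set(receptor_chains), set(ligand_chains)

    rec_key_space: list[ResidueKey] | None = None
    lig_key_space: list[ResidueKey] | None = None
    rec_hits: dict[ResidueKey, set[int]] = {}
    lig_hits: dict[ResidueKey, set[int]] = {}
    contact_sets: list[ContactSet] = []

    for i, pose in enumerate(ensemble):
        _, _, rec_keys = _side_atoms(pose, receptor_chains, heavy_only=True)
        _, _, lig_keys = _side_atoms(pose, ligand_chains, heavy_only=True)
        if rec_key_space is None:
            rec_key_space = rec_keys
            lig_key_space = lig_keys
            rec_hits = {k: set() for k in rec_keys}
            lig_hits = {k: set() for k in lig_keys}
        elif rec_keys != rec_key_space:
            raise CongruenceError(
                f"pose {i}: receptor residue key space differs from pose 0"
            )
        cs = residue_contacts(pose, receptor_chains, ligand_chains, cutoff=cutoff, atoms=atoms)
        contact_sets.append(cs)
        for key in cs.receptor_residues:
            rec_hits[key].add(i)
        for key in cs.ligand_residues:
            lig_hits.setdefault(key, set()).add(i)

    n = len(ensemble)
    return EnsembleProfiles(
        receptor=PrevalenceProfile(
            {k: frozenset(v) for k, v in rec_hits.items()}, n_poses=n, label=label
        ),
        ligand=PrevalenceProfile(
            {k: frozenset(v) for k, v in lig_hits.items()}, n_poses=n, label=label
        ),
        contact_sets=contact_sets,
    )


def fold_dimer_symmetry(
    profile: PrevalenceProfile, chain_map: Mapping[ResidueKey, ResidueKey]
) -> PrevalenceProfile:
    """Fold the two equivalent binding sites of a C2 dimer onto one numbering.

    ``chain_map`` maps each residue key of the reference subunit to its
    symmetry mate in the other subunit (a bijection covering both subunits).
    The folded count for a position is the number of poses in which the
    residue OR its mate was in contact (union rule: the two sites are
    regarded as equivalent).
    """
    mates = set(chain_map.values())
    if len(mates) != len(chain_map):
        raise SymmetryMapError("chain_map is not injective")
    if mates & set(chain_map.keys()):
        raise SymmetryMapError("chain_map maps a residue onto the reference subunit itself")
    covered = set(chain_map.keys()) | mates
    missing = set(profile.pose_hits) - covered
    if missing:
        raise SymmetryMapError(
            f"chain_map does not cover {len(missing)} profiled residues, "
            f"e.g. {sorted(missing)[:3]}"
        )
    folded: dict[ResidueKey, frozenset[int]] = {}
    for key, mate in chain_map.items():
        folded[key] = profile.pose_hits.get(key, frozenset()) | profile.pose_hits.get(
            mate, frozenset()
        )
    return PrevalenceProfile(folded, n_poses=profile.n_poses, label=profile.label + "|folded")


def average_profiles(profiles: Sequence[PrevalenceProfile]) -> AveragedProfile:
    """Unweighted per-residue mean and sample SD of frequency across ensembles.

    Each ensemble counts once regardless of its pose count, matching the
    convention of averaging the per-crystal-structure docking sets
    symmetrically.
    """
    if len(profiles) < 2:
        raise InputError("need at least 2 profiles to average")
    key_space = set(profiles[0].pose_hits)
    for i, p in enumerate(profiles[1:], start=1):
        if set(p.pose_hits) != key_space:
            raise CongruenceError(f"profile {i} has a different residue key space")
    mean: dict[ResidueKey, float] = {}
    sd: dict[ResidueKey, float] = {}
    for key in key_space:
        freqs = np.array([p[key] for p in profiles])
        mean[key] = float(freqs.mean())
        sd[key] = float(freqs.std(ddof=1))
    return AveragedProfile(mean=mean, sd=sd, n_ensembles=len(profiles))


@dataclass
class LocalizationResult:
    domain_fractions: dict[str, float]
    localization_index: float
    localized: bool
    top_residues: list[ResidueKey]


def domain_localization(
    averaged: AveragedProfile,
    partition: DomainPartition,
    top_k: int = 20,
    localized_threshold: float = 0.8,
) -> LocalizationResult:
    """Share of the top-k most-contacted residues falling in each domain.

    Residues are ranked by mean frequency, ties broken by ascending
    (chain, residue number). The localization index is the largest domain
    share; the profile is called "localized" when that share reaches the
    threshold (0.8 by default) — the quantitative version of frequent
    contacts clustering within one domain rather than scattering over the
    protein.
    """
    if not averaged.mean:
        raise InputError("empty averaged profile")
    if top_k > len(averaged.mean):
        raise InputError(f"top_k={top_k} exceeds {len(averaged.mean)} profiled residues")
    ranked = sorted(averaged.mean.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [key for key, _ in ranked[:top_k]]
    counts: dict[str, int] = {}
    for key in top:
        domain = partition.assign(key)
        counts[domain] = counts.get(domain, 0) + 1
    fractions = {domain: n / top_k for domain, n in counts.items()}
    index = max(fractions.values())
    return LocalizationResult(
        domain_fractions=fractions,
        localization_index=index,
        localized=index >= localized_threshold,
        top_residues=top,
    )


@dataclass
class CompositeSiteResult:
    fraction: float
    per_pose: np.ndarray  # bool vector, one entry per pose


def composite_site_fraction(
    ensemble: Sequence[Structure],
    receptor_chains: Iterable[str] = ("A", "B"),
    ligand_chains: Iterable[str] = ("L",),
    cutoff: float = 3.0,
    min_per_subunit: int = 3,
) -> CompositeSiteResult:
    """Fraction of poses whose interface is composite (built from both subunits).

    A pose is composite when at least ``min_per_subunit`` contacting receptor
    residues come from EACH of the two subunit chains.
    """
    receptor_chains = sorted(set(receptor_chains))
    if len(receptor_chains) != 2:
        raise PartitionError(
            f"composite-site analysis needs exactly 2 receptor chains, got {receptor_chains}"
        )
    if not ensemble:
        raise InputError("ensemble must contain at least one pose")
    flags = []
    for pose in ensemble:
        cs = residue_contacts(pose, receptor_chains, ligand_chains, cutoff=cutoff)
        per_chain = {c: 0 for c in receptor_chains}
        for chain, _, _ in cs.receptor_residues:
            per_chain[chain] += 1
        flags.append(all(per_chain[c] >= min_per_subunit for c in receptor_chains))
    per_pose = np.array(flags, dtype=bool)
    return CompositeSiteResult(fraction=float(per_pose.mean()), per_pose=per_pose)
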