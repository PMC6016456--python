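"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments (seed included): the
same call reproduces byte-identical output, and a "truth" record carrying
the planted ground truth is returned alongside the data so recovery tests
can compare pipeline output against construction.

The structural generators emulate the study geometry — a C2-symmetric
receptor homodimer with a docked monomeric ligand — with deliberately
minimal residues (a Cα plus one pseudo side-chain atom per receptor
residue, one atom per ligand residue). That is sufficient because every
downstream quantity (contacts at 3 Å, prevalence, iRMSD, RMSF) is defined
on heavy-atom distances and residue keys, not on chemistry.

Planted contacts use exact counts, not Bernoulli draws: a residue with
target frequency 0.8 over 30 poses is placed in contact in exactly 24
poses, so prevalence recovery is exact rather than statistical. A
``bernoulli=True`` flag switches to sampled counts for stochastic tests.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import seq3

from .binding import (
    TitrationCurve,
    bound_fraction_depletion,
    competitive_bound_fraction,
    hill_fraction,
)
from .errors import GenerationError, InputError
from .structio import Atom, Residue, ResidueKey, Structure, Trajectory

__all__ = [
    "make_dimer_complex",
    "make_pose_ensemble",
    "make_trajectory",
    "make_msa",
    "make_titration",
    "make_funnel_points",
    "dimer_chain_map",
]

_SPACING = 4.8  # Å between consecutive residues along the chain axis
_CHAIN_OFFSET = 6.0  # Å from the C2 axis to each subunit
_CONTACT_DISTANCE = 2.6  # Å, planted probe-to-Cα distance (margin 0.4 below 3.0)
_FAR_OFFSET = 36.0  # Å, ligand blob clearance from the receptor


def dimer_chain_map(n_res: int, chain_a: str = "A", chain_b: str = "B") -> dict[ResidueKey, ResidueKey]:
    """Residue-key bijection between the two subunits of the synthetic dimer."""
    return {(chain_a, i, ""): (chain_b, i, "") for i in range(1, n_res + 1)}


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def _receptor_chain(chain_id: str, n_res: int, sequence: str, flip: bool) -> list[Residue]:
    """One subunit: residues along x at y = ±offset; chain B is the exact C2
    image (rotation by π about the x axis) of chain A."""
    sign = -1.0 if flip else 1.0
    residues = []
    for i in range(1, n_res + 1):
        ca = np.array([_SPACING * (i - 1), sign * _CHAIN_OFFSET, 0.0])
        cb = ca + np.array([0.0, sign * 1.2, 0.0])
        name3 = seq3(sequence[i - 1]).upper()
        residues.append(
            Residue(chain_id, i, "", name3, [
                Atom("CA", "C", ca), Atom("CB", "C", cb),
            ])
        )
    return residues


def _ligand_chain(
    rng: np.random.Generator,
    n_res: int,
    sequence: str,
    site_keys: Sequence[ResidueKey],
    receptor_ca: Mapping[ResidueKey, np.ndarray],
    jitter_sigma: float = 0.0,
    chain_id: str = "L",
) -> list[Residue]:
    """Ligand residues: one probe atom per planted contact, the rest in a far blob.

    A probe sits ``_CONTACT_DISTANCE`` Å outward (away from the partner
    subunit) from the planted residue's Cα, which keeps every non-planted
    receptor residue at least 3.3 Å from all ligand atoms.
    """
    if len(site_keys) > n_res:
        raise GenerationError(
            f"{len(site_keys)} planted contacts need {len(site_keys)} ligand "
            f"residues but only {n_res} are available"
        )
    coords = []
    for key in site_keys:
        ca = receptor_ca[key]
        sign = 1.0 if key[0] == "A" else -1.0
        dist = _CONTACT_DISTANCE - 0.4 * rng.random()  # within [2.2, 2.6]
        coords.append(ca + np.array([0.0, sign * dist, 0.0]))
    n_blob = n_res - len(site_keys)
    blob_center = np.array([_SPACING * n_blob / 2.0, _FAR_OFFSET, 0.0])
    # the non-contacting body of the ligand moves rigidly between poses
    rigid_shift = rng.normal(0.0, jitter_sigma, size=3) if jitter_sigma > 0 else np.zeros(3)
    for j in range(n_blob):
        coords.append(blob_center + np.array([_SPACING * j, 0.0, 0.0]) + rigid_shift)
    residues = []
    for i, xyz in enumerate(coords, start=1):
        name3 = seq3(sequence[i - 1]).upper()
        residues.append(Residue(chain_id, i, "", name3, [Atom("CA", "C", xyz)]))
    return residues


def make_dimer_complex(
    n_res_per_subunit: int = 30,
    n_res_ligand: int = 20,
    site_residues: Iterable[ResidueKey] | None = None,
    composite: bool = False,
    n_sites: int = 6,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """C2-symmetric dimer (chains A, B) plus a docked ligand monomer (chain L).

    Exactly the ``site_residues`` have heavy atoms within 3.0 Å of the
    ligand (minimum distances ≤ 2.6 Å); every other receptor residue stays
    ≥ 3.3 Å away, so the 3 Å contact cutoff sits inside a ≥ 0.3 Å margin on
    both sides. When ``site_residues`` is omitted, ``n_sites`` residues are
    drawn at random — from both subunits when ``composite``, else from
    chain A only.
    """
    rng = np.random.default_rng(seed)
    seq_rec = _random_sequence(rng, n_res_per_subunit)
    seq_lig = _random_sequence(rng, n_res_ligand)
    if site_residues is None:
        numbers = rng.choice(np.arange(1, n_res_per_subunit + 1), size=n_sites, replace=False)
        if composite:
            half = n_sites // 2
            site_residues = [("A", int(n), "") for n in numbers[:half]] + [
                ("B", int(n), "") for n in numbers[half:]
            ]
        else:
            site_residues = [("A", int(n), "") for n in numbers]
    site_residues = sorted(site_residues)
    for chain, num, _ in site_residues:
        if chain not in ("A", "B") or not 1 <= num <= n_res_per_subunit:
            raise GenerationError(f"planted site residue ({chain}, {num}) outside the receptor")

    chain_a = _receptor_chain("A", n_res_per_subunit, seq_rec, flip=False)
    chain_b = _receptor_chain("B", n_res_per_subunit, seq_rec, flip=True)
    receptor_ca = {r.key: r.atoms[0].coord for r in chain_a + chain_b}
    chain_l = _ligand_chain(rng, n_res_ligand, seq_lig, site_residues, receptor_ca)

    structure = Structure(id="synthetic-dimer-complex", source=f"synth(seed={seed})")
    structure.chains = {"A": chain_a, "B": chain_b, "L": chain_l}
    truth = {
        "site_residues": list(site_residues),
        "chain_map": dimer_chain_map(n_res_per_subunit),
        # C2 operator mapping chain A onto chain B: rotation by π about x
        "symmetry_rotation": np.diag([1.0, -1.0, -1.0]),
        "symmetry_translation": np.zeros(3),
        "receptor_sequence": seq_rec,
        "ligand_sequence": seq_lig,
        "seed": seed,
    }
    return structure, truth


def make_pose_ensemble(
    base: Structure,
    target_freqs: Mapping[ResidueKey, float],
    n_poses: int = 30,
    jitter_sigma: float = 0.5,
    bernoulli: bool = False,
    seed: int = 0,
) -> tuple[list[Structure], dict]:
    """Docked-pose ensemble with planted per-residue contact frequencies.

    For each residue with target frequency f the residue is in contact in
    exactly round(f·n_poses) poses (or a Binomial(n, f) draw when
    ``bernoulli``); contact pose sets are chosen by seeded permutation. The
    receptor is identical across poses; the ligand blob is rigidly jittered
    by ``jitter_sigma``.
    """
    rng = np.random.default_rng(seed)
    n_lig = len(base.chains["L"])
    counts: dict[ResidueKey, int] = {}
    pose_sets: dict[ResidueKey, set[int]] = {}
    for key, f in target_freqs.items():
        if not 0.0 <= f <= 1.0:
            raise InputError(f"target frequency {f} for {key} outside [0, 1]")
        k = int(rng.binomial(n_poses, f)) if bernoulli else int(round(f * n_poses))
        counts[key] = k
        pose_sets[key] = set(rng.permutation(n_poses)[:k].tolist())

    receptor_ca = {
        r.key: r.atoms[0].coord for c in ("A", "B") for r in base.chains[c]
    }
    lig_seq = "".join(
        # recover one-letter codes from residue names for bookkeeping
        _three_to_one(r.name3) for r in base.chains["L"]
    )
    poses = []
    for p in range(n_poses):
        in_contact = sorted(k for k, s in pose_sets.items() if p in s)
        if len(in_contact) > n_lig:
            raise GenerationError(
                f"pose {p}: {len(in_contact)} simultaneous planted contacts "
                f"exceed the {n_lig} ligand residues (conflicting targets)"
            )
        chain_l = _ligand_chain(
            rng, n_lig, lig_seq, in_contact, receptor_ca, jitter_sigma=jitter_sigma
        )
        pose = Structure(id=f"pose-{p:03d}", source=base.source)
        pose.chains = {"A": base.chains["A"], "B": base.chains["B"], "L": chain_l}
        poses.append(pose)
    truth = {
        "target_freqs": dict(target_freqs),
        "planted_counts": counts,
        "planted_freqs": {k: c / n_poses for k, c in counts.items()},
        "pose_sets": {k: sorted(v) for k, v in pose_sets.items()},
        "n_poses": n_poses,
        "seed": seed,
    }
    return poses, truth


def _three_to_one(name3: str) -> str:
    from Bio.SeqUtils import seq1

    one = seq1(name3.capitalize(), undef_code="X")
    return one if one.isalpha() else "X"


def make_trajectory(
    topology: Structure,
    sigma: Mapping[ResidueKey, float] | float,
    n_frames: int = 200,
    dt: float = 2.0,
    drift: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Trajectory of iid isotropic Gaussian displacements around the topology.

    Per-residue amplitudes ``sigma`` (Å per coordinate axis) imply an
    expected RMSF of σ·√3. ``drift`` adds a global rigid translation ramp
    that superposition-based analyses must remove.
    """
    rng = np.random.default_rng(seed)
    base = topology.coords()
    keys = topology.atom_residue_keys()
    if isinstance(sigma, Mapping):
        per_atom = np.array([sigma.get(k, 0.0) for k in keys])
    else:
        per_atom = np.full(len(keys), float(sigma))
    frames = np.empty((n_frames, base.shape[0], 3))
    for f in range(n_frames):
        noise = rng.normal(0.0, 1.0, size=base.shape) * per_atom[:, None]
        frame = base + noise
        if drift:
            frame = frame + np.array([0.01 * f, 0.0, 0.0])
        frames[f] = frame
    traj = Trajectory(topology=topology, frames=frames, dt=dt)
    truth = {
        "sigma": (dict(sigma) if isinstance(sigma, Mapping) else float(sigma)),
        "expected_rmsf": {k: float(s * np.sqrt(3.0)) for k, s in zip(keys, per_atom)},
        "n_frames": n_frames,
        "dt": dt,
        "drift": drift,
        "seed": seed,
    }
    return traj, truth


def make_msa(
    n_rows: int = 12,
    n_clade: int = 4,
    n_cols: int = 60,
    specific_columns: Iterable[int] | Mapping[int, str] = (),
    gap_rate: float = 0.02,
    sub_rate: float = 0.1,
    seed: int = 0,
) -> tuple["Msa", dict]:
    """Alignment with planted clade-specific columns and controlled noise.

    Rows 0..n_clade−1 form the clade ("in"); the rest are "out". Background
    columns carry a per-column consensus residue: clade rows always show the
    consensus and out-clade row 0 is pinned to it, so background noise and
    gaps (restricted to the remaining out-clade rows) can never create a
    spurious clade-specific column. Planted columns give the clade a
    residue drawn from outside the out-clade residue set by construction.
    """
    from .evolution import AA20, Msa, MsaRow

    rng = np.random.default_rng(seed)
    if not 2 <= n_clade < n_rows:
        raise InputError("need 2 ≤ n_clade < n_rows")
    if isinstance(specific_columns, Mapping):
        planted = dict(specific_columns)
    else:
        planted = {int(c): None for c in specific_columns}
    if any(c < 0 or c >= n_cols for c in planted):
        raise InputError("planted column outside the alignment")

    aa = np.array(list(AA20))
    grid = np.empty((n_rows, n_cols), dtype="<U1")
    consensus = rng.choice(aa, size=n_cols)
    for col in range(n_cols):
        c = consensus[col]
        grid[:, col] = c
        if col in planted:
            others = [x for x in AA20 if x != c]
            s = planted[col] or str(rng.choice(others))
            planted[col] = s
            grid[:n_clade, col] = s
            # out-clade rows never carry the planted residue
            pool = [x for x in AA20 if x != s]
            grid[n_clade:, col] = rng.choice(pool, size=n_rows - n_clade)
        else:
            # noise and gaps only in out-clade rows 1.., consensus pinned in row n_clade
            for r in range(n_clade + 1, n_rows):
                u = rng.random()
                if u < gap_rate:
                    grid[r, col] = "-"
                elif u < gap_rate + sub_rate:
                    grid[r, col] = str(rng.choice([x for x in AA20 if x != c]))

    rows = [
        MsaRow(
            id=f"seq{r:02d}",
            clade="in" if r < n_clade else "out",
            seq="".join(grid[r]),
        )
        for r in range(n_rows)
    ]
    msa = Msa(rows=rows)
    truth = {
        "specific_columns": planted,
        "clade_ids": [f"seq{r:02d}" for r in range(n_clade)],
        "consensus": "".join(consensus),
        "degapped": {row.id: row.seq.replace("-", "") for row in rows},
        "seed": seed,
    }
    return msa, truth


def make_titration(
    model: str,
    params: Mapping[str, float],
    x_grid: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TitrationCurve, dict]:
    """Titration curve from an exact forward model plus iid Gaussian noise.

    Models and their parameters:

    - ``single-site``: ligand-depletion bound fraction; kd, probe_conc,
      f_min, f_max.
    - ``hill``: Hill occupancy; k_half, n, probe_conc, f_min, f_max.
    - ``displacement``: exact competitive equilibrium versus competitor
      concentration; probe_kd, competitor_kd, protein_conc, probe_conc,
      top, bottom.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x_grid, dtype=float)
    p = dict(params)
    if model == "single-site":
        fb = bound_fraction_depletion(x, p["probe_conc"], p["kd"])
        y = p["f_min"] + (p["f_max"] - p["f_min"]) * fb
        curve_kwargs = {"probe_conc": p["probe_conc"]}
    elif model == "hill":
        fb = hill_fraction(x, p["k_half"], p["n"])
        y = p["f_min"] + (p["f_max"] - p["f_min"]) * fb
        curve_kwargs = {"probe_conc": p["probe_conc"]}
    elif model == "displacement":
        fb = competitive_bound_fraction(
            x, p["protein_conc"], p["probe_conc"], p["probe_kd"], p["competitor_kd"]
        )
        fb0 = competitive_bound_fraction(
            np.array([0.0]), p["protein_conc"], p["probe_conc"], p["probe_kd"],
            p["competitor_kd"],
        )[0]
        y = p["bottom"] + (p["top"] - p["bottom"]) * fb / fb0
        curve_kwargs = {
            "probe_conc": p["probe_conc"],
            "fixed_protein_conc": p["protein_conc"],
        }
    else:
        raise InputError(f"unknown titration model {model!r}")
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    curve = TitrationCurve(x=x, y=y, **curve_kwargs)
    truth = {"model": model, "params": p, "noise_sigma": noise_sigma, "seed": seed}
    return curve, truth


def make_funnel_points(
    n: int = 200,
    noise_sigma: float = 1.0,
    irmsd_max: float = 10.0,
    shuffled: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """(score, iRMSD) cloud with or without a planted funnel.

    Scores equal iRMSD plus Gaussian noise (a monotone funnel); with
    ``shuffled`` the scores are randomly permuted, destroying the
    score-geometry coupling while keeping both marginals.
    """
    rng = np.random.default_rng(seed)
    irmsd = rng.uniform(0.0, irmsd_max, size=n)
    score = irmsd + rng.normal(0.0, noise_sigma, size=n)
    if shuffled:
        score = rng.permutation(score)
    points = np.column_stack([score, irmsd])
    truth = {"is_funnel": not shuffled, "noise_sigma": noise_sigma, "seed": seed}
    return points, truth
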