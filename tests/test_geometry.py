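"""Superposition, iRMSD, funnel, trajectory RMSD/RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

from iface import (
    average_complex,
    equilibration_time,
    funnel_analysis,
    interface_rmsd,
    kabsch_superpose,
    make_dimer_complex,
    make_funnel_points,
    make_pose_ensemble,
    make_trajectory,
    rmsd_trace,
    rmsf,
    rmsf_delta,
)
from iface.errors import CongruenceError, InputError, SymmetryMapError
from iface.structio import Trajectory
from tests.conftest import horn_quaternion_superpose


def test_identity_superposition():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    res = kabsch_superpose(pts, pts)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(res.translation, 0.0, atol=1e-12)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)


def test_exact_rigid_motion_recovered():
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(25, 3))
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    mobile = ref @ R.T + np.array([1.0, 2.0, 3.0])
    res = kabsch_superpose(mobile, ref)
    assert res.rmsd < 1e-8
    np.testing.assert_allclose(res.apply(mobile), ref, atol=1e-8)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_kabsch_agrees_with_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(10, 3))
    R = Rotation.random(rng=rng).as_matrix()
    mobile = ref @ R.T + rng.normal(size=3) + rng.normal(scale=0.1, size=(10, 3))
    ours = kabsch_superpose(mobile, ref)
    _, _, oracle_rmsd = horn_quaternion_superpose(mobile, ref)
    assert ours.rmsd == pytest.approx(oracle_rmsd, abs=1e-6)
    assert np.linalg.det(ours.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superposition_invariant_under_premotion():
    rng = np.random.default_rng(3)
    ref = rng.normal(size=(12, 3))
    mobile = ref + rng.normal(scale=0.3, size=(12, 3))
    base = kabsch_superpose(mobile, ref).rmsd
    R = Rotation.random(rng=rng).as_matrix()
    moved = mobile @ R.T + np.array([4.0, -7.0, 2.0])
    assert kabsch_superpose(moved, ref).rmsd == pytest.approx(base, abs=1e-8)


def test_kabsch_errors():
    pts = np.zeros((2, 3))
    with pytest.raises(InputError):
        kabsch_superpose(pts, pts)
    with pytest.raises(CongruenceError):
        kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(InputError, match="collinear"):
        kabsch_superpose(line, line)


@pytest.fixture(scope="module")
def jittered_ensemble():
    st, truth = make_dimer_complex(seed=21)
    poses, _ = make_pose_ensemble(
        st, {("A", 3, ""): 1.0, ("A", 5, ""): 0.6}, n_poses=6, jitter_sigma=0.8, seed=22
    )
    return st, truth, poses


def test_average_complex_midpoint(jittered_ensemble):
    st, _, _ = jittered_ensemble
    coords = st.coords()
    lig_mask = st.atom_mask(chains={"L"})
    d = np.array([2.0, 0.0, 0.0])
    plus = st.with_coords(np.where(lig_mask[:, None], coords + d, coords))
    minus = st.with_coords(np.where(lig_mask[:, None], coords - d, coords))
    result = average_complex([plus, minus], receptor_chains={"A", "B"})
    np.testing.assert_allclose(result.reference.coords(), coords, atol=1e-9)


def test_average_complex_identical_poses(jittered_ensemble):
    st, _, _ = jittered_ensemble
    result = average_complex([st, st, st], receptor_chains={"A", "B"})
    np.testing.assert_allclose(result.reference.coords(), st.coords(), atol=1e-9)
    assert result.medoid_index == 0


def test_medoid_matches_brute_force(jittered_ensemble):
    _, _, poses = jittered_ensemble
    result = average_complex(poses, receptor_chains={"A", "B"})
    stacked = result.superposed_coords
    n = stacked.shape[0]
    means = []
    for i in range(n):
        vals = [
            np.sqrt(((stacked[i] - stacked[j]) ** 2).sum(axis=1).mean())
            for j in range(n) if j != i
        ]
        means.append(np.mean(vals))
    assert result.medoid_index == int(np.argmin(means))


def test_interface_rmsd_zero_on_self(jittered_ensemble):
    st, _, _ = jittered_ensemble
    assert interface_rmsd(st, st, {"A", "B"}, {"L"}) == pytest.approx(0.0, abs=1e-12)


def test_interface_rmsd_closed_form():
    """Displace ligand interface CAs by 2 Å with equal receptor/ligand interface
    counts: iRMSD = sqrt(n_lig * 2^2 / (n_lig + n_rec)) = 2/sqrt(2)."""
    st, _ = make_dimer_complex(n_res_per_subunit=8, n_res_ligand=8,
                               site_residues=[("A", i, "") for i in range(1, 9)],
                               seed=30)
    from iface.geometry import _interface_residues

    iface_set = _interface_residues(st, {"A", "B"}, {"L"}, 10.0)
    n_rec = sum(1 for k in iface_set if k[0] in "AB")
    n_lig = sum(1 for k in iface_set if k[0] == "L")
    assert n_rec == n_lig == 8  # every planted residue and its probe

    coords = st.coords()
    lig_mask = st.atom_mask(chains={"L"})
    moved = st.with_coords(np.where(lig_mask[:, None], coords + [0, 0, 2.0], coords))
    value = interface_rmsd(moved, st, {"A", "B"}, {"L"})
    assert value == pytest.approx(2.0 / np.sqrt(2.0), abs=1e-9)


def test_interface_rmsd_direct_recomputation(jittered_ensemble):
    st, _, poses = jittered_ensemble
    from iface.geometry import _interface_residues

    iface_set = _interface_residues(st, {"A", "B"}, {"L"}, 10.0)
    for pose in poses:
        value = interface_rmsd(pose, st, {"A", "B"}, {"L"})
        # brute-force recomputation: fit on receptor CAs, measure interface CAs
        rec_mask = st.atom_mask(chains={"A", "B"}, atom_names=("CA",))
        fit = kabsch_superpose(pose.coords()[rec_mask], st.coords()[rec_mask])
        moved = fit.apply(pose.coords())
        keys = st.atom_residue_keys()
        names = [a.name for _, a in st.atoms()]
        sel = np.array([k in iface_set and n == "CA" for k, n in zip(keys, names)])
        d = moved[sel] - st.coords()[sel]
        assert value == pytest.approx(float(np.sqrt((d * d).sum(1).mean())), abs=1e-9)


def test_interface_cutoff_monotone(jittered_ensemble):
    st, _, _ = jittered_ensemble
    from iface.geometry import _interface_residues

    small = _interface_residues(st, {"A", "B"}, {"L"}, 5.0)
    large = _interface_residues(st, {"A", "B"}, {"L"}, 12.0)
    assert small <= large
    with pytest.raises(InputError):
        interface_rmsd(st, st, {"A", "B"}, {"L"}, interface_cutoff=0.5)


def test_funnel_perfect_monotone():
    irmsd = np.linspace(0.1, 8.0, 40)
    res = funnel_analysis(np.column_stack([irmsd, irmsd]))
    assert res.rho == pytest.approx(1.0)
    assert res.is_funnel
    anti = funnel_analysis(np.column_stack([-irmsd, irmsd]))
    assert anti.rho == pytest.approx(-1.0)
    assert not anti.is_funnel


def test_funnel_vs_shuffled_null():
    pts, truth = make_funnel_points(n=200, seed=7)
    assert funnel_analysis(pts).is_funnel
    null_pts, null_truth = make_funnel_points(n=200, shuffled=True, seed=7)
    assert not funnel_analysis(null_pts).is_funnel
    assert null_truth["is_funnel"] is False


def test_funnel_rho_matches_rank_correlation_oracle():
    for seed in range(20):
        pts, _ = make_funnel_points(n=60, noise_sigma=2.0, seed=seed)
        rho = funnel_analysis(pts).rho
        # from-scratch Spearman: Pearson correlation of the ranks
        rs, ri = rankdata(pts[:, 0]), rankdata(pts[:, 1])
        oracle = float(np.corrcoef(rs, ri)[0, 1])
        assert rho == pytest.approx(oracle, abs=1e-12)


def test_funnel_errors():
    with pytest.raises(InputError):
        funnel_analysis([(1.0, 1.0)] * 10)
    with pytest.raises(InputError, match="constant"):
        funnel_analysis([(1.0, float(i)) for i in range(30)])


@pytest.fixture(scope="module")
def small_traj():
    st, truth = make_dimer_complex(seed=40)
    traj, ttruth = make_trajectory(st, sigma=0.3, n_frames=40, dt=2.0, seed=41)
    return st, traj


def test_rmsd_trace_static_and_translated(small_traj):
    st, _ = small_traj
    static = Trajectory(st, np.repeat(st.coords()[None], 5, axis=0), dt=2.0)
    trace = rmsd_trace(static, st)
    np.testing.assert_allclose(trace[:, 1], 0.0, atol=1e-9)
    np.testing.assert_allclose(trace[:, 0], np.arange(5) * 2.0)

    frames = np.stack([st.coords() + [0.1 * k, 0, 0] for k in range(5)])
    translated = Trajectory(st, frames, dt=2.0)
    np.testing.assert_allclose(rmsd_trace(translated, st)[:, 1], 0.0, atol=1e-9)


def test_rmsd_trace_matches_per_frame_kabsch(small_traj):
    st, traj = small_traj
    trace = rmsd_trace(traj, st)
    mask = st.atom_mask(atom_names=("CA",))
    for i in range(traj.n_frames):
        expected = kabsch_superpose(traj.frames[i][mask], st.coords()[mask]).rmsd
        assert trace[i, 1] == pytest.approx(expected, abs=1e-12)


def test_equilibration_time():
    times = np.arange(50, dtype=float) * 2.0
    const = np.column_stack([times, np.ones(50)])
    res = equilibration_time(const)
    assert res.reached and res.time_ps == 0.0

    rising = np.column_stack([times, np.linspace(0, 10, 50)])
    assert not equilibration_time(rising).reached

    piecewise = np.column_stack([times, np.where(np.arange(50) < 25,
                                                 np.linspace(0, 5, 50), 5.0)])
    piece = equilibration_time(piecewise, window=10, band=0.5)
    assert piece.reached
    assert piece.time_ps == pytest.approx(25 * 2.0, abs=2 * 2.0)

    with pytest.raises(InputError):
        equilibration_time(const, window=100)


def test_rmsf_static_and_single_axis():
    st, _ = make_dimer_complex(seed=50)
    static = Trajectory(st, np.repeat(st.coords()[None], 10, axis=0), dt=1.0)
    profile = rmsf(static)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in profile.values.values())

    # one atom oscillating ±d along x around its mean, align disabled
    frames = np.repeat(st.coords()[None], 10, axis=0)
    d = 0.7
    frames[::2, 0, 0] += d
    frames[1::2, 0, 0] -= d
    osc = Trajectory(st, frames, dt=1.0)
    prof = rmsf(osc, align=False)
    first_key = st.atom_residue_keys()[0]
    assert prof[first_key] == pytest.approx(d, abs=1e-12)
    others = [v for k, v in prof.values.items() if k != first_key]
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in others)


def test_rmsf_closed_form_recovery():
    st, _ = make_dimer_complex(n_res_per_subunit=20, seed=51)
    sigma = 0.5
    traj, truth = make_trajectory(st, sigma=sigma, n_frames=2000, seed=52)
    profile = rmsf(traj)
    expected = sigma * np.sqrt(3.0)
    values = np.array(list(profile.values.values()))
    assert np.all(np.abs(values - expected) / expected < 0.05)


def test_rmsf_order_independence():
    st, _ = make_dimer_complex(seed=53)
    traj, _ = make_trajectory(st, sigma=0.4, n_frames=50, seed=54)
    shuffled = Trajectory(
        st, traj.frames[np.random.default_rng(0).permutation(50)], dt=traj.dt
    )
    a = rmsf(traj).values
    b = rmsf(shuffled).values
    assert all(a[k] == pytest.approx(b[k], abs=1e-9) for k in a)


def test_rmsf_alignment_removes_drift():
    st, _ = make_dimer_complex(seed=55)
    traj, _ = make_trajectory(st, sigma=0.2, n_frames=300, drift=True, seed=56)
    profile = rmsf(traj, align=True)
    expected = 0.2 * np.sqrt(3.0)
    values = np.array(list(profile.values.values()))
    assert np.all(np.abs(values - expected) / expected < 0.2)


def test_rmsf_single_frame_error():
    st, _ = make_dimer_complex(seed=57)
    with pytest.raises(InputError):
        rmsf(Trajectory(st, st.coords()[None], dt=1.0))


def test_rmsf_delta_asymmetric_planting():
    st, truth = make_dimer_complex(n_res_per_subunit=20, seed=60)
    sigma = {}
    for res in st.residues():
        chain = res.chain_id
        sigma[res.key] = 0.25 if chain == "A" else 0.5
    traj, _ = make_trajectory(st, sigma=sigma, n_frames=400, seed=61)
    profile = rmsf(traj)
    interface = [("A", i, "") for i in range(1, 21)]
    delta = rmsf_delta(profile, truth["chain_map"], interface)
    assert delta.fraction_lower == 1.0
    assert all(d < 0 for d in delta.deltas.values())


def test_rmsf_delta_null_symmetry():
    st, truth = make_dimer_complex(n_res_per_subunit=60, seed=62)
    traj, _ = make_trajectory(st, sigma=0.4, n_frames=300, seed=63)
    profile = rmsf(traj)
    interface = [("A", i, "") for i in range(1, 61)]
    delta = rmsf_delta(profile, truth["chain_map"], interface)
    # statistically identical copies: fraction near 0.5 within binomial error
    assert abs(delta.fraction_lower - 0.5) < 3 * 0.5 / np.sqrt(60)


def test_rmsf_delta_errors():
    st, truth = make_dimer_complex(seed=64)
    traj, _ = make_trajectory(st, sigma=0.3, n_frames=20, seed=65)
    profile = rmsf(traj)
    with pytest.raises(InputError):
        rmsf_delta(profile, truth["chain_map"], [])
    with pytest.raises(SymmetryMapError):
        rmsf_delta(profile, truth["chain_map"], [("L", 1, "")])
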