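import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import spinscape as sp


def _frame(positions, mol_ids, masses=None, box=None):
    return sp.FrameCoordinates(np.asarray(positions, float),
                               np.asarray(mol_ids), masses, box)


# ---------------------------------------------------------------------------
# micelle membership


def test_single_candidate_inside_cutoff_included():
    f = _frame([[0, 0, 0], [1.0, 0, 0]], ["pep", "c1"])
    assert sp.micelle_members(f, {"pep"}, {"c1"}, 1.8) == {"c1"}


def test_candidate_beyond_cutoff_excluded():
    f = _frame([[0, 0, 0], [2.5, 0, 0]], ["pep", "c1"])
    assert sp.micelle_members(f, {"pep"}, {"c1"}, 1.8) == set()


def test_hand_placed_distances_select_exactly_three():
    dists = [0.5, 1.3, 1.7, 1.9, 3.0]
    pos = [[0.0, 0.0, 0.0]] + [[d, 0.0, 0.0] for d in dists]
    ids = ["pep"] + [f"c{i}" for i in range(5)]
    members = sp.micelle_members(_frame(pos, ids), {"pep"},
                                 {f"c{i}" for i in range(5)}, 1.8)
    assert members == {"c0", "c1", "c2"}


def test_membership_uses_minimum_image():
    # candidate at x = L - 0.1 is only 0.2 nm from a peptide atom at x = 0.1
    f = _frame([[0.1, 2.0, 2.0], [3.9, 2.0, 2.0]], ["pep", "c1"],
               box=np.array([4.0, 4.0, 4.0]))
    assert sp.micelle_members(f, {"pep"}, {"c1"}, 1.0) == {"c1"}


def test_membership_monotone_in_cutoff():
    rng = np.random.default_rng(5)
    pos = np.vstack([[0, 0, 0], rng.uniform(-3, 3, size=(20, 3))])
    ids = ["pep"] + [f"c{i}" for i in range(20)]
    f = _frame(pos, ids)
    cands = {f"c{i}" for i in range(20)}
    prev = set()
    for cutoff in (0.5, 1.0, 2.0, 4.0, 8.0):
        cur = sp.micelle_members(f, {"pep"}, cands, cutoff)
        assert prev <= cur
        prev = cur


def test_empty_peptide_selection_rejected():
    f = _frame([[0, 0, 0]], ["c1"])
    with pytest.raises(ValueError, match="peptide"):
        sp.micelle_members(f, {"pep"}, {"c1"}, 1.8)


# ---------------------------------------------------------------------------
# radius of gyration


def test_rg_two_point_closed_form():
    f = _frame([[0, 0, 0], [2.0, 0, 0]], ["m", "m"])
    assert sp.radius_of_gyration(f, {"m"}) == pytest.approx(1.0)


def test_rg_coincident_atoms_is_zero():
    f = _frame([[1, 1, 1]] * 4, ["m"] * 4)
    assert sp.radius_of_gyration(f, {"m"}) == pytest.approx(0.0)


def test_rg_unit_cube_closed_form():
    corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                       dtype=float)
    f = _frame(corners, ["m"] * 8)
    assert sp.radius_of_gyration(f, {"m"}) == pytest.approx(np.sqrt(3) / 2, rel=1e-12)


def test_rg_mass_weighting():
    f = _frame([[0, 0, 0], [2.0, 0, 0]], ["m", "m"], masses=np.array([1.0, 3.0]))
    # com at 1.5; Rg^2 = (1*1.5^2 + 3*0.5^2)/4 = 0.75
    assert sp.radius_of_gyration(f, {"m"}) == pytest.approx(np.sqrt(0.75))


def test_rg_rigid_motion_invariance():
    rng = np.random.default_rng(9)
    pos = rng.normal(size=(15, 3))
    f1 = _frame(pos, ["m"] * 15)
    R = Rotation.from_rotvec([0.4, 0.1, -0.9]).as_matrix()
    f2 = _frame(pos @ R.T + np.array([3.0, -1.0, 2.0]), ["m"] * 15)
    assert sp.radius_of_gyration(f2, {"m"}) == pytest.approx(
        sp.radius_of_gyration(f1, {"m"}), rel=1e-12)


# ---------------------------------------------------------------------------
# Stokes-Einstein


def test_required_radius_for_six_ns_timescale():
    # inverting the rigid-sphere relation at tau = 6 ns, 310 K, 0.69 mPa s
    r = sp.invert_radius(6.0, 310.0, 0.69)
    assert round(r, 1) == 3.0


def test_timescale_at_three_nm_is_about_six_ns():
    tau = sp.stokes_einstein_timescale(3.0, 310.0, 0.69)
    assert tau == pytest.approx(6.0, abs=0.3)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(r=st.floats(0.3, 10.0), T=st.floats(270.0, 370.0),
       eta=st.floats(0.2, 10.0))
def test_invert_radius_is_exact_inverse(r, T, eta):
    tau = sp.stokes_einstein_timescale(r, T, eta)
    assert sp.invert_radius(tau, T, eta) == pytest.approx(r, rel=1e-12)


def test_invert_viscosity_round_trip():
    tau = sp.stokes_einstein_timescale(1.6, 310.0, 7.5)
    assert sp.invert_viscosity(tau, 310.0, 1.6) == pytest.approx(7.5, rel=1e-12)


def test_cubic_radius_scaling():
    t1 = sp.stokes_einstein_timescale(1.0, 310.0, 0.69)
    t2 = sp.stokes_einstein_timescale(2.0, 310.0, 0.69)
    assert t2 / t1 == pytest.approx(8.0, rel=1e-12)


def test_standard_convention_is_pi_times_longer():
    a = sp.stokes_einstein_timescale(2.0, 300.0, 1.0, convention="sixpi")
    b = sp.stokes_einstein_timescale(2.0, 300.0, 1.0, convention="standard")
    assert b / a == pytest.approx(np.pi, rel=1e-12)


def test_non_positive_inputs_rejected():
    with pytest.raises(ValueError):
        sp.stokes_einstein_timescale(-1.0, 310.0, 0.69)
    with pytest.raises(ValueError):
        sp.invert_radius(6.0, 0.0, 0.69)


# ---------------------------------------------------------------------------
# principal axes


def _rod(direction, n=5, spacing=0.3):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.arange(n)[:, None] * spacing * d


def test_parallel_rods_angle_zero():
    assert sp.principal_axis_angle(_rod([0, 0, 1]), _rod([0, 0, 1])) == pytest.approx(0.0, abs=1e-6)


def test_perpendicular_rods_angle_ninety():
    assert sp.principal_axis_angle(_rod([0, 0, 1]), _rod([1, 0, 0])) == pytest.approx(90.0, abs=1e-6)


def test_diagonal_rod_angle_forty_five():
    assert sp.principal_axis_angle(_rod([0, 0, 1]), _rod([1, 0, 1])) == pytest.approx(45.0, abs=1e-6)


def test_angle_folds_into_first_quadrant():
    # antiparallel rods are the same axis
    a = _rod([0, 0, 1])
    b = _rod([0, 0, -1])
    assert sp.principal_axis_angle(a, b) == pytest.approx(0.0, abs=1e-6)


def test_degenerate_selection_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        sp.principal_axis_angle(np.zeros((4, 3)), _rod([0, 0, 1]))
    cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                    dtype=float)
    with pytest.raises(ValueError, match="degenerate"):
        sp.principal_axis_angle(cube, _rod([0, 0, 1]))


# ---------------------------------------------------------------------------
# rotation removal


def _rigid_rotation_trajectory(n_frames=8, n_atoms=12, seed=2, noise=0.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3))
    frames = np.empty((n_frames, n_atoms, 3))
    frames[0] = base
    for f in range(1, n_frames):
        R = Rotation.from_rotvec(rng.normal(scale=0.5, size=3)).as_matrix()
        frames[f] = base @ R.T
        if noise:
            frames[f] += rng.normal(scale=noise, size=(n_atoms, 3))
    return frames


def test_pure_rotation_is_exactly_undone():
    frames = _rigid_rotation_trajectory()
    out = sp.remove_rotation(frames)
    for f in range(frames.shape[0]):
        np.testing.assert_allclose(out[f], frames[0], atol=1e-6)


def test_identity_trajectory_unchanged():
    frames = np.tile(_rigid_rotation_trajectory()[0], (5, 1, 1))
    np.testing.assert_allclose(sp.remove_rotation(frames), frames, atol=1e-9)


def test_noisy_rotation_rmsd_bounded_by_noise_floor():
    sigma = 0.01
    frames = _rigid_rotation_trajectory(noise=sigma)
    out = sp.remove_rotation(frames)
    for f in range(1, frames.shape[0]):
        rmsd = np.sqrt(np.mean(np.sum((out[f] - frames[0]) ** 2, axis=1)))
        assert rmsd <= 2 * sigma


def test_remove_rotation_preserves_internal_distances():
    frames = _rigid_rotation_trajectory(noise=0.02)
    out = sp.remove_rotation(frames)
    for f in range(frames.shape[0]):
        d_in = np.linalg.norm(frames[f][:, None] - frames[f][None, :], axis=2)
        d_out = np.linalg.norm(out[f][:, None] - out[f][None, :], axis=2)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)


def test_collinear_reference_rejected():
    frames = np.tile(_rod([0, 0, 1], n=6), (3, 1, 1))
    with pytest.raises(ValueError, match="collinear"):
        sp.remove_rotation(frames)
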