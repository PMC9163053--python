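"""Gauss linking numbers, change-in-linking classification, and the
entanglement arm of the misfold criterion."""

import numpy as np
import pytest

from misfoldscan import synthgen
from misfoldscan.entangle import (CASE_GAIN, CASE_GAIN_SWITCH, CASE_LOSS,
                                  CASE_LOSS_SWITCH, CASE_NO_CHANGE,
                                  CASE_PURE_SWITCH, EntanglementChangeProfile,
                                  change_profile, classify_change,
                                  entangle_misfold_flag, g_timeseries,
                                  gauss_linking, linking_kernel,
                                  native_linking)
from misfoldscan.struct_io import CAStructure, NativeContactMap, Trajectory

from oracles import dense_gauss_integral, rotation_matrix


def ring_and_thread(radius=5.0, n_ring=12, z_dir=1.0, n_pad=6):
    """Planar ring closed by a contact, C-tail passing once through its
    center perpendicular to the plane. Returns (coords, contact)."""
    ang = 2 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n_ring)])
    # N-pad approaching in-plane from outside
    n_pad_pts = np.column_stack([radius + 3.0 * np.arange(n_pad, 0, -1),
                                 np.zeros(n_pad), np.zeros(n_pad)])
    # connector descending outside the disk, then under the center
    conn = np.array([[radius + 4.0, 0, 0],
                     [radius + 4.0, 0, -z_dir * 9.0],
                     [0.3, 0.0, -z_dir * 9.0]])
    # the passage itself plus a C-pad continuing away
    zs = z_dir * np.linspace(-6.0, 9.0, 6)
    thread = np.column_stack([np.full(6, 0.3), np.zeros(6), zs])
    c_pad = np.column_stack([np.full(n_pad, 0.3), np.zeros(n_pad),
                             z_dir * (9.0 + 3.0 * np.arange(1, n_pad + 1))])
    coords = np.vstack([n_pad_pts, ring, conn, thread, c_pad])
    i, j = n_pad + 1, n_pad + n_ring
    return coords, (i, j)


def oracle_g(coords, contact, n):
    """Independent 100×-refined Gauss double integral over the counted
    ranges: loop residues i..j vs C-tail residues j+4..N−5."""
    i, j = contact
    return dense_gauss_integral(coords[i - 1:j], coords[j + 3:n - 5])


class TestGaussLinking:
    def test_coplanar_disjoint_loop_and_tails_unentangled(self):
        # loop and both tails all in the z = 0 plane, tails outside the disk
        ang = 2 * np.pi * np.arange(12) / 12
        ring = np.column_stack([5 * np.cos(ang), 5 * np.sin(ang), np.zeros(12)])
        n_tail = np.column_stack([5 + 3.0 * np.arange(8, 0, -1), np.zeros(8),
                                  np.zeros(8)])
        c_tail = np.column_stack([5 + 3.0 * np.arange(1, 13),
                                  np.full(12, -2.0), np.zeros(12)])
        coords = np.vstack([n_tail, ring, c_tail])
        s = CAStructure(coords, synthetic_stretched=True)
        assert gauss_linking(s, (9, 20)).g == 0

    def test_single_thread_matches_dense_oracle_and_mirror(self):
        coords, contact = ring_and_thread()
        s = CAStructure(coords, synthetic_stretched=True)
        res = gauss_linking(s, contact)
        assert abs(res.g_c) == 1
        # fine-grained numerical double-integral oracle
        expected = oracle_g(coords, contact, coords.shape[0])
        assert abs(res.g_c_raw - expected) < 0.05
        # mirror image flips the sign
        mirrored = coords.copy()
        mirrored[:, 2] *= -1
        res_m = gauss_linking(CAStructure(mirrored, synthetic_stretched=True),
                              contact)
        assert res_m.g_c == -res.g_c

    def test_double_thread_magnitude_two(self, loop_thread_system):
        spec = synthgen.SyntheticSpec(recipe="loop_thread", planted_g=2,
                                      n_residues=60, seed=1)
        _, contacts = synthgen.make_structure(spec)
        ent = synthgen.make_entangled_structure(spec)
        contact = tuple(contacts.pairs[0])
        res = gauss_linking(ent, contact)
        assert abs(res.g) == 2
        expected = oracle_g(ent.coords, contact, ent.n_residues)
        assert abs(res.g_c_raw - expected) < 0.1

    def test_discretized_sum_converges_to_dense_oracle(self):
        coords, contact = ring_and_thread()
        res = gauss_linking(CAStructure(coords, synthetic_stretched=True),
                            contact)
        coarse = res.g_c_raw
        dense = oracle_g(coords, contact, coords.shape[0])
        denser = dense_gauss_integral(
            coords[contact[0] - 1:contact[1]],
            coords[contact[1] + 3:coords.shape[0] - 5], refine=200)
        # refinement changes the value far less than the coarse-dense gap
        assert abs(dense - denser) < 1e-3
        assert abs(coarse - dense) < 0.05

    def test_invalid_contact_rejected(self):
        coords, _ = ring_and_thread()
        s = CAStructure(coords, synthetic_stretched=True)
        with pytest.raises(ValueError):
            gauss_linking(s, (5, 500))

    def test_empty_ranges_give_zero_partials(self):
        coords, _ = ring_and_thread()
        s = CAStructure(coords, synthetic_stretched=True)
        n = s.n_residues
        # contact hugging the termini leaves no counted tail segments
        res = gauss_linking(s, (1, n))
        assert res.g_n_raw == 0.0 and res.g_c_raw == 0.0 and res.g == 0

    def test_singular_midpoints_skipped_with_warning(self):
        coords, contact = ring_and_thread()
        coords[0] = coords[2]
        coords[1] = coords[3]  # duplicate a segment -> coincident midpoints
        with pytest.warns(RuntimeWarning, match="midpoint"):
            linking_kernel(coords)


class TestLinkingInvariances:
    def test_rigid_motion_and_uniform_scaling(self):
        coords, contact = ring_and_thread()
        s = CAStructure(coords, synthetic_stretched=True)
        base = gauss_linking(s, contact)
        rot = rotation_matrix([0.3, -1, 2], 0.9)
        moved = CAStructure(coords @ rot.T + np.array([10.0, -4.0, 2.0]),
                            synthetic_stretched=True)
        assert gauss_linking(moved, contact).g == base.g
        scaled = CAStructure(coords * 2.5, synthetic_stretched=True)
        res_s = gauss_linking(scaled, contact)
        assert res_s.g == base.g
        assert abs(res_s.g_c_raw - base.g_c_raw) < 1e-9

    def test_mirror_flips_every_partial(self):
        for g in (-2, -1, 1, 2):
            spec = synthgen.SyntheticSpec(recipe="loop_thread", planted_g=g,
                                          n_residues=60, seed=4)
            _, contacts = synthgen.make_structure(spec)
            ent = synthgen.make_entangled_structure(spec)
            contact = tuple(contacts.pairs[0])
            res = gauss_linking(ent, contact)
            mir = ent.coords.copy()
            mir[:, 2] *= -1
            res_m = gauss_linking(CAStructure(mir, synthetic_stretched=True),
                                  contact)
            assert res_m.g_n_raw == pytest.approx(-res.g_n_raw)
            assert res_m.g_c_raw == pytest.approx(-res.g_c_raw)

    def test_nonthreading_random_placements_give_zero(self):
        rng = np.random.default_rng(42)
        ang = 2 * np.pi * np.arange(12) / 12
        ring = np.column_stack([5 * np.cos(ang), 5 * np.sin(ang), np.zeros(12)])
        hits = 0
        for _ in range(25):
            # random straight tail far outside the loop's convex hull
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            origin = rng.normal(size=3)
            origin *= (40.0 / np.linalg.norm(origin))
            tail = origin + 3.0 * np.arange(14)[:, None] * direction
            conn = np.array([[5 + 3.0, 0, 0], [origin[0], origin[1], origin[2]]])
            coords = np.vstack([
                np.column_stack([5 + 3.0 * np.arange(6, 0, -1), np.zeros(6),
                                 np.zeros(6)]),
                ring, conn, tail])
            s = CAStructure(coords, synthetic_stretched=True)
            hits += gauss_linking(s, (7, 18)).g != 0
        assert hits == 0


class TestPlantedRecovery:
    @pytest.mark.parametrize("planted", [-2, -1, 0, 1, 2])
    def test_all_planted_linking_numbers_recovered(self, planted):
        """Every planted g in {-2..+2} recovered across 10 seeds each."""
        for seed in range(10):
            spec = synthgen.SyntheticSpec(recipe="loop_thread",
                                          planted_g=planted, n_residues=60,
                                          seed=seed)
            native, contacts = synthgen.make_structure(spec)
            struct = (synthgen.make_entangled_structure(spec) if planted
                      else native)
            res = gauss_linking(struct, tuple(contacts.pairs[0]))
            assert res.g == planted, f"seed {seed}: got {res.g}"


class TestClassifyChange:
    @pytest.mark.parametrize("gn, gf, expected", [
        (0, 0, CASE_NO_CHANGE),
        (1, 1, CASE_NO_CHANGE),
        (-2, -2, CASE_NO_CHANGE),
        (0, 1, CASE_GAIN),
        (0, -2, CASE_GAIN),
        (1, 2, CASE_GAIN),
        (-1, -2, CASE_GAIN),
        (1, 0, CASE_LOSS),
        (-2, -1, CASE_LOSS),
        (2, 0, CASE_LOSS),
        (1, -2, CASE_GAIN_SWITCH),
        (-1, 2, CASE_GAIN_SWITCH),
        (2, -1, CASE_LOSS_SWITCH),
        (-2, 1, CASE_LOSS_SWITCH),
        (1, -1, CASE_PURE_SWITCH),
        (-2, 2, CASE_PURE_SWITCH),
    ])
    def test_taxonomy(self, gn, gf, expected):
        assert classify_change(gn, gf) == expected

    def test_exhaustive_partition(self):
        # every (g_native, g_frame) pair lands in exactly one case
        for gn in range(-3, 4):
            for gf in range(-3, 4):
                k = classify_change(gn, gf)
                assert 0 <= k <= 5
                assert (k == CASE_NO_CHANGE) == (gn == gf)


def _mini_traj(frames, dt=1.0):
    coords = np.stack([f for f in frames])
    top = CAStructure(coords[0], synthetic_stretched=True)
    return Trajectory(coords, dt * np.arange(coords.shape[0]), top)


class TestChangeProfile:
    def test_native_trajectory_has_zero_fc(self, loop_thread_system):
        spec, native, contacts, _ = loop_thread_system
        g_nat = native_linking(native, contacts)
        traj = _mini_traj([native.coords] * 5)
        ref = np.array([0, 0, 0, 0, 0, 1.0])
        profile = change_profile(traj, contacts, g_nat, ref_profile=ref)
        np.testing.assert_allclose(profile.f_c, 0.0)
        assert not profile.entangled

    def test_planted_half_and_half_arithmetic(self, loop_thread_system):
        spec, native, contacts, entangled = loop_thread_system
        g_nat = native_linking(native, contacts)
        # half the frames entangled (case 0: gain), half native (case 5)
        frames = [entangled.coords] * 4 + [native.coords] * 4
        traj = _mini_traj(frames)
        ref = np.array([0.1, 0, 0, 0, 0, 0.9])
        profile = change_profile(traj, contacts, g_nat, ref_profile=ref)
        assert profile.p[0] == pytest.approx(0.5)
        assert profile.p[5] == pytest.approx(0.5)
        assert profile.f_c[0] == pytest.approx(abs(0.5 - 0.1))

    def test_profile_equals_exhaustive_label_count(self, loop_thread_system):
        spec, native, contacts, entangled = loop_thread_system
        g_nat = native_linking(native, contacts)
        rng = np.random.default_rng(9)
        picks = rng.random(12) < 0.4
        frames = [entangled.coords if p else native.coords for p in picks]
        traj = _mini_traj(frames)
        profile = change_profile(traj, contacts, g_nat)
        counts = np.zeros(6)
        for lab in profile.case_labels.ravel():
            counts[lab] += 1
        np.testing.assert_allclose(profile.p, counts / counts.sum())
        assert profile.n_instances == 12 * contacts.n_contacts


class TestGTimeseries:
    def test_native_frame_zero_and_full_change_one(self, loop_thread_system):
        spec, native, contacts, entangled = loop_thread_system
        g_nat = native_linking(native, contacts)
        traj = _mini_traj([native.coords, entangled.coords])
        g_t = g_timeseries(traj, contacts, g_nat)
        assert g_t[0] == 0.0
        # the loop contact stays formed in the threaded conformation and its
        # g changed -> every (single) contact counts
        assert g_t[1] == 1.0

    def test_planted_changed_fraction(self, helix_system):
        _, native, contacts = helix_system
        g_nat = native_linking(native, contacts)
        traj = _mini_traj([native.coords] * 3)
        np.testing.assert_allclose(g_timeseries(traj, contacts, g_nat), 0.0)


class TestMisfoldFlag:
    def _profile(self, fractions, ref, times=None):
        f = np.asarray(fractions, dtype=float)
        times = np.arange(f.shape[0], dtype=float) if times is None else times
        return EntanglementChangeProfile(
            times=times, case_labels=np.zeros((f.shape[0], 1), int),
            case_counts=np.zeros(6), p=np.zeros(6), g_t=np.zeros(f.shape[0]),
            frame_fractions=f, ref_profile=np.asarray(ref, dtype=float))

    def test_all_zero_fc_is_false(self):
        ref = np.array([0, 0, 0, 0, 0, 1.0])
        prof = self._profile(np.tile([0, 0, 0, 0, 0, 1.0], (5, 1)), ref)
        assert not entangle_misfold_flag(prof, tail_ns=4)

    def test_large_fc_is_true(self):
        ref = np.zeros(6)
        frac = np.tile([0, 0, 0.5, 0, 0, 0.5], (5, 1))
        assert entangle_misfold_flag(self._profile(frac, ref), tail_ns=4)

    def test_boundary_exactly_point_one_is_true(self):
        ref = np.zeros(6)
        frac = np.tile([0.1, 0, 0, 0, 0, 0.9], (5, 1))
        assert entangle_misfold_flag(self._profile(frac, ref), tail_ns=4)
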