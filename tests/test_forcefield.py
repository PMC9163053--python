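"""Potential-energy terms: well depths, 12-10-6 minima, screening, and an
independent brute-force re-implementation oracle."""

import numpy as np
import pytest

from misfoldscan.forcefield import (COULOMB_KCAL, ForceFieldParams,
                                    NativeContactParams, bond_angles,
                                    contact_well_depth, dihedral_angles,
                                    potential_energy)
from misfoldscan.struct_io import CAStructure, NativeContactMap

from oracles import rotation_matrix


class TestWellDepth:
    def test_two_hbond_contact(self):
        p = NativeContactParams({(1, 5): 2}, {(1, 5): 0.5}, eta=1.0)
        assert contact_well_depth(p, (1, 5)) == pytest.approx(2 * 0.75 + 0.5)

    def test_zero_hbonds_zero_eta(self):
        p = NativeContactParams({(1, 5): 0}, {(1, 5): 0.4}, eta=0.0)
        assert contact_well_depth(p, (1, 5)) == 0.0

    def test_mixed_terms(self):
        p = NativeContactParams({(2, 9): 1}, {(2, 9): 0.4}, eta=1.2)
        assert contact_well_depth(p, (2, 9)) == pytest.approx(1.23)

    def test_unknown_pair(self):
        p = NativeContactParams({}, {})
        with pytest.raises(KeyError):
            contact_well_depth(p, (1, 2))

    def test_negative_hbond_count_rejected(self):
        with pytest.raises(ValueError):
            NativeContactParams({(1, 5): -1}, {(1, 5): 0.1})


def _toy_params(n, rng=None, sigma=5.0, eps=1.0, pairs=()):
    n_torsions = max(n - 3, 0)
    charges = np.zeros(n)
    if rng is not None:
        charges = rng.choice([-1.0, 0.0, 1.0], size=n)
        tk = rng.uniform(0, 0.5, (n_torsions, 4))
        td = rng.uniform(-np.pi, np.pi, (n_torsions, 4))
    else:
        tk = np.zeros((n_torsions, 4))
        td = np.zeros((n_torsions, 4))
    return ForceFieldParams(
        k_bond=50.0, r0=3.8, torsion_k=tk, torsion_delta=td,
        k_alpha=106.4, k_beta=26.3, theta_alpha=1.6, theta_beta=2.27,
        eps_alpha=4.3, gamma=0.1, charges=charges, eps_r=78.5,
        debye_length=10.0,
        contact_eps={p: eps for p in pairs},
        contact_sigma={p: sigma for p in pairs})


class TestNativeTerm:
    def test_minimum_at_sigma_depth_eps(self):
        # two interacting beads held at r = sigma by padding the chain
        sigma, eps = 6.0, 2.5
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0],
                           [0, 3.8, 0], [0, sigma, 0],
                           [0, sigma + 3.8, 0.0]])
        s = CAStructure(coords, synthetic_stretched=True)
        cmap = NativeContactMap(np.array([[1, 5]]), np.array([sigma]))
        params = _toy_params(6, sigma=sigma, eps=eps, pairs=[(1, 5)])
        params.eps_nonnative = 0.0
        d15 = np.linalg.norm(coords[0] - coords[4])
        assert d15 == pytest.approx(sigma)
        rec = potential_energy(s, params, cmap)
        assert rec.native == pytest.approx(-eps)
        # numerical derivative at the minimum vanishes
        def native_at(dr):
            c = coords.copy()
            c[4, 1] += dr
            return potential_energy(CAStructure(c, synthetic_stretched=True),
                                    params, cmap).native
        deriv = (native_at(1e-5) - native_at(-1e-5)) / 2e-5
        assert abs(deriv) < 1e-5

    def test_screened_coulomb_decays(self):
        # identical charge pair at r = l_D vs r = 10 l_D
        def elec(r):
            coords = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0],
                               [3.8 - r, 3.8, 0.0]])
            s = CAStructure(coords, synthetic_stretched=True)
            params = _toy_params(4)
            params.charges = np.array([1.0, 0, 0, 1.0])
            params.nonbonded_min_separation = 3
            params.eps_nonnative = 0.0
            empty = NativeContactMap(np.empty((0, 2), int), np.empty(0))
            return potential_energy(s, params, empty).electrostatic
        ld = 10.0
        assert abs(elec(10 * ld)) < 1e-3 * abs(elec(ld))

    def test_zero_distance_rejected(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0],
                           [3.8, 7.6, 0], [0.0, 7.6, 0], [0, 0, 0.0]])
        s = CAStructure(coords, synthetic_stretched=True)
        params = _toy_params(6)
        empty = NativeContactMap(np.empty((0, 2), int), np.empty(0))
        with pytest.raises(ValueError, match="zero"):
            potential_energy(s, params, empty)


def brute_force_energy(coords, params, native_pairs):
    """Term-by-term independent re-implementation with explicit loops."""
    n = len(coords)
    e_bond = sum(params.k_bond * (np.linalg.norm(coords[i + 1] - coords[i])
                                  - params.r0) ** 2 for i in range(n - 1))
    e_angle = 0.0
    for i in range(n - 2):
        u, v = coords[i] - coords[i + 1], coords[i + 2] - coords[i + 1]
        th = np.arccos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v))
        ea = params.k_alpha * (th - params.theta_alpha) ** 2 + params.eps_alpha
        eb = params.k_beta * (th - params.theta_beta) ** 2
        e_angle += -np.log(np.exp(-params.gamma * ea)
                           + np.exp(-params.gamma * eb)) / params.gamma
    e_tor = 0.0
    for i in range(n - 3):
        b1, b2, b3 = (coords[i + 1] - coords[i], coords[i + 2] - coords[i + 1],
                      coords[i + 3] - coords[i + 2])
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(np.dot(m1, n2), np.dot(n1, n2))
        for j in range(1, 5):
            e_tor += params.torsion_k[i, j - 1] * (
                1 + np.cos(j * phi - params.torsion_delta[i, j - 1]))
    e_el = e_nat = e_nn = 0.0
    for i in range(n):
        for j in range(i + params.nonbonded_min_separation, n):
            r = np.linalg.norm(coords[i] - coords[j])
            e_el += (COULOMB_KCAL * params.charges[i] * params.charges[j]
                     / (params.eps_r * r) * np.exp(-r / params.debye_length))
            if (i + 1, j + 1) in native_pairs:
                sig = params.contact_sigma[(i + 1, j + 1)]
                eps = params.contact_eps[(i + 1, j + 1)]
                e_nat += eps * (13 * (sig / r) ** 12 - 18 * (sig / r) ** 10
                                + 4 * (sig / r) ** 6)
            else:
                sig = params.sigma_nonnative
                e_nn += params.eps_nonnative * (
                    13 * (sig / r) ** 12 - 18 * (sig / r) ** 10
                    + 4 * (sig / r) ** 6)
    return e_bond + e_tor + e_angle + e_el + e_nat + e_nn


class TestFullEnergy:
    def _random_system(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        # random-walk chain with ~3.8 Å steps
        steps = rng.normal(size=(n - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        s = CAStructure(coords, synthetic_stretched=True)
        pairs = [(2, 9), (4, 15), (7, 19)]
        params = _toy_params(n, rng=rng, pairs=pairs)
        cmap = NativeContactMap(np.array(pairs),
                                np.array([np.linalg.norm(coords[i - 1]
                                                         - coords[j - 1])
                                          for i, j in pairs]))
        return s, params, cmap, set(pairs)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        s, params, cmap, pairs = self._random_system(seed)
        rec = potential_energy(s, params, cmap)
        oracle = brute_force_energy(s.coords, params, pairs)
        assert rec.total == pytest.approx(oracle, rel=1e-8)

    def test_rigid_motion_invariance(self):
        s, params, cmap, _ = self._random_system(5)
        rec = potential_energy(s, params, cmap)
        moved = s.transformed(rotation_matrix([1, 1, 0], 0.7), [3.0, -8.0, 1.0])
        rec2 = potential_energy(moved, params, cmap)
        assert rec2.total == pytest.approx(rec.total, rel=1e-8)

    def test_double_well_large_gamma_limit(self):
        # near theta_alpha with eps_alpha < 0, the alpha well dominates as
        # gamma grows (log-sum-exp -> min of the two wells)
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [5.0, 3.6, 0],
                           [8.8, 3.6, 0.0]])
        s = CAStructure(coords, synthetic_stretched=True)
        theta = bond_angles(coords)[0]
        deep = None
        for gamma in (0.05, 1.0, 50.0):
            params = _toy_params(4)
            params.gamma = gamma
            params.theta_alpha = theta
            params.eps_alpha = -2.0
            empty = NativeContactMap(np.empty((0, 2), int), np.empty(0))
            rec = potential_energy(s, params, empty)
            deep = rec.angle
        # at large gamma the angle term approaches the deeper single well
        expected = min(-2.0, params.k_beta * (theta - params.theta_beta) ** 2) * 2
        assert deep == pytest.approx(sum(
            min(params.k_alpha * (t - params.theta_alpha) ** 2 - 2.0,
                params.k_beta * (t - params.theta_beta) ** 2)
            for t in bond_angles(coords)), abs=1e-2)

    def test_missing_torsion_parameters_rejected(self):
        s, params, cmap, _ = self._random_system(6)
        params.torsion_k = params.torsion_k[:3]
        params.torsion_delta = params.torsion_delta[:3]
        with pytest.raises(KeyError, match="torsion"):
            potential_energy(s, params, cmap)

    def test_parameter_file_round_trip_json_and_yaml(self, tmp_path):
        import json

        import yaml

        from misfoldscan.forcefield import load_forcefield_params

        payload = {
            "bonds": {"k_b": 50.0, "r0": 3.8},
            "torsions": {"k": [[0.3, 0.2, 0.1, 0.05]],
                         "delta": [[0.0, 1.0, 2.0, 3.0]]},
            "angles": {"k_alpha": 106.4, "k_beta": 26.3, "theta_alpha": 1.6,
                       "theta_beta": 2.27, "eps_alpha": 4.3, "gamma": 0.1},
            "charges": {"q": [0.0, 1.0, 0.0, -1.0], "eps_r": 78.5,
                        "debye_length": 10.0},
            "contacts": [[1, 4, 1.5, 5.5]],
        }
        jf = tmp_path / "ff.json"
        jf.write_text(json.dumps(payload))
        yf = tmp_path / "ff.yaml"
        yf.write_text(yaml.safe_dump(payload))
        pj = load_forcefield_params(jf)
        py = load_forcefield_params(yf)
        assert pj.contact_eps == {(1, 4): 1.5} == py.contact_eps
        assert pj.k_bond == py.k_bond == 50.0
        np.testing.assert_allclose(pj.torsion_delta, py.torsion_delta)

    def test_dihedral_sign_right_hand_rule(self):
        # +90° twist about the central bond
        coords = np.array([[0, -3.8, 0], [0, 0, 0], [3.8, 0, 0],
                           [3.8, 0, 3.8]], dtype=float)
        phi = dihedral_angles(coords)[0]
        mirrored = coords.copy()
        mirrored[:, 2] *= -1
        assert dihedral_angles(mirrored)[0] == pytest.approx(-phi)
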