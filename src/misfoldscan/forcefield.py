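"""Coarse-grain potential-energy evaluation for validation and synthetic-
structure sanity checks. No dynamics.

The Cα-bead Gō-type potential is a sum of six terms: harmonic virtual bonds,
a four-term cosine torsion series, a double-well bond-angle potential (a
softmin of an α-favouring and a β-favouring well, controlled by the mixing
parameter γ), Debye–Hückel screened electrostatics, a 12-10-6 attractive well
on native contact pairs, and the same 12-10-6 form with a small ε acting as
repulsion on non-native pairs::

    E = Σ k_b (r − r₀)²
      + Σ_i Σ_{j=1..4} k_φ,ij (1 + cos[j φ_i − δ_ij])
      + Σ_i −(1/γ) ln{ e^{−γ(k_α(θ−θ_α)² + ε_α)} + e^{−γ k_β(θ−θ_β)²} }
      + Σ_{ij} q_i q_j e²/(4π ε₀ ε_r r_ij) · e^{−r_ij/l_D}
      + Σ_{ij ∈ NC} ε_ij^NC [13(σ/r)¹² − 18(σ/r)¹⁰ + 4(σ/r)⁶]
      + Σ_{ij ∉ NC} ε_ij^NN [13(σ/r)¹² − 18(σ/r)¹⁰ + 4(σ/r)⁶]

The 12-10-6 native well has its minimum exactly at (σ_ij, −ε_ij^NC) since
13 − 18 + 4 = −1 and the radial derivative vanishes at σ. Native well depths
follow ε_ij^NC = n_ij·ε_HB + η·ε_ij with ε_HB = 0.75 kcal/mol, n_ij the
hydrogen-bond count of the contact and ε_ij a pairwise statistical-potential
energy scaled by the domain/interface factor η (statistical-potential tables
and per-protein η values are inputs, not hard-coded).

Angles are radians internally; dihedral sign by the right-hand rule on
(i, i+1, i+2, i+3); energies in kcal/mol, distances in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .struct_io import CAStructure, NativeContactMap

__all__ = [
    "NativeContactParams",
    "ForceFieldParams",
    "EnergyRecord",
    "contact_well_depth",
    "potential_energy",
    "bond_angles",
    "dihedral_angles",
    "load_forcefield_params",
]

EPS_HB = 0.75  # kcal/mol per hydrogen bond
#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_KCAL = 332.0637


@dataclass
class NativeContactParams:
    """Per-contact well-depth inputs: ε_ij^NC = n_ij·ε_HB + η·ε_ij."""

    n_hbonds: dict  # (i, j) -> integer hydrogen-bond count
    eps_pair: dict  # (i, j) -> statistical-potential ε_ij (kcal/mol)
    eta: float = 1.0
    eps_hb: float = EPS_HB

    def __post_init__(self) -> None:
        for pair, n in self.n_hbonds.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"n_ij for {pair} must be a non-negative integer")


def contact_well_depth(params: NativeContactParams, pair) -> float:
    """Native-contact well depth ε_ij^NC = n_ij·ε_HB + η·ε_ij (kcal/mol)."""
    pair = (int(pair[0]), int(pair[1]))
    if pair not in params.n_hbonds or pair not in params.eps_pair:
        raise KeyError(f"contact {pair} not in parameter table")
    return params.n_hbonds[pair] * params.eps_hb + params.eta * params.eps_pair[pair]


@dataclass
class ForceFieldParams:
    """Full parameter set of the coarse-grain potential."""

    k_bond: float  # kcal/mol/Å²
    r0: float  # Å
    torsion_k: np.ndarray  # (n_torsions, 4) kcal/mol
    torsion_delta: np.ndarray  # (n_torsions, 4) rad
    k_alpha: float
    k_beta: float
    theta_alpha: float  # rad
    theta_beta: float  # rad
    eps_alpha: float
    gamma: float
    charges: np.ndarray  # (N,) elementary charges
    eps_r: float  # relative permittivity
    debye_length: float  # Å
    contact_eps: dict  # (i, j) -> ε_ij^NC > 0 (kcal/mol)
    contact_sigma: dict  # (i, j) -> σ_ij (Å)
    eps_nonnative: float = 0.000132  # kcal/mol
    sigma_nonnative: float = 5.0  # Å
    nonbonded_min_separation: int = 4

    def __post_init__(self) -> None:
        if self.k_bond <= 0 or self.gamma <= 0 or self.debye_length <= 0:
            raise ValueError("k_b, γ and l_D must be positive")
        if any(s <= 0 for s in self.contact_sigma.values()):
            raise ValueError("σ_ij must be positive")
        if any(e <= 0 for e in self.contact_eps.values()):
            raise ValueError("ε_ij^NC must be positive")
        self.torsion_k = np.atleast_2d(np.asarray(self.torsion_k, dtype=float))
        self.torsion_delta = np.atleast_2d(np.asarray(self.torsion_delta,
                                                      dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)


@dataclass
class EnergyRecord:
    """Per-term potential energies (kcal/mol) and their sum."""

    bond: float
    torsion: float
    angle: float
    electrostatic: float
    native: float
    nonnative: float

    @property
    def total(self) -> float:
        return (self.bond + self.torsion + self.angle + self.electrostatic
                + self.native + self.nonnative)

    def as_tsv(self) -> str:
        header = "bond\ttorsion\tangle\telectrostatic\tnative\tnonnative\ttotal"
        vals = [self.bond, self.torsion, self.angle, self.electrostatic,
                self.native, self.nonnative, self.total]
        return header + "\n" + "\t".join(f"{v:.6f}" for v in vals)


def load_forcefield_params(path) -> ForceFieldParams:
    """Read a parameter file (JSON or YAML) into :class:`ForceFieldParams`.

    Expected sections: ``bonds`` (k_b, r0), ``torsions`` (k: n×4, delta:
    n×4, degrees optional via ``degrees: true``), ``angles`` (k_alpha,
    k_beta, theta_alpha, theta_beta, eps_alpha, gamma — angles in radians
    unless ``degrees``), ``charges`` (q per residue, eps_r, debye_length),
    ``contacts`` (list of [i, j, eps, sigma]), and optionally ``nonnative``
    (eps, sigma, min_separation).
    """
    import json
    from pathlib import Path

    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)

    ang = payload["angles"]
    tor = payload["torsions"]
    scale = np.pi / 180.0 if payload.get("degrees") else 1.0
    contacts = payload.get("contacts", [])
    nn = payload.get("nonnative", {})
    return ForceFieldParams(
        k_bond=payload["bonds"]["k_b"], r0=payload["bonds"]["r0"],
        torsion_k=np.asarray(tor["k"], float),
        torsion_delta=np.asarray(tor["delta"], float) * scale,
        k_alpha=ang["k_alpha"], k_beta=ang["k_beta"],
        theta_alpha=ang["theta_alpha"] * scale,
        theta_beta=ang["theta_beta"] * scale,
        eps_alpha=ang["eps_alpha"], gamma=ang["gamma"],
        charges=np.asarray(payload["charges"]["q"], float),
        eps_r=payload["charges"]["eps_r"],
        debye_length=payload["charges"]["debye_length"],
        contact_eps={(int(i), int(j)): float(e) for i, j, e, _ in contacts},
        contact_sigma={(int(i), int(j)): float(s) for i, j, _, s in contacts},
        eps_nonnative=nn.get("eps", 0.000132),
        sigma_nonnative=nn.get("sigma", 5.0),
        nonbonded_min_separation=nn.get("min_separation", 4),
    )


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Bond angles θ_i (rad) for consecutive triples (i, i+1, i+2)."""
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedral_angles(coords: np.ndarray) -> np.ndarray:
    """Signed dihedrals φ_i (rad) for quadruples (i, i+1, i+2, i+3),
    right-hand rule."""
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def _lj_12_10_6(sigma_over_r: np.ndarray) -> np.ndarray:
    return (13.0 * sigma_over_r**12 - 18.0 * sigma_over_r**10
            + 4.0 * sigma_over_r**6)


def potential_energy(structure: CAStructure, params: ForceFieldParams,
                     contacts: NativeContactMap) -> EnergyRecord:
    """Evaluate all six terms of the potential for one conformation.

    Native pairs come from the contact map and must all be parameterized
    (ε_ij^NC, σ_ij); non-native pairs are every other pair with sequence
    separation ≥ ``nonbonded_min_separation``. Electrostatics run over the
    same non-bonded pair list. Zero interatomic distances are an error.
    """
    coords = structure.coords
    n = coords.shape[0]
    if params.charges.shape != (n,):
        raise ValueError("charges length must equal residue count")

    bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    e_bond = float(params.k_bond * np.sum((bonds - params.r0) ** 2))

    e_torsion = 0.0
    if n >= 4:
        phi = dihedral_angles(coords)
        if params.torsion_k.shape[0] != phi.size:
            raise KeyError(
                f"torsion table has {params.torsion_k.shape[0]} rows, "
                f"structure has {phi.size} torsions")
        j = np.arange(1, 5)[None, :]
        e_torsion = float(np.sum(params.torsion_k *
                                 (1.0 + np.cos(j * phi[:, None]
                                               - params.torsion_delta))))

    e_angle = 0.0
    if n >= 3:
        theta = bond_angles(coords)
        g = params.gamma
        well_a = -g * (params.k_alpha * (theta - params.theta_alpha) ** 2
                       + params.eps_alpha)
        well_b = -g * params.k_beta * (theta - params.theta_beta) ** 2
        # log-sum-exp, stably
        m = np.maximum(well_a, well_b)
        e_angle = float(np.sum(-(m + np.log(np.exp(well_a - m)
                                            + np.exp(well_b - m))) / g))

    native_pairs = {tuple(p) for p in contacts.pairs}
    ii, jj = np.triu_indices(n, k=params.nonbonded_min_separation)
    r = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    if np.any(r == 0):
        raise ValueError("zero interatomic distance")

    qq = params.charges[ii] * params.charges[jj]
    e_elec = float(np.sum(COULOMB_KCAL * qq / (params.eps_r * r)
                          * np.exp(-r / params.debye_length)))

    e_native = 0.0
    e_nonnative = 0.0
    for a, b, d in zip(ii, jj, r):
        pair = (int(a) + 1, int(b) + 1)
        if pair in native_pairs:
            if pair not in params.contact_eps or pair not in params.contact_sigma:
                raise KeyError(f"native contact {pair} lacks ε/σ parameters")
            e_native += params.contact_eps[pair] * _lj_12_10_6(
                params.contact_sigma[pair] / d)
        else:
            e_nonnative += params.eps_nonnative * _lj_12_10_6(
                params.sigma_nonnative / d)
    return EnergyRecord(e_bond, e_torsion, e_angle, e_elec,
                        float(e_native), float(e_nonnative))
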