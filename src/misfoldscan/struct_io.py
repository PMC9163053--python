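"""Structures, trajectories, residue sets, contact maps, and reference statistics.

Core containers used by every downstream metric:

* :class:`CAStructure` — a single Cα-resolution conformation (coordinates in Å,
  residues numbered 1..N).
* :class:`Trajectory` — an ordered stack of conformations with timestamps in ns
  and per-frame phase labels (synthesis | ejection | post_translational).
* :class:`NativeContactMap` — the native contact pairs shared by the fraction-of-
  native-contacts order parameter Q and the entanglement (linking-number) loops.
* :class:`ResidueSet` — named residue subsets (hydrophobic, DnaK sites,
  aggregation-prone regions, functional residues, peptide fragments).
* :class:`ReferenceEnsembleStats` — means/SDs of every order parameter over the
  native-state reference simulations, against which trajectories are judged.

Units and conventions: coordinates in Å, times in ns, residue numbering 1-based
and contiguous after reading. All interval logic is half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CAStructure",
    "Trajectory",
    "NativeContactMap",
    "ResidueSet",
    "ReferenceEnsembleStats",
    "HYDROPHOBIC_RESIDUES",
    "read_ca_structure",
    "write_ca_structure",
    "read_trajectory",
    "write_trajectory",
    "build_native_contacts",
    "hydrophobic_set",
    "read_residue_set",
    "read_client_list",
    "compute_reference_stats",
]

# Residues treated as hydrophobic for all surface-area metrics.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ILE", "VAL", "LEU", "PHE", "CYS", "MET", "ALA", "GLY", "TRP"}
)

# Physically plausible range for consecutive Cα–Cα virtual bonds (Å).
_BOND_MIN, _BOND_MAX = 2.0, 4.5

PHASES = ("synthesis", "ejection", "post_translational")


@dataclass
class CAStructure:
    """One interaction site per residue, placed at the Cα position.

    Parameters
    ----------
    coords : (N, 3) float array, Å
    residue_names : sequence of three-letter amino-acid codes, length N
    residue_ids : optional 1-based integer indices (defaults to 1..N)
    synthetic_stretched : skip the Cα–Cα virtual-bond-length sanity check
        (used for deliberately non-physical synthetic curves).
    """

    coords: np.ndarray
    residue_names: Sequence[str] = None
    residue_ids: np.ndarray = None
    synthetic_stretched: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        n = self.coords.shape[0]
        if n < 2:
            raise ValueError(f"a chain needs at least 2 residues, got {n}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.residue_names is None:
            self.residue_names = ["GLY"] * n
        self.residue_names = [str(r).upper() for r in self.residue_names]
        if len(self.residue_names) != n:
            raise ValueError("residue_names length must equal residue count")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, n + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.residue_ids.shape != (n,):
            raise ValueError("residue_ids length must equal residue count")
        if not self.synthetic_stretched:
            bonds = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            bad = np.where((bonds <= _BOND_MIN) | (bonds >= _BOND_MAX))[0]
            if bad.size:
                raise ValueError(
                    f"Cα–Cα virtual bond {bad[0] + 1}-{bad[0] + 2} is "
                    f"{bonds[bad[0]]:.2f} Å, outside ({_BOND_MIN}, {_BOND_MAX}) Å; "
                    "flag synthetic_stretched=True for deliberately stretched curves"
                )

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def distances(self, pairs: np.ndarray) -> np.ndarray:
        """Pairwise Cα distances (Å) for 1-based ``(i, j)`` residue pairs."""
        pairs = np.asarray(pairs, dtype=int)
        d = self.coords[pairs[:, 0] - 1] - self.coords[pairs[:, 1] - 1]
        return np.linalg.norm(d, axis=1)

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "CAStructure":
        """Return a rigidly transformed copy (rotation applied first)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, coords=xyz)


@dataclass
class Trajectory:
    """Stack of Cα snapshots with per-frame times (ns) and phase labels."""

    coords: np.ndarray  # (F, N, 3) Å
    times: np.ndarray  # (F,) ns, strictly increasing
    topology: CAStructure
    phases: np.ndarray = None  # (F,) str, one of PHASES
    nascent_lengths: np.ndarray = None  # (F,) residues present (synthesis phase)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        f, n, _ = self.coords.shape
        if n != self.topology.n_residues:
            raise ValueError(
                f"frame atom count {n} != topology residue count "
                f"{self.topology.n_residues}"
            )
        if self.times.shape != (f,):
            raise ValueError("times length must equal frame count")
        if f > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.phases is None:
            self.phases = np.array(["post_translational"] * f, dtype=object)
        self.phases = np.asarray(self.phases, dtype=object)
        if self.phases.shape != (f,):
            raise ValueError("phases length must equal frame count")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        if self.nascent_lengths is None:
            self.nascent_lengths = np.full(f, n, dtype=int)
        self.nascent_lengths = np.asarray(self.nascent_lengths, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def span_ns(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame(self, index: int) -> CAStructure:
        return replace(self.topology, coords=self.coords[index],
                       synthetic_stretched=True)

    def frames(self) -> Iterable[CAStructure]:
        for k in range(self.n_frames):
            yield self.frame(k)

    def tail_mask(self, tail_ns: float) -> np.ndarray:
        """Boolean mask of frames in the final ``tail_ns`` ns of the run."""
        return self.times >= self.times[-1] - tail_ns


@dataclass
class NativeContactMap:
    """Native contact pairs (1-based, i < j) with native distances in Å."""

    pairs: np.ndarray  # (M, 2) int
    native_distances: np.ndarray  # (M,) Å
    ss_mask: np.ndarray = None  # (N,) bool, residues inside secondary structure
    cutoff: float = np.nan
    min_separation: int = 0

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.native_distances = np.asarray(self.native_distances, dtype=float)
        if self.pairs.shape[0] != self.native_distances.shape[0]:
            raise ValueError("pairs and native_distances length mismatch")
        if self.pairs.size and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("contact pairs must satisfy i < j")
        if np.any(self.native_distances <= 0):
            raise ValueError("native distances must be positive")
        seen = {tuple(p) for p in self.pairs}
        if len(seen) != self.pairs.shape[0]:
            raise ValueError("duplicate contact pairs")
        if self.ss_mask is not None:
            self.ss_mask = np.asarray(self.ss_mask, dtype=bool)

    @property
    def n_contacts(self) -> int:
        return self.pairs.shape[0]

    def restrict(self, residues: Iterable[int]) -> "NativeContactMap":
        """Sub-map whose contacts have both residues inside ``residues``."""
        members = np.zeros(int(self.pairs.max(initial=0)) + 1, dtype=bool)
        for r in residues:
            if r < members.size:
                members[r] = True
        keep = members[self.pairs[:, 0]] & members[self.pairs[:, 1]]
        return NativeContactMap(self.pairs[keep], self.native_distances[keep],
                                self.ss_mask, self.cutoff, self.min_separation)


@dataclass(frozen=True)
class ResidueSet:
    """A named subset of residues (1-based indices)."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(int(m) for m in self.members))
        if any(m < 1 for m in self.members):
            raise ValueError("residue indices are 1-based; got index < 1")

    def indices(self) -> np.ndarray:
        return np.array(sorted(self.members), dtype=int)

    def validate(self, n_residues: int) -> None:
        high = [m for m in self.members if m > n_residues]
        if high:
            raise ValueError(
                f"residue set {self.name!r} has members beyond chain "
                f"length {n_residues}: {sorted(high)[:5]}"
            )


@dataclass
class ReferenceEnsembleStats:
    """Native-state-ensemble means and SDs for every order parameter.

    ``mean_Qmode``/``sd_Qmode`` are taken over all sliding windows of all
    native-state runs; ``mean_G``/``sd_G`` over all frames; ``mean_sasa`` maps
    a residue-set name to its mean aggregate SASA (Å²); ``mean_chi`` is the
    native mean of the functional-site structural overlap; ``ref_profile`` is
    the reference change-in-linking distribution P_ref(G_k), k = 0..5.
    """

    mean_Qmode: float = np.nan
    sd_Qmode: float = np.nan
    mean_G: float = np.nan
    sd_G: float = np.nan
    mean_sasa: dict = field(default_factory=dict)
    mean_chi: float = np.nan
    ref_profile: np.ndarray = None
    per_domain: dict = field(default_factory=dict)  # name -> (mean_Qmode, sd_Qmode)

    def __post_init__(self) -> None:
        if self.ref_profile is not None:
            self.ref_profile = np.asarray(self.ref_profile, dtype=float)
            total = self.ref_profile.sum()
            if total > 0 and not np.isclose(total, 1.0):
                raise ValueError("reference entanglement profile must sum to 1")

    @property
    def q_threshold(self) -> float:
        """Folded/misfolded Q_mode threshold: ⟨Q_mode^NS⟩ − 3σ."""
        return self.mean_Qmode - 3.0 * self.sd_Qmode

    @property
    def g_ceiling(self) -> float:
        """Default entanglement ceiling G_xs: ⟨G⟩_NS + 3·sd."""
        return self.mean_G + 3.0 * self.sd_G


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def read_ca_structure(path, chain: str = None) -> CAStructure:
    """Read a PDB file into a Cα-only structure.

    One bead per residue at the Cα position; residues are renumbered 1..N
    preserving file order. A residue lacking a Cα record raises ``ValueError``
    naming the residue. Waters and other het groups without a Cα are skipped.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    if chain is None:
        chains = list(model.get_chains())
        if not chains:
            raise ValueError(f"no chains in {path}")
        target = chains[0]
    else:
        if chain not in [c.id for c in model.get_chains()]:
            raise ValueError(f"chain {chain!r} not present in {path}")
        target = model[chain]

    coords, names = [], []
    for res in target.get_residues():
        hetflag = res.id[0].strip()
        if hetflag and not is_aa(res, standard=False):
            continue  # solvent / ligands
        if "CA" not in res:
            raise ValueError(
                f"residue {res.get_resname()}{res.id[1]} in chain "
                f"{target.id!r} has no CA atom"
            )
        coords.append(res["CA"].coord)
        names.append(res.get_resname())
    if not coords:
        raise ValueError(f"chain {target.id!r} in {path} contains no residues")
    return CAStructure(np.array(coords, dtype=float), names)


def write_ca_structure(path, structure: CAStructure) -> None:
    """Write a Cα-only structure as a minimal single-chain PDB file."""
    lines = []
    for k in range(structure.n_residues):
        x, y, z = structure.coords[k]
        lines.append(
            f"ATOM  {k + 1:5d}  CA  {structure.residue_names[k]:>3s} A"
            f"{structure.residue_ids[k]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def _resolve_times(n_frames, times, dt_ns, t0_ns):
    if times is not None:
        return np.asarray(times, dtype=float)
    if dt_ns is not None:
        return t0_ns + dt_ns * np.arange(n_frames)
    return np.arange(n_frames, dtype=float)


def read_trajectory(path, topology: CAStructure, times=None, dt_ns: float = None,
                    t0_ns: float = 0.0) -> Trajectory:
    """Read a trajectory in DCD/XTC (via mdtraj), plain XYZ, or CSV dialect.

    The CSV dialect has columns ``frame, time_ns, residue, x, y, z``. The XYZ
    dialect stores the time in the comment line as ``t= <ns>``. For binary
    formats the timestamps come from ``times`` or ``dt_ns``/``t0_ns``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcd", ".xtc"):
        import mdtraj as md

        t = md.load(str(path), top=_mdtraj_topology(topology))
        xyz = np.asarray(t.xyz, dtype=float) * 10.0  # nm -> Å
        frame_times = _resolve_times(xyz.shape[0], times, dt_ns, t0_ns)
    elif suffix == ".xyz":
        xyz, xyz_times = _read_xyz(path)
        frame_times = (np.asarray(xyz_times, dtype=float)
                       if times is None and dt_ns is None and xyz_times is not None
                       else _resolve_times(xyz.shape[0], times, dt_ns, t0_ns))
    elif suffix in (".csv", ".tsv"):
        xyz, frame_times = _read_csv_traj(path)
        if times is not None or dt_ns is not None:
            frame_times = _resolve_times(xyz.shape[0], times, dt_ns, t0_ns)
    else:
        raise ValueError(f"unsupported trajectory format: {suffix!r}")

    if xyz.shape[1] != topology.n_residues:
        raise ValueError(
            f"frame atom count {xyz.shape[1]} != topology residue count "
            f"{topology.n_residues}"
        )
    return Trajectory(xyz, frame_times, topology)


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory as DCD, plain XYZ, or CSV (dialects of read_trajectory)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        import mdtraj as md

        m = md.Trajectory(traj.coords / 10.0, _mdtraj_topology(traj.topology))
        m.save_dcd(str(path))
    elif suffix == ".xyz":
        names = traj.topology.residue_names
        with open(path, "w") as fh:
            for k in range(traj.n_frames):
                fh.write(f"{traj.n_residues}\n")
                fh.write(f"t= {traj.times[k]:.6f}\n")
                for r in range(traj.n_residues):
                    x, y, z = traj.coords[k, r]
                    fh.write(f"{names[r]:>3s} {x:.6f} {y:.6f} {z:.6f}\n")
    elif suffix in (".csv", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        with open(path, "w") as fh:
            fh.write(sep.join(["frame", "time_ns", "residue", "x", "y", "z"]) + "\n")
            for k in range(traj.n_frames):
                for r in range(traj.n_residues):
                    x, y, z = traj.coords[k, r]
                    fh.write(sep.join([str(k), f"{traj.times[k]:.6f}", str(r + 1),
                                       f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"]) + "\n")
    else:
        raise ValueError(f"unsupported trajectory format: {suffix!r}")


def _mdtraj_topology(structure: CAStructure):
    import mdtraj as md
    from mdtraj.core import element

    top = md.Topology()
    ch = top.add_chain()
    for k in range(structure.n_residues):
        res = top.add_residue(structure.residue_names[k], ch,
                              resSeq=int(structure.residue_ids[k]))
        top.add_atom("CA", element.carbon, res)
    return top


def _read_xyz(path):
    frames, times = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        natoms = int(lines[pos].split()[0])
        comment = lines[pos + 1]
        t = None
        if "t=" in comment:
            t = float(comment.split("t=")[1].split()[0])
        block = lines[pos + 2: pos + 2 + natoms]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        times.append(t)
        pos += 2 + natoms
    xyz = np.array(frames, dtype=float)
    if any(t is None for t in times):
        times = None
    return xyz, times


def _read_csv_traj(path):
    import pandas as pd

    sep = "\t" if Path(path).suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    frames = np.sort(df["frame"].unique())
    n_res = df[df["frame"] == frames[0]].shape[0]
    xyz = np.empty((frames.size, n_res, 3), dtype=float)
    times = np.empty(frames.size, dtype=float)
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("residue")
        if sub.shape[0] != n_res:
            raise ValueError(f"frame {f} has {sub.shape[0]} residues, expected {n_res}")
        xyz[k] = sub[["x", "y", "z"]].to_numpy()
        times[k] = sub["time_ns"].iloc[0]
    return xyz, times


# ---------------------------------------------------------------------------
# Contact maps and residue sets
# ---------------------------------------------------------------------------

def build_native_contacts(native: CAStructure, ss_mask, cutoff: float = 8.0,
                          min_separation: int = 4) -> NativeContactMap:
    """Build the native contact map from the reference structure.

    A native contact is a pair (i, j) with sequence separation
    ``j − i ≥ min_separation``, both residues inside secondary-structure
    elements (``ss_mask`` true), and native Cα–Cα distance ≤ ``cutoff`` Å.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 1:
        raise ValueError("min_separation must be ≥ 1")
    ss_mask = np.asarray(ss_mask, dtype=bool)
    n = native.n_residues
    if ss_mask.shape != (n,):
        raise ValueError(f"ss_mask length {ss_mask.shape} != residue count {n}")

    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(native.coords))
    ii, jj = np.triu_indices(n, k=min_separation)
    keep = (dist[ii, jj] <= cutoff) & ss_mask[ii] & ss_mask[jj]
    pairs = np.column_stack([ii[keep] + 1, jj[keep] + 1])
    return NativeContactMap(pairs, dist[ii[keep], jj[keep]], ss_mask,
                            cutoff, min_separation)


def hydrophobic_set(structure: CAStructure) -> ResidueSet:
    """Hydrophobic residue set: {Ile, Val, Leu, Phe, Cys, Met, Ala, Gly, Trp}."""
    members = [k + 1 for k, name in enumerate(structure.residue_names)
               if name in HYDROPHOBIC_RESIDUES]
    return ResidueSet("hydrophobic", frozenset(members))


def read_residue_set(path, name: str = None) -> ResidueSet:
    """Read a residue set from JSON ({"name":…, "residues":[…]}) or
    one-index-per-line text."""
    text = Path(path).read_text().strip()
    if text.startswith("{"):
        payload = json.loads(text)
        return ResidueSet(name or payload["name"], frozenset(payload["residues"]))
    members = [int(line.split()[0]) for line in text.splitlines() if line.strip()]
    return ResidueSet(name or Path(path).stem, frozenset(members))


def read_client_list(path) -> frozenset:
    """Chaperone client list: one gene/protein name per line."""
    lines = Path(path).read_text().splitlines()
    return frozenset(ln.strip() for ln in lines if ln.strip())


# ---------------------------------------------------------------------------
# Reference-ensemble statistics
# ---------------------------------------------------------------------------

def compute_reference_stats(native_runs: Sequence[Trajectory],
                            contacts: NativeContactMap,
                            native: CAStructure,
                            *,
                            residue_sets: Sequence[ResidueSet] = (),
                            func_set: ResidueSet = None,
                            domains: dict = None,
                            window_ns: float = 15.0,
                            formation_factor: float = 1.2,
                            sasa_kwargs: dict = None,
                            epsilon: float = None) -> ReferenceEnsembleStats:
    """Populate every reference mean/SD from the native-state runs.

    Aggregates over all frames (and all sliding windows, for Q_mode) of all
    supplied native-state trajectories: ⟨Q_mode^NS⟩ and its σ, ⟨G⟩ and its SD,
    the reference change-in-linking profile P_ref(G_k), mean aggregate SASA per
    residue set, and the native mean structural overlap ⟨χ⟩_NS when a
    functional set is given. ``domains`` maps a name to a residue range
    ``(start, stop)`` (1-based, inclusive) for per-domain Q_mode references.
    """
    if not native_runs:
        raise ValueError("at least one native-state trajectory is required")

    from . import entangle, function_chi, qmetrics, surface

    qmodes, g_all = [], []
    per_domain_acc = {name: [] for name in (domains or {})}
    case_counts = np.zeros(6, dtype=float)
    sasa_acc = {rs.name: [] for rs in residue_sets}
    chi_vals = []

    g_native = entangle.native_linking(native, contacts)
    for run in native_runs:
        qs = qmetrics.q_series(run, contacts, formation_factor=formation_factor)
        qm = qmetrics.qmode_series(qs, window_ns=window_ns)
        qmodes.extend(qm.qmode.tolist())
        for name, rng in (domains or {}).items():
            sub = qmetrics.q_series(run, contacts, formation_factor=formation_factor,
                                    residue_range=rng)
            per_domain_acc[name].extend(
                qmetrics.qmode_series(sub, window_ns=window_ns).qmode.tolist())
        profile = entangle.change_profile(run, contacts, g_native)
        g_all.extend(profile.g_t.tolist())
        case_counts += profile.case_counts
        if residue_sets:
            res = surface.sasa_trajectory(run, **(sasa_kwargs or {}))
            for rs in residue_sets:
                sasa_acc[rs.name].append(res.aggregate(rs))
        if func_set is not None:
            for k in range(run.n_frames):
                chi_vals.append(function_chi.chi(run.frame(k), func_set, native,
                                                 epsilon=epsilon))

    qmodes = np.asarray(qmodes, dtype=float)
    g_all = np.asarray(g_all, dtype=float)
    total = case_counts.sum()
    ref_profile = case_counts / total if total > 0 else np.zeros(6)

    stats = ReferenceEnsembleStats(
        mean_Qmode=float(qmodes.mean()),
        sd_Qmode=float(qmodes.std()),
        mean_G=float(g_all.mean()),
        sd_G=float(g_all.std()),
        mean_sasa={name: float(np.concatenate(vals).mean())
                   for name, vals in sasa_acc.items() if vals},
        mean_chi=float(np.mean(chi_vals)) if chi_vals else np.nan,
        ref_profile=ref_profile,
        per_domain={name: (float(np.mean(v)), float(np.std(v)))
                    for name, v in per_domain_acc.items()},
    )
    return stats
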