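"""Fraction of native contacts Q, the sliding-window mode Q_mode, and the
Q-based misfolding criterion.

Q is the proportion of native contacts formed in a conformation. A contact
(i, j) with native distance r_ij^0 counts as formed at time t when
r_ij(t) ≤ formation_factor · r_ij^0 (default factor 1.2, the usual Gō-analysis
convention). Q_mode is the modal Q over a sliding time window (default 15 ns,
advanced one frame at a time, windows defined on timestamps as [t, t+w)).

A domain or interface is called misfolded when its mean Q_mode over the final
100 ns of the post-translational phase falls below ⟨Q_mode^NS⟩ − 3σ, the
native-state-ensemble mean minus three standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .struct_io import (CAStructure, NativeContactMap, ReferenceEnsembleStats,
                        Trajectory)

__all__ = ["QSeries", "compute_Q", "q_series", "qmode_series", "q_misfold_flag"]

DEFAULT_FORMATION_FACTOR = 1.2
DEFAULT_WINDOW_NS = 15.0
DEFAULT_TAIL_NS = 100.0
#: Q values are rounded to this many decimals before frequency counting, so the
#: mode of a near-continuous series is well defined.
MODE_DECIMALS = 3


@dataclass
class QSeries:
    """Per-frame Q values and (after windowing) per-window modal values."""

    times: np.ndarray  # (F,) ns
    q: np.ndarray  # (F,) in [0, 1]
    window_ns: float = None
    window_times: np.ndarray = None  # window start times, ns
    qmode: np.ndarray = None  # modal Q per window
    domain: str = "overall"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != self.times.shape:
            raise ValueError("times and q must have equal length")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("Q values must lie in [0, 1]")


def _restrict(contacts: NativeContactMap, residue_range) -> NativeContactMap:
    if residue_range is None:
        return contacts
    lo, hi = residue_range
    return contacts.restrict(range(int(lo), int(hi) + 1))


def compute_Q(frame: CAStructure, contacts: NativeContactMap,
              formation_factor: float = DEFAULT_FORMATION_FACTOR,
              residue_range=None) -> float:
    """Fraction of native contacts formed in one conformation.

    ``residue_range`` (1-based, inclusive ``(start, stop)``) restricts the
    calculation to a domain or interface.
    """
    sub = _restrict(contacts, residue_range)
    if sub.n_contacts == 0:
        raise ValueError("empty contact set")
    d = frame.distances(sub.pairs)
    return float(np.mean(d <= formation_factor * sub.native_distances))


def q_series(traj: Trajectory, contacts: NativeContactMap,
             formation_factor: float = DEFAULT_FORMATION_FACTOR,
             residue_range=None, domain: str = "overall") -> QSeries:
    """Q(t) for every frame of a trajectory."""
    sub = _restrict(contacts, residue_range)
    if sub.n_contacts == 0:
        raise ValueError("empty contact set")
    idx = sub.pairs - 1
    diffs = traj.coords[:, idx[:, 0], :] - traj.coords[:, idx[:, 1], :]
    d = np.linalg.norm(diffs, axis=2)  # (F, M)
    formed = d <= formation_factor * sub.native_distances
    return QSeries(traj.times.copy(), formed.mean(axis=1), domain=domain)


def _window_mode(values: np.ndarray) -> float:
    """Mode of rounded Q values; ties broken toward the larger Q."""
    rounded = np.round(values, MODE_DECIMALS)
    uniq, counts = np.unique(rounded, return_counts=True)
    best = counts.max()
    return float(uniq[counts == best].max())


def qmode_series(q: QSeries, window_ns: float = DEFAULT_WINDOW_NS) -> QSeries:
    """Sliding-window modal Q.

    Windows are [t_k, t_k + window_ns) on timestamps, advanced one frame at a
    time; only windows fully contained in the trajectory span are kept. The
    modal value is always an attained Q value (Q is rounded to
    ``MODE_DECIMALS`` decimals before frequency counting; ties break toward
    the larger Q, biasing against false misfolding calls).
    """
    if window_ns <= 0:
        raise ValueError("window must be positive")
    t = q.times
    if t[-1] - t[0] < window_ns:
        raise ValueError("trajectory span is shorter than the window")
    starts, modes = [], []
    stop = np.searchsorted(t, t[-1] - window_ns, side="right")
    for k in range(stop):
        lo, hi = t[k], t[k] + window_ns
        inside = (t >= lo) & (t < hi)
        starts.append(lo)
        modes.append(_window_mode(q.q[inside]))
    return QSeries(q.times, q.q, window_ns=window_ns,
                   window_times=np.asarray(starts), qmode=np.asarray(modes),
                   domain=q.domain)


def q_misfold_flag(q: QSeries, ref: ReferenceEnsembleStats,
                   tail_ns: float = DEFAULT_TAIL_NS,
                   ref_key: str = None) -> bool:
    """Q-arm misfolding criterion for one domain/interface series.

    True iff the mean Q_mode over the final ``tail_ns`` ns is *below*
    ⟨Q_mode^NS⟩ − 3σ. ``ref_key`` selects a per-domain reference entry; by
    default the overall reference is used. The trajectory-level flag is the OR
    over its domain/interface series.
    """
    if q.qmode is None:
        raise ValueError("qmode_series must be applied before flagging")
    if ref_key is not None:
        if ref_key not in ref.per_domain:
            raise ValueError(f"no per-domain reference for {ref_key!r}")
        mean, sd = ref.per_domain[ref_key]
    else:
        mean, sd = ref.mean_Qmode, ref.sd_Qmode
    if not np.isfinite(mean) or not np.isfinite(sd):
        raise ValueError("reference Q_mode statistics are missing")
    t = q.window_times
    tail = t >= t[-1] - tail_ns
    tail_mean = float(q.qmode[tail].mean())
    return tail_mean < mean - 3.0 * sd
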