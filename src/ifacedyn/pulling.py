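"""Steered-pulling work accumulation and Jarzynski free-energy estimation.

A constant-velocity steered simulation drags one binding partner with a
harmonic trap of stiffness k (kcal/mol/Å²) whose centre moves at velocity v
(Å/ns) along a fixed unit direction; the instantaneous trap force on the
pulled coordinate x is F = k·(x₀ + v·t − x).  The external work is the trap
work W(t) = ∫ F·v dt (trapezoidal quadrature on the stored grid).

Over an ensemble of replicas started from the same initial conditions,
Jarzynski's equality  ⟨e^{−βW}⟩ = e^{−βΔF}  gives the free-energy profile
along the pulled distance λ = v·t.  Two estimators are provided:

* ``cumulant2`` — the second-order cumulant expansion
  ΔF ≈ ⟨W⟩ − β·Var(W)/2 (population variance), exact for Gaussian work
  distributions and the headline estimator here;
* ``exponential`` — the direct exponential average
  ΔF = −(1/β)·ln⟨e^{−βW}⟩ computed through log-sum-exp, reported alongside
  as a cross-check.

An ensemble should contain at least 10 replicas for the averages to be
meaningful; fewer replicas trigger a warning, not an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import logsumexp

from .structure_io import Structure, Trajectory

logger = logging.getLogger("ifacedyn")

#: Boltzmann constant in kcal/(mol·K).
K_BOLTZMANN = 0.0019872041

DEFAULT_TEMPERATURE = 300.0      # K
DEFAULT_PULL_VELOCITY = 10.0     # Å/ns
DEFAULT_SPRING_CONSTANT = 10.0   # kcal/mol/Å²
DEFAULT_DURATION = 2.0           # ns
MIN_REPLICAS = 10
SPRING_NETWORK_CUTOFF = 7.0      # Å, inclusive
MARKER_RESIDUES = (595, 591)     # helix defining the pull direction

CUMULANT2 = "cumulant2"
EXPONENTIAL = "exponential"


@dataclass
class PullingProtocol:
    """Constant-velocity harmonic-trap pulling parameters."""

    pull_velocity: float = DEFAULT_PULL_VELOCITY        # Å/ns
    spring_constant: float = DEFAULT_SPRING_CONSTANT    # kcal/mol/Å²
    direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )
    duration: float = DEFAULT_DURATION                  # ns
    temperature: float = DEFAULT_TEMPERATURE            # K

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.pull_velocity <= 0 or self.spring_constant <= 0 or self.temperature <= 0:
            raise ValueError("velocity, spring constant and temperature must be > 0")
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("direction must be a non-zero vector")
            self.direction = self.direction / norm

    @property
    def beta(self) -> float:
        return 1.0 / (K_BOLTZMANN * self.temperature)


def pull_direction(
    structure: Structure,
    chain_id: str,
    residue_from: int = MARKER_RESIDUES[0],
    residue_to: int = MARKER_RESIDUES[1],
) -> np.ndarray:
    """Unit pull direction from one marker residue's Cα toward another's."""
    a = structure.atoms[structure.calpha_index(chain_id, residue_from)].position
    b = structure.atoms[structure.calpha_index(chain_id, residue_to)].position
    vec = b - a
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("marker residues coincide; direction undefined")
    return vec / norm


@dataclass
class PullingRecord:
    """Time series of pulled position, trap force and accumulated work for
    one replica.  ``work[0]`` is always 0."""

    times: np.ndarray        # ns, strictly increasing
    positions: np.ndarray    # Å, pulled coordinate along the direction
    forces: np.ndarray       # kcal/mol/Å
    work: np.ndarray         # kcal/mol
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        self.work = np.asarray(self.work, dtype=float)
        n = self.times.size
        if not (self.positions.size == self.forces.size == self.work.size == n):
            raise ValueError("times/positions/forces/work must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(self.work[0]) > 1e-12:
            raise ValueError("accumulated work must start at 0")


@dataclass
class ReplicaEnsemble:
    """Pulling replicas sharing one protocol and one time grid."""

    records: list[PullingRecord]
    protocol: PullingProtocol = field(default_factory=PullingProtocol)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("ensemble needs at least one replica")
        grid = self.records[0].times
        for rec in self.records[1:]:
            if rec.times.shape != grid.shape or not np.allclose(rec.times, grid):
                raise ValueError(
                    f"replica {rec.replica_id}: time grid differs from the ensemble grid"
                )
        if len(self.records) < MIN_REPLICAS:
            warnings.warn(
                f"only {len(self.records)} replicas: Jarzynski averaging calls "
                f"for at least {MIN_REPLICAS} runs from the same initial conditions",
                stacklevel=2,
            )

    @property
    def times(self) -> np.ndarray:
        return self.records[0].times

    @property
    def work_matrix(self) -> np.ndarray:
        """(n_replicas, n_times) accumulated work."""
        return np.stack([r.work for r in self.records])


@dataclass
class PMFCurve:
    """Free energy vs pulled distance λ = v·t, with replica work statistics."""

    lam: np.ndarray            # Å
    delta_f: np.ndarray        # kcal/mol, second-cumulant estimator
    delta_f_exp: np.ndarray    # kcal/mol, direct exponential average
    mean_work: np.ndarray      # kcal/mol
    work_variance: np.ndarray  # (kcal/mol)², population
    n_replicas: int = 0

    def __post_init__(self) -> None:
        if np.any(self.delta_f > self.mean_work + 1e-9):
            raise ValueError("cumulant estimate exceeds the mean work")


@dataclass
class SpringNetwork:
    """Cα–Cα harmonic restraint network built from an initial structure."""

    pairs: list[tuple[int, int]]            # roster atom indices
    rest_lengths: np.ndarray                # Å
    spring_constant: float = DEFAULT_SPRING_CONSTANT

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def trap_force(protocol: PullingProtocol, t: float, x: float, x0: float = 0.0) -> float:
    """Trap force F = k·(x₀ + v·t − x); positive when the trap leads."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return protocol.spring_constant * (x0 + protocol.pull_velocity * t - x)


def accumulate_work(
    times: np.ndarray,
    forces: np.ndarray,
    pull_velocity: float,
) -> np.ndarray:
    """Trap work W(tₙ) = ∫ F·v dt by trapezoidal quadrature; W(t₀) = 0."""
    times = np.asarray(times, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return cumulative_trapezoid(forces * pull_velocity, times, initial=0.0)


def jarzynski_delta_f(
    works: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    method: str = CUMULANT2,
) -> float:
    """Free-energy estimate from an ensemble of work values at one λ."""
    works = np.asarray(works, dtype=float)
    if works.size < 2:
        raise ValueError("need at least 2 work values")
    if works.size < MIN_REPLICAS:
        warnings.warn(
            f"only {works.size} work values: the Jarzynski average calls for "
            f"at least {MIN_REPLICAS} replicas",
            stacklevel=2,
        )
    beta = 1.0 / (K_BOLTZMANN * temperature)
    if method == CUMULANT2:
        # population variance, consistent with the MSFD divisor-N convention
        return float(works.mean() - beta * works.var(ddof=0) / 2.0)
    if method == EXPONENTIAL:
        return float(-(logsumexp(-beta * works) - np.log(works.size)) / beta)
    raise ValueError(f"unknown Jarzynski method: {method!r}")


def pmf_curve(
    ensemble: ReplicaEnsemble,
    temperature: float | None = None,
    lambda_max: float | None = None,
) -> PMFCurve:
    """PMF along λ = v·t from the per-time work distribution across replicas.

    Both estimator variants are computed at every time point; ``lambda_max``
    truncates the curve to the early, more reliable pulling phase.
    """
    T = temperature if temperature is not None else ensemble.protocol.temperature
    beta = 1.0 / (K_BOLTZMANN * T)
    lam = ensemble.protocol.pull_velocity * (ensemble.times - ensemble.times[0])
    W = ensemble.work_matrix
    if lambda_max is not None:
        keep = lam <= lambda_max
        lam, W = lam[keep], W[:, keep]
    mean_w = W.mean(axis=0)
    var_w = W.var(axis=0, ddof=0)
    delta_f = mean_w - beta * var_w / 2.0
    n = W.shape[0]
    delta_f_exp = -(logsumexp(-beta * W, axis=0) - np.log(n)) / beta
    return PMFCurve(
        lam=lam,
        delta_f=delta_f,
        delta_f_exp=delta_f_exp,
        mean_work=mean_w,
        work_variance=var_w,
        n_replicas=n,
    )


def force_distance_profile(
    ensemble: ReplicaEnsemble,
    trajectories: Sequence[Trajectory],
    chain_id: str,
    marker_residues: tuple[int, int] = MARKER_RESIDUES,
    projection: bool = False,
) -> pd.DataFrame:
    """Replica-averaged (distance, force) profile.

    Per replica, distance(t) is the displacement of the Cα midpoint of the
    two marker residues from its position at t = 0 — its Euclidean magnitude
    by default, or its projection on the pull direction when ``projection``
    is set.  The returned frame has columns ``time_ns``, ``distance_A``,
    ``force_kcal_mol_A`` averaged over replicas at each time point.
    """
    if len(trajectories) != len(ensemble.records):
        raise ValueError("one trajectory per replica is required")
    r1, r2 = marker_residues
    dists = []
    for traj in trajectories:
        ref = traj.frame_structure(0)
        i1 = ref.calpha_index(chain_id, r1)
        i2 = ref.calpha_index(chain_id, r2)
        mid = 0.5 * (traj.frames[:, i1, :] + traj.frames[:, i2, :])
        disp = mid - mid[0]
        if projection:
            d = disp @ ensemble.protocol.direction
        else:
            d = np.linalg.norm(disp, axis=1)
        if d.shape[0] != ensemble.times.size:
            raise ValueError("trajectory frame count does not match the time grid")
        dists.append(d)
    forces = np.stack([r.forces for r in ensemble.records])
    return pd.DataFrame(
        {
            "time_ns": ensemble.times,
            "distance_A": np.mean(dists, axis=0),
            "force_kcal_mol_A": forces.mean(axis=0),
        }
    )


def build_spring_network(
    initial: Structure,
    chain_id: str,
    cutoff: float = SPRING_NETWORK_CUTOFF,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
) -> SpringNetwork:
    """Connect every Cα pair of one chain within ``cutoff`` (inclusive) by a
    harmonic restraint whose rest length is the initial distance."""
    ca = sorted(initial.calpha_map(chain_id).items())
    if len(ca) < 2:
        raise ValueError("spring network needs at least 2 CA atoms")
    idx = np.array([i for _, i in ca], dtype=int)
    xyz = initial.coords[idx]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    pairs = [(int(idx[i]), int(idx[j])) for i, j in zip(ii, jj)]
    return SpringNetwork(
        pairs=pairs,
        rest_lengths=d[ii, jj].astype(float),
        spring_constant=spring_constant,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PULLING_COLUMNS = ["replica", "time_ns", "position_A", "force_kcal_mol_A", "work_kcal_mol"]


def write_pulling_records(ensemble: ReplicaEnsemble, path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "replica": rec.replica_id,
                "time_ns": rec.times,
                "position_A": rec.positions,
                "force_kcal_mol_A": rec.forces,
                "work_kcal_mol": rec.work,
            }
        )
        for rec in ensemble.records
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pulling_records(
    path: str | Path, protocol: PullingProtocol | None = None
) -> ReplicaEnsemble:
    """Read replica records from CSV; the work column is recomputed from the
    force series when absent."""
    df = pd.read_csv(path)
    missing = [c for c in PULLING_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"pulling CSV lacks column(s): {missing}")
    protocol = protocol or PullingProtocol()
    records = []
    for replica, grp in df.groupby("replica", sort=True):
        times = grp["time_ns"].to_numpy()
        forces = grp["force_kcal_mol_A"].to_numpy()
        if "work_kcal_mol" in grp.columns and not grp["work_kcal_mol"].isna().any():
            work = grp["work_kcal_mol"].to_numpy()
        else:
            work = accumulate_work(times, forces, protocol.pull_velocity)
        records.append(
            PullingRecord(
                times=times,
                positions=grp["position_A"].to_numpy(),
                forces=forces,
                work=work,
                replica_id=int(replica),
            )
        )
    return ReplicaEnsemble(records=records, protocol=protocol)


def write_pmf_curve(curve: PMFCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "lambda_A": curve.lam,
            "dF_cumulant": curve.delta_f,
            "dF_exponential": curve.delta_f_exp,
            "mean_W": curve.mean_work,
            "var_W": curve.work_variance,
            "n_replicas": curve.n_replicas,
        }
    ).to_csv(path, index=False)
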