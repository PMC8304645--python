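"""Synthetic inputs with known ground truth.

Every stage of the interface analysis can be exercised without molecular
dynamics: toy two-chain complexes with an exactly known 7 Å contact set,
fluctuating trajectories whose inter-residue distance variance is
prescribed, and one-dimensional overdamped (Brownian) steered-pulling
ensembles whose free-energy profile has a closed form.  All generators are
pure functions of their spec + seed.

The Brownian generator is a deliberate scale reduction: it produces the
same mathematical object the Jarzynski machinery consumes — an ensemble of
work trajectories under a constant-velocity harmonic trap — while keeping
the true ΔF(λ) known exactly (0 for a flat potential,
κkλ²/(2(κ+k)) for a harmonic well of stiffness κ under a trap of
stiffness k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .contacts import ContactPair, ContactSet, SOURCE_STRUCTURE, contact_region
from .pulling import (
    K_BOLTZMANN,
    PullingProtocol,
    PullingRecord,
    ReplicaEnsemble,
)
from .structure_io import Atom, RegionMap, Structure, Trajectory, default_region_map

IID_GAUSSIAN = "iid-gaussian"
SINUSOIDAL = "sinusoidal"

FLAT = "flat"
HARMONIC = "harmonic"
DOUBLE_WELL = "double-well"


# ---------------------------------------------------------------------------
# Toy two-chain complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Geometry request for a toy two-chain complex.

    A fraction of the second chain's residues is placed in a contact zone
    where every Cα lies within 7 Å of every first-chain Cα; the rest sit
    ``gap`` Å away.  The first chain mimics the MTP alpha subunit (residues
    numbered from ``start_a``), the second mimics PDI (from ``start_b``).
    """

    n_residues_a: int = 5
    n_residues_b: int = 5
    gap: float = 50.0
    contact_fraction: float = 0.5
    seed: int = 0
    chain_a: str = "A"
    chain_b: str = "B"
    start_a: int = 604
    start_b: int = 26

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must lie in [0, 1]")
        if self.gap <= 12.0:
            raise ValueError(
                "gap must exceed 12 Å so non-contact residues stay beyond 7 Å"
            )
        if self.n_residues_a < 1 or self.n_residues_b < 1:
            raise ValueError("each chain needs at least one residue")


_CLUSTER_RADIUS = 1.2       # Å, Cα scatter within each cluster
_CONTACT_OFFSET = 4.0       # Å, contact-cluster centre distance from chain A
_SIDECHAIN_LENGTH = 1.5     # Å, dummy sidechain bond


def _cluster(rng: np.random.Generator, n: int, centre: np.ndarray) -> np.ndarray:
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= rng.uniform(0.0, _CLUSTER_RADIUS, size=(n, 1))
    return centre + pts


def make_toy_complex(
    spec: ToyComplexSpec, region_map: RegionMap | None = None
) -> tuple[Structure, ContactSet]:
    """Build the toy complex and its exact ground-truth 7 Å contact set.

    The ground truth is obtained by exhaustive Cα pair enumeration on the
    generated coordinates, so it holds whatever the random scatter did.
    """
    rng = np.random.default_rng(spec.seed)
    region_map = region_map or default_region_map(
        pdi_chain=spec.chain_b, mtp_chain=spec.chain_a
    )
    ca_a = _cluster(rng, spec.n_residues_a, np.zeros(3))
    n_contact = int(round(spec.contact_fraction * spec.n_residues_b))
    contact_centre = np.array([_CONTACT_OFFSET, 0.0, 0.0])
    far_centre = np.array([spec.gap, 0.0, 0.0])
    ca_b = np.vstack(
        [
            _cluster(rng, n_contact, contact_centre)
            if n_contact
            else np.empty((0, 3)),
            _cluster(rng, spec.n_residues_b - n_contact, far_centre)
            if spec.n_residues_b - n_contact
            else np.empty((0, 3)),
        ]
    )
    atoms: list[Atom] = []
    serial = 1
    for chain, start, cas in (
        (spec.chain_a, spec.start_a, ca_a),
        (spec.chain_b, spec.start_b, ca_b),
    ):
        for i, ca in enumerate(cas):
            resnum = start + i
            atoms.append(Atom(serial, "CA", "C", resnum, "GLY", chain, ca))
            serial += 1
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(
                Atom(serial, "CB", "C", resnum, "GLY", chain,
                     ca + _SIDECHAIN_LENGTH * direction)
            )
            serial += 1
    structure = Structure(atoms)
    # exact ground truth by brute force on the Cα coordinates
    pairs = set()
    for i, pa in enumerate(ca_a):
        for j, pb in enumerate(ca_b):
            if np.linalg.norm(pa - pb) <= 7.0:
                res_b = (spec.chain_b, spec.start_b + j)
                pairs.add(
                    ContactPair(
                        residue_a=(spec.chain_a, spec.start_a + i),
                        residue_b=res_b,
                        region=contact_region(region_map, *res_b),
                    )
                )
    return structure, ContactSet(pairs=frozenset(pairs), source=SOURCE_STRUCTURE)


# ---------------------------------------------------------------------------
# Fluctuating trajectories
# ---------------------------------------------------------------------------

@dataclass
class FluctuationSpec:
    """Trajectory request with a prescribed distance-fluctuation law.

    For each designated contact, the PDI-side residue is moved along the
    contact axis so that the Cα–Cα distance is
    ``base_distance + delta_k`` with

    * ``iid-gaussian``: delta ~ N(0, σ²)  →  true MSFD = σ²;
    * ``sinusoidal``:  delta = A·sin(2πk/period)  →  true MSFD = A²/2
      exactly when ``n_frames`` is a whole number of periods.
    """

    base: Structure
    contacts: Sequence[ContactPair]
    n_frames: int = 100
    model: str = IID_GAUSSIAN
    sigma: float = 0.5           # Å, iid-gaussian
    amplitude: float = 1.0       # Å, sinusoidal
    period: int = 100            # frames per sinusoid cycle
    base_distance: float = 20.0  # Å; large enough that distances stay positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.model not in (IID_GAUSSIAN, SINUSOIDAL):
            raise ValueError(f"unknown fluctuation model: {self.model!r}")
        seen = set()
        for c in self.contacts:
            if c.residue_b in seen:
                raise ValueError(
                    f"residue {c.residue_b} designated in more than one contact"
                )
            seen.add(c.residue_b)


def make_fluctuation_trajectory(
    spec: FluctuationSpec,
) -> tuple[Trajectory, dict[ContactPair, float]]:
    """Generate the trajectory and the exact per-contact MSFD ground truth."""
    rng = np.random.default_rng(spec.seed)
    base = spec.base
    coords0 = base.coords
    n_atoms = coords0.shape[0]
    frames = np.broadcast_to(coords0, (spec.n_frames, n_atoms, 3)).copy()
    truth: dict[ContactPair, float] = {}
    k = np.arange(spec.n_frames)
    for contact in spec.contacts:
        ia = base.calpha_index(*contact.residue_a)
        ib = base.calpha_index(*contact.residue_b)
        axis = coords0[ib] - coords0[ia]
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        if spec.model == IID_GAUSSIAN:
            delta = rng.normal(0.0, spec.sigma, size=spec.n_frames)
            truth[contact] = spec.sigma**2
        else:
            delta = spec.amplitude * np.sin(2.0 * np.pi * k / spec.period)
            truth[contact] = spec.amplitude**2 / 2.0
        target = coords0[ia] + np.outer(spec.base_distance + delta, axis)
        shift = target - coords0[ib]
        # move the whole designated residue rigidly with its Cα
        chain_b, resnum_b = contact.residue_b
        member = [
            i for i, a in enumerate(base.atoms)
            if a.chain_id == chain_b and a.residue_number == resnum_b
        ]
        for i in member:
            frames[:, i, :] = coords0[i] + shift
    times = np.arange(spec.n_frames, dtype=float)
    return Trajectory(list(base.atoms), frames, frame_times=times), truth


# ---------------------------------------------------------------------------
# Brownian steered pulling
# ---------------------------------------------------------------------------

@dataclass
class BrownianPullSpec:
    """One-dimensional overdamped steered-pulling request.

    The pulled coordinate obeys the Euler–Maruyama discretisation of

        γ·dx = (−U'(x) + k·(v·t − x))·dt + √(2·k_B·T·γ)·dW

    starting from the equilibrium distribution of U(x) + k·x²/2 (trap at
    the origin).  ``potential`` is ``("flat",)``, ``("harmonic", κ)`` or
    ``("double-well", barrier, x_min)`` with U in kcal/mol and x in Å.
    """

    potential: tuple = (FLAT,)
    protocol: PullingProtocol = field(default_factory=PullingProtocol)
    gamma: float = 1.0          # kcal·ns/(mol·Å²), friction
    dt: float = 1e-5            # ns
    n_replicas: int = 10
    seed: int = 0
    record_stride: int = 100

    def __post_init__(self) -> None:
        stiffness = self.protocol.spring_constant
        if self.potential[0] == HARMONIC:
            stiffness += self.potential[1]
        if stiffness * self.dt / self.gamma >= 0.1:
            raise ValueError(
                f"unstable time step: k·dt/γ = {stiffness * self.dt / self.gamma:.3g} "
                f"must stay below 0.1"
            )
        if self.potential[0] not in (FLAT, HARMONIC, DOUBLE_WELL):
            raise ValueError(f"unknown potential: {self.potential[0]!r}")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")


def _potential_funcs(potential: tuple) -> tuple[Callable, Callable]:
    """(U, U') for the requested potential."""
    kind = potential[0]
    if kind == FLAT:
        return (lambda x: np.zeros_like(x), lambda x: np.zeros_like(x))
    if kind == HARMONIC:
        kappa = float(potential[1])
        return (lambda x: 0.5 * kappa * x**2, lambda x: kappa * x)
    barrier, x_min = float(potential[1]), float(potential[2])
    # quartic double well U = barrier·((x/x_min)² − 1)²
    def u(x):
        return barrier * ((x / x_min) ** 2 - 1.0) ** 2

    def du(x):
        return 4.0 * barrier * x / x_min**2 * ((x / x_min) ** 2 - 1.0)

    return u, du


def brownian_ground_truth(spec: BrownianPullSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Exact ΔF(λ) for the generator's potential under its trap.

    Closed forms for flat (0) and harmonic (κkλ²/(2(κ+k))); numerical
    log-partition-function quadrature for the double well.
    """
    k = spec.protocol.spring_constant
    if spec.potential[0] == FLAT:
        return lambda lam: np.zeros_like(np.asarray(lam, dtype=float))
    if spec.potential[0] == HARMONIC:
        kappa = float(spec.potential[1])
        return lambda lam: kappa * k * np.asarray(lam, dtype=float) ** 2 / (
            2.0 * (kappa + k)
        )
    u, _ = _potential_funcs(spec.potential)
    beta = spec.protocol.beta

    def delta_f(lam):
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        x = np.linspace(-50.0, 50.0 + lam.max(), 20001)
        log_z0 = _log_trapz(-beta * (u(x) + 0.5 * k * x**2), x)
        out = np.empty_like(lam)
        for i, c in enumerate(lam):
            log_z = _log_trapz(-beta * (u(x) + 0.5 * k * (x - c) ** 2), x)
            out[i] = -(log_z - log_z0) / beta
        return out

    return delta_f


def _log_trapz(log_y: np.ndarray, x: np.ndarray) -> float:
    m = log_y.max()
    return float(m + np.log(np.trapezoid(np.exp(log_y - m), x)))


def simulate_brownian_pull(
    spec: BrownianPullSpec,
) -> tuple[ReplicaEnsemble, Callable[[np.ndarray], np.ndarray]]:
    """Simulate the ensemble; returns it with the exact ΔF(λ) oracle.

    Work is accumulated by per-step trapezoidal quadrature of F·v at the
    integration resolution and recorded every ``record_stride`` steps.
    """
    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    _, du = _potential_funcs(spec.potential)
    n_steps = int(round(proto.duration / spec.dt))
    n_rep = spec.n_replicas
    beta = proto.beta
    kT = K_BOLTZMANN * proto.temperature
    k = proto.spring_constant
    v = proto.pull_velocity
    gamma = spec.gamma

    # equilibrium start under U(x) + k·x²/2 via grid inverse-CDF sampling
    grid = np.linspace(-30.0, 30.0, 60001)
    u_fun, _ = _potential_funcs(spec.potential)
    log_p = -beta * (u_fun(grid) + 0.5 * k * grid**2)
    p = np.exp(log_p - log_p.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    x = np.interp(rng.uniform(size=n_rep), cdf, grid)

    noise_scale = np.sqrt(2.0 * kT * spec.dt / gamma)
    record_steps = list(range(0, n_steps + 1, spec.record_stride))
    if record_steps[-1] != n_steps:
        record_steps.append(n_steps)
    rec_set = set(record_steps)

    times = np.array([s * spec.dt for s in record_steps])
    pos = np.empty((n_rep, len(record_steps)))
    frc = np.empty((n_rep, len(record_steps)))
    wrk = np.empty((n_rep, len(record_steps)))

    work = np.zeros(n_rep)
    force = k * (0.0 - x)
    ptr = 0
    if 0 in rec_set:
        pos[:, 0], frc[:, 0], wrk[:, 0] = x, force, work
        ptr = 1
    for step in range(1, n_steps + 1):
        drift = (-du(x) + force) * (spec.dt / gamma)
        x = x + drift + noise_scale * rng.standard_normal(n_rep)
        new_force = k * (v * step * spec.dt - x)
        work = work + 0.5 * (force + new_force) * v * spec.dt
        force = new_force
        if step in rec_set:
            pos[:, ptr], frc[:, ptr], wrk[:, ptr] = x, force, work
            ptr += 1

    records = [
        PullingRecord(
            times=times,
            positions=pos[r],
            forces=frc[r],
            work=wrk[r] - wrk[r, 0],
            replica_id=r,
        )
        for r in range(n_rep)
    ]
    return ReplicaEnsemble(records=records, protocol=proto), brownian_ground_truth(spec)
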