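"""Structures, trajectories and region maps.

Coordinate containers for two-chain protein complexes and the residue-interval
region maps that the interface analysis keys on.  Structures are read from
fixed-column PDB text (``ATOM``/``HETATM``/``MODEL``/``ENDMDL`` records only);
trajectories come either from multi-model PDB files or from a plain
"frame-table" text format designed to be trivially diffable.

Units: coordinates and distances in Å, times in ns.

Residue numbering is always the author numbering found in the file; nothing
is renumbered.  Alternate locations are resolved to the highest-occupancy
conformer (ties: first listed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("ifacedyn")

UNASSIGNED = "unassigned"

#: Default region intervals (inclusive, author numbering) for the PDI chain:
#: the four thioredoxin-fold domains a/b/b'/a', the x linker and the termini.
PDI_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("N_terminal", 18, 25),
    ("a", 26, 133),
    ("b", 137, 232),
    ("b_prime", 235, 349),
    ("x", 350, 368),
    ("a_prime", 369, 479),
    ("C_terminal", 480, 508),
)

#: Default region intervals for the MTP alpha subunit.
MTP_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("beta_barrel", 19, 297),
    ("alpha_helical", 298, 603),
    ("lipid_binding", 604, 894),
)

#: Flexible C-terminal tail of the MTP alpha subunit (inclusive interval)
#: used by the high-fluctuation exclusion filter.
MTP_CTERM_TAIL: tuple[int, int] = (886, 894)


class PDBFormatError(ValueError):
    """A PDB coordinate record could not be parsed (carries the line number)."""


@dataclass
class Atom:
    """One atom: identity plus a Cartesian position in Å."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial} {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name} has empty element")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Structure:
    """An ordered collection of atoms grouped into chains.

    ``chains`` maps each chain id to its sorted, duplicate-free residue-number
    list; it is derived from the atoms and validated on construction.
    """

    atoms: list[Atom]
    chains: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        chains: dict[str, list[int]] = {}
        seen: set[tuple[str, int]] = set()
        for atom in self.atoms:
            key = atom.residue_key
            if key not in seen:
                seen.add(key)
                chains.setdefault(atom.chain_id, []).append(atom.residue_number)
        self.chains = {cid: sorted(nums) for cid, nums in chains.items()}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_indices(self, chain_ids: str | Iterable[str]) -> np.ndarray:
        """Indices of all atoms belonging to the given chain(s)."""
        wanted = {chain_ids} if isinstance(chain_ids, str) else set(chain_ids)
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.chain_id in wanted], dtype=int
        )

    def calpha_index(self, chain_id: str, residue_number: int) -> int:
        """Index of the Cα atom of one residue; raises ``KeyError`` if absent."""
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name.strip() == "CA"
            ):
                return i
        raise KeyError(f"no CA atom for residue {chain_id}:{residue_number}")

    def calpha_map(self, chain_id: str) -> dict[int, int]:
        """Mapping residue_number -> atom index of its Cα, for one chain.

        Residues without a Cα are omitted (with a logged warning).
        """
        out: dict[int, int] = {}
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.name.strip() == "CA":
                out.setdefault(a.residue_number, i)
        missing = set(self.chains.get(chain_id, ())) - set(out)
        if missing:
            logger.warning(
                "chain %s: %d residue(s) lack a CA atom and are skipped: %s",
                chain_id,
                len(missing),
                sorted(missing)[:10],
            )
        return out


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed atom roster.

    ``frames`` has shape (N, M, 3) for N frames over M roster atoms.
    ``frame_times`` (ns) is optional and, when present, matches N.
    """

    atom_roster: list[Atom]
    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (N, M, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.atom_roster):
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms, roster has "
                f"{len(self.atom_roster)}"
            )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, index: int) -> Structure:
        """Materialise one frame as a :class:`Structure`."""
        coords = self.frames[index]
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_number, a.residue_name,
                 a.chain_id, coords[i])
            for i, a in enumerate(self.atom_roster)
        ]
        return Structure(atoms)


@dataclass
class RegionMap:
    """Named inclusive residue intervals per chain.

    Intervals within a chain must not overlap; a residue falling in no
    interval maps to the sentinel ``"unassigned"``.
    """

    intervals: dict[str, tuple[tuple[str, int, int], ...]]

    def __post_init__(self) -> None:
        for chain, ivals in self.intervals.items():
            spans = sorted((lo, hi, name) for name, lo, hi in ivals)
            for (lo, hi, name) in spans:
                if lo > hi:
                    raise ValueError(f"{chain}/{name}: empty interval {lo}-{hi}")
            for (lo1, hi1, n1), (lo2, hi2, n2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"chain {chain}: intervals {n1} and {n2} overlap"
                    )

    def assign(self, chain_id: str, residue_number: int) -> str:
        if chain_id not in self.intervals:
            raise KeyError(f"chain {chain_id!r} is not in the region map")
        for name, lo, hi in self.intervals[chain_id]:
            if lo <= residue_number <= hi:
                return name
        return UNASSIGNED

    def region_names(self, chain_id: str) -> list[str]:
        return [name for name, _, _ in self.intervals[chain_id]]


def assign_region(region_map: RegionMap, chain_id: str, residue_number: int) -> str:
    """Region name containing ``residue_number`` on ``chain_id`` (or "unassigned")."""
    return region_map.assign(chain_id, residue_number)


def default_region_map(
    pdi_chain: str = "B",
    mtp_chain: str = "A",
    tail: tuple[int, int] = MTP_CTERM_TAIL,
) -> RegionMap:
    """Region map with the standard PDI domain layout and MTP subunit domains.

    ``tail`` only documents the MTP C-terminal tail bounds; the tail interval
    is consumed by the fluctuation exclusion filter, not by region lookup.
    """
    del tail  # recorded by callers that need it; lookup uses the domain spans
    return RegionMap({pdi_chain: PDI_REGIONS, mtp_chain: MTP_REGIONS})


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> tuple[Atom, str, float]:
    """Parse one ATOM/HETATM record -> (atom, altloc, occupancy)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: malformed coordinate record: {exc}") from exc
    if not element:
        # Fall back to the leading letter(s) of the atom name, as PDB files
        # without element columns are common for hand-written fixtures.
        element = "".join(c for c in name if c.isalpha())[:1] or "X"
    atom = Atom(serial, name, element, resnum, resname, chain, np.array([x, y, z]))
    return atom, altloc, occupancy


def _resolve_altlocs(
    records: list[tuple[Atom, str, float]]
) -> list[Atom]:
    """Keep one conformer per (chain, residue, atom name): highest occupancy,
    ties broken by file order."""
    best: dict[tuple[str, int, str, str], tuple[float, int, Atom]] = {}
    order: list[tuple[str, int, str, str]] = []
    for idx, (atom, altloc, occ) in enumerate(records):
        key = (atom.chain_id, atom.residue_number, atom.name, atom.residue_name)
        if key not in best:
            best[key] = (occ, idx, atom)
            order.append(key)
        elif altloc and occ > best[key][0]:
            best[key] = (occ, idx, atom)
    return [best[k][2] for k in order]


def _read_pdb_models(path: str | Path) -> list[list[tuple[Atom, str, float]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    in_model = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif record == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif record in ("ATOM", "HETATM"):
            current.append(_parse_pdb_atom(line, lineno))
    if current or not models:
        models.append(current)
    del in_model
    return models


def read_pdb(path: str | Path, model_index: int = 0) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Author residue numbering is preserved; alternate locations are resolved
    to the highest-occupancy conformer (ties: first listed).
    """
    models = _read_pdb_models(path)
    if not 0 <= model_index < len(models):
        raise IndexError(
            f"model_index {model_index} out of range: file has {len(models)} model(s)"
        )
    atoms = _resolve_altlocs(models[model_index])
    if not atoms:
        raise PDBFormatError(f"{path}: selected model contains no atoms")
    return Structure(atoms)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as single-model PDB text (%.3f coordinates)."""
    with open(path, "w") as fh:
        for atom in structure.atoms:
            fh.write(_format_pdb_line(atom))
        fh.write("END\n")


def _format_pdb_line(atom: Atom) -> str:
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.position
    return (
        f"ATOM  {atom.serial:>5d} {name}{'':1s}{atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}\n"
    )


# ---------------------------------------------------------------------------
# Trajectory reading / writing
# ---------------------------------------------------------------------------

FRAME_TABLE = "frame-table"
MULTI_MODEL_PDB = "multi-model-pdb"


def read_trajectory(path: str | Path, format: str = MULTI_MODEL_PDB) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a frame-table text file.

    All frames must share one atom roster; a frame with a deviating atom
    count raises ``ValueError`` naming the frame (1-based).
    """
    if format == MULTI_MODEL_PDB:
        traj = _read_multimodel_pdb(path)
    elif format == FRAME_TABLE:
        traj = _read_frame_table(path)
    else:
        raise ValueError(f"unknown trajectory format: {format!r}")
    logger.info("read %d frame(s) from %s", traj.n_frames, path)
    return traj


def _read_multimodel_pdb(path: str | Path) -> Trajectory:
    models = _read_pdb_models(path)
    if not any(models):
        raise PDBFormatError(f"{path}: no coordinate records found")
    if len(models) > 1 and not models[-1]:
        models = models[:-1]  # trailing empty block after the last ENDMDL
    roster = _resolve_altlocs(models[0])
    n_atoms = len(roster)
    frames = np.empty((len(models), n_atoms, 3))
    for k, model in enumerate(models):
        atoms = _resolve_altlocs(model)
        if len(atoms) != n_atoms:
            raise ValueError(
                f"frame {k + 1} has {len(atoms)} atoms, expected {n_atoms}"
            )
        frames[k] = [a.position for a in atoms]
    return Trajectory(roster, frames)


def _read_frame_table(path: str | Path) -> Trajectory:
    """Frame-table format: first line is the atom count M; then, per frame,
    M lines of ``index x y z``; frames separated by one blank line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trajectory file: {path}")
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty frame-table file")
    n_atoms = int(lines[0])
    frames: list[np.ndarray] = []
    block: list[list[float]] = []

    def flush() -> None:
        if block:
            if len(block) != n_atoms:
                raise ValueError(
                    f"frame {len(frames) + 1} has {len(block)} atoms, expected {n_atoms}"
                )
            frames.append(np.array(block))
            block.clear()

    for line in lines[1:]:
        if not line.strip():
            flush()
            continue
        parts = line.split()
        block.append([float(parts[1]), float(parts[2]), float(parts[3])])
    flush()
    if not frames:
        raise ValueError(f"{path}: no frames found")
    roster = [
        Atom(i + 1, "CA", "C", i + 1, "GLY", "A", frames[0][i])
        for i in range(n_atoms)
    ]
    return Trajectory(roster, np.array(frames))


def write_trajectory(
    trajectory: Trajectory, path: str | Path, format: str = FRAME_TABLE
) -> None:
    """Write a trajectory; frame-table uses ``%.17g`` so it round-trips exactly."""
    if format == FRAME_TABLE:
        with open(path, "w") as fh:
            fh.write(f"{len(trajectory.atom_roster)}\n")
            for frame in trajectory.frames:
                for i, (x, y, z) in enumerate(frame):
                    fh.write(f"{i + 1} {x:.17g} {y:.17g} {z:.17g}\n")
                fh.write("\n")
    elif format == MULTI_MODEL_PDB:
        with open(path, "w") as fh:
            for k in range(trajectory.n_frames):
                fh.write(f"MODEL     {k + 1:>4d}\n")
                for i, atom in enumerate(trajectory.atom_roster):
                    shifted = Atom(
                        atom.serial, atom.name, atom.element, atom.residue_number,
                        atom.residue_name, atom.chain_id, trajectory.frames[k, i],
                    )
                    fh.write(_format_pdb_line(shifted))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unknown trajectory format: {format!r}")
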