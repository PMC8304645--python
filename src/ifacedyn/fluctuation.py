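"""Mean-square fluctuation of distance (MSFD) over trajectories.

For an interface contact between residues *i* and *j*, with per-frame Cα–Cα
distance R_ij,k over N stored conformations,

    MSFD_ij = (1/N) Σ_k (R_ij,k − R̄_ij)²

i.e. the *population* variance (divisor N, matching the defining formula;
at the trajectory sizes of interest the distinction from N−1 is
negligible).  High MSFD marks a flexible, hence unstable, contact.

Two decision rules operate on MSFD tables:

* the C-terminal exclusion filter — contacts involving the flexible MTP
  C-terminal tail are dropped when their MSFD exceeds 14 Å² in at least
  one trajectory (both conditions strict / required);
* the pairwise comparison rule — between two conditions, a contact counts
  for a condition only when its MSFD there exceeds the other condition's
  by strictly more than a 1 Å² margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contacts import ContactPair, ContactSet

logger = logging.getLogger("ifacedyn")

EXCLUSION_THRESHOLD = 14.0   # Å², strict
COMPARISON_MARGIN = 1.0      # Å², strict
CONTACT_REGIONS = ("region1", "region2", "region3", "region3_prime")


@dataclass
class DistanceSeries:
    """Per-frame Cα–Cα distance (Å) for one interface contact."""

    contact: ContactPair
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("distance series must be one-dimensional")
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")


@dataclass
class MSFDTable:
    """MSFD per contact (Å²) for one labelled trajectory."""

    values: dict[ContactPair, float]
    label: str = ""
    n_frames: int = 0

    def __post_init__(self) -> None:
        bad = [c for c, v in self.values.items() if v < 0]
        if bad:
            raise ValueError(f"negative MSFD for {bad[0]}")

    @property
    def contacts(self) -> frozenset[ContactPair]:
        return frozenset(self.values)


@dataclass
class RegionAverages:
    """Mean MSFD per contact region, plus the pooled four-region mean."""

    means: dict[str, float]
    counts: dict[str, int]


def distance_series(trajectory, contact: ContactPair) -> DistanceSeries:
    """Per-frame Euclidean Cα–Cα distance for one contact."""
    ref = trajectory.frame_structure(0)
    ia = ref.calpha_index(*contact.residue_a)
    ib = ref.calpha_index(*contact.residue_b)
    vec = trajectory.frames[:, ia, :] - trajectory.frames[:, ib, :]
    return DistanceSeries(contact=contact, values=np.linalg.norm(vec, axis=1))


def msfd(series: DistanceSeries | np.ndarray) -> float:
    """Population variance (divisor N) of a distance series, in Å²."""
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series, float)
    if values.size < 2:
        raise ValueError("MSFD needs at least 2 frames")
    return float(np.mean((values - values.mean()) ** 2))


def msfd_table(
    trajectory, contacts: ContactSet, label: str = "", stride: int = 1
) -> MSFDTable:
    """MSFD of every contact in ``contacts`` over one trajectory.

    ``stride`` subsamples the stored frames (default 1: use them all),
    standing in for representative-conformation selection.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > 1:
        logger.info("MSFD over every %d-th of %d frames", stride, trajectory.n_frames)
    values = {
        c: msfd(distance_series(trajectory, c).values[::stride]) for c in contacts
    }
    n_used = len(range(0, trajectory.n_frames, stride))
    return MSFDTable(values=values, label=label, n_frames=n_used)


def _common_universe(tables: Sequence[MSFDTable]) -> frozenset[ContactPair]:
    universe = tables[0].contacts
    for t in tables[1:]:
        if t.contacts != universe:
            raise ValueError(
                f"MSFD tables cover different contact universes "
                f"({len(t.contacts)} vs {len(universe)} contacts)"
            )
    return universe


def apply_cterm_exclusion(
    tables: Sequence[MSFDTable],
    tail_region: tuple[int, int] = (886, 894),
    threshold: float = EXCLUSION_THRESHOLD,
) -> tuple[frozenset[ContactPair], dict[ContactPair, list[str]]]:
    """Partition contacts by the C-terminal-tail high-fluctuation rule.

    A contact is excluded iff its MTP-side residue number lies in
    ``tail_region`` (inclusive) AND its MSFD exceeds ``threshold`` (strictly)
    in at least one table.  Returns ``(kept, excluded)`` where ``excluded``
    maps each dropped contact to the labels of the trajectories that
    triggered it.
    """
    universe = _common_universe(tables)
    lo, hi = tail_region
    excluded: dict[ContactPair, list[str]] = {}
    for contact in universe:
        if not lo <= contact.residue_a[1] <= hi:
            continue
        triggers = [t.label for t in tables if t.values[contact] > threshold]
        if triggers:
            excluded[contact] = triggers
    kept = frozenset(universe - set(excluded))
    logger.info(
        "C-terminal exclusion: %d kept, %d excluded (threshold %.1f Å², tail %d-%d)",
        len(kept), len(excluded), threshold, lo, hi,
    )
    return kept, excluded


def compare_conditions(
    table_a: MSFDTable,
    table_b: MSFDTable,
    margin: float = COMPARISON_MARGIN,
) -> tuple[int, int, dict[ContactPair, float]]:
    """Count contacts strictly more than ``margin`` Å² higher per condition.

    Returns ``(n_a_higher, n_b_higher, deltas)`` with
    delta = MSFD_a − MSFD_b; contacts within the ±margin band count for
    neither condition.
    """
    universe = _common_universe([table_a, table_b])
    deltas = {c: table_a.values[c] - table_b.values[c] for c in universe}
    n_a = sum(1 for d in deltas.values() if d > margin)
    n_b = sum(1 for d in deltas.values() if -d > margin)
    return n_a, n_b, deltas


def region_average_msfd(
    table: MSFDTable,
    contacts: ContactSet | frozenset[ContactPair] | None = None,
    pooled: bool = True,
) -> RegionAverages:
    """Arithmetic mean MSFD per contact region.

    ``all_four`` is the pooled mean over every contact in regions 1, 2, 3
    and 3' (default), or the unweighted mean of the four region averages
    when ``pooled`` is False.  Regions with no member contacts are absent
    from the result, never reported as zero.
    """
    members = frozenset(contacts) if contacts is not None else table.contacts
    groups: dict[str, list[float]] = {}
    for contact in members:
        groups.setdefault(contact.region, []).append(table.values[contact])
    means = {r: float(np.mean(v)) for r, v in groups.items()}
    counts = {r: len(v) for r, v in groups.items()}
    in_four = [v for r in CONTACT_REGIONS for v in groups.get(r, [])]
    if in_four:
        if pooled:
            means["all_four"] = float(np.mean(in_four))
        else:
            means["all_four"] = float(
                np.mean([means[r] for r in CONTACT_REGIONS if r in means])
            )
        counts["all_four"] = len(in_four)
    return RegionAverages(means=means, counts=counts)
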