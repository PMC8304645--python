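"""End-to-end orchestration: per-condition trajectories to report tables.

The interface branch mirrors how the stability comparison is run on a pair
of conditions (e.g. the bare complex vs the ligand-bound complex): contact
detection per trajectory, union with an optional crystal structure, MSFD
per condition, the C-terminal high-fluctuation exclusion, the ±1 Å²
pairwise comparison, region averages, and Table-layout atom-pair / area
summaries on each condition's final conformation.  The pulling branch goes
from replica work records to PMF curves.

All report tables are pure functions of (config, input files); the
provenance block carries a config hash so reruns can be checked for
byte-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .contacts import (
    ContactPair,
    ContactSet,
    contact_region,
    contacts_from_structure,
    contacts_from_trajectory,
    count_interface_atom_pairs,
    interface_area,
    union_contacts,
    BURIED_SASA,
)
from .fluctuation import (
    MSFDTable,
    apply_cterm_exclusion,
    compare_conditions,
    msfd_table,
    region_average_msfd,
)
from .pulling import (
    PullingProtocol,
    pmf_curve,
    read_pulling_records,
    write_pmf_curve,
)
from .structure_io import (
    MULTI_MODEL_PDB,
    RegionMap,
    MTP_CTERM_TAIL,
    default_region_map,
    read_pdb,
    read_trajectory,
)

logger = logging.getLogger("ifacedyn")

#: Row order of the per-region summary tables, keyed to the PDI regions.
TABLE_ROWS = ("N_terminal", "a", "b", "b_prime", "x", "a_prime", "C_terminal")


class ConfigError(ValueError):
    """The analysis configuration is invalid."""


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs, with the standard constants as defaults."""

    conditions: dict[str, dict[str, str]]
    pdi_chain: str = "B"
    mtp_chain: str = "A"
    crystal_structure: str | None = None
    trajectory_format: str = MULTI_MODEL_PDB
    atom_pair_cutoff: float = 5.0
    contact_cutoff: float = 7.0
    comparison_margin: float = 1.0
    exclusion_threshold: float = 14.0
    tail: tuple[int, int] = MTP_CTERM_TAIL
    heavy_only: bool = False
    area_method: str = BURIED_SASA
    temperature: float = 300.0
    pull_velocity: float = 10.0
    spring_constant: float = 10.0
    lambda_max: float | None = None
    output_dir: str = "ifacedyn_report"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        for cutoff_name in ("atom_pair_cutoff", "contact_cutoff",
                            "comparison_margin", "exclusion_threshold"):
            if getattr(self, cutoff_name) <= 0:
                raise ConfigError(f"{cutoff_name} must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition labels must be unique")
        self.tail = (int(self.tail[0]), int(self.tail[1]))

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        import tomllib

        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except FileNotFoundError:
            raise
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "tail" in raw:
            raw["tail"] = tuple(raw["tail"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def region_map(self) -> RegionMap:
        return default_region_map(pdi_chain=self.pdi_chain, mtp_chain=self.mtp_chain)


@dataclass
class RunReport:
    """Report tables plus a provenance block."""

    tables: dict[str, pd.DataFrame]
    provenance: dict[str, Any] = field(default_factory=dict)

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str) + "\n"
        )


def _contact_sort_key(c: ContactPair) -> tuple:
    return (c.residue_a, c.residue_b)


def _region_table(total: float, by_region: dict[str, float], value_name: str) -> pd.DataFrame:
    rows = []
    for region in TABLE_ROWS:
        rows.append({"region": region, value_name: by_region.get(region, 0)})
    unassigned = by_region.get("unassigned", 0)
    if unassigned:
        rows.append({"region": "unassigned", value_name: unassigned})
    rows.append({"region": "All", value_name: total})
    rows.append(
        {
            "region": "All_except_C_terminal",
            value_name: total - by_region.get("C_terminal", 0),
        }
    )
    return pd.DataFrame(rows)


def msfd_table_to_frame(table: MSFDTable) -> pd.DataFrame:
    rows = [
        {
            "chain_a": c.residue_a[0],
            "residue_a": c.residue_a[1],
            "chain_b": c.residue_b[0],
            "residue_b": c.residue_b[1],
            "region": c.region,
            "msfd_A2": table.values[c],
        }
        for c in sorted(table.values, key=_contact_sort_key)
    ]
    return pd.DataFrame(rows)


def msfd_table_from_frame(df: pd.DataFrame, label: str = "") -> MSFDTable:
    values = {
        ContactPair(
            residue_a=(str(r.chain_a), int(r.residue_a)),
            residue_b=(str(r.chain_b), int(r.residue_b)),
            region=str(r.region),
        ): float(r.msfd_A2)
        for r in df.itertuples()
    }
    return MSFDTable(values=values, label=label)


def run_interface_analysis(config: AnalysisConfig) -> RunReport:
    """Contacts → union → MSFD → exclusion → comparisons → region tables."""
    region_map = config.region_map()
    stage = "load"
    try:
        trajectories = {
            label: read_trajectory(paths["trajectory"], format=config.trajectory_format)
            for label, paths in config.conditions.items()
        }
        contact_sets = {}
        stage = "contacts"
        for label, traj in trajectories.items():
            contact_sets[label] = contacts_from_trajectory(
                traj, config.mtp_chain, config.pdi_chain,
                cutoff=config.contact_cutoff, region_map=region_map,
            )
        sets = list(contact_sets.values())
        if config.crystal_structure:
            crystal = read_pdb(config.crystal_structure)
            sets.append(
                contacts_from_structure(
                    crystal, config.mtp_chain, config.pdi_chain,
                    cutoff=config.contact_cutoff, region_map=region_map,
                )
            )
        master = union_contacts(sets)
        logger.info("master contact set: %d contacts", len(master))

        stage = "msfd"
        tables = {
            label: msfd_table(traj, master, label=label)
            for label, traj in trajectories.items()
        }
        kept, excluded = apply_cterm_exclusion(
            list(tables.values()),
            tail_region=config.tail,
            threshold=config.exclusion_threshold,
        )
        kept_tables = {
            label: MSFDTable(
                values={c: t.values[c] for c in kept}, label=label, n_frames=t.n_frames
            )
            for label, t in tables.items()
        }

        stage = "tables"
        out_tables: dict[str, pd.DataFrame] = {}
        for label, t in tables.items():
            out_tables[f"msfd_{label}"] = msfd_table_to_frame(t)
        out_tables["excluded_contacts"] = pd.DataFrame(
            [
                {
                    "chain_a": c.residue_a[0],
                    "residue_a": c.residue_a[1],
                    "chain_b": c.residue_b[0],
                    "residue_b": c.residue_b[1],
                    "triggering_conditions": ";".join(labels),
                }
                for c, labels in sorted(excluded.items(), key=lambda kv: _contact_sort_key(kv[0]))
            ],
            columns=["chain_a", "residue_a", "chain_b", "residue_b",
                     "triggering_conditions"],
        )

        labels = sorted(config.conditions)
        comparison_rows = []
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                n_a, n_b, _ = compare_conditions(
                    kept_tables[la], kept_tables[lb], margin=config.comparison_margin
                )
                comparison_rows.append(
                    {"condition_a": la, "condition_b": lb,
                     "n_a_higher": n_a, "n_b_higher": n_b,
                     "margin_A2": config.comparison_margin}
                )
        out_tables["msfd_comparisons"] = pd.DataFrame(comparison_rows)

        avg_rows = []
        for label in labels:
            averages = region_average_msfd(kept_tables[label])
            for region in sorted(averages.means):
                avg_rows.append(
                    {"condition": label, "region": region,
                     "mean_msfd_A2": averages.means[region],
                     "n_contacts": averages.counts[region]}
                )
        out_tables["region_average_msfd"] = pd.DataFrame(avg_rows)

        stage = "pairs-and-areas"
        for label, traj in trajectories.items():
            final = traj.frame_structure(traj.n_frames - 1)
            pairs = count_interface_atom_pairs(
                final, config.mtp_chain, config.pdi_chain,
                cutoff=config.atom_pair_cutoff, region_map=region_map,
                heavy_only=config.heavy_only,
            )
            out_tables[f"atom_pairs_{label}"] = _region_table(
                pairs.total, pairs.by_region, "n_atom_pairs"
            )
            area = interface_area(
                final, config.mtp_chain, config.pdi_chain,
                method=config.area_method, region_map=region_map,
            )
            out_tables[f"interface_area_{label}"] = _region_table(
                area.total, area.by_region, "area_A2"
            )
    except (FileNotFoundError, ValueError, KeyError) as exc:
        raise type(exc)(f"interface analysis failed at stage {stage!r}: {exc}") from exc

    return RunReport(
        tables=out_tables,
        provenance={
            "analysis": "interface",
            "config_hash": config.config_hash(),
            "version": __version__,
            "n_contacts_master": len(master),
            "n_contacts_kept": len(kept),
        },
    )


def run_pulling_analysis(config: AnalysisConfig) -> RunReport:
    """Replica work records → PMF curves per condition."""
    protocol = PullingProtocol(
        pull_velocity=config.pull_velocity,
        spring_constant=config.spring_constant,
        temperature=config.temperature,
    )
    out_tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for label in sorted(config.conditions):
        paths = config.conditions[label]
        if "pulling" not in paths:
            raise ConfigError(f"condition {label!r} has no 'pulling' record path")
        ensemble = read_pulling_records(paths["pulling"], protocol=protocol)
        curve = pmf_curve(
            ensemble, temperature=config.temperature, lambda_max=config.lambda_max
        )
        out_tables[f"pmf_{label}"] = pd.DataFrame(
            {
                "lambda_A": curve.lam,
                "dF_cumulant": curve.delta_f,
                "dF_exponential": curve.delta_f_exp,
                "mean_W": curve.mean_work,
                "var_W": curve.work_variance,
                "n_replicas": curve.n_replicas,
            }
        )
        summary_rows.append(
            {
                "condition": label,
                "n_replicas": curve.n_replicas,
                "lambda_end_A": float(curve.lam[-1]),
                "dF_end_kcal_mol": float(curve.delta_f[-1]),
            }
        )
    out_tables["pmf_summary"] = pd.DataFrame(summary_rows)
    return RunReport(
        tables=out_tables,
        provenance={
            "analysis": "pulling",
            "config_hash": config.config_hash(),
            "version": __version__,
        },
    )
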