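"""Orchestration: run all three metrics over named conditions from one config.

A run is described by an :class:`AnalysisConfig` (usually read from YAML):
named conditions (trajectory + reference + chain), the loop regions, the
donor/acceptor selections and threshold, and the landscape parameters.  The
pipeline computes flexibility and hydride occupancy per condition, fits the
dihedral-PCA landscape on the POOLED conditions (running conditions
separately would produce incomparable projections and is deliberately
unsupported), and emits per-condition TSV tables plus one JSON report with a
provenance block (config hash, seeds, package version).

A failing stage is recorded in the report with its condition and stage name;
the remaining stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalytic_geometry import DEFAULT_THRESHOLD, active_occupancy, distance_series
from .exceptions import ConfdynError, ConfigError
from .flexibility import (
    RegionSet,
    default_loop_regions,
    region_rmsd_series,
    regions_from_string,
)
from .landscape import fit_landscape, free_energy_surface, kmeans_states, phi_psi_matrix
from .structure_io import (
    SelectionExpression,
    parse_selection,
    read_multimodel_pdb,
    select_atoms,
)

logger = logging.getLogger(__name__)

DEFAULT_DONOR = "resname MNA, atom C4, hetero"
DEFAULT_ACCEPTOR = "resname FAD, atom N5, hetero"


@dataclass(frozen=True)
class Condition:
    name: str
    trajectory: str
    reference: str | None = None
    chain: str = "A"


@dataclass
class AnalysisConfig:
    conditions: list[Condition]
    regions: RegionSet
    donor: SelectionExpression
    acceptor: SelectionExpression
    threshold: float = DEFAULT_THRESHOLD
    bins: int = 60
    k: int = 3
    seed: int = 0
    dihedral_mode: str = "raw"
    output_dir: str = "confdyn_out"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("need at least one condition")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigError("condition names must be unique")

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        try:
            conditions = [
                Condition(
                    name=c["name"],
                    trajectory=c["trajectory"],
                    reference=c.get("reference"),
                    chain=c.get("chain", "A"),
                )
                for c in raw["conditions"]
            ]
        except KeyError as exc:
            raise ConfigError(f"condition entry missing field {exc}") from exc
        if not conditions:
            raise ConfigError("need at least one condition")
        chain = conditions[0].chain
        regions_raw = raw.get("regions", "default")
        regions = (
            default_loop_regions(chain)
            if regions_raw == "default"
            else regions_from_string(regions_raw, chain)
        )
        return cls(
            conditions=conditions,
            regions=regions,
            donor=parse_selection(raw.get("donor", DEFAULT_DONOR)),
            acceptor=parse_selection(raw.get("acceptor", DEFAULT_ACCEPTOR)),
            threshold=float(raw.get("threshold", DEFAULT_THRESHOLD)),
            bins=int(raw.get("bins", 60)),
            k=int(raw.get("k", 3)),
            seed=int(raw.get("seed", 0)),
            dihedral_mode=raw.get("dihedral_mode", "raw"),
            output_dir=raw.get("output_dir", "confdyn_out"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def semantic_dict(self) -> dict:
        """All fields that affect results (used for the provenance hash)."""
        return {
            "conditions": [
                {
                    "name": c.name,
                    "trajectory": c.trajectory,
                    "reference": c.reference,
                    "chain": c.chain,
                }
                for c in self.conditions
            ],
            "regions": [
                [r.name, r.chain_id, r.start, r.end] for r in self.regions.regions
            ],
            "donor": repr(self.donor),
            "acceptor": repr(self.acceptor),
            "threshold": self.threshold,
            "bins": self.bins,
            "k": self.k,
            "seed": self.seed,
            "dihedral_mode": self.dihedral_mode,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Machine-readable combined results with a provenance block."""

    flexibility: dict[str, dict] = field(default_factory=dict)
    occupancy: dict[str, dict] = field(default_factory=dict)
    landscape: dict = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "flexibility": self.flexibility,
            "occupancy": self.occupancy,
            "landscape": self.landscape,
            "errors": self.errors,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_analysis(config: AnalysisConfig, write_outputs: bool = True) -> Report:
    """Run flexibility, hydride occupancy and the pooled landscape per config."""
    out_dir = Path(config.output_dir) / config.config_hash()
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    report = Report(
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    )

    ensembles: dict[str, tuple] = {}
    for cond in config.conditions:
        try:
            traj = read_multimodel_pdb(cond.trajectory)
            ref = (
                read_multimodel_pdb(cond.reference).frame(0)
                if cond.reference
                else None
            )
            ensembles[cond.name] = (cond, traj, ref)
        except (ConfdynError, OSError) as exc:
            report.errors.append(
                {"condition": cond.name, "stage": "load", "error": str(exc)}
            )

    for name, (cond, traj, ref) in ensembles.items():
        t0 = time.perf_counter()
        try:
            fit_expr = SelectionExpression(
                chain=cond.chain, atom_names=frozenset({"CA"}), hetero=False
            )
            fit_sel = select_atoms(traj, fit_expr)
            region_sel = select_atoms(traj, config.regions.to_expression())
            flex = region_rmsd_series(traj, ref, fit_sel, region_sel)
            report.flexibility[name] = flex.summary()
            if write_outputs:
                pd.DataFrame(
                    {
                        "frame_index": np.arange(flex.n_frames),
                        "rmsd_angstrom": flex.per_frame_rmsd,
                    }
                ).to_csv(out_dir / f"{name}_flexibility.tsv", sep="\t", index=False)
        except ConfdynError as exc:
            report.errors.append(
                {"condition": name, "stage": "flexibility", "error": str(exc)}
            )
        logger.info("flexibility[%s]: %.2fs", name, time.perf_counter() - t0)

        t0 = time.perf_counter()
        try:
            donor = select_atoms(traj, config.donor)
            acceptor = select_atoms(traj, config.acceptor)
            dists = distance_series(traj, donor, acceptor)
            series = active_occupancy(dists, config.threshold, donor, acceptor)
            report.occupancy[name] = series.summary()
            if write_outputs:
                pd.DataFrame(
                    {
                        "frame_index": np.arange(series.n_frames),
                        "distance_angstrom": series.distances,
                        "active": series.active_mask.astype(int),
                    }
                ).to_csv(out_dir / f"{name}_hydride.tsv", sep="\t", index=False)
        except ConfdynError as exc:
            report.errors.append(
                {"condition": name, "stage": "hydride", "error": str(exc)}
            )
        logger.info("hydride[%s]: %.2fs", name, time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        matrices = [
            phi_psi_matrix(traj, cond.chain, condition_label=name)
            for name, (cond, traj, _) in ensembles.items()
        ]
        if not matrices:
            raise ConfigError("no condition loaded successfully")
        model = fit_landscape(matrices, dihedral_mode=config.dihedral_mode)
        model.fes = free_energy_surface(model.pooled_projection(), bins=config.bins)
        centers, labels, occupancy = kmeans_states(model, k=config.k, seed=config.seed)
        report.landscape = {
            "explained_variance": [float(v) for v in model.explained_variance],
            "explained_variance_ratio": [
                float(v) for v in model.explained_variance_ratio()
            ],
            "cluster_centers": centers.tolist(),
            "occupancy": occupancy,
            "dihedral_mode": config.dihedral_mode,
        }
        if write_outputs:
            rows = []
            for name, proj in model.projections.items():
                for i in range(proj.shape[0]):
                    rows.append(
                        (name, proj[i, 0], proj[i, 1], labels[name][i])
                    )
            pd.DataFrame(
                rows, columns=["condition", "pc1", "pc2", "cluster_label"]
            ).to_csv(out_dir / "landscape.tsv", sep="\t", index=False)
    except ConfdynError as exc:
        report.errors.append({"condition": "*", "stage": "landscape", "error": str(exc)})
    logger.info("landscape: %.2fs", time.perf_counter() - t0)

    if write_outputs:
        (out_dir / "report.json").write_text(report.to_json())
    return report
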