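"""End-to-end orchestration: simulate inputs, run every stage, write a manifest.

A run is fully described by a :class:`PipelineConfig` (serialisable to/from
YAML) plus its input files; the manifest records the effective config and a
SHA-256 hash of every artefact, so two runs with the same seed and inputs
produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, compare, footfall, haz, phases, stays, synth
from .geo import read_units_geojson, write_units_geojson

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "simulate", "run_all"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run: paths, parameters, one seed."""

    outdir: str = "hazsense_run"
    trajectories: str = "trajectories.csv"
    units: str = "units.geojson"
    features: str = "features.csv"
    seed: int = 0
    d_max_m: float = 50.0
    t_min_s: float = 300.0
    benchmark_start: str = "2020-01-01"
    benchmark_end: str = "2020-02-29"
    n_min: int = 2
    n_max: int = 15
    linkage: str = "ward"
    cv_folds: int = 10
    n_param_draws: int = 15
    calendar_path: str | None = None  # None -> packaged default calendar

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def calendar(self) -> list[phases.RestrictionPhase]:
        if self.calendar_path:
            return phases.calendar_from_yaml(self.calendar_path)
        return phases.default_calendar()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate(config: PipelineConfig, scenario: synth.SyntheticScenario | None = None) -> dict:
    """Write the synthetic input bundle: trajectories, units, features, ledger.

    Uses the packaged demo scenario (re-seeded from the config) unless an
    explicit scenario is given.  Returns a manifest of the written files.
    """
    if scenario is None:
        scenario = synth.demo_scenario(seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    units = synth.generate_units(
        scenario.grid_rows, scenario.grid_cols, scenario.cell_size_m, scenario.origin
    )
    assignment = synth.archetype_assignment(units["unit_id"], scenario)
    points, ledger = synth.generate_trajectories(scenario, units, assignment)
    feats = synth.generate_urban_features(units, assignment, scenario)

    units_out = units.merge(
        assignment.rename("archetype"), left_on="unit_id", right_index=True, how="left"
    )
    paths = {
        "trajectories": outdir / config.trajectories,
        "units": outdir / config.units,
        "features": outdir / config.features,
        "ledger": outdir / "planted_stays.csv",
    }
    synth.write_trajectories(points, paths["trajectories"])
    write_units_geojson(units_out, paths["units"])
    feats.to_csv(paths["features"], index=False)
    ledger_out = ledger.copy()
    for col in ("start_time", "end_time"):
        ledger_out[col] = ledger_out[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    ledger_out.to_csv(paths["ledger"], index=False)
    logger.info(
        "simulated %d points, %d planted stays over %d units", len(points), len(ledger), len(units)
    )
    return {name: {"path": str(p), "sha256": _sha256(p)} for name, p in paths.items()}


def run_all(config: PipelineConfig) -> dict:
    """Run detect-stays -> footfall -> recovery -> delineate -> compare -> associate.

    Inputs are the files named in the config (produce them with
    :func:`simulate` for the demo).  Writes every stage's artefact under
    ``outdir`` and returns the manifest (also written as ``manifest.json``).
    Stage failures abort with the stage name; artefacts already written are
    listed in the raised error's message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calendar = config.calendar()
    artefacts: dict[str, Path] = {}
    counts: dict[str, int] = {}
    stage = "validate-inputs"
    try:
        for name in ("trajectories", "units", "features"):
            path = outdir / getattr(config, name)
            if not path.exists():
                raise FileNotFoundError(f"missing input file: {path}")

        stage = "detect-stays"
        traj = stays.read_trajectories(outdir / config.trajectories)
        params = stays.StayParams(config.d_max_m, config.t_min_s)
        stay_table = stays.detect_stays_all(traj, params)
        counts["points_read"] = len(traj)
        counts["stays_detected"] = len(stay_table)
        artefacts["stays"] = outdir / "stays.csv"
        stays.write_stays(stay_table, artefacts["stays"])

        stage = "footfall"
        units = read_units_geojson(outdir / config.units)
        assigned = footfall.assign_stays_to_units(stay_table, units)
        counts["stays_assigned"] = len(stay_table) - assigned.attrs["n_unassigned"]
        matrix = footfall.build_footfall_matrix(
            assigned, units["unit_id"], calendar[0].start_date, calendar[-1].end_date, strict=False
        )
        artefacts["matrix"] = outdir / "matrix.csv"
        footfall.write_matrix(matrix, artefacts["matrix"])

        stage = "recovery"
        rec = footfall.recovery_index(
            matrix,
            dt.date.fromisoformat(config.benchmark_start),
            dt.date.fromisoformat(config.benchmark_end),
        )
        recovery_df = pd.DataFrame(
            {
                "date": [d.date().isoformat() for d in rec.daily.index],
                "daily_index_pct": rec.daily.to_numpy().round(4),
                "rolling_index_pct": rec.rolling.to_numpy().round(4),
            }
        )
        artefacts["recovery"] = outdir / "recovery.csv"
        recovery_df.to_csv(artefacts["recovery"], index=False)

        stage = "delineate"
        partitions = haz.delineate_per_phase(
            matrix, calendar, config.n_min, config.n_max, config.linkage
        )
        counts["partitions"] = len(partitions)
        hazdir = outdir / "hazs"
        hazdir.mkdir(exist_ok=True)
        for name, part in partitions.items():
            slug = name.lower().replace(" ", "_")
            artefacts[f"partition_{slug}"] = hazdir / f"{slug}.csv"
            haz.write_partition(part, artefacts[f"partition_{slug}"])

        stage = "compare"
        phase_parts = [partitions[p.name] for p in calendar]
        cmatrix = compare.pairwise_matrix(phase_parts)
        artefacts["comparison"] = outdir / "contingency.csv"
        cmatrix.round(6).to_csv(artefacts["comparison"])

        stage = "associate"
        feats = pd.read_csv(outdir / config.features)
        results, accuracy, importance = association.per_phase_association(
            feats,
            list(partitions.values()),
            cv_folds=config.cv_folds,
            n_param_draws=config.n_param_draws,
            seed=config.seed,
        )
        counts["association_results"] = len(results)
        artefacts["accuracy"] = outdir / "accuracy.csv"
        accuracy.round(6).to_csv(artefacts["accuracy"])
        artefacts["importance"] = outdir / "importance.csv"
        importance.round(6).to_csv(artefacts["importance"])
    except Exception as exc:
        inventory = sorted(str(p) for p in artefacts.values())
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}; partial outputs: {inventory}"
        ) from exc

    manifest = {
        "config": config.to_dict(),
        "counts": counts,
        "artefacts": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(artefacts.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", counts)
    return manifest
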