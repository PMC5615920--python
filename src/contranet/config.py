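"""Scenario files, validation, and run outputs.

A scenario is declared in a small YAML document (schema version 1):

.. code-block:: yaml

    schema: 1
    name: my-network
    filaments: {count: 100, length: 3.0, rigidity: 0.01}   # or rigid: true
    domain: {kind: disc, radius: 4.0}                      # or periodic + side
    connectors:
      motor: {subunits: [plus_motor, plus_motor], count: 800}
      crosslinker: {subunits: [side_binder, side_binder], count: 800}
    turnover: {enabled: false, rate: 0.0}
    simulation: {dt: 0.001, t_end: 10.0, seed: 1}

Unknown keys are rejected with the offending key named; omitted keys take
the documented defaults of the corresponding dataclasses.  Outputs are plain
text: a frames CSV (header row, UTF-8, '.' decimal), a summary JSON, the
resolved scenario echoed back as YAML, and a run log.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import yaml

from .connectors import ConnectorType, SubunitKind
from .observables import TrajectorySummary
from .simulate import Trajectory
from .world import Domain, FilamentSpec, Scenario, SimParams, TurnoverSpec

__all__ = [
    "load_config",
    "scenario_to_dict",
    "write_outputs",
    "read_frames",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_FILAMENT_KEYS = {"count", "length", "rigidity", "rigid"}
_DOMAIN_KEYS = {"kind", "radius", "side"}
_CONNECTOR_KEYS = {
    "subunits", "count", "v0", "stall_force", "k_on", "k_off",
    "capture_range", "end_range", "stiffness", "backbone_length",
}
_TURNOVER_KEYS = {"enabled", "rate"}
_SIM_KEYS = {
    "dt", "kT", "drag", "drag_connector", "segment_length", "seed",
    "t_end", "sample_interval",
}
_TOP_KEYS = {"schema", "name", "filaments", "domain", "connectors", "turnover", "simulation"}


class ConfigError(ValueError):
    pass


def _check_keys(section: str, data: dict, allowed: set) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' in section '{section}'")


def load_config(path: str | Path) -> Scenario:
    """Load and validate a scenario file; returns a fully resolved Scenario."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("(top level)", data, _TOP_KEYS)
    version = data.get("schema", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {version!r}")

    fil_raw = data.get("filaments", {})
    _check_keys("filaments", fil_raw, _FILAMENT_KEYS)
    try:
        filaments = FilamentSpec(**fil_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"filaments: {exc}") from exc

    dom_raw = dict(data.get("domain", {"kind": "disc", "radius": 15.0}))
    _check_keys("domain", dom_raw, _DOMAIN_KEYS)
    try:
        domain = Domain(**dom_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"domain: {exc}") from exc

    connectors = []
    for cname, craw in (data.get("connectors", {}) or {}).items():
        _check_keys(f"connectors.{cname}", craw, _CONNECTOR_KEYS)
        craw = dict(craw)
        try:
            subunits = tuple(SubunitKind(s) for s in craw.pop("subunits"))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"connectors.{cname}: bad or missing subunits ({exc})") from exc
        if len(subunits) != 2:
            raise ConfigError(f"connectors.{cname}: exactly two subunits required")
        try:
            connectors.append(ConnectorType(subunits=subunits, name=cname, **craw))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"connectors.{cname}: {exc}") from exc

    to_raw = data.get("turnover", {})
    _check_keys("turnover", to_raw, _TURNOVER_KEYS)
    try:
        turnover = TurnoverSpec(**to_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"turnover: {exc}") from exc

    sim_raw = dict(data.get("simulation", {}))
    _check_keys("simulation", sim_raw, _SIM_KEYS)
    if "seed" in sim_raw:
        sim_raw["rng_seed"] = sim_raw.pop("seed")
    try:
        params = SimParams(**sim_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc

    return Scenario(
        filaments=filaments,
        connectors=tuple(connectors),
        domain=domain,
        params=params,
        turnover=turnover,
        name=str(data.get("name", path.stem)),
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    """Resolved scenario (all defaults filled) as a YAML-serializable dict."""
    def clean(value):
        if isinstance(value, float) and math.isinf(value):
            return "inf"
        return value

    connectors = {}
    for ct in scenario.connectors:
        d = dataclasses.asdict(ct)
        name = d.pop("name")
        d["subunits"] = [s.value for s in ct.subunits]
        connectors[name] = {k: clean(v) for k, v in d.items()}
    params = dataclasses.asdict(scenario.params)
    params["seed"] = params.pop("rng_seed")
    # internal numerics knobs are echoed but not part of the public schema
    for key in ("projection_iterations", "projection_tol", "neighbor_stride", "neighbor_margin"):
        params.pop(key, None)
    return {
        "schema": SCHEMA_VERSION,
        "name": scenario.name,
        "filaments": {k: clean(v) for k, v in dataclasses.asdict(scenario.filaments).items()},
        "domain": {k: v for k, v in dataclasses.asdict(scenario.domain).items() if v},
        "connectors": connectors,
        "turnover": dataclasses.asdict(scenario.turnover),
        "simulation": params,
    }


def write_outputs(
    trajectory: Trajectory,
    summary: TrajectorySummary,
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Write frames CSV, summary JSON, resolved config echo, and a run log.

    Refuses a non-empty existing directory unless ``force`` is set.
    Re-reading the frames with :func:`read_frames` and re-fitting reproduces
    the summary's contraction rate bit-exactly.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True / --force)")
    out.mkdir(parents=True, exist_ok=True)

    paths = {
        "frames": out / "frames.csv",
        "summary": out / "summary.json",
        "config": out / "scenario.yaml",
        "log": out / "run.log",
    }
    with open(paths["frames"], "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "time", "object_type", "object_id", "point_index", "x", "y"])
        for fi, (t, frame) in enumerate(zip(trajectory.times, trajectory.frames)):
            for oid in range(frame.shape[0]):
                for pi in range(frame.shape[1]):
                    wr.writerow(
                        [fi, repr(float(t)), "filament", oid, pi,
                         repr(float(frame[oid, pi, 0])), repr(float(frame[oid, pi, 1]))]
                    )
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(trajectory.scenario), fh, sort_keys=False)
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write(
            f"scenario: {trajectory.scenario.name}\n"
            f"seed: {trajectory.scenario.params.rng_seed}\n"
            f"frames: {trajectory.n_frames}\n"
            f"events: {trajectory.events}\n"
        )
    return paths


def read_frames(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a frames CSV back into (times, frames) arrays."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    times = df.groupby("frame")["time"].first().to_numpy()
    n_frames = df["frame"].nunique()
    n_obj = df["object_id"].nunique()
    n_pts = df["point_index"].nunique()
    xy = df[["x", "y"]].to_numpy().reshape(n_frames, n_obj, n_pts, 2)
    return times, xy
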