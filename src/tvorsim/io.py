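"""Trial, trajectory and manifest file formats.

No standard bioinformatics container fits oculomotor time series, so trials
are stored as delimited text with a JSON sidecar:

* ``<trial>.tsv`` — one row per eye sample with columns
  ``t  chair_x  chair_v  chair_a  eye_pos  eye_vel  mask`` (chair signals
  interpolated onto the 1 kHz eye grid; mask is 0/1);
* ``<trial>.tsv.json`` — schema version, condition metadata and, for
  synthetic trials, the generating ground truth.

Floats are printed with 17 significant digits so write -> read round-trips
are bit-identical. A session manifest is a JSON index of trial files with
their metadata and the session seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .chair_kinematics import ChairTrajectory, StimulusProtocol
from .dynamic_model import ModelParameters
from .exceptions import ParseError
from .synthetic_data import EyeTrace, Trial

SCHEMA_VERSION = 1

TRIAL_COLUMNS = ("t", "chair_x", "chair_v", "chair_a", "eye_pos", "eye_vel", "mask")

META_VOCABULARY = {
    "direction": {"left", "right"},
    "target": {"on", "off"},
    "epoch": {"pre", "post"},
    "eye": {"L", "R"},
}


def _validate_meta(meta: dict, where: str):
    for key, allowed in META_VOCABULARY.items():
        if key in meta and meta[key] is not None and meta[key] not in allowed:
            raise ParseError(
                f"{where}: metadata field {key!r} has value {meta[key]!r}, "
                f"allowed values are {sorted(allowed)}"
            )


def write_trial(trial: Trial, path) -> Path:
    """Write a trial to ``path`` (TSV) with its JSON sidecar."""
    path = Path(path)
    te = trial.eye.time
    data = np.column_stack(
        [
            te,
            np.interp(te, trial.chair.time, trial.chair.position),
            np.interp(te, trial.chair.time, trial.chair.velocity),
            np.interp(te, trial.chair.time, trial.chair.acceleration),
            trial.eye.position,
            trial.eye.velocity,
            trial.eye.mask.astype(float),
        ]
    )
    header = f"tvor-trial schema={SCHEMA_VERSION}\n" + "\t".join(TRIAL_COLUMNS)
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "meta": trial.meta,
        "ground_truth": trial.ground_truth,
    }
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=1, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trial(path) -> Trial:
    """Read a trial written by :func:`write_trial`.

    The chair trajectory is returned on the eye grid (as stored).
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="\t")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse trial table: {exc}") from None
    if data.ndim != 2 or data.shape[1] != len(TRIAL_COLUMNS):
        raise ParseError(
            f"{path}: expected {len(TRIAL_COLUMNS)} columns {TRIAL_COLUMNS}, "
            f"got shape {data.shape}"
        )
    sidecar_path = Path(f"{path}.json")
    if not sidecar_path.exists():
        raise ParseError(f"{path}: missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    meta = sidecar.get("meta", {})
    _validate_meta(meta, str(sidecar_path))

    t = data[:, 0]
    chair = ChairTrajectory(t, data[:, 1], data[:, 2], data[:, 3])
    eye = EyeTrace(t, data[:, 4], data[:, 5], data[:, 6] > 0.5)
    return Trial(chair, eye, meta=meta, ground_truth=sidecar.get("ground_truth"))


def write_session(trials: list[Trial], directory, seed: int | None = None) -> Path:
    """Write all trials plus a manifest.json into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, trial in enumerate(trials):
        name = f"trial_{i:04d}.tsv"
        write_trial(trial, directory / name)
        records.append({"path": name, "meta": trial.meta})
    manifest = {"schema_version": SCHEMA_VERSION, "seed": seed, "trials": records}
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=_jsonify))
    return manifest_path


def read_session(manifest_path) -> list[Trial]:
    """Read every trial referenced by a session manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    trials = []
    for rec in manifest.get("trials", []):
        trial_path = manifest_path.parent / rec["path"]
        if not trial_path.exists():
            raise ParseError(f"{manifest_path}: referenced trial {rec['path']} does not exist")
        trials.append(read_trial(trial_path))
    return trials


def write_trajectory(traj: ChairTrajectory, path) -> Path:
    """Write a chair trajectory (columns t, x, v, a) with a protocol sidecar."""
    path = Path(path)
    data = np.column_stack([traj.time, traj.position, traj.velocity, traj.acceleration])
    header = f"tvor-trajectory schema={SCHEMA_VERSION}\nt\tx\tv\ta"
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header)
    sidecar = {"schema_version": SCHEMA_VERSION}
    if traj.protocol is not None:
        sidecar["protocol"] = dataclasses.asdict(traj.protocol)
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trajectory(path) -> ChairTrajectory:
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter="\t")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse trajectory table: {exc}") from None
    if data.ndim != 2 or data.shape[1] != 4:
        raise ParseError(f"{path}: expected 4 columns (t, x, v, a), got shape {data.shape}")
    protocol = None
    sidecar_path = Path(f"{path}.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if "protocol" in sidecar:
            protocol = StimulusProtocol(**sidecar["protocol"])
    return ChairTrajectory(data[:, 0], data[:, 1], data[:, 2], data[:, 3], protocol=protocol)


def load_params(path) -> ModelParameters:
    """Load model parameters from a YAML/JSON mapping of field overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: parameter file must contain a mapping")
    valid = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(raw) - valid
    if unknown:
        raise ParseError(f"{path}: unknown parameter fields {sorted(unknown)}")
    if "plant_tcs" in raw and raw["plant_tcs"] is not None:
        raw["plant_tcs"] = tuple(raw["plant_tcs"])
    return ModelParameters(**raw)


def dump_params(params: ModelParameters, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(params)))
    return path
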