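"""Plain-text serialization of epoch sets and evoked tables.

An epoch dataset is stored as two files in a directory:

``epochs.tsv``
    one row per (trial, electrode) with columns
    ``trial  electrode_id  condition  phase  rejected  s0 .. sN``
    (amplitudes in microvolts, full float64 precision);
``epochs.json``
    sidecar with sampling rate, time axis, task label and electrode
    metadata.

The reader validates structure and raises :class:`EpochFileError` naming
the offending field or row rather than propagating a pandas traceback.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ElectrodeMeta, EpochSet, EvokedTable, Hemisphere, Region

__all__ = ["EpochFileError", "write_epochs", "read_epochs", "write_evoked", "read_evoked"]

_FLOAT_FMT = "%.17g"


class EpochFileError(ValueError):
    """Malformed epoch/evoked file."""


def _sample_columns(n: int) -> list[str]:
    return [f"s{i}" for i in range(n)]


def write_epochs(epochs: EpochSet, meta: list[ElectrodeMeta], path: str | Path) -> Path:
    """Write ``epochs.tsv`` + ``epochs.json`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_trials, n_elec, n_samples = epochs.data.shape
    rows = epochs.data.reshape(n_trials * n_elec, n_samples)
    frame = pd.DataFrame(rows, columns=_sample_columns(n_samples))
    frame.insert(0, "trial", np.repeat(np.arange(n_trials), n_elec))
    frame.insert(1, "electrode_id", np.tile(np.asarray(epochs.electrode_ids, dtype=object), n_trials))
    frame.insert(2, "condition", np.repeat(epochs.condition, n_elec))
    col = 3
    if epochs.phase is not None:
        frame.insert(col, "phase", np.repeat(epochs.phase, n_elec))
        col += 1
    frame.insert(col, "rejected", np.repeat(epochs.rejected.astype(int), n_elec))
    frame.to_csv(path / "epochs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    sidecar = {
        "fs": epochs.fs,
        "times_ms": [float(t) for t in epochs.times],
        "task": epochs.task,
        "electrodes": [
            {
                "electrode_id": m.electrode_id,
                "region": m.region.value,
                "hemisphere": m.hemisphere.value,
                "patient": m.patient,
            }
            for m in meta
        ],
    }
    (path / "epochs.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _parse_meta(entries: list[dict]) -> list[ElectrodeMeta]:
    meta = []
    for i, entry in enumerate(entries):
        for key in ("electrode_id", "region", "hemisphere"):
            if key not in entry:
                raise EpochFileError(f"electrode entry {i}: missing field {key!r}")
        try:
            region = Region(entry["region"])
        except ValueError:
            raise EpochFileError(
                f"electrode entry {i}: unknown region label {entry['region']!r}"
            ) from None
        try:
            hemi = Hemisphere(entry["hemisphere"])
        except ValueError:
            raise EpochFileError(
                f"electrode entry {i}: unknown hemisphere {entry['hemisphere']!r}"
            ) from None
        meta.append(
            ElectrodeMeta(
                electrode_id=str(entry["electrode_id"]),
                region=region,
                hemisphere=hemi,
                patient=str(entry.get("patient", "sim")),
            )
        )
    return meta


def read_epochs(path: str | Path) -> tuple[EpochSet, list[ElectrodeMeta]]:
    """Inverse of :func:`write_epochs`; raises :class:`EpochFileError` on
    unknown labels, missing fields or truncated rows."""
    path = Path(path)
    tsv, sidecar_file = path / "epochs.tsv", path / "epochs.json"
    for f in (tsv, sidecar_file):
        if not f.exists():
            raise EpochFileError(f"missing file {f}")
    try:
        sidecar = json.loads(sidecar_file.read_text())
    except json.JSONDecodeError as exc:
        raise EpochFileError(f"sidecar is not valid JSON: {exc}") from None
    for key in ("fs", "times_ms", "task", "electrodes"):
        if key not in sidecar:
            raise EpochFileError(f"sidecar: missing field {key!r}")
    meta = _parse_meta(sidecar["electrodes"])
    times = np.asarray(sidecar["times_ms"], dtype=float)
    n_samples = len(times)
    sample_cols = _sample_columns(n_samples)

    try:
        frame = pd.read_csv(
            tsv,
            sep="\t",
            dtype={"electrode_id": str, "condition": str, "phase": str},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise EpochFileError(f"epochs.tsv: malformed table: {exc}") from None
    missing = [c for c in ["trial", "electrode_id", "condition", "rejected", *sample_cols] if c not in frame.columns]
    if missing:
        raise EpochFileError(f"epochs.tsv: missing columns {missing}")
    samples = frame[sample_cols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(samples).all(axis=1))
    if bad.size:
        raise EpochFileError(f"epochs.tsv: truncated or non-numeric sample row at index {int(bad[0])}")

    electrode_ids = [m.electrode_id for m in meta]
    n_elec = len(electrode_ids)
    trials = frame["trial"].to_numpy()
    n_trials = int(trials.max()) + 1 if len(trials) else 0
    if len(frame) != n_trials * n_elec:
        raise EpochFileError(
            f"epochs.tsv: expected {n_trials * n_elec} rows "
            f"({n_trials} trials x {n_elec} electrodes), found {len(frame)}"
        )
    elec_index = {eid: k for k, eid in enumerate(electrode_ids)}
    unknown = set(frame["electrode_id"]) - set(elec_index)
    if unknown:
        raise EpochFileError(f"epochs.tsv: electrode ids not in sidecar: {sorted(unknown)}")

    data = np.empty((n_trials, n_elec, n_samples))
    condition = np.empty(n_trials, dtype=object)
    phase = np.empty(n_trials, dtype=object)
    rejected = np.zeros(n_trials, dtype=bool)
    has_phase = "phase" in frame.columns
    e_idx = frame["electrode_id"].map(elec_index).to_numpy()
    data[trials, e_idx, :] = samples
    for row, (t, cond, rej) in enumerate(zip(trials, frame["condition"], frame["rejected"])):
        condition[t] = cond
        rejected[t] = bool(rej)
        phase[t] = str(frame["phase"].iloc[row]) if has_phase else ""

    epochs = EpochSet(
        data=data,
        times=times,
        fs=float(sidecar["fs"]),
        condition=condition,
        rejected=rejected,
        electrode_ids=electrode_ids,
        task=str(sidecar["task"]),
        phase=phase if has_phase else None,
    )
    return epochs, meta


def write_evoked(evoked: EvokedTable, meta: list[ElectrodeMeta], path: str | Path) -> Path:
    """Write ``evoked.tsv`` + ``evoked.json`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_elec, n_cond, n_samples = evoked.data.shape
    rows = evoked.data.reshape(n_elec * n_cond, n_samples)
    frame = pd.DataFrame(rows, columns=_sample_columns(n_samples))
    frame.insert(0, "electrode_id", np.repeat(np.asarray(evoked.electrode_ids, dtype=object), n_cond))
    frame.insert(1, "condition", np.tile(np.asarray(evoked.conditions, dtype=object), n_elec))
    frame.insert(2, "n_trials", evoked.n_trials.reshape(-1))
    frame.to_csv(path / "evoked.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "fs": evoked.fs,
        "times_ms": [float(t) for t in evoked.times],
        "task": evoked.task,
        "electrodes": [
            {
                "electrode_id": m.electrode_id,
                "region": m.region.value,
                "hemisphere": m.hemisphere.value,
                "patient": m.patient,
            }
            for m in meta
        ],
    }
    (path / "evoked.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_evoked(path: str | Path) -> tuple[EvokedTable, list[ElectrodeMeta]]:
    path = Path(path)
    tsv, sidecar_file = path / "evoked.tsv", path / "evoked.json"
    for f in (tsv, sidecar_file):
        if not f.exists():
            raise EpochFileError(f"missing file {f}")
    sidecar = json.loads(sidecar_file.read_text())
    meta = _parse_meta(sidecar["electrodes"])
    times = np.asarray(sidecar["times_ms"], dtype=float)
    sample_cols = _sample_columns(len(times))
    frame = pd.read_csv(
        tsv,
        sep="\t",
        dtype={"electrode_id": str, "condition": str},
        float_precision="round_trip",
    )
    missing = [c for c in ["electrode_id", "condition", "n_trials", *sample_cols] if c not in frame.columns]
    if missing:
        raise EpochFileError(f"evoked.tsv: missing columns {missing}")
    electrode_ids = [m.electrode_id for m in meta]
    conditions = list(dict.fromkeys(frame["condition"]))
    n_elec, n_cond = len(electrode_ids), len(conditions)
    if len(frame) != n_elec * n_cond:
        raise EpochFileError("evoked.tsv: row count does not match electrodes x conditions")
    data = np.empty((n_elec, n_cond, len(times)))
    n_trials = np.zeros((n_elec, n_cond), dtype=int)
    e_map = {eid: k for k, eid in enumerate(electrode_ids)}
    c_map = {c: k for k, c in enumerate(conditions)}
    for _, row in frame.iterrows():
        e, c = e_map[row["electrode_id"]], c_map[row["condition"]]
        data[e, c] = row[sample_cols].to_numpy(dtype=float)
        n_trials[e, c] = int(row["n_trials"])
    evoked = EvokedTable(
        data=data,
        times=times,
        fs=float(sidecar["fs"]),
        electrode_ids=electrode_ids,
        conditions=conditions,
        n_trials=n_trials,
        task=str(sidecar["task"]),
    )
    return evoked, meta
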