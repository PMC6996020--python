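"""On-disk session bundles.

A session directory holds plain-text files plus a YAML manifest:

* ``lfp.csv`` — ``time_s, hpc_uv, mpfc_uv`` at the LFP rate, voltages
  quantized to 0.1 µV (the declared precision of the round trip);
* ``events.csv`` — ``trial_id, run, door_raise_s, decision_cross_s, arm``;
* ``tracking.csv`` — ``time_s, speed_cm_s`` at the tracking rate;
* ``manifest.yaml`` — animal/group metadata, sampling rates, channel
  map, file names, and (for synthetic sessions) the generative truth.

All times are seconds from recording start (one clock origin per
session); intervals are half-open ``[start, end)``.  A missing tracking
file is reported as a flag on the loaded bundle, not an error, because
behavioural-only analyses remain possible without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SessionBundle

__all__ = ["SessionValidationError", "write_session", "read_session",
           "write_cohort", "read_cohort", "LFP_QUANTUM_UV"]

LFP_QUANTUM_UV = 0.1
MANIFEST_NAME = "manifest.yaml"


class SessionValidationError(ValueError):
    pass


def write_session(bundle: SessionBundle, directory) -> Path:
    """Write one session bundle; returns the manifest path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    n = len(bundle.lfp["hpc"])
    t = np.arange(n) / bundle.fs_lfp
    lfp_df = pd.DataFrame({"time_s": t})
    for ch, x in bundle.lfp.items():
        lfp_df[f"{ch}_uv"] = np.round(np.asarray(x) / LFP_QUANTUM_UV) * LFP_QUANTUM_UV
    lfp_df.to_csv(d / "lfp.csv", index=False,
                  float_format="%.6f")
    bundle.events.to_csv(d / "events.csv", index=False)
    files = {"lfp": "lfp.csv", "events": "events.csv"}
    if bundle.tracking is not None:
        bundle.tracking.to_csv(d / "tracking.csv", index=False,
                               float_format="%.4f")
        files["tracking"] = "tracking.csv"

    manifest = {
        "animal_id": bundle.animal_id,
        "group": bundle.group,
        "fs_lfp": float(bundle.fs_lfp),
        "fs_track": float(bundle.fs_track),
        "channel_map": {ch: ch for ch in bundle.lfp},
        "units": "uV",
        "lfp_quantum_uv": LFP_QUANTUM_UV,
        "files": files,
        "truth": _plain(bundle.truth),
    }
    path = d / MANIFEST_NAME
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def _plain(obj):
    """YAML-safe copy (numpy scalars to python scalars)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_session(manifest_path) -> SessionBundle:
    """Load and validate a session bundle from its manifest."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    with open(manifest_path) as fh:
        m = yaml.safe_load(fh)
    d = manifest_path.parent

    lfp_path = d / m["files"]["lfp"]
    if not lfp_path.exists():
        raise SessionValidationError(f"missing LFP file {lfp_path}")
    lfp_df = pd.read_csv(lfp_path)
    channels = [c[:-3] for c in lfp_df.columns if c.endswith("_uv")]
    if len(set(channels)) != len(channels) or not channels:
        raise SessionValidationError(f"bad channel columns in {lfp_path}")
    lfp = {ch: lfp_df[f"{ch}_uv"].to_numpy(float) for ch in channels}

    events = pd.read_csv(d / m["files"]["events"])
    truth = dict(m.get("truth") or {})

    tracking = None
    flags = []
    tr_name = m["files"].get("tracking")
    if tr_name and (d / tr_name).exists():
        tracking = pd.read_csv(d / tr_name)
    else:
        flags.append("tracking-unavailable")
    truth["io_flags"] = flags

    bundle = SessionBundle(
        animal_id=str(m["animal_id"]), group=str(m.get("group", "")),
        lfp=lfp, fs_lfp=float(m["fs_lfp"]), events=events,
        tracking=tracking, fs_track=float(m["fs_track"]), truth=truth)
    try:
        bundle.validate()
    except ValueError as e:
        raise SessionValidationError(str(e)) from e
    if tracking is not None:
        tmax = tracking["time_s"].to_numpy()
        if len(tmax) and not np.all(np.diff(tmax) > 0):
            raise SessionValidationError("tracking time not strictly increasing")
        if len(tmax) and tmax[-1] > bundle.duration_s + 1.0:
            flags.append("tracking-extends-beyond-lfp")
    return bundle


def write_cohort(bundles, directory) -> Path:
    """Write a list of bundles into per-animal subdirectories + index."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bundles:
        write_session(b, d / b.animal_id)
        rows.append({"animal_id": b.animal_id, "group": b.group,
                     "path": b.animal_id})
    index = pd.DataFrame(rows)
    index.to_csv(d / "index.csv", index=False)
    return d / "index.csv"


def read_cohort(directory) -> list:
    d = Path(directory)
    index = pd.read_csv(d / "index.csv")
    return [read_session(d / row["path"]) for _, row in index.iterrows()]
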