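"""Standard-format I/O: the internal HDF5 recording container, NIfTI export
of volumetric maps, ground-truth / marker / report JSON and CSV, and
YAML scenario files.

HDF5 layout::

    /data                 channels x samples, float64
    /fs                   scalar
    /channels/id          string array
    /channels/position    (n, 3) metres
    /channels/orientation (n, 3) unit vectors
    /history              JSON-encoded list of processing steps
    /run_id               string

Import from vendor MEG container formats is delegated to MNE-Python when it
is importable; otherwise a descriptive error is raised.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import (
    ConductorModel,
    EventSpec,
    GroundTruth,
    PropagationSpec,
    Recording,
    Scenario,
    SensorArray,
)
from .exceptions import IedmapError, ParameterError

__all__ = [
    "save_recording",
    "load_recording",
    "save_ground_truth",
    "load_ground_truth",
    "save_map_nifti",
    "save_markers",
    "scenario_from_yaml",
    "scenario_to_yaml",
]


def save_recording(rec: Recording, path: "str | Path") -> None:
    if rec.sensors is None:
        raise ParameterError("recording has no sensor geometry to store")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f["fs"] = float(rec.fs)
        g = f.create_group("channels")
        g.create_dataset("id", data=np.array(rec.sensors.channel_ids, dtype="S"))
        g.create_dataset("position", data=rec.sensors.positions)
        g.create_dataset("orientation", data=rec.sensors.orientations)
        f["history"] = json.dumps(rec.history)
        f["run_id"] = rec.run_id


def load_recording(path: "str | Path", fmt: str = "internal_hdf5") -> Recording:
    """Load a recording; ``fmt`` is ``internal_hdf5`` or ``standard_meg_container``."""
    if fmt == "standard_meg_container":
        return _load_via_mne(path)
    if fmt != "internal_hdf5":
        raise ParameterError(f"unknown recording format {fmt!r}")
    try:
        with h5py.File(path, "r") as f:
            for key in ("data", "fs", "channels"):
                if key not in f:
                    raise IedmapError(f"container missing required field '{key}'")
            ch = f["channels"]
            for key in ("id", "position", "orientation"):
                if key not in ch:
                    raise IedmapError(f"container missing required field 'channels/{key}'")
            sensors = SensorArray(
                channel_ids=[s.decode() for s in ch["id"][()]],
                positions=ch["position"][()],
                orientations=ch["orientation"][()],
            )
            return Recording(
                data=f["data"][()],
                fs=float(f["fs"][()]),
                sensors=sensors,
                run_id=f["run_id"][()].decode() if "run_id" in f else "run",
                history=json.loads(f["history"][()]) if "history" in f else [],
            )
    except OSError as exc:
        raise IedmapError(f"cannot read container {path}: {exc}") from exc


def _load_via_mne(path: "str | Path") -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise IedmapError("standard MEG container import requires MNE-Python") from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, meg=True)
    if len(picks) == 0:
        raise IedmapError("no MEG channels found in container")
    ids, pos, ori = [], [], []
    for p in picks:
        ch = raw.info["chs"][p]
        ids.append(ch["ch_name"])
        loc = ch["loc"]
        pos.append(loc[:3])
        n = loc[9:12]
        norm = np.linalg.norm(n)
        if norm == 0:
            raise IedmapError(f"channel {ch['ch_name']} is missing an orientation")
        ori.append(n / norm)
    sensors = SensorArray(channel_ids=ids, positions=np.array(pos), orientations=np.array(ori))
    return Recording(data=raw.get_data(picks=picks), fs=float(raw.info["sfreq"]),
                     sensors=sensors, run_id=Path(path).stem)


def save_ground_truth(gt: GroundTruth, path: "str | Path") -> None:
    payload = {
        "source_positions_m": gt.source_positions.tolist(),
        "event_intervals_s": [[[float(a), float(b)] for a, b in iv] for iv in gt.event_intervals],
        "event_peaks_s": [[float(t) for t in pk] for pk in gt.event_peaks],
        "propagation_links": [[list(a), list(b)] for a, b in gt.propagation_links],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: "str | Path") -> GroundTruth:
    raw = json.loads(Path(path).read_text())
    return GroundTruth(
        source_positions=np.asarray(raw["source_positions_m"]),
        event_intervals=[[tuple(p) for p in iv] for iv in raw["event_intervals_s"]],
        event_peaks=raw["event_peaks_s"],
        propagation_links=[(tuple(a), tuple(b)) for a, b in raw["propagation_links"]],
    )


def save_map_nifti(vmap, path: "str | Path", background: float = 0.0) -> None:
    """Write a volumetric map as a NIfTI volume.

    The affine maps voxel indices to positions in mm; voxels outside the
    mask get ``background`` (pass ``np.nan`` for a NaN background).
    """
    import nibabel as nib

    pos_mm = vmap.positions * 1000.0
    s = vmap.grid.spacing_mm
    origin = pos_mm.min(axis=0)
    ijk = np.round((pos_mm - origin) / s).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, background, dtype=np.float32)
    vals = np.where(vmap.valid, vmap.values, background)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = vals.astype(np.float32)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = s
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def save_markers(markers, path_csv: "str | Path") -> None:
    """Markers as CSV: peak position (mm) and marker time (s) per row."""
    p = markers.peak_position * 1000.0
    lines = ["x_mm,y_mm,z_mm,time_s"]
    for t in markers.times:
        lines.append(f"{p[0]:.3f},{p[1]:.3f},{p[2]:.3f},{t:.6f}")
    Path(path_csv).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# scenario YAML
# ---------------------------------------------------------------------------


def scenario_from_yaml(path: "str | Path") -> tuple[Scenario, ConductorModel, int]:
    """Load a scenario file.

    Schema (keys in any order)::

        duration: 120.0         # s
        fs: 1200.0              # Hz
        seed: 1
        n_channels: 64
        conductor: {center: [0, 0, 0], radius: 0.09}
        background: {rms_t: 1.2e-13, alpha_fraction: 0.35, sensor_noise_rms_t: 2.5e-14}
        sources:
          - position: [0.02, 0.035, 0.055]
            kind: spike_wave
            rate: 0.2
            duration: 0.8
            amplitude_nam: 40.0
            waveform_policy: fixed_template
        propagation: {from: 0, to: 1, lag: 0.42, probability: 1.0}  # optional

    Returns (scenario, conductor, n_channels).
    """
    raw = yaml.safe_load(Path(path).read_text())
    cond_raw = raw.get("conductor", {})
    conductor = ConductorModel(
        center=np.asarray(cond_raw.get("center", [0.0, 0.0, 0.0])),
        radius=float(cond_raw.get("radius", 0.09)),
    )
    sources = []
    for s in raw.get("sources", []):
        spec = EventSpec(
            kind=s["kind"],
            rate=float(s.get("rate", 0.2)),
            duration=float(s.get("duration", 0.5)),
            amplitude=float(s.get("amplitude_nam", 40.0)),
            jitter=float(s.get("jitter", 0.0)),
            waveform_policy=s.get(
                "waveform_policy",
                "resample_each_event" if s["kind"] == "polymorphic_burst" else "fixed_template",
            ),
        )
        sources.append((np.asarray(s["position"], dtype=float), spec))
    prop = None
    if "propagation" in raw and raw["propagation"]:
        p = raw["propagation"]
        prop = PropagationSpec(
            from_idx=int(p["from"]), to_idx=int(p["to"]),
            lag=float(p["lag"]), probability=float(p.get("probability", 1.0)),
        )
    bg = raw.get("background", {})
    scenario = Scenario(
        sources=sources,
        duration=float(raw.get("duration", 120.0)),
        fs=float(raw.get("fs", 1200.0)),
        seed=int(raw.get("seed", 0)),
        propagation=prop,
        background_rms=float(bg.get("rms_t", 1.2e-13)),
        alpha_fraction=float(bg.get("alpha_fraction", 0.35)),
        sensor_noise_rms=float(bg.get("sensor_noise_rms_t", 2.5e-14)),
    )
    return scenario, conductor, int(raw.get("n_channels", 64))


def scenario_to_yaml(scenario: Scenario, conductor: ConductorModel, n_channels: int,
                     path: "str | Path") -> None:
    doc = {
        "duration": scenario.duration,
        "fs": scenario.fs,
        "seed": scenario.seed,
        "n_channels": n_channels,
        "conductor": {"center": conductor.center.tolist(), "radius": conductor.radius},
        "background": {
            "rms_t": scenario.background_rms,
            "alpha_fraction": scenario.alpha_fraction,
            "sensor_noise_rms_t": scenario.sensor_noise_rms,
        },
        "sources": [
            {
                "position": pos.tolist(),
                "kind": spec.kind,
                "rate": spec.rate,
                "duration": spec.duration,
                "amplitude_nam": spec.amplitude,
                "jitter": spec.jitter,
                "waveform_policy": spec.waveform_policy,
            }
            for pos, spec in scenario.sources
        ],
    }
    if scenario.propagation is not None:
        p = scenario.propagation
        doc["propagation"] = {"from": p.from_idx, "to": p.to_idx, "lag": p.lag,
                              "probability": p.probability}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
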